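"""Two-part association between a zero-inflated OTU table and a phenotype.

Zero-inflated OTU abundances violate the distributional assumptions of a
single linear model, so each OTU is tested in two parts:

* a **binary** part — does detection of the OTU (count > 0) associate with
  the phenotype?  Implemented as OLS of the residual phenotype on the 0/1
  presence indicator, equivalent to a pooled-variance two-sample t-test.
* a **quantitative** part — among the samples where the OTU is present,
  does its abundance associate with the phenotype?  The abundance is
  transformed as the z-score of the natural-log relative abundance among
  present samples, and the phenotype regressed on it.

Both parts yield a signed z-score (normal quantile of the two-sided t
p-value, carrying the effect's sign).  A **meta** statistic combines them by
Stouffer's weighted-Z with weights sqrt(n_total) and sqrt(n_present).  The
final per-OTU p-value is the minimum of the available part p-values.  That
minimum is anticonservative under the null, so it is calibrated by
permuting the phenotype (one shared permutation per iteration across all
OTUs) and computing an empirical p-value with the +1 correction, never zero.
Benjamini-Hochberg FDR is then applied to the permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import relative_abundance
from .tables import CountTable, RelAbundanceTable, ResidualPhenotype

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # keeps p in (0, 1] when a fit is exact

__all__ = [
    "TwoPartConfig",
    "binary_test",
    "quantitative_test",
    "meta_combine",
    "two_part_single",
    "permutation_correct",
    "bh_fdr",
    "run_two_part",
    "prepare_two_part",
    "two_part_stats",
]


@dataclass
class TwoPartConfig:
    """Settings for the two-part association scan.

    min_present
        Minimum number of detected samples for the quantitative part; below
        it that part is skipped for the OTU.
    n_perm
        Number of phenotype permutations for the empirical p-value.
    fdr_alpha
        Benjamini-Hochberg significance threshold on the permutation p.
    seed
        Seed for the permutation stream.
    """

    min_present: int = 5
    n_perm: int = 1000
    fdr_alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.min_present < 3:
            raise ValueError("min_present must be >= 3 (regression needs df > 0)")


class PreparedTwoPart(NamedTuple):
    """Phenotype-independent per-OTU structures reused across permutations."""

    presence: np.ndarray      # float (m, n): 0/1 detection
    q: np.ndarray             # float (m, n): z-scored ln rel abundance, 0 where absent
    n_present: np.ndarray     # int (m,)
    valid_binary: np.ndarray  # bool (m,): >= 2 samples in each detection state
    valid_quant: np.ndarray   # bool (m,): n_present >= min_present, nonzero spread
    log_mean: np.ndarray      # float (m,): mean ln rel abundance among present
    log_sd: np.ndarray        # float (m,): sd (ddof=1) of ln rel abundance among present


class TwoPartStats(NamedTuple):
    beta1: np.ndarray
    z_b: np.ndarray
    p_b: np.ndarray
    beta2: np.ndarray
    z_q: np.ndarray
    p_q: np.ndarray
    z_meta: np.ndarray
    p_meta: np.ndarray
    p_final: np.ndarray
    z_report: np.ndarray


def prepare_two_part(rel_values: np.ndarray, presence: np.ndarray | None = None,
                     min_present: int = 5) -> PreparedTwoPart:
    """Precompute presence and the transformed abundance matrix.

    ``rel_values`` is the OTU x sample relative-abundance matrix;
    ``presence`` defaults to ``rel_values > 0``.  The quantitative feature is
    the natural log of the relative abundance, z-scored (ddof=1) across the
    present samples of each OTU, and exactly 0 where the OTU is absent.
    """
    rel = np.asarray(rel_values, dtype=float)
    pres = rel > 0 if presence is None else np.asarray(presence, dtype=bool)
    m, n = rel.shape
    n_present = pres.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(pres, np.log(np.where(pres, rel, 1.0)), 0.0)
    np_safe = np.maximum(n_present, 1)
    log_mean = logs.sum(axis=1) / np_safe
    centered = np.where(pres, logs - log_mean[:, None], 0.0)
    ss = (centered ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_sd = np.sqrt(ss / np.maximum(n_present - 1, 1))
    has_spread = (n_present >= 2) & (log_sd > 0)
    sd_safe = np.where(has_spread, log_sd, 1.0)
    q = np.where(pres, centered / sd_safe[:, None], 0.0)
    valid_binary = (n_present >= 2) & (n_present <= n - 2)
    valid_quant = (n_present >= min_present) & has_spread
    return PreparedTwoPart(pres.astype(float), q, n_present.astype(np.int64),
                           valid_binary, valid_quant, log_mean, log_sd)


def _signed_z(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    return np.sign(t) * sps.norm.isf(np.clip(p, _P_FLOOR, 1.0) / 2.0)


def two_part_stats(y: np.ndarray, prep: PreparedTwoPart) -> TwoPartStats:
    """Vectorized binary / quantitative / meta statistics for one phenotype.

    All arrays are per-OTU; entries of invalid parts are NaN.  The final
    p-value is the minimum over the valid parts and ``z_report`` is the
    signed z of the part attaining it.
    """
    y = np.asarray(y, dtype=float)
    P, Q = prep.presence, prep.q
    n = y.size
    n_present = prep.n_present
    m = P.shape[0]
    nan = np.full(m, np.nan)

    ybar = y.mean()
    syy = float(((y - ybar) ** 2).sum())
    sum_y_present = P @ y
    sum_y2 = float((y * y).sum())
    # "no variance in y" (p = 1) is distinct from "exact fit" (p -> 0)
    y_flat = syy <= 1e-10 * max(sum_y2, 1e-300)

    # binary part: OLS of y on the 0/1 indicator
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = n_present * (n - n_present) / n
        sxy = sum_y_present - n_present * ybar
        beta1 = np.where(prep.valid_binary, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        beta1 = np.where(y_flat & prep.valid_binary, 0.0, beta1)
        sse_b = np.clip(syy - beta1 * sxy, 0.0, None)
        df_b = n - 2
        se_b = np.sqrt(sse_b / max(df_b, 1) / np.where(sxx > 0, sxx, 1.0))
        t_b = np.where(se_b > 0, beta1 / np.where(se_b > 0, se_b, 1.0),
                       np.where(beta1 == 0, 0.0, np.inf) * np.sign(beta1))
        t_b = np.where(y_flat, 0.0, t_b)
    p_b = np.where(prep.valid_binary,
                   np.clip(2.0 * sps.t.sf(np.abs(t_b), max(df_b, 1)), _P_FLOOR, 1.0), np.nan)
    z_b = np.where(prep.valid_binary, _signed_z(t_b, p_b), np.nan)
    beta1 = np.where(prep.valid_binary, beta1, np.nan)

    # quantitative part: among present samples, OLS of y on q (q is centered
    # within the present set, so Q @ y is already the centered cross-product)
    with np.errstate(divide="ignore", invalid="ignore"):
        np_safe = np.maximum(n_present, 1)
        ybar_j = sum_y_present / np_safe
        sqq = (Q * Q).sum(axis=1)
        sqy = Q @ y
        beta2 = np.where(prep.valid_quant, sqy / np.where(sqq > 0, sqq, 1.0), np.nan)
        sum_y2_present = P @ (y * y)
        syy_j = np.clip(sum_y2_present - n_present * ybar_j ** 2, 0.0, None)
        yj_flat = syy_j <= 1e-10 * np.maximum(sum_y2_present, 1e-300)
        beta2 = np.where(yj_flat & prep.valid_quant, 0.0, beta2)
        sse_q = np.clip(syy_j - beta2 * sqy, 0.0, None)
        df_q = np.maximum(n_present - 2, 1)
        se_q = np.sqrt(sse_q / df_q / np.where(sqq > 0, sqq, 1.0))
        t_q = np.where(se_q > 0, beta2 / np.where(se_q > 0, se_q, 1.0),
                       np.where(beta2 == 0, 0.0, np.inf) * np.sign(beta2))
        t_q = np.where(yj_flat, 0.0, t_q)
    p_q = np.where(prep.valid_quant,
                   np.clip(2.0 * sps.t.sf(np.abs(t_q), df_q), _P_FLOOR, 1.0), nan)
    z_q = np.where(prep.valid_quant, _signed_z(t_q, p_q), np.nan)
    beta2 = np.where(prep.valid_quant, beta2, np.nan)

    # meta part: Stouffer weighted-Z; falls back to the single valid part
    both = prep.valid_binary & prep.valid_quant
    either = prep.valid_binary | prep.valid_quant
    w_b, w_q = np.sqrt(float(n)), np.sqrt(n_present.astype(float))
    with np.errstate(invalid="ignore"):
        z_meta = np.where(
            both,
            (w_b * np.nan_to_num(z_b) + w_q * np.nan_to_num(z_q))
            / np.sqrt(n + n_present),
            np.where(prep.valid_binary, np.nan_to_num(z_b), np.nan_to_num(z_q)),
        )
    z_meta = np.where(either, z_meta, np.nan)
    p_meta = np.where(either,
                      np.clip(2.0 * sps.norm.sf(np.abs(z_meta)), _P_FLOOR, 1.0), nan)

    parts_p = np.stack([p_b, p_q, p_meta])          # (3, m)
    parts_z = np.stack([z_b, z_q, z_meta])
    with np.errstate(invalid="ignore"):
        all_nan = np.isnan(parts_p).all(axis=0)
        p_masked = np.where(np.isnan(parts_p), np.inf, parts_p)
        argmin = p_masked.argmin(axis=0)
        p_final = np.where(all_nan, np.nan, p_masked[argmin, np.arange(m)])
        z_report = np.where(all_nan, np.nan, parts_z[argmin, np.arange(m)])
    return TwoPartStats(beta1, z_b, p_b, beta2, z_q, p_q, z_meta, p_meta,
                        p_final, z_report)


def _stats_for_vectors(y, rel, presence, min_present):
    prep = prepare_two_part(np.atleast_2d(rel), None if presence is None
                            else np.atleast_2d(presence), min_present)
    return two_part_stats(np.asarray(y, dtype=float), prep)


def binary_test(y_resid: np.ndarray, presence: np.ndarray) -> tuple[float, float, float]:
    """Presence/absence part for a single OTU: (beta1, z_b, p_b).

    Returns NaNs when either detection state has fewer than 2 samples.
    """
    y = np.asarray(y_resid, dtype=float)
    pres = np.asarray(presence, dtype=bool)
    if y.shape != pres.shape:
        raise ValueError("y_resid and presence lengths differ")
    rel = np.where(pres, 0.5, 0.0)  # placeholder abundances; quant part unused
    st = _stats_for_vectors(y, rel, pres, min_present=max(3, y.size + 1))
    return float(st.beta1[0]), float(st.z_b[0]), float(st.p_b[0])


def quantitative_test(y_resid: np.ndarray, rel_abund: np.ndarray,
                      presence: np.ndarray | None = None,
                      min_present: int = 5) -> tuple[float, float, float]:
    """Among-present abundance part for a single OTU: (beta2, z_q, p_q)."""
    y = np.asarray(y_resid, dtype=float)
    rel = np.asarray(rel_abund, dtype=float)
    if y.shape != rel.shape:
        raise ValueError("y_resid and rel_abund lengths differ")
    st = _stats_for_vectors(y, rel, presence, min_present)
    return float(st.beta2[0]), float(st.z_q[0]), float(st.p_q[0])


def meta_combine(z_b: float, n_total: int, z_q: float,
                 n_present: int) -> tuple[float, float]:
    """Stouffer weighted-Z of the two parts: (z_meta, p_meta).

    Weights are sqrt(n_total) and sqrt(n_present); a NaN part defers to the
    other.  Both NaN returns (nan, nan).
    """
    b_ok, q_ok = np.isfinite(z_b), np.isfinite(z_q)
    if not b_ok and not q_ok:
        return float("nan"), float("nan")
    if b_ok and q_ok:
        z = (np.sqrt(n_total) * z_b + np.sqrt(n_present) * z_q) / np.sqrt(n_total + n_present)
    else:
        z = z_b if b_ok else z_q
    p = float(np.clip(2.0 * sps.norm.sf(abs(z)), _P_FLOOR, 1.0))
    return float(z), p


def two_part_single(y_resid: np.ndarray, rel_abund: np.ndarray,
                    presence: np.ndarray | None = None,
                    cfg: TwoPartConfig | None = None) -> dict:
    """Full per-OTU record (dict of the TwoPartStats fields) for one OTU."""
    cfg = cfg or TwoPartConfig()
    y = np.asarray(y_resid, dtype=float)
    st = _stats_for_vectors(y, rel_abund, presence, cfg.min_present)
    rec = {k: float(getattr(st, k)[0]) for k in TwoPartStats._fields}
    rec["n_present"] = int(np.count_nonzero(
        np.asarray(rel_abund) > 0 if presence is None else presence))
    return rec


def permutation_correct(y_resid: np.ndarray, prep: PreparedTwoPart,
                        p_final_obs: np.ndarray, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Empirical p-values for the min-p statistic under phenotype permutation.

    One shared permutation of the phenotype per iteration is applied across
    all OTUs, preserving between-OTU correlation.  Counting uses <= with the
    +1 numerator and denominator, so the smallest attainable value is
    ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y_resid, dtype=float)
    obs = np.asarray(p_final_obs, dtype=float)
    hits = np.zeros(obs.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm_stats = two_part_stats(rng.permutation(y), prep)
        with np.errstate(invalid="ignore"):
            hits += np.nan_to_num(perm_stats.p_final <= obs, nan=False).astype(np.int64)
    p_perm = (1.0 + hits) / (n_perm + 1.0)
    return np.where(np.isnan(obs), np.nan, p_perm)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_two_part(table: CountTable, y_resid: ResidualPhenotype | np.ndarray,
                 cfg: TwoPartConfig | None = None,
                 rel_table: RelAbundanceTable | None = None) -> pd.DataFrame:
    """Two-part scan of every OTU against the residual phenotype.

    Runs the per-OTU parts, calibrates the min-p by ``cfg.n_perm`` phenotype
    permutations, and applies BH-FDR to the permutation p-values.  Returns a
    DataFrame with one row per OTU that has at least one valid part, columns
    ``otu_id, n_present, beta1, z_b, p_b, beta2, z_q, p_q, z_meta, p_meta,
    p_final, z_report, p_perm, q_fdr, significant``.
    """
    cfg = cfg or TwoPartConfig()
    if isinstance(y_resid, ResidualPhenotype):
        if y_resid.sample_ids != table.sample_ids:
            raise ValueError("phenotype and table sample order differ; align first")
        y = y_resid.y_resid
    else:
        y = np.asarray(y_resid, dtype=float)
    if table.n_samples < 10:
        raise ValueError("two-part association needs at least 10 samples")
    if y.shape != (table.n_samples,):
        raise ValueError("phenotype length does not match the table")
    rel = rel_table if rel_table is not None else relative_abundance(table)
    if rel.otu_ids != table.otu_ids or rel.sample_ids != table.sample_ids:
        raise ValueError("relative-abundance table does not match the count table")

    prep = prepare_two_part(rel.values, table.presence(), cfg.min_present)
    obs = two_part_stats(y, prep)
    valid = ~np.isnan(obs.p_final)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("run_two_part: %d OTUs had no valid part (too few or too many "
                    "detections) and were excluded", n_dropped)

    rng = np.random.default_rng(cfg.seed)
    p_perm = permutation_correct(y, prep, obs.p_final, cfg.n_perm, rng)

    res = pd.DataFrame({
        "otu_id": table.otu_ids,
        "n_present": prep.n_present,
        "beta1": obs.beta1, "z_b": obs.z_b, "p_b": obs.p_b,
        "beta2": obs.beta2, "z_q": obs.z_q, "p_q": obs.p_q,
        "z_meta": obs.z_meta, "p_meta": obs.p_meta,
        "p_final": obs.p_final, "z_report": obs.z_report,
        "p_perm": p_perm,
    })
    res = res.loc[valid].reset_index(drop=True)
    res["q_fdr"] = bh_fdr(res["p_perm"].to_numpy())
    res["significant"] = res["q_fdr"] < cfg.fdr_alpha
    return res
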