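"""Alpha diversity, group comparison, and the functional correlation screen.

Diversity indices are computed on the rarefied table (equal depth is what
makes observed-species counts comparable across samples): observed species,
Shannon entropy (natural log by default) and Good's coverage
``1 - F1/N`` with F1 the number of singleton OTUs.  Group differences use
the Wilcoxon rank-sum test (signed-rank when paired) with BH-FDR across the
metrics tested together.  The functional screen ranks KO/pathway-like
features by Spearman correlation with the residual phenotype and selects
those with FDR-adjusted p below and |r| above the configured thresholds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import bh_fdr
from .tables import CountTable

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.4
DEFAULT_Q_THRESHOLD = 0.05

__all__ = [
    "observed_species",
    "shannon",
    "goods_coverage",
    "alpha_diversity",
    "group_compare",
    "spearman_screen",
]


def observed_species(counts_column: np.ndarray) -> int:
    """Number of OTUs with a nonzero count."""
    c = np.asarray(counts_column)
    return int(np.count_nonzero(c > 0))


def shannon(counts_column: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy -sum p_i log p_i over detected OTUs (nats by default)."""
    c = np.asarray(counts_column, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an empty sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def goods_coverage(counts_column: np.ndarray) -> float:
    """Good's coverage 1 - F1/N (F1 = singleton OTUs, N = total tags)."""
    c = np.asarray(counts_column)
    total = c.sum()
    if total <= 0:
        raise ValueError("Good's coverage undefined for an empty sample")
    f1 = int(np.count_nonzero(c == 1))
    return 1.0 - f1 / float(total)


def alpha_diversity(table: CountTable, shannon_base: float | None = None) -> pd.DataFrame:
    """Per-sample diversity records for a (rarefied) count table."""
    recs = []
    for j, s in enumerate(table.sample_ids):
        col = table.counts[:, j]
        recs.append({
            "sample_id": s,
            "observed_species": observed_species(col),
            "shannon": shannon(col, base=shannon_base),
            "goods_coverage": goods_coverage(col),
        })
    return pd.DataFrame(recs)


def group_compare(group_a: pd.DataFrame, group_b: pd.DataFrame,
                  metrics: tuple[str, ...] = ("observed_species", "shannon", "goods_coverage"),
                  paired: bool = False) -> pd.DataFrame:
    """Wilcoxon comparison of diversity metrics between two groups.

    Rank-sum (Mann-Whitney) by default; signed-rank when ``paired`` (rows
    must then correspond one-to-one).  BH-FDR is applied across the metrics
    tested together.
    """
    rows = []
    for metric in metrics:
        a = np.asarray(group_a[metric], dtype=float)
        b = np.asarray(group_b[metric], dtype=float)
        if paired:
            if a.size != b.size:
                raise ValueError("paired comparison needs equal group sizes")
            if a.size < 3:
                raise ValueError("need at least 3 pairs")
            diff = a - b
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(a, b)
        else:
            if min(a.size, b.size) < 3:
                raise ValueError("need at least 3 samples per group")
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"metric": metric, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(np.clip(out["p"].to_numpy(), 1e-300, 1.0))
    return out


def spearman_screen(feature_matrix: pd.DataFrame, y_resid: np.ndarray,
                    r_thresh: float = DEFAULT_R_THRESHOLD,
                    q_thresh: float = DEFAULT_Q_THRESHOLD) -> pd.DataFrame:
    """Spearman correlation of every feature with the residual phenotype.

    ``feature_matrix`` is feature x sample, columns aligned with
    ``y_resid``.  Constant features (correlation undefined) are excluded
    and logged.  A feature is ``selected`` iff its BH-FDR q is below
    ``q_thresh`` AND |r| exceeds ``r_thresh``.
    """
    y = np.asarray(y_resid, dtype=float)
    vals = feature_matrix.to_numpy(dtype=float)
    if vals.shape[1] != y.size:
        raise ValueError("feature matrix samples do not match the phenotype")
    n = y.size
    const = vals.std(axis=1) == 0
    if const.any():
        logger.info("spearman_screen: excluding %d constant features", int(const.sum()))
    keep = ~const
    ids = feature_matrix.index[keep].tolist()
    sub = vals[keep]

    # Spearman r = Pearson on ranks (average ties), vectorized over features;
    # p from the scipy t-approximation with n-2 df.
    ry = sps.rankdata(y)
    rx = np.apply_along_axis(sps.rankdata, 1, sub)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (ry_c ** 2).sum())
    r = np.clip((rx_c @ ry_c) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = np.clip(2.0 * sps.t.sf(np.abs(t), n - 2), 1e-300, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame({
        "feature_id": ids,
        "spearman_r": r,
        "p": p,
        "q_fdr": q,
        "selected": (q < q_thresh) & (np.abs(r) > r_thresh),
    })
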