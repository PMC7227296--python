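"""Cross-validated estimate of the phenotypic variance explained by the
microbiome ("microbiability").

The cohort is split repeatedly into an 80% discovery and a 20% validation
set.  On the discovery set the two-part scan estimates, per OTU, the
presence effect beta1, the abundance slope beta2 and the min-p association
p-value.  For each discovery p-value threshold, the selected OTUs define an
additive microbiome score on the held-out samples,

    r_m(i) = sum_j beta1_j * b_j(i) + beta2_j * q_j(i),

where b_j(i) is detection of OTU j in validation sample i and q_j(i) the
log relative abundance standardized with the *discovery-set* mean and SD
(0 when absent).  The squared Pearson correlation between r_m and the
covariate-corrected phenotype over the validation samples estimates the
variance explained; the sweep reports its mean and SD over repeats per
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import ShuffleSplit

from .association import permutation_correct, prepare_two_part, two_part_stats
from .preprocess import relative_abundance
from .tables import CountTable, RelAbundanceTable, ResidualPhenotype

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1e-4, 1e-3, 1e-2, 0.05, 0.1)

__all__ = ["CvConfig", "SelectedEffects", "microbiome_score", "cv_variance_explained"]


@dataclass
class CvConfig:
    """Cross-validation settings for the threshold sweep.

    thresholds
        Discovery p-value cutoffs to sweep (the study design spans 1e-4 to
        0.1).  Selection uses the analytic min-p by default; set
        ``use_permutation_in_discovery`` to calibrate it by permutation
        inside every repeat (much slower).
    literal_score
        Use the literal sum ``beta1 + b_j + beta2*q_j`` instead of
        ``beta1*b_j + beta2*q_j`` for sensitivity analysis; the constant
        offset cannot change a squared correlation, only the unweighted
        ``b_j`` term can.
    """

    n_repeats: int = 100
    discovery_fraction: float = 0.8
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    use_permutation_in_discovery: bool = False
    n_perm: int = 1000
    min_present: int = 5
    literal_score: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.discovery_fraction < 1:
            raise ValueError("discovery_fraction must lie in (0, 1)")
        if any(not 0 < t < 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        self.thresholds = tuple(sorted(self.thresholds))


@dataclass
class SelectedEffects:
    """Discovery-set effects and transform parameters for selected OTUs."""

    otu_ids: list[str]
    beta1: np.ndarray     # NaN->0 where the binary part was invalid
    beta2: np.ndarray
    log_mean: np.ndarray  # discovery mean of ln relative abundance among present
    log_sd: np.ndarray


def microbiome_score(effects: SelectedEffects, rel_values: np.ndarray,
                     otu_ids: list[str], presence: np.ndarray | None = None,
                     literal: bool = False) -> np.ndarray:
    """Additive microbiome score r_m for each column of ``rel_values``.

    ``rel_values`` holds validation-sample relative abundances for
    ``otu_ids``; OTUs in ``effects`` that are missing from it contribute 0
    (logged).  q is computed with the discovery-set standardization.
    """
    rel = np.asarray(rel_values, dtype=float)
    n = rel.shape[1]
    if not effects.otu_ids:
        return np.zeros(n)
    pos = {o: j for j, o in enumerate(otu_ids)}
    r_m = np.zeros(n)
    pres_all = rel > 0 if presence is None else np.asarray(presence, dtype=bool)
    missing = []
    for k, otu in enumerate(effects.otu_ids):
        j = pos.get(otu)
        if j is None:
            missing.append(otu)
            continue
        b = pres_all[j].astype(float)
        if effects.log_sd[k] > 0:
            with np.errstate(divide="ignore"):
                q = np.where(pres_all[j],
                             (np.log(np.where(pres_all[j], rel[j], 1.0))
                              - effects.log_mean[k]) / effects.log_sd[k],
                             0.0)
        else:
            q = np.zeros(n)
        b1 = 0.0 if np.isnan(effects.beta1[k]) else effects.beta1[k]
        b2 = 0.0 if np.isnan(effects.beta2[k]) else effects.beta2[k]
        if literal:
            r_m += b1 + b + b2 * q
        else:
            r_m += b1 * b + b2 * q
    if missing:
        logger.info("microbiome_score: %d selected OTUs absent from the validation "
                    "table, scored as 0: %s", len(missing), missing)
    return r_m


def _r_squared(r_m: np.ndarray, y: np.ndarray) -> float:
    if r_m.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(r_m, y)[0, 1]
    return float(r * r)


def cv_variance_explained(table: CountTable, y_resid: ResidualPhenotype | np.ndarray,
                          cfg: CvConfig | None = None,
                          rel_table: RelAbundanceTable | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold sweep of cross-validated variance explained.

    Returns ``(summary, repeats)``: ``summary`` has one row per threshold
    with ``mean_r2, sd_r2, mean_n_selected``; ``repeats`` one row per
    (repeat, threshold) with ``r2`` and ``n_selected``.  R^2 is defined as 0
    when nothing is selected or the score is constant on the validation set.
    """
    cfg = cfg or CvConfig()
    if isinstance(y_resid, ResidualPhenotype):
        if y_resid.sample_ids != table.sample_ids:
            raise ValueError("phenotype and table sample order differ; align first")
        y = y_resid.y_resid
    else:
        y = np.asarray(y_resid, dtype=float)
    n = table.n_samples
    val_frac = 1.0 - cfg.discovery_fraction
    if int(round(n * val_frac)) < 5:
        raise ValueError("validation split would have fewer than 5 samples")
    rel = rel_table if rel_table is not None else relative_abundance(table)
    rel_vals = rel.values
    presence = table.presence()

    splitter = ShuffleSplit(n_splits=cfg.n_repeats, test_size=val_frac,
                            random_state=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep, (disc, val) in enumerate(splitter.split(np.zeros(n))):
        prep = prepare_two_part(rel_vals[:, disc], presence[:, disc], cfg.min_present)
        st = two_part_stats(y[disc], prep)
        p_sel = st.p_final
        if cfg.use_permutation_in_discovery:
            p_sel = permutation_correct(y[disc], prep, st.p_final, cfg.n_perm, rng)
        for thr in cfg.thresholds:
            with np.errstate(invalid="ignore"):
                sel = np.flatnonzero(np.nan_to_num(p_sel, nan=np.inf) <= thr)
            if sel.size == 0:
                rows.append((rep, thr, 0, 0.0))
                continue
            eff = SelectedEffects(
                otu_ids=[table.otu_ids[j] for j in sel],
                beta1=st.beta1[sel], beta2=st.beta2[sel],
                log_mean=prep.log_mean[sel], log_sd=np.nan_to_num(prep.log_sd[sel]),
            )
            r_m = microbiome_score(eff, rel_vals[:, val], table.otu_ids,
                                   presence[:, val], literal=cfg.literal_score)
            rows.append((rep, thr, int(sel.size), _r_squared(r_m, y[val])))
    repeats = pd.DataFrame(rows, columns=["repeat", "threshold", "n_selected", "r2"])
    summary = (repeats.groupby("threshold", as_index=False)
               .agg(mean_r2=("r2", "mean"), sd_r2=("r2", "std"),
                    mean_n_selected=("n_selected", "mean")))
    summary["sd_r2"] = summary["sd_r2"].fillna(0.0)
    return summary, repeats
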