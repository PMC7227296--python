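"""Rarefaction, relative abundance, OTU filtering and phenotype residualization.

The pipeline mirrors standard amplicon practice for a cross-sectional growth
study: equalize sequencing effort by rarefying every sample to a common depth
(default 40,000 tags), convert to within-sample fractions, drop OTUs that are
too rare on average (< 0.1% mean relative abundance) or detected in too few
animals (< 3% of samples), and regress the phenotype on the categorical
covariates (sex, cage) so that downstream association works on residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable, RelAbundanceTable, ResidualPhenotype, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 40_000
DEFAULT_MIN_MEAN_ABUNDANCE = 0.001
DEFAULT_MIN_PREVALENCE = 0.03

__all__ = [
    "rarefy",
    "relative_abundance",
    "filter_otus",
    "FilterReport",
    "residualize_phenotype",
    "DEFAULT_RAREFACTION_DEPTH",
    "DEFAULT_MIN_MEAN_ABUNDANCE",
    "DEFAULT_MIN_PREVALENCE",
]


def rarefy(table: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | np.random.Generator | None = None) -> CountTable:
    """Subsample every sample to ``depth`` tags without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.  A
    sample exactly at ``depth`` is returned unchanged (the draw is
    exhaustive).  Reproducible for a fixed seed.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = table.sample_sums()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} tags; cannot rarefy")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.empty((table.n_otus, len(kept_ids)), dtype=np.int64)
    col = 0
    for j in range(table.n_samples):
        if not keep[j]:
            continue
        column = table.counts[:, j]
        if totals[j] == depth:
            out[:, col] = column
        else:
            out[:, col] = rng.multivariate_hypergeometric(column, depth, method="marginals")
        col += 1
    return CountTable(list(table.otu_ids), kept_ids, out, table.taxonomy)


def relative_abundance(table: CountTable) -> RelAbundanceTable:
    """Column-wise fractions; errors on an all-zero sample."""
    totals = table.sample_sums()
    if (totals == 0).any():
        j = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total count")
    vals = table.counts / totals[np.newaxis, :]
    return RelAbundanceTable(list(table.otu_ids), list(table.sample_ids), vals, table.taxonomy)


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_removed_abundance: int
    n_removed_prevalence: int


def filter_otus(rel_table: RelAbundanceTable, count_table: CountTable | None = None,
                min_mean_abund: float = DEFAULT_MIN_MEAN_ABUNDANCE,
                min_prevalence: float = DEFAULT_MIN_PREVALENCE,
                abundance_statistic: str = "mean",
                renormalize: bool = False,
                ) -> tuple[RelAbundanceTable, CountTable | None, FilterReport]:
    """Drop rare OTUs by mean relative abundance and prevalence.

    An OTU is kept iff its abundance statistic (mean across samples by
    default; ``"max"`` as an alternative) is >= ``min_mean_abund`` AND its
    prevalence (fraction of samples with a nonzero value) is >=
    ``min_prevalence``.  Both thresholds are inclusive, so the removal rules
    are the strict ``< 0.1%`` and ``< 3%``.  Retained fractions are kept
    as-is unless ``renormalize`` is set.
    """
    if not (0 <= min_mean_abund <= 1 and 0 <= min_prevalence <= 1):
        raise ValueError("filter thresholds must lie in [0, 1]")
    vals = rel_table.values
    if abundance_statistic == "mean":
        stat = vals.mean(axis=1)
    elif abundance_statistic == "max":
        stat = vals.max(axis=1) if vals.size else np.zeros(rel_table.n_otus)
    else:
        raise ValueError(f"unknown abundance statistic {abundance_statistic!r}")
    prevalence = (vals > 0).mean(axis=1)
    pass_abund = stat >= min_mean_abund
    pass_prev = prevalence >= min_prevalence
    keep = pass_abund & pass_prev
    if not keep.any():
        raise ValueError("filtering removed every OTU")
    report = FilterReport(
        n_input=rel_table.n_otus,
        n_kept=int(keep.sum()),
        n_removed_abundance=int((~pass_abund).sum()),
        n_removed_prevalence=int((~pass_prev).sum()),
    )
    logger.info("filter_otus: kept %d/%d OTUs (%d failed abundance, %d failed prevalence)",
                report.n_kept, report.n_input,
                report.n_removed_abundance, report.n_removed_prevalence)
    ids = [o for o, k in zip(rel_table.otu_ids, keep) if k]
    new_vals = vals[keep]
    if renormalize:
        sums = new_vals.sum(axis=0)
        if (sums == 0).any():
            raise ValueError("renormalization impossible: a sample lost all its OTUs")
        new_vals = new_vals / sums[np.newaxis, :]
    tax = None
    if rel_table.taxonomy is not None:
        tax = {o: rel_table.taxonomy[o] for o in ids if o in rel_table.taxonomy}
    out_rel = RelAbundanceTable(ids, list(rel_table.sample_ids), new_vals, tax,
                                require_unit_sums=False)
    out_counts = None
    if count_table is not None:
        if count_table.otu_ids != rel_table.otu_ids:
            raise ValueError("count table OTU order does not match the relative table")
        out_counts = count_table.select_otus(np.asarray(keep))
    return out_rel, out_counts, report


def residualize_phenotype(metadata: SampleMetadata,
                          covariates: tuple[str, ...] = ("sex", "cage"),
                          ) -> ResidualPhenotype:
    """Residuals of ADG after ordinary least squares on dummy-coded covariates.

    Within every covariate level the residuals average zero (the OLS
    group-mean property), so the returned phenotype carries no sex or cage
    signal.  A covariate with one level per sample is rejected: it would
    absorb the phenotype entirely.
    """
    df = metadata.frame
    n = len(df)
    if n < 2:
        raise ValueError("residualization needs at least 2 samples")
    y = metadata.adg
    if np.isnan(y).any():
        raise ValueError("adg contains missing values")
    X = [np.ones(n)]
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        levels = df[cov].astype(str)
        n_levels = levels.nunique()
        if n_levels == n and n > 1:
            raise ValueError(
                f"covariate {cov!r} has one level per sample and would absorb the "
                "phenotype; drop it from the correction"
            )
        singles = levels.value_counts()
        singles = singles[singles == 1]
        if len(singles):
            logger.info("residualize_phenotype: covariate %r has %d single-sample "
                        "levels whose residuals are forced to 0", cov, len(singles))
        dummies = pd.get_dummies(levels, drop_first=True, dtype=float)
        X.append(dummies.to_numpy())
    X = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return ResidualPhenotype(metadata.sample_ids, resid)
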