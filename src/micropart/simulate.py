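"""Synthetic cohorts with the structure the association pipeline assumes.

The generator emulates a ~105-animal fattening cohort profiled by 16S
amplicon sequencing: zero-inflated, compositional OTU counts at library
sizes of at least 40,000 tags, a two-level sex factor, a litter-like cage
grouping with several animals per cage, and a continuous growth phenotype
(ADG, g/day) carrying planted presence (beta1) and abundance (beta2) OTU
effects with a controllable microbiome variance fraction.

Counts arise from a two-part latent model that mirrors the association
model exactly: each OTU j has a detection probability pi_j (Beta-drawn);
present OTUs get log-normal latent abundances which are renormalized to the
simplex per sample; sequencing is a multinomial draw at a random library
size.  The phenotype's quantitative feature q_j is the z-scored natural-log
latent relative abundance among present samples — the same transform the
association module applies — so parameter recovery is well-posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .association import prepare_two_part
from .tables import CountTable, RelAbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "SyntheticCohort",
    "simulate_otu_table",
    "make_truth",
    "simulate_phenotype",
    "simulate_cohort",
    "simulate_functional_table",
]


@dataclass
class SimulationParams:
    """Generator settings; defaults emulate the study cohort's scale.

    Effect sizes ``beta1`` (phenotype shift when the OTU is detected) and
    ``beta2`` (phenotype slope per SD of the log-abundance feature) are on
    the phenotype scale (g/day).  When ``target_h2m`` is set, the residual
    noise is rescaled so the microbiome term contributes that fraction of
    the total phenotypic variance; otherwise ``noise_sd`` is used directly.
    """

    n_samples: int = 105
    n_otus: int = 1500
    library_size_range: tuple[int, int] = (40_000, 150_000)
    prevalence_beta: tuple[float, float] = (0.6, 1.8)
    prevalence_min: float = 0.01
    log_mean_sd: float = 1.5
    log_sigma: float = 1.0
    n_causal_binary: int = 5
    n_causal_quant: int = 5
    beta1: float = 3.0
    beta2: float = 1.5
    target_h2m: float | None = 0.15
    mu_adg: float = 32.7
    sex_effect: float = 1.5
    cage_sd: float = 1.0
    noise_sd: float = 3.0
    rabbits_per_cage: int = 6
    causal_prevalence_range: tuple[float, float] = (0.25, 0.75)
    causal_min_abundance: float = 0.001

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_otus < 1:
            raise ValueError("need at least 2 samples and 1 OTU")
        lo, hi = self.library_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid library size range")
        if self.target_h2m is not None and not 0 <= self.target_h2m < 1:
            raise ValueError("target_h2m must lie in [0, 1)")
        if self.n_causal_binary + self.n_causal_quant > self.n_otus:
            raise ValueError("more causal OTUs than OTUs")
        if not 0 < self.prevalence_min <= 1:
            raise ValueError("prevalence_min must lie in (0, 1]")
        if self.rabbits_per_cage < 1:
            raise ValueError("rabbits_per_cage must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted causal OTUs, their effects and the realized variance split."""

    causal_otu_ids: list[str]
    beta1: np.ndarray          # presence effect per causal OTU (0 if none)
    beta2: np.ndarray          # abundance effect per causal OTU (0 if none)
    realized_h2m: float = float("nan")
    realized_var_fractions: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "otu_id": self.causal_otu_ids,
            "beta1": self.beta1,
            "beta2": self.beta2,
        })


@dataclass
class SyntheticCohort:
    table: CountTable
    latent: RelAbundanceTable
    metadata: SampleMetadata
    truth: SyntheticTruth
    prevalence_probs: np.ndarray


def _spawn(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_otu_table(params: SimulationParams,
                       seed: int | np.random.Generator | None = None,
                       ) -> tuple[CountTable, RelAbundanceTable, np.ndarray]:
    """Draw a zero-inflated compositional count table.

    Returns the counts, the latent relative-abundance table the counts were
    drawn from, and the per-OTU detection probabilities pi_j.  An all-zero
    sample (possible at tiny n_otus) is redrawn with a log message.
    """
    rng = _spawn(seed)
    m, n = params.n_otus, params.n_samples
    a, b = params.prevalence_beta
    pi = np.clip(rng.beta(a, b, size=m), params.prevalence_min, 1.0)
    log_mu = rng.normal(0.0, params.log_mean_sd, size=m)

    otu_ids = [f"OTU_{j + 1:05d}" for j in range(m)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    latent = np.zeros((m, n))
    for i in range(n):
        for _attempt in range(100):
            present = rng.random(m) < pi
            if present.any():
                break
            logger.info("simulate_otu_table: sample %s drawn empty, regenerating", sample_ids[i])
        else:  # pragma: no cover - pi floor makes this unreachable in practice
            raise RuntimeError("could not draw a nonempty sample")
        raw = np.zeros(m)
        raw[present] = np.exp(log_mu[present]
                              + params.log_sigma * rng.standard_normal(int(present.sum())))
        latent[:, i] = raw / raw.sum()

    lo, hi = params.library_size_range
    lib = rng.integers(lo, hi + 1, size=n)
    counts = np.empty((m, n), dtype=np.int64)
    for i in range(n):
        counts[:, i] = rng.multinomial(lib[i], latent[:, i])
    table = CountTable(otu_ids, sample_ids, counts)
    latent_tab = RelAbundanceTable(otu_ids, sample_ids, latent)
    return table, latent_tab, pi


def make_truth(params: SimulationParams, otu_ids: list[str], pi: np.ndarray,
               seed: int | np.random.Generator | None = None,
               latent: RelAbundanceTable | None = None) -> SyntheticTruth:
    """Pick causal OTUs and assign planted effects.

    Causal OTUs are drawn among those with detection probability inside
    ``causal_prevalence_range`` — so both the presence and abundance parts
    are identifiable — and, when the latent table is given, with mean
    relative abundance at least ``causal_min_abundance``, so planted taxa
    survive the standard rare-OTU filter.  Binary-effect and
    abundance-effect OTUs are disjoint.
    """
    rng = _spawn(seed)
    n_causal = params.n_causal_binary + params.n_causal_quant
    if n_causal == 0:
        return SyntheticTruth([], np.zeros(0), np.zeros(0))
    lo, hi = params.causal_prevalence_range
    in_window = (pi >= lo) & (pi <= hi)
    if latent is not None:
        in_window &= latent.values.mean(axis=1) >= params.causal_min_abundance
    eligible = np.flatnonzero(in_window)
    if eligible.size < n_causal:
        eligible = np.argsort(np.abs(pi - (lo + hi) / 2))[:max(n_causal, 1)]
        logger.info("make_truth: widened causal prevalence window to find %d OTUs", n_causal)
    chosen = rng.choice(eligible, size=n_causal, replace=False)
    beta1 = np.concatenate([np.full(params.n_causal_binary, params.beta1),
                            np.zeros(params.n_causal_quant)])
    beta2 = np.concatenate([np.zeros(params.n_causal_binary),
                            np.full(params.n_causal_quant, params.beta2)])
    ids = [otu_ids[j] for j in chosen]
    return SyntheticTruth(ids, beta1, beta2)


def _microbiome_term(latent: RelAbundanceTable, truth: SyntheticTruth) -> np.ndarray:
    """Sum over causal OTUs of beta1 * presence + beta2 * q, per sample."""
    if not truth.causal_otu_ids:
        return np.zeros(latent.n_samples)
    pos = {o: j for j, o in enumerate(latent.otu_ids)}
    idx = [pos[o] for o in truth.causal_otu_ids]
    sub = latent.values[idx]
    prep = prepare_two_part(sub, min_present=3)
    return truth.beta1 @ prep.presence + truth.beta2 @ prep.q


def simulate_phenotype(latent: RelAbundanceTable, truth: SyntheticTruth,
                       params: SimulationParams,
                       seed: int | np.random.Generator | None = None,
                       ) -> tuple[SampleMetadata, SyntheticTruth]:
    """Draw sex, cage and the phenotype y for the cohort.

    y = mu + sex_effect * I(male) + cage effect + sum_j (beta1_j b_j +
    beta2_j q_j) + noise.  With ``target_h2m`` set, the noise variance is
    solved so the microbiome term's share of var(y) hits the target; the
    realized fraction on the drawn data is reported in the returned truth.
    """
    rng = _spawn(seed)
    n = latent.n_samples
    g = _microbiome_term(latent, truth)
    var_g = float(np.var(g))
    if params.target_h2m == 0 and truth.causal_otu_ids and var_g > 0:
        raise ValueError("target_h2m=0 contradicts nonzero planted effects")

    order = rng.permutation(n)
    sex = np.empty(n, dtype=object)
    n_male = (n + 1) // 2
    sex[order[:n_male]] = "male"
    sex[order[n_male:]] = "female"
    cage_of = rng.permutation(n) // params.rabbits_per_cage
    cage_labels = np.array([f"cage_{c + 1:03d}" for c in cage_of])
    cage_effects = rng.normal(0.0, params.cage_sd, size=int(cage_of.max()) + 1)

    fixed = params.sex_effect * (sex == "male").astype(float) + cage_effects[cage_of]
    if params.target_h2m is None or var_g == 0:
        noise_sd = params.noise_sd
    else:
        h = params.target_h2m
        var_noise = var_g * (1 - h) / h - float(np.var(fixed))
        if var_noise < 0:
            raise ValueError(
                f"target_h2m={h} unreachable: sex/cage variance {np.var(fixed):.3g} "
                f"already exceeds the allowed non-microbiome share"
            )
        noise_sd = float(np.sqrt(var_noise))
    eps = noise_sd * rng.standard_normal(n)
    y = params.mu_adg + fixed + g + eps
    realized = float(var_g / np.var(y)) if np.var(y) > 0 else 0.0

    frame = pd.DataFrame({
        "sample_id": latent.sample_ids,
        "sex": sex,
        "cage": cage_labels,
        "adg": y,
    })
    truth_out = replace(truth, realized_h2m=realized)
    return SampleMetadata(frame), truth_out


def simulate_cohort(params: SimulationParams,
                    seed: int | np.random.Generator | None = None) -> SyntheticCohort:
    """One-call cohort: counts, latent abundances, metadata and planted truth."""
    rng = _spawn(seed)
    table, latent, pi = simulate_otu_table(params, rng)
    truth = make_truth(params, table.otu_ids, pi, rng, latent)
    metadata, truth = simulate_phenotype(latent, truth, params, rng)
    return SyntheticCohort(table, latent, metadata, truth, pi)


def simulate_functional_table(y: np.ndarray, n_features: int = 500, n_hits: int = 10,
                              signal: float = 1.0, noise_sd: float = 1.0,
                              seed: int | np.random.Generator | None = None,
                              normalize: bool = True,
                              ) -> tuple[pd.DataFrame, list[str]]:
    """Functional-feature (KO/pathway-like) matrix for the correlation screen.

    The first ``n_hits`` features are noisy monotone transforms of the
    phenotype (``exp(signal * z(y) + noise)``); the rest are independent
    log-normal noise.  With ``normalize`` the columns are scaled to sum to 1
    (relative abundances); set it to False to keep exact within-feature
    monotonicity at ``noise_sd=0``.  Returns the feature x sample frame and
    the planted feature ids.
    """
    rng = _spawn(seed)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_hits > n_features:
        raise ValueError("n_hits cannot exceed n_features")
    sd = y.std()
    z = (y - y.mean()) / sd if sd > 0 else np.zeros(n)
    rows = np.empty((n_features, n))
    for k in range(n_hits):
        rows[k] = np.exp(signal * z + noise_sd * rng.standard_normal(n))
    rows[n_hits:] = np.exp(rng.standard_normal((n_features - n_hits, n)))
    if normalize:
        rows = rows / rows.sum(axis=0)[np.newaxis, :]
    ids = [f"K{k + 1:05d}" for k in range(n_features)]
    frame = pd.DataFrame(rows, index=ids,
                         columns=[f"S{i + 1:04d}" for i in range(n)])
    return frame, ids[:n_hits]
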