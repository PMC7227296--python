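"""Core tabular containers for OTU count data and sample metadata.

The central object is :class:`CountTable`, an OTU-by-sample matrix of
non-negative integer counts (the unit of observation in amplicon surveys),
optionally annotated with a taxonomy string per OTU.  A
:class:`RelAbundanceTable` holds the per-sample fractions derived from it.
Sample covariates and the growth phenotype (average daily gain, ADG) live in
:class:`SampleMetadata`; the covariate-corrected phenotype used by every
downstream association step is a :class:`ResidualPhenotype`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "ResidualPhenotype",
]


def _check_unique(ids, kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountTable:
    """OTU x sample matrix of non-negative integer counts.

    Parameters
    ----------
    otu_ids, sample_ids
        Unique, ordered identifiers for the rows and columns.
    counts
        Integer array of shape ``(len(otu_ids), len(sample_ids))``.
    taxonomy
        Optional map from OTU id to a taxonomy string.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = _check_unique(self.otu_ids, "OTU")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if counts.size:
            if not np.issubdtype(counts.dtype, np.integer):
                if np.isnan(counts.astype(float)).any():
                    r, c = np.argwhere(np.isnan(counts.astype(float)))[0]
                    raise ValueError(
                        f"NaN count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
                    )
                if not np.array_equal(counts, np.floor(counts)):
                    bad = np.argwhere(counts != np.floor(counts))[0]
                    raise ValueError(
                        f"non-integer count at OTU {self.otu_ids[bad[0]]!r}, "
                        f"sample {self.sample_ids[bad[1]]!r}"
                    )
            if (counts < 0).any():
                r, c = np.argwhere(counts < 0)[0]
                raise ValueError(
                    f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
        self.counts = counts.astype(np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise ValueError(f"taxonomy given for unknown OTU ids: {sorted(unknown)}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def presence(self) -> np.ndarray:
        """Boolean OTU x sample detection matrix (count > 0)."""
        return self.counts > 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_otus(self, keep: np.ndarray) -> "CountTable":
        """Subset rows by a boolean mask or index array, preserving order."""
        idx = np.arange(self.n_otus)[keep] if np.asarray(keep).dtype == bool else np.asarray(keep)
        ids = [self.otu_ids[i] for i in idx]
        tax = {i: self.taxonomy[i] for i in ids if i in self.taxonomy} if self.taxonomy else None
        return CountTable(ids, list(self.sample_ids), self.counts[idx], tax)

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountTable(list(self.otu_ids), list(sample_ids), self.counts[:, idx], self.taxonomy)


@dataclass
class RelAbundanceTable:
    """OTU x sample matrix of within-sample fractions.

    Columns sum to 1 for every sample on construction; after OTU filtering the
    retained fractions are kept as-is (sums may drop below 1) unless the caller
    renormalizes, so ``require_unit_sums`` is only enforced when requested.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    taxonomy: dict[str, str] | None = None
    require_unit_sums: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.otu_ids = _check_unique(self.otu_ids, "OTU")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if vals.size and (np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any()):
            raise ValueError("relative abundances must lie in [0, 1]")
        if self.require_unit_sums and vals.size:
            sums = vals.sum(axis=0)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                j = int(np.argmax(bad))
                raise ValueError(
                    f"sample {self.sample_ids[j]!r} fractions sum to {sums[j]!r}, not 1"
                )
        self.values = vals

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)


REQUIRED_METADATA_COLUMNS = ("sample_id", "sex", "cage")


@dataclass
class SampleMetadata:
    """Per-sample covariates and phenotype.

    Wraps a DataFrame with columns ``sample_id``, ``sex``, ``cage`` and
    ``adg`` (g/day).  ``adg`` may be derived upstream from weaning/finishing
    weights (kg) and the day span between the two weighings.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in (*REQUIRED_METADATA_COLUMNS, "adg"):
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        adg = pd.to_numeric(df["adg"])
        if not np.isfinite(adg.dropna()).all():
            raise ValueError("adg must be finite where present")
        df["adg"] = adg
        df["sex"] = df["sex"].astype("category")
        df["cage"] = df["cage"].astype("category")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def adg(self) -> np.ndarray:
        return self.frame["adg"].to_numpy(dtype=float)

    def select_samples(self, sample_ids: list[str]) -> "SampleMetadata":
        df = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        df["sex"] = df["sex"].cat.remove_unused_categories()
        df["cage"] = df["cage"].cat.remove_unused_categories()
        return SampleMetadata(df)


@dataclass
class ResidualPhenotype:
    """Covariate-corrected phenotype: residuals of ADG after OLS on covariates."""

    sample_ids: list[str]
    y_resid: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        y = np.asarray(self.y_resid, dtype=float)
        if y.shape != (len(self.sample_ids),):
            raise ValueError("y_resid length does not match sample ids")
        if y.size and not np.isfinite(y).all():
            raise ValueError("residual phenotype must be finite")
        self.y_resid = y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "y_resid": self.y_resid})
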