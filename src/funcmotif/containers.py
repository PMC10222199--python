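"""Core data containers: the community count table and the per-sample property.

An :class:`AbundanceTable` holds non-negative integer read counts for ``n``
samples by ``p`` microbial families (e.g. 57 soils by 60 bacterial families at
a rarefied depth of 3000 reads).  A :class:`PropertyVector` holds one measured
ecosystem property per sample — basal soil respiration, straw mineralization
or the priming effect, at a given incubation time — aligned to the table by
sample identifier, never by row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError

__all__ = ["AbundanceTable", "PropertyVector"]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Sample x family matrix of non-negative integer read counts."""

    sample_ids: list[str]
    family_ids: list[str]
    counts: np.ndarray
    community_label: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.family_ids = [str(f) for f in self.family_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.family_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.family_ids)} families"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = np.round(counts).astype(np.int64)
            if not np.allclose(counts, as_int, rtol=0, atol=0):
                raise ValidationError("counts must be exactly representable as integers")
            counts = as_int
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"family {self.family_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.family_ids, "family")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def sample_depths(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-family observation frequency: fraction of samples with count > 0."""
        return (self.counts > 0).mean(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Counts divided by per-sample depth (rows with zero depth stay zero)."""
        depth = self.sample_depths.astype(float)
        safe = np.where(depth > 0, depth, 1.0)
        return self.counts / safe[:, None]

    def family_totals(self) -> pd.Series:
        """Total reads per family across all samples."""
        return pd.Series(self.counts.sum(axis=0), index=self.family_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.family_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, community_label: str = "") -> "AbundanceTable":
        return cls(
            sample_ids=list(map(str, frame.index)),
            family_ids=list(map(str, frame.columns)),
            counts=frame.to_numpy(),
            community_label=community_label,
        )

    def subset_families(self, keep: list[str]) -> "AbundanceTable":
        idx = [self.family_ids.index(f) for f in keep]
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            family_ids=[self.family_ids[i] for i in idx],
            counts=self.counts[:, idx],
            community_label=self.community_label,
        )


@dataclass
class PropertyVector:
    """One ecosystem property value per sample, in measurement order.

    ``label`` is free text such as ``"priming_effect_7d"``; ``units`` is carried
    as metadata only and never enters any computation.
    """

    sample_ids: list[str]
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValidationError("property values must be 1-D")
        if len(values) != len(self.sample_ids):
            raise ValidationError("property length does not match sample ids")
        if not np.all(np.isfinite(values)):
            bad = [self.sample_ids[i] for i in np.flatnonzero(~np.isfinite(values))]
            raise ValidationError(f"non-finite property value for samples {bad}")
        _check_unique(self.sample_ids, "sample")
        self.values = values

    def __len__(self) -> int:
        return len(self.sample_ids)

    def align_to(self, sample_ids: list[str]) -> "PropertyVector":
        """Reorder to the reference sample order; missing samples are an error."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise AlignmentError(f"samples missing from property table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return PropertyVector(
            sample_ids=list(sample_ids),
            values=self.values[idx],
            label=self.label,
            units=self.units,
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids, name=self.label or "value")
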