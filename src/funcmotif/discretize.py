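"""One-hot encoding of family abundances into relative-abundance classes.

Each family is segmented into 1, 2 or 3 classes of relative abundance so that
every class is observed in roughly 30% of samples: ubiquitous families get
three classes (noted 1/3, 2/3, 3/3 from least to most abundant), families seen
in about a third of samples keep a single presence class (1/1), families in
between get two (1/2, 2/2).  Within a family, the samples where it occurs are
rank-ordered by relative abundance and split into contiguous blocks whose
sizes differ by at most one, so classes are equally populated by construction.

The resulting binary sample x class table is the input of the functional
clustering route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceTable
from .exceptions import ParameterError, SegmentationError, ValidationError

__all__ = [
    "ClassDescriptor",
    "ClassEncoding",
    "class_count_for_frequency",
    "segment_family",
    "encode_all",
]

#: target observation frequency each class is centered on
CLASS_TARGET_FREQUENCY = 0.30


@dataclass(frozen=True)
class ClassDescriptor:
    """One relative-abundance class: family, index c of k, value thresholds."""

    family_id: str
    class_index: int  # 1-based, 1 = least abundant
    n_classes: int
    lower: float  # smallest abundance value assigned to this class
    upper: float  # largest abundance value assigned to this class
    frequency: float  # fraction of samples carrying this class

    @property
    def name(self) -> str:
        return f"{self.family_id}|{self.class_index}/{self.n_classes}"


@dataclass
class ClassEncoding:
    """Binary sample x class indicator table with class metadata."""

    sample_ids: list[str]
    classes: list[ClassDescriptor]
    indicators: np.ndarray  # (n_samples, n_classes) of 0/1

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicators)
        if ind.shape != (len(self.sample_ids), len(self.classes)):
            raise ValidationError("indicator shape inconsistent with ids")
        if ind.size and not np.isin(ind, (0, 1)).all():
            raise ValidationError("indicators must be binary")
        self.indicators = ind.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    @property
    def family_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.classes:
            if c.family_id not in seen:
                seen.append(c.family_id)
        return seen

    def columns_of_family(self, family_id: str) -> list[int]:
        return [i for i, c in enumerate(self.classes) if c.family_id == family_id]

    def subset_classes(self, columns: list[int]) -> "ClassEncoding":
        return ClassEncoding(
            sample_ids=list(self.sample_ids),
            classes=[self.classes[i] for i in columns],
            indicators=self.indicators[:, columns],
        )

    def drop_families(self, families: set[str]) -> "ClassEncoding":
        keep = [i for i, c in enumerate(self.classes) if c.family_id not in families]
        return self.subset_classes(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.indicators, index=self.sample_ids, columns=self.class_names
        )


def class_count_for_frequency(frequency: float) -> int:
    """Number of abundance classes for a family observed at this frequency.

    The rule centers classes on a 30% observation frequency:
    ``clamp(round_half_up(frequency / 0.30), 1, 3)``, so ubiquitous families
    get 3 classes and families near 30% keep a single class.
    """
    if not 0.0 < frequency <= 1.0:
        raise ParameterError(f"frequency must lie in (0, 1], got {frequency}")
    return int(min(3, max(1, math.floor(frequency / CLASS_TARGET_FREQUENCY + 0.5))))


def segment_family(
    counts: np.ndarray,
    n_classes: int,
    values: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Split one family's presences into equally-populated abundance classes.

    ``counts`` decides presence (count > 0); ranking uses ``values`` when given
    (depth-normalized abundances) and raw counts otherwise.  Present samples
    are rank-ordered (stable, so ties keep input order) and cut into
    ``n_classes`` contiguous blocks whose sizes differ by at most one, larger
    blocks at the low-abundance end.  Returns the (n_samples, n_classes)
    indicator matrix and per-class (lower, upper) value bounds.
    """
    counts = np.asarray(counts)
    if values is None:
        values = counts.astype(float)
    else:
        values = np.asarray(values, dtype=float)
    if not 1 <= n_classes <= 3:
        raise ParameterError(f"n_classes must be 1..3, got {n_classes}")
    present = np.flatnonzero(counts > 0)
    m = present.size
    if m < n_classes:
        raise SegmentationError(
            f"family has {m} presences, fewer than {n_classes} classes"
        )
    order = present[np.argsort(values[present], kind="stable")]
    base, rem = divmod(m, n_classes)
    sizes = [base + 1 if c < rem else base for c in range(n_classes)]
    indicators = np.zeros((counts.shape[0], n_classes), dtype=np.int8)
    bounds: list[tuple[float, float]] = []
    start = 0
    for c, size in enumerate(sizes):
        block = order[start : start + size]
        indicators[block, c] = 1
        bounds.append((float(values[block].min()), float(values[block].max())))
        start += size
    return indicators, bounds


def encode_all(table: AbundanceTable) -> ClassEncoding:
    """Encode every family of an abundance table into abundance classes.

    Class order follows family input order, then ascending class index.
    Ranking uses raw counts when all sample depths are equal (the rarefied
    case) and depth-normalized abundances otherwise.
    """
    depths = table.sample_depths
    uniform_depth = depths.size == 0 or np.all(depths == depths[0])
    rel = None if uniform_depth else table.relative_abundance()
    n = table.n_samples
    blocks: list[np.ndarray] = []
    classes: list[ClassDescriptor] = []
    for j, family in enumerate(table.family_ids):
        col = table.counts[:, j]
        freq = float((col > 0).sum()) / n
        if freq == 0.0:
            raise SegmentationError(f"family {family!r} is absent from every sample")
        k = class_count_for_frequency(freq)
        vals = None if rel is None else rel[:, j]
        ind, bounds = segment_family(col, k, values=vals)
        blocks.append(ind)
        for c in range(k):
            classes.append(
                ClassDescriptor(
                    family_id=family,
                    class_index=c + 1,
                    n_classes=k,
                    lower=bounds[c][0],
                    upper=bounds[c][1],
                    frequency=float(ind[:, c].mean()),
                )
            )
    indicators = (
        np.hstack(blocks) if blocks else np.zeros((n, 0), dtype=np.int8)
    )
    return ClassEncoding(
        sample_ids=list(table.sample_ids), classes=classes, indicators=indicators
    )
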