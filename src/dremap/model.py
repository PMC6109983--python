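"""Core in-memory records shared by every pipeline stage.

All coordinates are 0-based half-open on the forward genome strand,
regardless of the dialect they were read from; conversion happens only at
I/O boundaries (:mod:`dremap.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: Canonical base order used by every matrix in the package.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open convention: abutting intervals ([0,100) vs [100,200)) do not
    overlap.
    """
    return a.scaffold == b.scaffold and a.start < b.end and b.start < a.end


@dataclass
class Peak:
    """A called ChIP-seq enrichment interval.

    ``summit_offset`` is the offset of the point of maximal enrichment from
    ``interval.start`` (narrowPeak column 10), or ``None`` when the caller
    did not report one; :attr:`summit` then falls back to the interval
    midpoint so that summit-based assignment stays total.
    """

    interval: GenomicInterval
    name: str = ""
    signal: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.name!r}: negative signal {self.signal}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"peak {self.name!r}: summit offset {self.summit_offset} "
                f"outside [0, {len(self.interval)})"
            )

    @property
    def summit(self) -> int:
        """Absolute summit coordinate (midpoint when no summit was called)."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass
class GeneModel:
    """A stranded gene with its exon structure.

    The TSS is the 5' terminus in transcription orientation: ``start`` for
    "+" genes, ``end - 1`` for "-" genes; the TTS is the opposite terminus.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.scaffold != self.interval.scaffold:
                raise ValueError(f"gene {self.gene_id}: exon on wrong scaffold")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass
class CoverageTrack:
    """Dense per-base coverage, one float vector per scaffold.

    ``library_size`` is the total tag count the track was derived from and
    is the denominator of counts-per-million scaling downstream.
    """

    values: dict[str, np.ndarray]
    library_size: float
    step: int = 1

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for name, vec in self.values.items():
            if np.any(vec < 0):
                raise ValueError(f"negative coverage on scaffold {name}")

    def scaffold_length(self, scaffold: str) -> int:
        return len(self.values[scaffold]) * self.step

    def densified(self) -> "CoverageTrack":
        """Per-base copy of a step-binned track (identity when step == 1)."""
        if self.step == 1:
            return self
        return CoverageTrack({k: np.repeat(v, self.step)
                              for k, v in self.values.items()},
                             self.library_size, step=1)


@dataclass
class ExpressionTable:
    """gene_id -> RPKM per condition label."""

    rpkm: pd.DataFrame  # index gene_id, columns condition labels

    def __post_init__(self) -> None:
        if self.rpkm.index.has_duplicates:
            dupes = self.rpkm.index[self.rpkm.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("negative RPKM values")

    @property
    def conditions(self) -> list[str]:
        return list(self.rpkm.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    def values_for(self, condition: str) -> pd.Series:
        if condition not in self.rpkm.columns:
            raise KeyError(f"condition {condition!r} not in expression table")
        return self.rpkm[condition]


@dataclass
class PWM:
    """A position frequency/probability matrix over A,C,G,T.

    ``matrix`` is 4 x W in :data:`BASES` row order. After
    :meth:`normalized` every column sums to one.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x W")
        if self.matrix.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")
        if np.any(self.background <= 0) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be positive and sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def normalized(self, pseudocount: float = 0.01) -> "PWM":
        """Column-normalized copy after adding ``pseudocount`` per cell."""
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        m = self.matrix + pseudocount
        sums = m.sum(axis=0)
        if np.any(sums == 0):
            raise ValueError("all-zero PWM column with zero pseudocount")
        return PWM(self.motif_id, m / sums, self.background.copy())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))
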