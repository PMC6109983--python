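"""Generic genomic-interval computations shared by every downstream stage.

Three primitives live here: an overlap index over interval sets, the
five-way genome partition (promoter-TSS / exon / intron / TTS / intergenic)
used to annotate peak summits, and nearest-TSS assignment.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import GeneModel, GenomicInterval, Peak, overlaps

#: Partition labels in priority order (highest first). When windows collide,
#: the earlier label wins: promoter-proximal assignment dominates.
PARTITION_LABELS = ("promoter-TSS", "exon", "intron", "TTS", "intergenic")

PROMOTER_UPSTREAM = 1000   # bp upstream of the TSS (transcription orientation)
PROMOTER_DOWNSTREAM = 200  # bp downstream of the TSS
TTS_UPSTREAM = 200         # bp upstream of the TTS
TTS_DOWNSTREAM = 1000      # bp downstream of the TTS


class IntervalIndex:
    """Overlap queries against a fixed interval set (intervaltree-backed)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self._trees.setdefault(iv.scaffold, IntervalTree()).addi(iv.start, iv.end, iv)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.scaffold)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def query(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.scaffold)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.overlap(iv.start, iv.end)),
                      key=lambda g: (g.start, g.end))


def _oriented_window(anchor: int, strand: str, upstream: int, downstream: int,
                     scaffold_len: int) -> tuple[int, int]:
    """Half-open window of ``upstream`` bases 5' and ``downstream`` bases 3'
    of an anchor base, in transcription orientation, clipped to the scaffold.

    The anchor base itself counts as the first downstream base.
    """
    if strand == "+":
        start, end = anchor - upstream, anchor + downstream
    else:
        start, end = anchor - downstream + 1, anchor + upstream + 1
    return max(0, start), min(scaffold_len, end)


class GenomePartition:
    """Every base of every scaffold carries exactly one of the five labels."""

    def __init__(self, labels: dict[str, np.ndarray]):
        self._labels = labels  # scaffold -> int8 array of label indices

    @property
    def scaffolds(self) -> list[str]:
        return list(self._labels)

    def scaffold_length(self, scaffold: str) -> int:
        return len(self._labels[scaffold])

    def label_at(self, scaffold: str, pos: int) -> str:
        arr = self._labels.get(scaffold)
        if arr is None:
            raise KeyError(f"unknown scaffold {scaffold!r}")
        if not (0 <= pos < len(arr)):
            raise IndexError(f"position {pos} outside scaffold {scaffold} "
                             f"of length {len(arr)}")
        return PARTITION_LABELS[arr[pos]]

    def segments(self, scaffold: str) -> list[tuple[int, int, str]]:
        """Run-length encoding: (start, end, label) tiles without gaps."""
        arr = self._labels[scaffold]
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        return [(int(s), int(e), PARTITION_LABELS[arr[s]]) for s, e in zip(starts, ends)]

    def label_counts(self) -> dict[str, int]:
        """Total bases per label across all scaffolds."""
        totals = np.zeros(len(PARTITION_LABELS), dtype=np.int64)
        for arr in self._labels.values():
            totals += np.bincount(arr, minlength=len(PARTITION_LABELS))
        return {lab: int(totals[i]) for i, lab in enumerate(PARTITION_LABELS)}


def build_partition(genes: Sequence[GeneModel],
                    scaffold_lengths: dict[str, int]) -> GenomePartition:
    """Tile the genome with the five annotation labels.

    Windows: promoter-TSS is the strand-oriented [TSS-1kb, TSS+200bp);
    TTS mirrors it as [TTS-200bp, TTS+1kb); exons and introns come from the
    gene structure; everything else is intergenic. Collisions resolve by the
    fixed priority promoter-TSS > exon > intron > TTS > intergenic,
    implemented by painting labels from lowest to highest priority.
    """
    idx = {lab: i for i, lab in enumerate(PARTITION_LABELS)}
    labels = {name: np.full(length, idx["intergenic"], dtype=np.int8)
              for name, length in scaffold_lengths.items()}
    for g in genes:
        iv = g.interval
        if iv.scaffold not in labels:
            raise ValueError(f"gene {g.gene_id} on unknown scaffold {iv.scaffold!r}")
        n = len(labels[iv.scaffold])
        if iv.end > n:
            raise ValueError(
                f"gene {g.gene_id} extends to {iv.end} beyond scaffold "
                f"{iv.scaffold} of length {n}"
            )
    # paint in reverse priority so that higher-priority labels overwrite
    for g in genes:
        arr = labels[g.interval.scaffold]
        # TTS window hangs off the gene's 3' boundary, mirroring the
        # promoter window's anchoring on the 5' boundary
        if g.strand == "+":
            s, e = g.interval.end - TTS_UPSTREAM, g.interval.end + TTS_DOWNSTREAM
        else:
            s, e = g.interval.start - TTS_DOWNSTREAM, g.interval.start + TTS_UPSTREAM
        arr[max(0, s):min(len(arr), e)] = idx["TTS"]
    for g in genes:
        arr = labels[g.interval.scaffold]
        arr[g.interval.start:g.interval.end] = idx["intron"]
    for g in genes:
        arr = labels[g.interval.scaffold]
        exons = g.exons if g.exons else [g.interval]
        for ex in exons:
            arr[ex.start:ex.end] = idx["exon"]
    for g in genes:
        arr = labels[g.interval.scaffold]
        s, e = _oriented_window(g.tss, g.strand, PROMOTER_UPSTREAM,
                                PROMOTER_DOWNSTREAM, len(arr))
        arr[s:e] = idx["promoter-TSS"]
    return GenomePartition(labels)


def assign_peak_region(peak: Peak, partition: GenomePartition) -> str:
    """Annotation label at the peak summit (the paper's assignment rule for
    peaks spanning several annotation regions)."""
    return partition.label_at(peak.interval.scaffold, peak.summit)


class TSSIndex:
    """Sorted per-scaffold TSS arrays for bulk nearest-TSS queries.

    Ties (two TSSs equidistant from the query point) break toward the
    lexicographically smallest gene_id. Genes on other scaffolds are never
    considered.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        by_scaffold: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            by_scaffold.setdefault(g.interval.scaffold, []).append((g.tss, g.gene_id))
        self._pos: dict[str, np.ndarray] = {}
        self._ids: dict[str, list[str]] = {}
        for scaf, pairs in by_scaffold.items():
            # sort by position, then gene_id, so equal positions keep the
            # lexicographically smallest id first
            pairs.sort()
            self._pos[scaf] = np.array([p for p, _ in pairs], dtype=np.int64)
            self._ids[scaf] = [gid for _, gid in pairs]

    def nearest(self, scaffold: str, point: int) -> tuple[str, int] | None:
        """(gene_id, signed distance point - TSS) or None if the scaffold
        carries no gene."""
        pos = self._pos.get(scaffold)
        if pos is None or len(pos) == 0:
            return None
        i = int(np.searchsorted(pos, point))
        candidates = set()
        for j in (i - 1, i):
            if 0 <= j < len(pos):
                # genes sharing one TSS position sort by id, so the first
                # entry at that position is the lexicographic tie-winner
                candidates.add(int(np.searchsorted(pos, pos[j], side="left")))
        ids = self._ids[scaffold]
        best = min(candidates, key=lambda j: (abs(point - int(pos[j])), ids[j]))
        return ids[best], point - int(pos[best])


def distance_to_nearest_tss(iv: GenomicInterval | Peak,
                            genes: Sequence[GeneModel] | TSSIndex
                            ) -> tuple[str, int] | None:
    """Nearest gene by TSS distance from the interval's reference point.

    The reference point is the summit for peaks and the midpoint for plain
    intervals — the same summit-based convention as region assignment.
    Distance is signed (point - TSS, genome orientation); 0 means the point
    sits on the TSS.
    """
    if isinstance(iv, Peak):
        scaffold, point = iv.interval.scaffold, iv.summit
    else:
        scaffold, point = iv.scaffold, iv.midpoint
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    return index.nearest(scaffold, point)


def overlap_fraction(set_a: Sequence[GenomicInterval],
                     set_b: Sequence[GenomicInterval]
                     ) -> tuple[int, float | None]:
    """How many intervals of A overlap (>=1 bp) at least one interval of B.

    Returns (count, count/len(A)); the fraction is None when A is empty.
    """
    if not set_a:
        return 0, None
    index = IntervalIndex(set_b)
    count = sum(1 for iv in set_a if index.any_overlap(iv))
    return count, count / len(set_a)
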