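"""Promoter and distal-regulatory-element (DRE) calling from histone marks.

The operational definitions implemented here: a DRE is an H3K4me1 peak
whose summit lies more than 1.5 kb from every TSS; a promoter element is an
H3K4me3 peak whose summit lies within 1.5 kb of some TSS; either kind is
*active* when its source peak overlaps at least one H3K27ac peak (>= 1 bp).
H3K4me1 peaks within 1.5 kb of a TSS are dropped entirely — promoter
elements derive only from H3K4me3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomePartition, IntervalIndex, TSSIndex, assign_peak_region
from .model import GeneModel, GenomicInterval, Peak

#: Summit-to-TSS distance (bp) separating promoter-proximal from distal.
PROXIMAL_DISTANCE = 1500

#: Default |distance| histogram edges (bp): 1.5, 5, 10, 20, 50, 100 kb.
DEFAULT_DISTANCE_EDGES = (1500, 5000, 10000, 20000, 50000, 100000)


@dataclass
class RegulatoryElement:
    """A promoter or DRE with activity status and nearest-gene linkage."""

    source_peak: Peak
    kind: str                      # "promoter" | "DRE"
    active: bool
    condition: str = ""
    nearest_gene: str | None = None
    tss_distance: int | None = None

    @property
    def interval(self) -> GenomicInterval:
        return self.source_peak.interval

    @property
    def summit(self) -> int:
        return self.source_peak.summit


@dataclass
class CooccurrenceSummary:
    """Joint histone-mark occupancy counts in one genomic context.

    In the ``TSS`` context the unit of counting is a TSS and both
    denominators equal the number of TSSs; in the ``intergenic`` context the
    unit is an intergenic peak of the given mark, so each mark carries its
    own denominator.
    """

    context: str
    me3_with_ac: int
    me3_without_ac: int
    me1_with_ac: int
    me1_without_ac: int
    denominator_me3: int
    denominator_me1: int

    def fraction(self, field: str) -> float | None:
        value = getattr(self, field)
        denom = self.denominator_me3 if "me3" in field else self.denominator_me1
        return None if denom == 0 else value / denom


def call_elements(me1_peaks: Sequence[Peak], me3_peaks: Sequence[Peak],
                  ac_peaks: Sequence[Peak], genes: Sequence[GeneModel],
                  condition: str = "",
                  proximal_distance: int = PROXIMAL_DISTANCE
                  ) -> list[RegulatoryElement]:
    """Call promoters (H3K4me3) and DREs (H3K4me1), marking H3K27ac activity.

    Peaks on gene-free scaffolds have no defined TSS distance; H3K4me1
    peaks there still qualify as DREs (trivially distal) but carry no
    target gene, while H3K4me3 peaks there cannot be promoters.
    """
    if not genes:
        raise ValueError("empty gene set: TSS distances are undefined")
    tss_index = TSSIndex(genes)
    ac_index = IntervalIndex([p.interval for p in ac_peaks])

    elements: list[RegulatoryElement] = []
    for peak in me3_peaks:
        hit = tss_index.nearest(peak.interval.scaffold, peak.summit)
        if hit is None:
            continue
        gene_id, dist = hit
        if abs(dist) <= proximal_distance:
            elements.append(RegulatoryElement(
                peak, "promoter", ac_index.any_overlap(peak.interval),
                condition, gene_id, dist,
            ))
    for peak in me1_peaks:
        hit = tss_index.nearest(peak.interval.scaffold, peak.summit)
        if hit is None:
            elements.append(RegulatoryElement(
                peak, "DRE", ac_index.any_overlap(peak.interval),
                condition, None, None,
            ))
        else:
            gene_id, dist = hit
            if abs(dist) > proximal_distance:
                elements.append(RegulatoryElement(
                    peak, "DRE", ac_index.any_overlap(peak.interval),
                    condition, gene_id, dist,
                ))
            # H3K4me1 within the proximal window is dropped, not reclassified
    elements.sort(key=lambda e: (e.interval.scaffold, e.interval.start,
                                 e.kind, e.source_peak.name))
    return elements


def cooccurrence_at_tss(me1_peaks: Sequence[Peak], me3_peaks: Sequence[Peak],
                        ac_peaks: Sequence[Peak], genes: Sequence[GeneModel],
                        window: int = PROXIMAL_DISTANCE) -> CooccurrenceSummary:
    """Joint mark occupancy over TSS windows.

    A mark is present at a TSS iff some peak of that mark overlaps
    [TSS - window, TSS + window). Counts TSSs marked by me3-and-ac,
    me1-and-ac, and by each methyl mark alone; denominator = all TSSs.
    """
    me1_index = IntervalIndex([p.interval for p in me1_peaks])
    me3_index = IntervalIndex([p.interval for p in me3_peaks])
    ac_index = IntervalIndex([p.interval for p in ac_peaks])
    me3_ac = me3_only = me1_ac = me1_only = 0
    n_tss = 0
    for g in genes:
        n_tss += 1
        start = max(0, g.tss - window)
        win = GenomicInterval(g.interval.scaffold, start, g.tss + window)
        has_me1 = me1_index.any_overlap(win)
        has_me3 = me3_index.any_overlap(win)
        has_ac = ac_index.any_overlap(win)
        if has_me3 and has_ac:
            me3_ac += 1
        if has_me3 and not has_ac:
            me3_only += 1
        if has_me1 and has_ac:
            me1_ac += 1
        if has_me1 and not has_ac:
            me1_only += 1
    return CooccurrenceSummary("TSS", me3_ac, me3_only, me1_ac, me1_only,
                               n_tss, n_tss)


def cooccurrence_intergenic(me1_peaks: Sequence[Peak], me3_peaks: Sequence[Peak],
                            ac_peaks: Sequence[Peak],
                            partition: GenomePartition) -> CooccurrenceSummary:
    """Joint mark occupancy among intergenic peaks.

    Restricted to methyl-mark peaks whose summit is labeled intergenic;
    counts those that do / do not overlap an H3K27ac peak. Each mark's
    denominator is its own intergenic peak count.
    """
    ac_index = IntervalIndex([p.interval for p in ac_peaks])

    def split(peaks: Sequence[Peak]) -> tuple[int, int, int]:
        with_ac = without_ac = total = 0
        for p in peaks:
            if assign_peak_region(p, partition) != "intergenic":
                continue
            total += 1
            if ac_index.any_overlap(p.interval):
                with_ac += 1
            else:
                without_ac += 1
        return with_ac, without_ac, total

    me3_ac, me3_only, n_me3 = split(me3_peaks)
    me1_ac, me1_only, n_me1 = split(me1_peaks)
    return CooccurrenceSummary("intergenic", me3_ac, me3_only, me1_ac, me1_only,
                               n_me3, n_me1)


def tss_distance_histogram(elements: Sequence[RegulatoryElement],
                           bin_edges: Sequence[int] = DEFAULT_DISTANCE_EDGES
                           ) -> tuple[np.ndarray, list[str]]:
    """Histogram of |summit-to-TSS| distances for elements with a target.

    ``bin_edges`` define bins [e0,e1), [e1,e2), ..., plus an open top bin
    [e_last, inf). Returns (counts, bin labels).
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError(f"bin edges must be strictly increasing: {edges}")
    dists = [abs(e.tss_distance) for e in elements if e.tss_distance is not None]
    counts, _ = np.histogram(dists, bins=edges + [np.inf])
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)]
    labels.append(f"[{edges[-1]},inf)")
    return counts, labels


def elements_to_frame(elements: Sequence[RegulatoryElement]) -> pd.DataFrame:
    """BED9+-style table: one row per element."""
    rows = []
    for e in elements:
        iv = e.interval
        rows.append({
            "scaffold": iv.scaffold, "start": iv.start, "end": iv.end,
            "name": e.source_peak.name, "signal": e.source_peak.signal,
            "strand": iv.strand, "summit": e.summit, "kind": e.kind,
            "active": int(e.active), "condition": e.condition,
            "nearest_gene": e.nearest_gene if e.nearest_gene is not None else ".",
            "tss_distance": e.tss_distance if e.tss_distance is not None else ".",
        })
    return pd.DataFrame(rows)
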