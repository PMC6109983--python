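"""Two-condition peak and signal comparison.

Differential histone-modification calls follow an operational twofold rule
on library-scaled coverage: a region whose treated/control density ratio
exceeds 2 is *increased*, below 0.5 *decreased*, otherwise *stable*. No
significance testing is performed and the output column is a fold-class,
not a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .elements import RegulatoryElement
from .model import CoverageTrack, GenomicInterval, Peak
from .intervals import IntervalIndex

DEFAULT_PSEUDOCOUNT = 0.5  # density units; stabilizes folds at empty regions


@dataclass
class DynamicsCall:
    """A region's normalized signal in two conditions and its fold-class."""

    region: GenomicInterval
    signal_control: float
    signal_treated: float
    fold_change: float
    klass: str                    # "increased" | "decreased" | "stable"
    presence: str | None = None   # "both" | "treated_only" | "control_only"


def union_regions(peaks_control: Sequence[Peak],
                  peaks_treated: Sequence[Peak]) -> list[GenomicInterval]:
    """Merge the combined peak set into connected components.

    Two peaks connect when they share >= 1 bp (half-open abutment does not
    connect). Each component is emitted as its min-start/max-end envelope,
    so every input peak maps into exactly one region.
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for p in list(peaks_control) + list(peaks_treated):
        by_scaffold.setdefault(p.interval.scaffold, []).append(
            (p.interval.start, p.interval.end))
    regions: list[GenomicInterval] = []
    for scaffold in sorted(by_scaffold):
        spans = sorted(by_scaffold[scaffold])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:               # strict: touching intervals stay apart
                cur_e = max(cur_e, e)
            else:
                regions.append(GenomicInterval(scaffold, cur_s, cur_e))
                cur_s, cur_e = s, e
        regions.append(GenomicInterval(scaffold, cur_s, cur_e))
    return regions


def region_signal(region: GenomicInterval, track: CoverageTrack) -> float:
    """Depth-normalized density: mean per-base coverage x 1e6/library_size."""
    vec = track.values.get(region.scaffold)
    if vec is None:
        raise ValueError(f"region on scaffold {region.scaffold!r} absent from track")
    if track.step == 1:
        n = len(vec)
        if region.end > n:
            raise ValueError(
                f"region {region.scaffold}:{region.start}-{region.end} outside "
                f"track of length {n}")
        mean = float(vec[region.start:region.end].mean())
    else:
        # step-binned track: weight partial bins by their covered width
        n = len(vec) * track.step
        if region.end > n:
            raise ValueError(
                f"region {region.scaffold}:{region.start}-{region.end} outside "
                f"track of length {n}")
        total = 0.0
        b0, b1 = region.start // track.step, (region.end - 1) // track.step
        for b in range(b0, b1 + 1):
            lo = max(region.start, b * track.step)
            hi = min(region.end, (b + 1) * track.step)
            total += float(vec[b]) * (hi - lo)
        mean = total / (region.end - region.start)
    return mean * 1e6 / track.library_size


def classify_dynamics(regions: Sequence[GenomicInterval],
                      track_control: CoverageTrack,
                      track_treated: CoverageTrack,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      inclusive: bool = False) -> list[DynamicsCall]:
    """Fold-classify each region between two library-scaled tracks.

    fold = (treated + pseudocount) / (control + pseudocount). With
    ``inclusive=False`` (generic rule) the boundaries are strict
    (fold > 2 / fold < 0.5); ``inclusive=True`` applies the at-least-twofold
    boundary (fold >= 2 / fold <= 0.5).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    calls = []
    for region in regions:
        sc = region_signal(region, track_control)
        st = region_signal(region, track_treated)
        fold = (st + pseudocount) / (sc + pseudocount)
        if (fold >= 2) if inclusive else (fold > 2):
            klass = "increased"
        elif (fold <= 0.5) if inclusive else (fold < 0.5):
            klass = "decreased"
        else:
            klass = "stable"
        calls.append(DynamicsCall(region, sc, st, fold, klass))
    return calls


def presence_calls(peaks_control: Sequence[Peak],
                   peaks_treated: Sequence[Peak]
                   ) -> tuple[list[str], list[str]]:
    """Condition-specificity label per peak.

    Returns two lists aligned with the inputs: control peaks labeled
    "both"/"control_only", treated peaks "both"/"treated_only". A peak is
    condition-specific iff it overlaps no peak of the other condition.
    """
    treated_index = IntervalIndex([p.interval for p in peaks_treated])
    control_index = IntervalIndex([p.interval for p in peaks_control])
    control_labels = [
        "both" if treated_index.any_overlap(p.interval) else "control_only"
        for p in peaks_control
    ]
    treated_labels = [
        "both" if control_index.any_overlap(p.interval) else "treated_only"
        for p in peaks_treated
    ]
    return control_labels, treated_labels


def dre_h3k27ac_dynamics(dres: Sequence[RegulatoryElement],
                         track_control: CoverageTrack,
                         track_treated: CoverageTrack,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT
                         ) -> list[DynamicsCall]:
    """H3K27ac fold-class at each DRE's source-peak interval.

    Uses the at-least-twofold boundary (fold >= 2 counts as increased), the
    convention for enhancer-activation counting.
    """
    regions = [e.interval for e in dres]
    return classify_dynamics(regions, track_control, track_treated,
                             pseudocount, inclusive=True)
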