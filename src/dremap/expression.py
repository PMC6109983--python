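"""Connecting regulatory elements to transcription.

Covers expression categorization (none/low/medium/high), strand-oriented
TSS metaprofiles, and mean log-expression comparisons across element
classes (active vs poised DRE targets, H3K27ac-only sites, all genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .elements import RegulatoryElement
from .model import CoverageTrack, ExpressionTable, GeneModel

CATEGORIES = ("none", "low", "medium", "high")
DEFAULT_NONE_THRESHOLD = 1.0  # RPKM below this counts as not expressed
DEFAULT_FLANK = 2000          # bp either side of the TSS
DEFAULT_BIN = 50              # bp per metaprofile bin


def categorize_expression(expr: ExpressionTable, condition: str,
                          none_threshold: float = DEFAULT_NONE_THRESHOLD
                          ) -> dict[str, str]:
    """Four expression categories from one condition's RPKM values.

    Genes below ``none_threshold`` are "none"; the rest are ranked by
    (RPKM, gene_id) and split into equal-size tertiles low/medium/high,
    with any remainder going to the lower tertiles.
    """
    values = expr.values_for(condition)
    if len(values) == 0:
        raise ValueError("empty expression table")
    out: dict[str, str] = {}
    expressed = []
    for gene_id, rpkm in values.items():
        if rpkm < none_threshold:
            out[gene_id] = "none"
        else:
            expressed.append((float(rpkm), gene_id))
    expressed.sort()
    n = len(expressed)
    q, r = divmod(n, 3)
    size_low = q + (1 if r >= 1 else 0)
    size_med = q + (1 if r >= 2 else 0)
    for rank, (_, gene_id) in enumerate(expressed):
        if rank < size_low:
            out[gene_id] = "low"
        elif rank < size_low + size_med:
            out[gene_id] = "medium"
        else:
            out[gene_id] = "high"
    return out


@dataclass
class MetaProfile:
    """Per-bin mean signal around the TSS, per expression category.

    Bin centers are bp relative to the TSS in transcription orientation
    (negative = upstream). Categories with no genes are absent from
    ``profiles`` rather than zero.
    """

    bin_centers: np.ndarray
    profiles: dict[str, np.ndarray]
    n_genes: dict[str, int]

    def central_bin(self, category: str) -> float:
        mid = len(self.bin_centers) // 2
        return float(self.profiles[category][mid])

    def value_at(self, category: str, offset: float) -> float:
        """Mean signal in the bin whose center is closest to ``offset``."""
        i = int(np.argmin(np.abs(self.bin_centers - offset)))
        return float(self.profiles[category][i])


def tss_metaprofile(track: CoverageTrack, genes: Sequence[GeneModel],
                    categories: Mapping[str, str],
                    flank: int = DEFAULT_FLANK,
                    bin_size: int = DEFAULT_BIN) -> MetaProfile:
    """Average strand-oriented TSS windows within each expression category.

    Each gene contributes the window [TSS - flank, TSS + flank), reversed
    for "-" genes so upstream is always negative. Windows truncated by a
    scaffold end contribute only their fully covered bins.
    """
    if flank % bin_size != 0:
        raise ValueError(f"flank {flank} not divisible by bin size {bin_size}")
    if track.step != 1:
        raise ValueError("metaprofile requires a per-base track")
    n_bins = 2 * flank // bin_size
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    n_genes: dict[str, int] = {}
    for g in genes:
        cat = categories.get(g.gene_id)
        if cat is None:
            continue
        vec = track.values.get(g.interval.scaffold)
        if vec is None:
            continue
        tss = g.tss
        if g.strand == "+":
            lo, hi = tss - flank, tss + flank
        else:
            # shifted by one so the TSS base maps to the first downstream
            # position after orientation flip
            lo, hi = tss - flank + 1, tss + flank + 1
        window = np.full(2 * flank, np.nan)
        src_lo, src_hi = max(0, lo), min(len(vec), hi)
        if src_hi > src_lo:
            window[src_lo - lo:src_hi - lo] = vec[src_lo:src_hi]
        if g.strand == "-":
            window = window[::-1]
        binned = window.reshape(n_bins, bin_size)
        bin_ok = ~np.isnan(binned).any(axis=1)
        bin_mean = np.where(bin_ok, np.nanmean(np.where(np.isnan(binned), 0, binned), axis=1), 0.0)
        if cat not in sums:
            sums[cat] = np.zeros(n_bins)
            counts[cat] = np.zeros(n_bins, dtype=np.int64)
            n_genes[cat] = 0
        sums[cat] += np.where(bin_ok, bin_mean, 0.0)
        counts[cat] += bin_ok
        n_genes[cat] += 1
    centers = np.arange(n_bins) * bin_size - flank + bin_size / 2
    profiles = {}
    for cat in sums:
        with np.errstate(invalid="ignore"):
            prof = np.where(counts[cat] > 0, sums[cat] / np.maximum(counts[cat], 1), np.nan)
        profiles[cat] = prof
    return MetaProfile(centers, profiles, n_genes)


def mean_log_expression(gene_ids: Iterable[str], expr: ExpressionTable,
                        condition: str, dedup: bool = True
                        ) -> tuple[float | None, int, int]:
    """Mean log2(RPKM + 1) over a gene set.

    Returns (mean, n_used, n_dropped); genes absent from the table are
    dropped and tallied. With ``dedup`` (default) each gene counts once no
    matter how many elements point at it.
    """
    values = expr.values_for(condition)
    ids = list(gene_ids)
    if dedup:
        ids = sorted(set(ids))
    used, dropped = [], 0
    for gid in ids:
        if gid in values.index:
            used.append(np.log2(float(values[gid]) + 1.0))
        else:
            dropped += 1
    if not used:
        return None, 0, dropped
    return float(np.mean(used)), len(used), dropped


def expression_by_element_class(classes: Mapping[str, Sequence],
                                expr: ExpressionTable, condition: str,
                                dedup: bool = True) -> dict[str, dict]:
    """Mean log2(RPKM+1) of nearest genes per element class.

    ``classes`` maps a class label to either regulatory elements (their
    ``nearest_gene`` is used) or plain gene-id strings; a class of all gene
    ids reproduces the global mean. Classes with zero mapped genes are
    absent from the result.
    """
    out: dict[str, dict] = {}
    for label, members in classes.items():
        gene_ids = []
        for m in members:
            if isinstance(m, RegulatoryElement):
                if m.nearest_gene is not None:
                    gene_ids.append(m.nearest_gene)
            elif isinstance(m, str):
                gene_ids.append(m)
            else:
                raise TypeError(f"class {label!r}: unsupported member {type(m)}")
        mean, n_used, n_dropped = mean_log_expression(gene_ids, expr, condition, dedup)
        if mean is None:
            continue
        out[label] = {"mean_log2_rpkm": mean, "n_genes": n_used,
                      "n_dropped": n_dropped}
    return out
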