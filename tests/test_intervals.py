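"""Interval engine: overlap, five-way partition, nearest TSS — each checked
against an independent brute-force oracle on random instances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dremap
from dremap import GeneModel, GenomicInterval, Peak
from dremap.intervals import (PARTITION_LABELS, TSSIndex, assign_peak_region,
                              build_partition, distance_to_nearest_tss,
                              overlap_fraction)
from conftest import make_genes, make_peak


# -- brute-force oracles ----------------------------------------------------

def brute_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    if a.scaffold != b.scaffold:
        return False
    shared = set(range(a.start, a.end)) & set(range(b.start, b.end))
    return len(shared) > 0


def brute_partition_label(genes, pos: int, scaffold: str) -> str:
    """Per-base labeling by explicit priority, windows enumerated directly."""
    def in_window(s, e):
        return s <= pos < e
    for g in genes:
        if g.interval.scaffold != scaffold:
            continue
        if g.strand == "+":
            s, e = g.tss - 1000, g.tss + 200
        else:
            s, e = g.tss - 199, g.tss + 1001
        if in_window(s, e):
            return "promoter-TSS"
    for g in genes:
        if g.interval.scaffold == scaffold:
            exons = g.exons if g.exons else [g.interval]
            if any(in_window(ex.start, ex.end) for ex in exons):
                return "exon"
    for g in genes:
        if g.interval.scaffold == scaffold and in_window(g.interval.start,
                                                         g.interval.end):
            return "intron"
    for g in genes:
        if g.interval.scaffold != scaffold:
            continue
        if g.strand == "+":
            s, e = g.interval.end - 200, g.interval.end + 1000
        else:
            s, e = g.interval.start - 1000, g.interval.start + 200
        if in_window(s, e):
            return "TTS"
    return "intergenic"


def brute_nearest_tss(genes, scaffold: str, point: int):
    best = None
    for g in genes:
        if g.interval.scaffold != scaffold:
            continue
        key = (abs(point - g.tss), g.gene_id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is None:
        return None
    return best[1].gene_id, point - best[1].tss


def random_intervals(rng, n, scaffolds=("s1", "s2"), span=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(GenomicInterval(scaffolds[rng.integers(0, len(scaffolds))],
                                   start, start + int(rng.integers(1, max_len))))
    return out


def random_gene_layout(rng, scaffold_len=8000, max_genes=6):
    genes, cursor, i = [], 0, 0
    while cursor < scaffold_len - 600 and i < max_genes:
        start = cursor + int(rng.integers(100, 800))
        length = int(rng.integers(300, 1500))
        end = min(start + length, scaffold_len)
        if end - start < 50:
            break
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        e1 = (end - start) // 3
        exons = [GenomicInterval("s", start, start + e1, strand),
                 GenomicInterval("s", end - e1, end, strand)]
        genes.append(GeneModel(f"g{i:02d}", GenomicInterval("s", start, end, strand),
                               exons))
        cursor = end
        i += 1
    return genes


# -- overlaps ---------------------------------------------------------------

class TestOverlaps:
    def test_examples(self):
        a = GenomicInterval("s", 0, 100)
        assert dremap.overlaps(a, GenomicInterval("s", 50, 150))
        assert not dremap.overlaps(a, GenomicInterval("s", 100, 200))  # abutting
        assert not dremap.overlaps(a, GenomicInterval("t", 50, 150))

    @given(st.integers(0, 200), st.integers(1, 50),
           st.integers(0, 200), st.integers(1, 50))
    def test_symmetric_and_matches_brute_force(self, s1, l1, s2, l2):
        a = GenomicInterval("s", s1, s1 + l1)
        b = GenomicInterval("s", s2, s2 + l2)
        assert dremap.overlaps(a, b) == dremap.overlaps(b, a) == brute_overlaps(a, b)

    def test_random_pairs_against_brute_force(self, rng):
        ivs = random_intervals(rng, 120, span=2000)
        for a in ivs[:60]:
            for b in ivs[60:]:
                assert dremap.overlaps(a, b) == brute_overlaps(a, b)


# -- partition --------------------------------------------------------------

class TestPartition:
    def test_worked_example(self):
        g = GeneModel("g1", GenomicInterval("s", 5000, 8000, "+"),
                      [GenomicInterval("s", 5000, 8000, "+")])
        p = build_partition([g], {"s": 20000})
        assert p.segments("s") == [
            (0, 4000, "intergenic"), (4000, 5200, "promoter-TSS"),
            (5200, 8000, "exon"), (8000, 9000, "TTS"),
            (9000, 20000, "intergenic"),
        ]
        assert p.label_at("s", 7900) == "exon"   # exon outranks TTS
        assert p.label_at("s", 4500) == "promoter-TSS"

    def test_empty_gene_set_is_all_intergenic(self):
        p = build_partition([], {"s": 5000})
        assert p.segments("s") == [(0, 5000, "intergenic")]

    def test_gene_beyond_scaffold_end_is_an_error(self):
        g = make_genes([("s", 100, 900, "+")])[0]
        with pytest.raises(ValueError, match="beyond scaffold"):
            build_partition([g], {"s": 500})

    def test_partition_tiles_every_base_once(self, rng):
        for _ in range(10):
            genes = random_gene_layout(rng)
            p = build_partition(genes, {"s": 8000})
            assert sum(e - s for s, e, _ in p.segments("s")) == 8000

    def test_per_base_agreement_with_brute_force(self, rng):
        for _ in range(15):
            genes = random_gene_layout(rng)
            p = build_partition(genes, {"s": 8000})
            for pos in rng.integers(0, 8000, size=200):
                assert p.label_at("s", int(pos)) == \
                    brute_partition_label(genes, int(pos), "s")


class TestAssignPeakRegion:
    def test_summit_labeling(self):
        g = GeneModel("g1", GenomicInterval("s", 5000, 8000, "+"),
                      [GenomicInterval("s", 5000, 8000, "+")])
        p = build_partition([g], {"s": 20000, "bare": 1000})
        assert assign_peak_region(make_peak("s", 4000, 5000, summit=500), p) \
            == "promoter-TSS"
        assert assign_peak_region(make_peak("bare", 100, 300), p) == "intergenic"
        with pytest.raises(IndexError):
            assign_peak_region(make_peak("bare", 900, 1200, summit=250), p)

    def test_planted_category_mix_recovered(self, noise_free_sim):
        """Summit labels over the planted peaks match the generator design:
        promoter-mark summits in promoter-TSS, enhancer summits intergenic."""
        ds = noise_free_sim
        p = build_partition(ds.genes, ds.scaffold_lengths)
        me3 = [assign_peak_region(pk, p) for pk in ds.peaks[("H3K4me3", "control")]]
        me1 = [assign_peak_region(pk, p) for pk in ds.peaks[("H3K4me1", "control")]]
        assert me3.count("promoter-TSS") / len(me3) > 0.98
        assert me1.count("intergenic") / len(me1) > 0.98


# -- nearest TSS ------------------------------------------------------------

class TestNearestTSS:
    def test_examples_and_tie_rule(self):
        genes = make_genes([("s", 900, 1600, "+"), ("s", 1200, 1900, "+")],
                           ids=["ga", "gb"])
        assert distance_to_nearest_tss(GenomicInterval("s", 950, 1051), genes) \
            == ("ga", 100)
        tie_genes = make_genes([("s", 900, 1600, "+"), ("s", 1100, 1900, "+")],
                               ids=["zz", "aa"])
        gene, dist = distance_to_nearest_tss(GenomicInterval("s", 950, 1051),
                                             tie_genes)
        assert gene == "aa" and dist == -100

    def test_peak_uses_summit_not_midpoint(self):
        genes = make_genes([("s", 1000, 2000, "+")])
        peak = make_peak("s", 0, 1000, summit=999)
        assert distance_to_nearest_tss(peak, genes) == ("g000", -1)

    def test_no_same_scaffold_gene_returns_none(self):
        genes = make_genes([("s", 100, 600, "+")])
        assert distance_to_nearest_tss(GenomicInterval("t", 0, 10), genes) is None

    def test_random_agreement_with_exhaustive_search(self, rng):
        genes = []
        for i in range(60):
            scaf = f"s{rng.integers(1, 4)}"
            start = int(rng.integers(0, 50_000))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            genes.append(GeneModel(f"g{i:03d}",
                                   GenomicInterval(scaf, start, start + 500, strand)))
        index = TSSIndex(genes)
        for _ in range(300):
            scaf = f"s{rng.integers(1, 5)}"
            point = int(rng.integers(0, 50_000))
            assert index.nearest(scaf, point) == brute_nearest_tss(genes, scaf, point)

    def test_invariant_under_gene_order(self, rng):
        genes = make_genes([("s", 100, 600, "+"), ("s", 5000, 6000, "-"),
                            ("s", 9000, 9500, "+")])
        shuffled = list(genes)
        rng.shuffle(shuffled)
        iv = GenomicInterval("s", 4000, 4001)
        assert distance_to_nearest_tss(iv, genes) == \
            distance_to_nearest_tss(iv, shuffled)


# -- overlap fraction -------------------------------------------------------

class TestOverlapFraction:
    def test_identity_and_disjoint(self):
        a = [GenomicInterval("s", 0, 10), GenomicInterval("s", 20, 30)]
        assert overlap_fraction(a, a) == (2, 1.0)
        b = [GenomicInterval("s", 100, 110)]
        assert overlap_fraction(a, b) == (0, 0.0)
        assert overlap_fraction([], a) == (0, None)

    def test_random_agreement_with_brute_force(self, rng):
        a = random_intervals(rng, 80)
        b = random_intervals(rng, 80)
        count, frac = overlap_fraction(a, b)
        brute = sum(1 for x in a if any(brute_overlaps(x, y) for y in b))
        assert count == brute and frac == pytest.approx(brute / len(a))
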