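"""Promoter/DRE calling, activity marking, co-occurrence and distances."""

import numpy as np
import pytest

import dremap
from dremap import GenomicInterval
from dremap.elements import (call_elements, cooccurrence_at_tss,
                             cooccurrence_intergenic, tss_distance_histogram)
from dremap.intervals import build_partition
from conftest import make_genes, make_peak


@pytest.fixture()
def one_gene():
    # "+" gene with TSS at 50_000 on a 200 kb scaffold
    return make_genes([("s", 50_000, 55_000, "+")], ids=["gene1"])


class TestCallElements:
    def test_distal_me1_with_ac_is_active_dre(self, one_gene):
        me1 = [make_peak("s", 54_500, 55_500, "e1", summit=500)]  # 5 kb from TSS
        ac = [make_peak("s", 54_800, 55_200, "a1")]
        (el,) = call_elements(me1, [], ac, one_gene)
        assert el.kind == "DRE" and el.active
        assert el.nearest_gene == "gene1" and el.tss_distance == 5000

    def test_proximal_me1_is_dropped_not_reclassified(self, one_gene):
        me1 = [make_peak("s", 50_300, 51_300, "e1", summit=500)]  # 800 bp
        assert call_elements(me1, [], [], one_gene) == []

    def test_me3_near_tss_is_promoter(self, one_gene):
        me3 = [make_peak("s", 49_000, 50_200, "m3", summit=1000)]
        (el,) = call_elements([], me3, [], one_gene)
        assert el.kind == "promoter" and not el.active
        assert el.tss_distance == 0

    def test_me3_far_from_tss_is_no_element(self, one_gene):
        me3 = [make_peak("s", 80_000, 81_000, "m3", summit=500)]
        assert call_elements([], me3, [], one_gene) == []

    def test_boundary_exactly_1500_bp(self, one_gene):
        # promoter rule is <= 1500, DRE rule is > 1500
        me3 = [make_peak("s", 48_000, 48_501, "m3", summit=500)]  # exactly 1500
        (el,) = call_elements([], me3, [], one_gene)
        assert el.kind == "promoter"
        me1 = [make_peak("s", 48_000, 48_501, "m1", summit=500)]
        assert call_elements(me1, [], [], one_gene) == []

    def test_empty_gene_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty gene set"):
            call_elements([], [], [], [])

    def test_gene_free_scaffold_dre_has_no_target(self, one_gene):
        me1 = [make_peak("bare", 10_000, 11_000, "e1", summit=500)]
        (el,) = call_elements(me1, [], [], one_gene)
        assert el.kind == "DRE" and el.nearest_gene is None

    def test_active_flag_monotone_under_added_ac(self, one_gene, rng):
        me1 = [make_peak("s", 30_000 + 3000 * i, 31_000 + 3000 * i, f"e{i}",
                         summit=500) for i in range(5)]
        ac = [make_peak("s", 30_100, 30_400, "a0")]
        before = {e.source_peak.name: e.active
                  for e in call_elements(me1, [], ac, one_gene)}
        more_ac = ac + [make_peak("s", int(rng.integers(25_000, 45_000)), 46_000,
                                  f"extra{k}") for k in range(3)]
        after = {e.source_peak.name: e.active
                 for e in call_elements(me1, [], more_ac, one_gene)}
        for name, was_active in before.items():
            if was_active:
                assert after[name]

    def test_element_calls_invariant_under_peak_order(self, one_gene, rng):
        me1 = [make_peak("s", 30_000 + 2500 * i, 31_000 + 2500 * i, f"e{i}",
                         summit=400) for i in range(8)]
        me3 = [make_peak("s", 49_200, 50_400, "m3", summit=800)]
        ac = [make_peak("s", 30_200, 30_800, "a1"),
              make_peak("s", 35_200, 35_600, "a2")]
        ref = call_elements(me1, me3, ac, one_gene)
        for _ in range(3):
            m1, m3_, a = list(me1), list(me3), list(ac)
            rng.shuffle(m1), rng.shuffle(a)
            assert call_elements(m1, m3_, a, one_gene) == ref

    def test_noise_free_recovery_is_exact(self, noise_free_sim):
        ds = noise_free_sim
        els = call_elements(ds.peaks[("H3K4me1", "control")],
                            ds.peaks[("H3K4me3", "control")],
                            ds.peaks[("H3K27ac", "control")],
                            ds.genes, "control")
        scores = dremap.truth_compare(els, ds.truth)
        for kind in ("promoter", "active_DRE", "poised_DRE"):
            assert scores[kind].precision == 1.0
            assert scores[kind].recall == 1.0


class TestCooccurrence:
    def brute_tss(self, me1, me3, ac, genes, window=1500):
        counts = dict(me3_ac=0, me3_only=0, me1_ac=0, me1_only=0)
        for g in genes:
            win = GenomicInterval(g.interval.scaffold, max(0, g.tss - window),
                                  g.tss + window)
            has = {name: any(dremap.overlaps(p.interval, win) for p in plist)
                   for name, plist in (("me1", me1), ("me3", me3), ("ac", ac))}
            if has["me3"] and has["ac"]:
                counts["me3_ac"] += 1
            if has["me3"] and not has["ac"]:
                counts["me3_only"] += 1
            if has["me1"] and has["ac"]:
                counts["me1_ac"] += 1
            if has["me1"] and not has["ac"]:
                counts["me1_only"] += 1
        return counts

    def test_no_peaks_all_zero(self, one_gene=None):
        genes = make_genes([("s", 50_000, 55_000, "+")])
        co = cooccurrence_at_tss([], [], [], genes)
        assert (co.me3_with_ac, co.me1_with_ac, co.me3_without_ac,
                co.me1_without_ac) == (0, 0, 0, 0)
        assert co.denominator_me3 == 1

    def test_single_tss_with_both_marks(self):
        genes = make_genes([("s", 50_000, 55_000, "+")])
        me3 = [make_peak("s", 49_500, 50_500, "m3")]
        ac = [make_peak("s", 49_800, 50_100, "a")]
        co = cooccurrence_at_tss([], me3, ac, genes)
        assert co.me3_with_ac == 1 and co.me3_without_ac == 0

    def test_tss_context_matches_brute_force_on_random_layouts(self, rng):
        for _ in range(10):
            starts = np.sort(rng.choice(np.arange(2000, 40_000, 1200), size=6,
                                        replace=False))
            genes = make_genes([("s", int(s), int(s) + 800,
                                 "+" if rng.integers(0, 2) else "-")
                                for s in starts])
            def rand_peaks(n, tag):
                out = []
                for i in range(n):
                    start = int(rng.integers(0, 45_000))
                    out.append(make_peak("s", start, start + int(rng.integers(200, 2000)),
                                         f"{tag}{i}"))
                return out
            me1, me3, ac = rand_peaks(8, "m1"), rand_peaks(8, "m3"), rand_peaks(8, "ac")
            co = cooccurrence_at_tss(me1, me3, ac, genes)
            brute = self.brute_tss(me1, me3, ac, genes)
            assert (co.me3_with_ac, co.me3_without_ac, co.me1_with_ac,
                    co.me1_without_ac) == (brute["me3_ac"], brute["me3_only"],
                                           brute["me1_ac"], brute["me1_only"])

    def test_intergenic_context(self, rng):
        genes = make_genes([("s", 20_000, 24_000, "+")])
        partition = build_partition(genes, {"s": 60_000})
        me1 = [make_peak("s", 40_000, 41_000, "far", summit=500),
               make_peak("s", 20_500, 21_500, "genic", summit=500)]
        ac = [make_peak("s", 40_200, 40_600, "a")]
        co = cooccurrence_intergenic(me1, [], ac, partition)
        assert co.context == "intergenic"
        assert co.denominator_me1 == 1          # only the distal peak counts
        assert co.me1_with_ac == 1 and co.me1_without_ac == 0
        all_genic = cooccurrence_intergenic([me1[1]], [], ac, partition)
        assert all_genic.denominator_me1 == 0


class TestDistanceHistogram:
    def make_dre(self, dist):
        peak = make_peak("s", 1000, 2000, f"d{dist}", summit=500)
        return dremap.RegulatoryElement(peak, "DRE", False, "", "g1", dist)

    def test_single_dre_in_expected_bin(self):
        counts, labels = tss_distance_histogram([self.make_dre(7000)])
        assert dict(zip(labels, counts))["[5000,10000)"] == 1
        assert counts.sum() == 1

    def test_empty_and_unsorted_edges(self):
        counts, _ = tss_distance_histogram([])
        assert counts.sum() == 0
        with pytest.raises(ValueError, match="increasing"):
            tss_distance_histogram([], bin_edges=(5000, 1500))

    def test_known_mixture_proportions_recovered(self, rng):
        """5000 distances from a fixed mixture over the histogram bins land in
        the right bins within +/-3% of the mixture weights."""
        edges = [1500, 5000, 10_000, 20_000, 50_000, 100_000, 200_000]
        weights = np.array([0.10, 0.35, 0.25, 0.15, 0.10, 0.05])
        n = 5000
        bins = rng.choice(len(weights), size=n, p=weights)
        dres = [self.make_dre(int(rng.integers(edges[b], edges[b + 1])))
                for b in bins]
        counts, _ = tss_distance_histogram(dres, bin_edges=edges[:-1])
        assert counts.sum() == n
        observed = counts[:len(weights)] / n
        np.testing.assert_allclose(observed, weights, atol=0.03)
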