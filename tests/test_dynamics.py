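"""Two-condition comparison: union regions, scaled signals, fold classes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dremap
from dremap import CoverageTrack, GenomicInterval
from dremap.dynamics import (classify_dynamics, dre_h3k27ac_dynamics,
                             presence_calls, region_signal, union_regions)
from conftest import make_peak


def brute_components(peaks):
    """Connected components under >=1 bp overlap via union-find."""
    items = [(p.interval.scaffold, p.interval.start, p.interval.end)
             for p in peaks]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            si, s1, e1 = items[i]
            sj, s2, e2 = items[j]
            if si == sj and s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i, (scaf, s, e) in enumerate(items):
        groups.setdefault(find(i), []).append((scaf, s, e))
    return sorted((g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
                  for g in groups.values())


def flat_track(length=1000, value=0.0, library_size=1e6, scaffold="s"):
    return CoverageTrack({scaffold: np.full(length, value)}, library_size)


class TestUnionRegions:
    def test_overlapping_pair_merges(self):
        regions = union_regions([make_peak("s", 0, 100)], [make_peak("s", 50, 150)])
        assert regions == [GenomicInterval("s", 0, 150)]

    def test_abutting_peaks_stay_separate(self):
        regions = union_regions([make_peak("s", 0, 100)], [make_peak("s", 100, 200)])
        assert [(r.start, r.end) for r in regions] == [(0, 100), (100, 200)]

    def test_random_sets_match_union_find_oracle(self, rng):
        for _ in range(20):
            peaks = [make_peak(f"s{rng.integers(1, 3)}", int(s), int(s) + int(w))
                     for s, w in zip(rng.integers(0, 3000, size=40),
                                     rng.integers(1, 400, size=40))]
            k = int(rng.integers(0, 40))
            got = union_regions(peaks[:k], peaks[k:])
            assert sorted((r.scaffold, r.start, r.end) for r in got) == \
                brute_components(peaks)


class TestRegionSignal:
    def test_identity_scaling(self):
        track = flat_track(value=2.0, library_size=1e6)
        assert region_signal(GenomicInterval("s", 100, 200), track) == 2.0

    def test_zero_coverage(self):
        assert region_signal(GenomicInterval("s", 0, 50), flat_track()) == 0.0

    def test_region_outside_track_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            region_signal(GenomicInterval("s", 900, 1100), flat_track())

    def test_matches_per_base_arithmetic(self, rng):
        vec = rng.uniform(0, 10, size=2000)
        track = CoverageTrack({"s": vec}, library_size=5e5)
        for _ in range(50):
            start = int(rng.integers(0, 1500))
            end = start + int(rng.integers(1, 500))
            expect = vec[start:end].mean() * 1e6 / 5e5
            assert region_signal(GenomicInterval("s", start, end), track) \
                == pytest.approx(expect)

    def test_step_binned_track_matches_densified(self, rng):
        bins = rng.uniform(0, 5, size=100)
        stepped = CoverageTrack({"s": bins}, library_size=1e6, step=10)
        dense = CoverageTrack({"s": np.repeat(bins, 10)}, library_size=1e6)
        for _ in range(30):
            start = int(rng.integers(0, 900))
            end = start + int(rng.integers(1, 100))
            iv = GenomicInterval("s", start, end)
            assert region_signal(iv, stepped) == pytest.approx(region_signal(iv, dense))


class TestClassifyDynamics:
    def test_threshold_rule(self):
        ctrl = flat_track(value=1.0)
        trt = flat_track(value=3.0)
        (call,) = classify_dynamics([GenomicInterval("s", 0, 100)], ctrl, trt,
                                    pseudocount=0.0)
        assert call.fold_change == pytest.approx(3.0)
        assert call.klass == "increased"

    def test_equal_signals_are_stable(self):
        track = flat_track(value=2.0)
        (call,) = classify_dynamics([GenomicInterval("s", 0, 100)], track, track,
                                    pseudocount=0.0)
        assert call.fold_change == pytest.approx(1.0) and call.klass == "stable"

    def test_boundary_strict_vs_inclusive(self):
        ctrl, trt = flat_track(value=1.0), flat_track(value=2.0)
        region = [GenomicInterval("s", 0, 100)]
        strict = classify_dynamics(region, ctrl, trt, pseudocount=0.0)[0]
        inclusive = classify_dynamics(region, ctrl, trt, pseudocount=0.0,
                                      inclusive=True)[0]
        assert strict.klass == "stable" and inclusive.klass == "increased"

    def test_negative_pseudocount_is_an_error(self):
        with pytest.raises(ValueError, match="pseudocount"):
            classify_dynamics([], flat_track(), flat_track(), pseudocount=-1)

    @given(st.floats(0, 20), st.floats(0, 20))
    def test_antisymmetric_under_track_swap(self, a, b):
        ctrl, trt = flat_track(value=a), flat_track(value=b)
        region = [GenomicInterval("s", 0, 100)]
        fwd = classify_dynamics(region, ctrl, trt, pseudocount=0.5)[0]
        rev = classify_dynamics(region, trt, ctrl, pseudocount=0.5)[0]
        expected = {"increased": "decreased", "decreased": "increased",
                    "stable": "stable"}[fwd.klass]
        assert rev.klass == expected
        assert rev.fold_change == pytest.approx(1 / fwd.fold_change)

    def test_fold_invariant_under_joint_rescaling(self, rng):
        vec_c, vec_t = rng.uniform(0, 8, 500), rng.uniform(0, 8, 500)
        region = [GenomicInterval("s", 50, 450)]
        base = classify_dynamics(
            region, CoverageTrack({"s": vec_c}, 2e5),
            CoverageTrack({"s": vec_t}, 3e5), 0.5)[0]
        scaled = classify_dynamics(
            region, CoverageTrack({"s": vec_c * 7}, 2e5 * 7),
            CoverageTrack({"s": vec_t * 7}, 3e5 * 7), 0.5)[0]
        assert scaled.fold_change == pytest.approx(base.fold_change)
        assert scaled.klass == base.klass

    def test_planted_fourfold_gains_recovered(self, default_sim):
        """At depth 30 with Poisson noise, >=95% of planted fourfold gains
        classify as increased and <=5% of stable regions as changed."""
        ds = default_sim
        regions = [GenomicInterval(r.scaffold, r.start, r.end)
                   for r in ds.truth.elements.itertuples() if r.kind != "promoter"]
        calls = classify_dynamics(regions, ds.tracks[("H3K27ac", "control")],
                                  ds.tracks[("H3K27ac", "treated")], 0.5)
        rec = dremap.dynamics_recovery(calls, ds.truth)
        assert rec["gain"]["increased_fraction"] >= 0.95
        assert rec["stable"]["increased_fraction"] <= 0.05
        assert rec["stable"]["n_planted"] >= 500


class TestPresenceCalls:
    def test_identical_sets_all_both(self):
        peaks = [make_peak("s", 0, 100), make_peak("s", 500, 600)]
        ctrl, trt = presence_calls(peaks, list(peaks))
        assert ctrl == ["both", "both"] and trt == ["both", "both"]

    def test_disjoint_sets_all_specific(self):
        ctrl, trt = presence_calls([make_peak("s", 0, 100)],
                                   [make_peak("s", 500, 600)])
        assert ctrl == ["control_only"] and trt == ["treated_only"]

    def test_partition_property_and_brute_force(self, rng):
        for _ in range(10):
            a = [make_peak("s", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 5000, 30), rng.integers(1, 300, 30))]
            b = [make_peak("s", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 5000, 30), rng.integers(1, 300, 30))]
            ctrl, trt = presence_calls(a, b)
            assert len(ctrl) == len(a) and len(trt) == len(b)
            for label, p in zip(ctrl, a):
                brute = any(dremap.overlaps(p.interval, q.interval) for q in b)
                assert (label == "both") == brute


class TestDreDynamics:
    def test_fivefold_density_is_increased(self):
        ctrl = flat_track(value=1.0)
        trt = flat_track(value=5.0)
        el = dremap.RegulatoryElement(make_peak("s", 100, 300), "DRE", False)
        (call,) = dre_h3k27ac_dynamics([el], ctrl, trt)
        assert call.klass == "increased"

    def test_zero_coverage_both_sides_is_stable(self):
        el = dremap.RegulatoryElement(make_peak("s", 100, 300), "DRE", False)
        (call,) = dre_h3k27ac_dynamics([el], flat_track(), flat_track(),
                                       pseudocount=0.1)
        assert call.fold_change == pytest.approx(1.0) and call.klass == "stable"
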