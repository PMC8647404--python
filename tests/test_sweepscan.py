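"""Window geometry, diversity/Fst estimators, region calling, gene overlap."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import balding_nichols_genotypes
from popsweep.sweepscan import (
    SweepConfig,
    SweepRegion,
    WindowStat,
    call_selected_regions,
    intersect_genes,
    make_windows,
    scan,
    venn_counts,
    window_fst,
    window_pi,
)


class TestMakeWindows:
    @pytest.mark.parametrize("length,expected", [
        (250_000, 16),           # floor((250000-100000)/10000) + 1
        (100_000, 1),
        (99_999, 0),
    ])
    def test_window_counts(self, length, expected):
        assert len(make_windows(length, SweepConfig())) == expected

    def test_geometry(self):
        w = make_windows(130_000, SweepConfig())
        assert w == [(0, 100_000), (10_000, 110_000), (20_000, 120_000),
                     (30_000, 130_000)]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SweepConfig(window_bp=1000, step_bp=2000)
        with pytest.raises(ValueError):
            SweepConfig(pi_ratio_low=1.5)


def _pi_oracle(genotypes, window_bp):
    """O(n^2) pairwise-difference counter over expanded allele lists."""
    total = 0.0
    for site in genotypes.T:
        alleles = []
        for g in site:
            if g >= 0:
                alleles += [1] * int(g) + [0] * (2 - int(g))
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(abs(a - b) for a, b in itertools.combinations(alleles, 2))
        total += diffs / (n * (n - 1) / 2)
    return total / window_bp


class TestWindowPi:
    def test_closed_form_single_site(self):
        # k=2 alt among n=4 alleles: pi_site = 2*(1/2)*(1/2)*(4/3) = 2/3
        g = np.array([[1], [1]])
        assert window_pi(g, 100) == pytest.approx((2 / 3) / 100)

    def test_monomorphic_window_is_zero(self):
        assert window_pi(np.zeros((5, 8), dtype=int), 1000) == 0.0
        assert window_pi(np.full((5, 8), 2), 1000) == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        g = rng.integers(-1, 3, size=(12, 50)).astype(np.int8)
        assert window_pi(g, 10_000) == pytest.approx(
            _pi_oracle(g, 10_000), abs=1e-12)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            window_pi(np.zeros((2, 2), dtype=int), 0)

    @given(arrays(np.int8, (6, 20), elements=st.integers(-1, 2)))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_sample_order_and_allele_relabel(self, g):
        base = window_pi(g, 1000)
        perm = np.random.default_rng(0).permutation(g.shape[0])
        assert window_pi(g[perm], 1000) == pytest.approx(base, abs=1e-12)
        flipped = np.where(g >= 0, 2 - g, -1).astype(np.int8)
        assert window_pi(flipped, 1000) == pytest.approx(base, abs=1e-12)


class TestWindowFst:
    def test_fixed_difference_is_one(self):
        ga = np.full((10, 1), 2)
        gb = np.zeros((10, 1), dtype=int)
        assert window_fst(ga, gb) == pytest.approx(1.0)

    def test_hand_computed_negative_value(self):
        # p1 = p2 = 0.5 with n1 = n2 = 10 alleles:
        # (0 - 0.25/9 - 0.25/9) / 0.5 = -0.1111...
        g = np.array([[0], [1], [1], [1], [2]])
        assert window_fst(g, g.copy()) == pytest.approx(-1 / 9, abs=1e-9)

    def test_undefined_when_no_variation(self):
        g = np.zeros((5, 3), dtype=int)
        assert window_fst(g, g) is None

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        ga = rng.integers(0, 3, size=(8, 40))
        gb = rng.integers(0, 3, size=(6, 40))
        for est in ("hudson", "weir_cockerham"):
            assert window_fst(ga, gb, est) == pytest.approx(
                window_fst(gb, ga, est), abs=1e-12)

    def test_split_population_has_near_zero_fst(self):
        """Pooling halves of one population: E[Fst] = 0."""
        rng = np.random.default_rng(11)
        g = balding_nichols_genotypes(rng, 20_000, [0.05], 40)
        assert abs(window_fst(g[:20], g[20:])) < 0.02

    def test_weir_cockerham_agrees_with_hudson_at_large_n(self):
        rng = np.random.default_rng(13)
        g = balding_nichols_genotypes(rng, 20_000, [0.1, 0.1], 50)
        h = window_fst(g[:50], g[50:], "hudson")
        w = window_fst(g[:50], g[50:], "weir_cockerham")
        assert h == pytest.approx(w, abs=0.01)


class TestScan:
    def test_empty_input_all_ineligible(self):
        stats = scan(np.zeros((4, 0), dtype=np.int8), np.array([], dtype=int),
                     "c1", 120_000, [0, 1], [2, 3])
        assert stats and all(not w.eligible for w in stats)

    def test_single_window_composition(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 100_001), 30, replace=False))
        cfg = SweepConfig(min_sites_per_window=1)
        (w,) = scan(g, pos, "c1", 100_000, list(range(5)), list(range(5, 10)),
                    cfg)
        assert w.pi_a == pytest.approx(window_pi(g[:5], 100_000))
        assert w.pi_b == pytest.approx(window_pi(g[5:], 100_000))
        assert w.fst == pytest.approx(window_fst(g[:5], g[5:]))

    def test_site_to_window_membership(self):
        """A variant at position p contributes to exactly the windows whose
        half-open span contains p - 1."""
        cfg = SweepConfig(window_bp=100, step_bp=30, min_sites_per_window=1)
        positions = np.array([1, 30, 31, 100, 101, 150, 190])
        g = np.ones((4, len(positions)), dtype=np.int8)
        g[0] = 0    # polymorphic everywhere
        stats = scan(g, positions, "c1", 220, [0, 1], [2, 3], cfg)
        for w in stats:
            expected = int(((positions - 1 >= w.start)
                            & (positions - 1 < w.end)).sum())
            assert w.n_sites == expected

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            scan(np.zeros((2, 2), dtype=np.int8), np.array([5, 1]), "c1",
                 100_000, [0], [1])


def _wstat(fst, ratio, chrom="c1", start=0, end=100_000, eligible=True):
    return WindowStat(chrom, start, end, 50, 1e-3, 1e-3, fst, ratio, eligible)


class TestRegionCalling:
    @pytest.mark.parametrize("fst,ratio,wanted", [
        (0.30, 2.5, True),
        (0.30, 1.0, False),
        (0.20, 3.0, False),
        (0.30, 0.4, True),
        (0.25, 2.5, False),      # threshold is strict
    ])
    def test_threshold_logic(self, fst, ratio, wanted):
        regions = call_selected_regions([_wstat(fst, ratio)])
        assert bool(regions) == wanted

    def test_direction_names_low_diversity_population(self):
        (r1,) = call_selected_regions([_wstat(0.4, 3.0)])
        assert r1.direction == "B"
        (r2,) = call_selected_regions([_wstat(0.4, 0.3)])
        assert r2.direction == "A"

    def test_overlapping_windows_merge_maximally(self):
        stats = [_wstat(0.4, 3.0, start=s, end=s + 100_000)
                 for s in (0, 10_000, 20_000, 200_000)]
        regions = call_selected_regions(stats)
        assert [(r.start, r.end, r.n_windows) for r in regions] == \
            [(0, 120_000, 3), (200_000, 300_000, 1)]

    def test_opposite_directions_not_merged(self):
        stats = [_wstat(0.4, 3.0, start=0, end=100_000),
                 _wstat(0.4, 0.3, start=10_000, end=110_000)]
        assert len(call_selected_regions(stats)) == 2

    def test_ineligible_windows_never_selected(self):
        assert not call_selected_regions([_wstat(0.9, 9.0, eligible=False)])

    def test_raising_fst_min_is_monotone(self):
        rng = np.random.default_rng(2)
        stats = [_wstat(float(f), float(r), start=s * 10_000,
                        end=s * 10_000 + 100_000)
                 for s, (f, r) in enumerate(zip(rng.uniform(0, 0.6, 40),
                                                rng.uniform(0.1, 4.0, 40)))]
        covered_prev = None
        for fst_min in (0.1, 0.25, 0.4, 0.55):
            regions = call_selected_regions(
                stats, SweepConfig(fst_min=fst_min))
            covered = set()
            for r in regions:
                covered.update(range(r.start, r.end, 10_000))
            if covered_prev is not None:
                assert covered <= covered_prev
            covered_prev = covered


class TestGeneIntersection:
    def test_halfopen_overlap_rules(self, toy):
        ann, _ = toy
        inc = SweepRegion("c1", 8100, 8400, "A", 1)     # overlaps gP by 223 bp
        (r1,), genes = intersect_genes([inc], ann)
        assert genes == {"gP"}
        adj = SweepRegion("c1", 8323, 9000, "A", 1)     # book-ended: excluded
        (_, ), genes2 = intersect_genes([adj], ann)
        assert genes2 == set()

    def test_matches_quadratic_all_pairs_oracle(self, small_dataset):
        from popsweep.annotate import load_annotation
        ds, paths = small_dataset
        ann = load_annotation(paths["gff3"], paths["ref"])
        rng = np.random.default_rng(8)
        regions = [SweepRegion("chr1", int(s), int(s) + 9_000, "A", 1)
                   for s in rng.integers(0, 90_000, size=5)]
        _, genes = intersect_genes(regions, ann)
        expected = set()
        for region in regions:
            for g in ds.genes:
                if g.start < region.end and region.start < g.end:
                    expected.add(g.gene_id)
        assert genes == expected


class TestVenn:
    def test_two_sets(self):
        counts = venn_counts({"x": {"a", "b"}, "y": {"b", "c"}})
        assert counts[("x",)] == 1
        assert counts[("y",)] == 1
        assert counts[("x", "y")] == 1

    def test_identical_sets_all_in_intersection(self):
        counts = venn_counts({"x": {"a", "b"}, "y": {"a", "b"}})
        assert counts[("x", "y")] == 2
        assert counts[("x",)] == counts[("y",)] == 0

    def test_three_random_sets_match_enumeration(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(40)]
        sets = {name: {g for g in universe if rng.random() < 0.4}
                for name in ("u", "v", "w")}
        counts = venn_counts(sets)
        # brute-force: every element lands in exactly one exclusive cell
        total = sum(counts.values())
        assert total == len(set().union(*sets.values()))
        for combo, c in counts.items():
            exact = [g for g in universe
                     if all(g in sets[n] for n in combo)
                     and not any(g in sets[n] for n in sets if n not in combo)]
            assert len(exact) == c

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            venn_counts({"only": {"a"}})
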