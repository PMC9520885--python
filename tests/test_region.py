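"""Critical region, consensus, specific variants, frequencies, LD, loops."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from finehap import region as creg
from finehap.io import load_table2_frequencies
from finehap.panel import GenomicInterval
from finehap.simulate import planted_truth_panel


def paths_from_strings(rows):
    return np.array([list(r) for r in rows], dtype=object)


class TestSharedSegment:
    def test_all_target_whole_locus_flagged(self):
        paths = paths_from_strings(["TTTT", "TTTT", "TTTT"])
        iv = creg.find_shared_segment(paths, "T", [10, 20, 30, 40])
        assert (iv.start, iv.end) == (10, 40)
        assert iv.boundary_evidence == (0, 0)
        assert iv.below_threshold

    def test_engineered_boundaries(self):
        """Three chromosomes share sites 2..4 and all switch at both flanks."""
        paths = paths_from_strings(["ATTTA", "BTTTB", "CTTTC"])
        iv = creg.find_shared_segment(paths, "T", [100, 200, 300, 400, 500])
        assert (iv.start, iv.end) == (200, 400)
        assert iv.boundary_evidence == (3, 3)
        assert not iv.below_threshold

    def test_split_run_returns_wider_with_left_tie(self):
        # one chromosome off-label in the middle splits the run; the wider
        # run wins, ties broken to the left
        paths = paths_from_strings(["TTTTTTT",
                                    "TTTATTT"])
        iv = creg.find_shared_segment(paths, "T", np.arange(1, 8),
                                      min_boundary_events=0)
        assert (iv.start, iv.end) == (1, 3)

    def test_no_shared_site_returns_none(self):
        paths = paths_from_strings(["AB", "BA"])
        assert creg.find_shared_segment(paths, "A", [1, 2]) is None

    def test_invariant_to_chromosome_order(self, rng):
        rows = ["AATTTAA", "BTTTTTB", "TTTTTCC"]
        pos = np.arange(10, 80, 10)
        a = creg.find_shared_segment(paths_from_strings(rows), "T", pos)
        b = creg.find_shared_segment(paths_from_strings(rows[::-1]), "T", pos)
        assert (a.start, a.end) == (b.start, b.end)
        assert a.boundary_evidence == b.boundary_evidence


class TestExtendInterval:
    def test_published_arithmetic(self):
        """23.9 kb extended 5% per side -> 1.2 kb per side, 26.3 kb total."""
        iv = GenomicInterval("chr17", 100_001, 123_900)
        assert iv.width == 23_900
        out = creg.extend_interval(iv, frac=0.05)
        assert out.width == 26_300
        assert iv.start - out.start == 1200
        assert out.end - iv.end == 1200

    def test_zero_fraction_is_identity(self):
        iv = GenomicInterval("chr1", 500, 1499)
        out = creg.extend_interval(iv, frac=0.0)
        assert (out.start, out.end) == (iv.start, iv.end)

    def test_ten_kb_case(self):
        iv = GenomicInterval("chr1", 10_001, 20_000)  # 10.0 kb
        out = creg.extend_interval(iv, frac=0.05)
        assert out.width == 11_000

    @given(frac=st.floats(min_value=0.01, max_value=0.5))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_width_increases_with_fraction(self, frac):
        iv = GenomicInterval("chr1", 50_000, 80_000)
        small = creg.extend_interval(iv, frac=frac, per_side_rounding=0)
        big = creg.extend_interval(iv, frac=frac + 0.05, per_side_rounding=0)
        assert big.width > small.width
        noop = creg.extend_interval(creg.extend_interval(iv, 0.0), frac,
                                    per_side_rounding=0)
        assert (noop.start, noop.end) == (small.start, small.end)

    def test_clipped_at_origin_warns(self):
        iv = GenomicInterval("chr1", 100, 2099)
        with pytest.warns(UserWarning, match="clipped"):
            out = creg.extend_interval(iv, frac=0.5)
        assert out.start == 1


class TestConsensus:
    def test_identical_chromosomes(self):
        a = np.tile([0, 1, 0, 1], (4, 1))
        c = creg.build_consensus(a)
        assert np.array_equal(c.alleles, [0, 1, 0, 1])
        assert np.all(c.support == 1.0)

    def test_majority_and_tie(self):
        a = np.array([[1], [1], [1], [0]])
        c = creg.build_consensus(a)
        assert c.alleles[0] == 1 and c.support[0] == 0.75
        tie = creg.build_consensus(np.array([[1], [1], [0], [0]]))
        assert tie.alleles[0] == creg.AMBIGUOUS

    def test_support_range_invariant(self, rng):
        a = rng.integers(0, 2, size=(9, 40))
        c = creg.build_consensus(a)
        ok = c.alleles != creg.AMBIGUOUS
        assert np.all(c.support[ok] >= 0.5) and np.all(c.support[ok] <= 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            creg.build_consensus(np.empty((1, 5)))


class TestSpecificVariants:
    def test_identical_consensuses_call_nothing(self):
        c1 = creg.build_consensus(np.tile([0, 1], (3, 1)), "t")
        c2 = creg.build_consensus(np.tile([0, 1], (3, 1)), "o")
        calls, _ = creg.call_specific_variants(c1, [c2])
        assert calls == []

    def test_must_differ_from_every_group(self):
        target = creg.build_consensus(np.tile([1, 1], (3, 1)), "t")
        o1 = creg.build_consensus(np.tile([0, 0], (3, 1)), "o1")
        o2 = creg.build_consensus(np.tile([0, 1], (3, 1)), "o2")
        calls, _ = creg.call_specific_variants(target, [o1, o2])
        assert [c.site_index for c in calls] == [0]

    def test_ambiguous_sites_excluded(self):
        target = creg.build_consensus(np.tile([1, 1], (4, 1)), "t")
        other = creg.build_consensus(np.array([[0, 0], [0, 0], [0, 1], [0, 1]]), "o")
        calls, excluded = creg.call_specific_variants(target, [other])
        assert [c.site_index for c in calls] == [0]
        assert excluded.tolist() == [1]

    def test_planted_truth_recovery_zero_false_positives(self):
        """With injected on-target variants (freq >= 0.75) and zero off-target
        frequency, the calls are exactly the injected positions."""
        for seed in range(15):
            panel, groups, inj, _ = planted_truth_panel(seed=seed)
            cons = {}
            for g in np.unique(groups):
                ind = np.flatnonzero(groups == g)
                chroms = np.concatenate([2 * ind, 2 * ind + 1])
                cons[g] = creg.build_consensus(panel.alleles[chroms], group=g)
            others = [c for g, c in cons.items() if g != "AA_hap4"]
            calls, _ = creg.call_specific_variants(cons["AA_hap4"], others)
            assert sorted(c.site_index for c in calls) == sorted(inj.tolist())


class TestFrequencyTable:
    def test_full_carriage_and_counting(self, rng):
        alleles = rng.integers(0, 2, size=(8, 10)).astype(np.uint8)
        alleles[:4, 3] = 1
        groups = np.array(["g1"] * 4 + ["g2"] * 4, dtype=object)
        tab = creg.frequency_table(alleles, groups, [3, 5])
        assert tab["g1(2n=4)"].iloc[0] == 1.0
        expect = alleles[4:, 5].mean()
        assert tab["g2(2n=4)"].iloc[1] == pytest.approx(expect)

    def test_published_table_pattern(self):
        """Zero-frequency filter on both European-ancestry backgrounds keeps
        all nine variants; max carrier frequency in target homozygotes 0.97."""
        t2 = load_table2_frequencies()
        zero_ea = t2[(t2["EA_Hap1_2n69"] == 0) & (t2["EA_Hap2_2n118"] == 0)]
        assert len(zero_ea) == 9
        assert t2["AA_Hap4_asthmatic_hom_2n36"].max() == 0.97

    def test_unassigned_chromosomes_ignored(self):
        alleles = np.zeros((4, 5), dtype=np.uint8)
        groups = np.array(["a", "a", "", ""], dtype=object)
        tab = creg.frequency_table(alleles, groups, [0])
        assert list(tab.columns) == ["a(2n=2)"]


class TestPairwiseR2:
    def test_exact_copy_gives_one(self):
        a = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [1, 1], [0, 0]])
        r2 = creg.pairwise_r2(a, [0, 1])
        assert r2[0, 1] == pytest.approx(1.0)

    def test_equilibrium_gives_zero(self):
        # AB, Ab, aB, ab each x2 -> p_AB = p_A p_B
        a = np.array([[1, 1]] * 2 + [[1, 0]] * 2 + [[0, 1]] * 2 + [[0, 0]] * 2)
        r2 = creg.pairwise_r2(a, [0, 1])
        assert r2[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_quarter(self):
        # AB x3, ab x3, Ab x1, aB x1: r2 = (0.375 - 0.25)^2 / 0.0625 = 0.25
        a = np.array([[1, 1]] * 3 + [[0, 0]] * 3 + [[1, 0]], )
        a = np.vstack([a, [[0, 1]]])
        r2 = creg.pairwise_r2(a, [0, 1])
        assert r2[0, 1] == pytest.approx(0.25)

    def test_monomorphic_site_is_nan(self):
        a = np.array([[0, 1], [0, 0], [0, 1], [0, 0]])
        r2 = creg.pairwise_r2(a, [0, 1])
        assert np.isnan(r2[0, 1])

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=(12, 4))
        r2 = creg.pairwise_r2(a, range(4))
        vals = r2[np.isfinite(r2)]
        assert np.all(vals >= -1e-12) and np.all(vals <= 1 + 1e-12)


class TestLoopAnnotation:
    def _fixtures(self):
        loops = pd.DataFrame({
            "a_start": [1000, 5000], "a_end": [2000, 6000],
            "b_start": [50_000, 70_000], "b_end": [51_000, 71_000],
            "score": [6.0, 4.9]})
        promoters = pd.DataFrame({"gene": ["P1", "P2"],
                                  "start": [50_500, 70_500],
                                  "end": [50_600, 70_600]})
        return loops, promoters

    def test_score_threshold(self):
        loops, promoters = self._fixtures()
        links = creg.annotate_variants_with_loops([5500], loops, promoters)
        assert links.empty  # the only nearby loop scores 4.9

    def test_flank_boundary_inclusive(self):
        loops, promoters = self._fixtures()
        links = creg.annotate_variants_with_loops([2999], loops, promoters,
                                                  flank=1000)
        assert links["gene"].tolist() == ["P1"]
        links = creg.annotate_variants_with_loops([3001], loops, promoters,
                                                  flank=1000)
        assert links.empty

    def test_matches_brute_force_intersection(self, rng):
        loops = pd.DataFrame({
            "a_start": rng.integers(0, 5000, 10),
            "score": rng.uniform(3, 8, 10)})
        loops["a_end"] = loops["a_start"] + rng.integers(100, 500, 10)
        loops["b_start"] = rng.integers(20_000, 30_000, 10)
        loops["b_end"] = loops["b_start"] + rng.integers(100, 500, 10)
        promoters = pd.DataFrame({"gene": [f"P{i}" for i in range(5)],
                                  "start": rng.integers(20_000, 30_000, 5)})
        promoters["end"] = promoters["start"] + 200
        variants = rng.integers(0, 6000, 8)
        links = creg.annotate_variants_with_loops(variants, loops, promoters,
                                                  min_score=5, flank=500)
        expected = set()
        for v in variants:
            for _, lp in loops.iterrows():
                if lp.score < 5:
                    continue
                if lp.a_start - 500 <= v <= lp.a_end + 500:
                    for _, pr in promoters.iterrows():
                        if lp.b_start <= pr.end and pr.start <= lp.b_end:
                            expected.add((int(v), pr.gene))
        got = set(zip(links["position"], links["gene"]))
        assert got == expected

    def test_malformed_interval_rejected(self):
        loops, promoters = self._fixtures()
        loops.loc[0, "a_end"] = 10
        with pytest.raises(ValueError, match="malformed"):
            creg.annotate_variants_with_loops([1500], loops, promoters)
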