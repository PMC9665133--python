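import numpy as np
import pytest
from scipy import stats

from lriscape import tad_annotation as ta
from lriscape.genomic_io import ChromStateSegment, Gene, GenomicInterval, TAD
from helpers import frag, iv, make_interaction


def seg(chrom, start, end, state):
    return ChromStateSegment(GenomicInterval(chrom, start, end), state)


GROUPS = ta.StateGroupMap()


class TestClassifyTads:
    def test_categories(self, tads_chr1):
        # T0: LRI end in PAd only; T1: interaction but no LRI; T2: nothing
        lri_ends = {"PAd": [frag("chr1", 100, 4100)], "Diff": [], "Adip": []}
        all_ends = [frag("chr1", 100, 4100), frag("chr1", 1_500_000, 1_504_000)]
        anns = {a.tad_id: a for a in ta.classify_tads(lri_ends, all_ends, tads_chr1)}
        assert anns["T0"].category == "PAd only"
        assert anns["T1"].category == "none"
        assert anns["T2"].category == "excluded"
        assert not anns["T2"].has_any_interaction

    def test_all_and_subset_categories(self, tads_chr1):
        f = frag("chr1", 100, 4100)
        anns = {a.tad_id: a for a in ta.classify_tads(
            {"PAd": [f], "Diff": [f], "Adip": [f]}, [f], tads_chr1)}
        assert anns["T0"].category == "all"
        anns2 = {a.tad_id: a for a in ta.classify_tads(
            {"PAd": [], "Diff": [f], "Adip": [f]}, [f], tads_chr1)}
        assert anns2["T0"].category == "Diff and Adip"

    def test_every_tad_categorized_once(self, tads_chr1, rng):
        frags = [frag("chr1", int(s), int(s) + 1000)
                 for s in rng.integers(0, 9_000_000, 50)]
        anns = ta.classify_tads({"PAd": frags[:10], "Diff": [], "Adip": []},
                                frags, tads_chr1)
        assert len(anns) == len(tads_chr1)
        counts = {}
        for a in anns:
            counts[a.category] = counts.get(a.category, 0) + 1
        assert sum(counts.values()) == len(tads_chr1)


class TestFragmentStateAssignment:
    def test_fully_quiescent(self):
        f = frag("chr1", 100, 600)
        assert ta.fragment_state_assignment(
            f, [seg("chr1", 0, 1000, "Quies")], GROUPS) == "quiescent"

    def test_majority_wins(self):
        # 60% enhancer / 40% promoter coverage
        f = frag("chr1", 0, 1000)
        segs = [seg("chr1", 0, 600, "EnhA1"), seg("chr1", 600, 1000, "TssA")]
        assert ta.fragment_state_assignment(f, segs, GROUPS) == "enhancer"

    def test_tie_break_order(self):
        f = frag("chr1", 0, 1000)
        segs = [seg("chr1", 0, 500, "TssA"), seg("chr1", 500, 1000, "EnhA1")]
        assert ta.fragment_state_assignment(f, segs, GROUPS) == "promoter"

    def test_no_overlap_is_other(self):
        f = frag("chr2", 0, 1000)
        assert ta.fragment_state_assignment(
            f, [seg("chr1", 0, 1000, "Quies")], GROUPS) == "other"

    def test_matches_per_base_majority_oracle(self, rng):
        """Coverage argmax equals a brute-force per-base vote on random tilings."""
        states = ["Quies", "TssA", "EnhA1", "Tx", "ZNF/Rpts"]
        for _ in range(30):
            bounds = np.sort(rng.choice(np.arange(1, 10_000), size=8, replace=False))
            bounds = [0, *bounds.tolist(), 10_000]
            labels = [states[int(i)] for i in rng.integers(0, len(states), len(bounds) - 1)]
            segs = [seg("chr1", a, b, s) for a, b, s in zip(bounds[:-1], bounds[1:], labels)]
            s0 = int(rng.integers(0, 9_000))
            f = frag("chr1", s0, s0 + int(rng.integers(100, 1000)))
            # brute force: per-base group counts, same tie-break order
            per_base = {}
            for pos in range(f.interval.start, f.interval.end):
                for sg in segs:
                    if sg.interval.start <= pos < sg.interval.end:
                        g = GROUPS.group(sg.state)
                        per_base[g] = per_base.get(g, 0) + 1
                        break
            best = max(per_base.values())
            expected = next(g for g in ta.GROUP_TIEBREAK_ORDER
                            if per_base.get(g, 0) == best)
            assert ta.fragment_state_assignment(f, segs, GROUPS) == expected


class TestTadStateCoverage:
    def test_single_segment(self):
        tad = TAD(iv("chr1", 0, 100_000), "T")
        cov = ta.tad_state_coverage(tad, [seg("chr1", 10_000, 40_000, "Quies")], GROUPS)
        assert cov.coverage["quiescent"] == pytest.approx(0.3)
        assert cov.coverage["active"] == 0.0

    def test_fully_active(self):
        tad = TAD(iv("chr1", 0, 50_000), "T")
        segs = [seg("chr1", 0, 25_000, "Tx"), seg("chr1", 25_000, 50_000, "TxWk")]
        cov = ta.tad_state_coverage(tad, segs, GROUPS)
        assert cov.coverage["active"] == pytest.approx(1.0)

    def test_adjacent_segments_sum(self):
        tad = TAD(iv("chr1", 0, 100_000), "T")
        segs = [seg("chr1", 0, 10_000, "EnhA1"), seg("chr1", 10_000, 25_000, "EnhW1")]
        cov = ta.tad_state_coverage(tad, segs, GROUPS)
        assert cov.coverage["enhancer"] == pytest.approx(0.25)


class TestCompareTadCoverage:
    def make_cov(self, vals):
        return [ta.TADStateCoverage(f"T{i}", {"quiescent": v, "active": 0.0,
                                              "promoter": 0.0, "enhancer": 0.0})
                for i, v in enumerate(vals)]

    def test_identical_constant_samples(self):
        res = ta.compare_tad_coverage(self.make_cov([0.5] * 4),
                                      self.make_cov([0.5] * 4), "quiescent")
        assert res["p_value"] == 1.0 and res["direction"] == "none"

    def test_exact_small_sample_p(self):
        # n=3 vs 3 complete separation: two-sided exact rank-sum p = 2/C(6,3) = 0.1
        res = ta.compare_tad_coverage(self.make_cov([0.9, 0.8, 0.7]),
                                      self.make_cov([0.1, 0.2, 0.3]), "quiescent")
        assert res["direction"] == "lri_higher"
        assert res["p_value"] == pytest.approx(0.1)

    def test_empty_arm_errors(self):
        with pytest.raises(ValueError):
            ta.compare_tad_coverage(self.make_cov([]), self.make_cov([0.1]), "quiescent")

    def test_matches_scipy_on_large_ties(self, rng):
        a = rng.integers(0, 5, 40) / 4.0
        b = rng.integers(0, 5, 35) / 4.0
        res = ta.rank_sum_compare(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert res[1] == pytest.approx(ref.pvalue)


class TestBoundaryCrossing:
    def test_none_and_all(self, tads_chr1):
        inside = make_interaction(bait_start=0, bait_end=4000,
                                  oe_start=500_000, oe_end=504_000)
        crossing = make_interaction(bait_start=900_000, bait_end=904_000,
                                    oe_start=1_100_000, oe_end=1_104_000)
        assert ta.boundary_crossing_fraction([inside] * 3, tads_chr1) == 0.0
        assert ta.boundary_crossing_fraction([crossing] * 2, tads_chr1) == 1.0
        assert ta.boundary_crossing_fraction(
            [inside, inside, inside, crossing], tads_chr1) == 0.25


class TestMarkerGeneTest:
    def build(self, counts_by_cat, tads_chr1):
        """Place marker genes so the contingency table equals counts_by_cat."""
        f_all = frag("chr1", 100, 1100)        # T0 -> category "all"
        f_none = frag("chr1", 1_000_100, 1_001_100)  # T1 -> none (SRI ends only)
        anns = ta.classify_tads(
            {"PAd": [f_all], "Diff": [f_all], "Adip": [f_all]},
            [f_all, f_none], tads_chr1,
        )
        markers = {}
        for ct, (n_all, n_none) in counts_by_cat.items():
            genes = []
            for i in range(n_all):
                genes.append(Gene(f"{ct}_all{i}", iv("chr1", 10, 2000)))
            for i in range(n_none):
                genes.append(Gene(f"{ct}_none{i}", iv("chr1", 1_000_010, 1_002_000)))
            markers[ct] = genes
        return markers, anns

    def test_flat_table(self, tads_chr1):
        markers, anns = self.build({"PAd": (10, 10), "Adip": (10, 10)}, tads_chr1)
        res = ta.marker_gene_category_test(markers, anns, tads_chr1)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_pearson_value_matches_hand_formula(self, tads_chr1):
        # [[30,10],[10,30]]: expected all 20, chi2 = 4 * (10^2/20) = 20
        markers, anns = self.build({"PAd": (30, 10), "Adip": (10, 30)}, tads_chr1)
        res = ta.marker_gene_category_test(markers, anns, tads_chr1)
        assert res["chi2"] == pytest.approx(20.0)
        assert res["p_value"] == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_low_expected_category_dropped(self, tads_chr1):
        # "none" column expected counts < 5 in every row -> dropped -> <2 categories
        markers, anns = self.build({"PAd": (30, 2), "Adip": (28, 3)}, tads_chr1)
        with pytest.raises(ValueError, match="categories"):
            ta.marker_gene_category_test(markers, anns, tads_chr1)
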