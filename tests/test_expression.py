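import math

import numpy as np
import pytest
from scipy import stats

from lriscape import expression as ex
from lriscape import tad_annotation as ta
from lriscape.genomic_io import Gene, GenomicInterval
from helpers import frag, iv, make_interaction


def em(gene_ids, labels, values):
    return ex.ExpressionMatrix(list(gene_ids), list(labels), np.asarray(values, float))


class TestExpressionMatrix:
    def test_invariants(self):
        with pytest.raises(ValueError):
            em(["g1"], ["s1"], [[-1.0]])
        with pytest.raises(ValueError):
            em(["g1", "g1"], ["s1"], [[1.0], [2.0]])

    def test_tsv_roundtrip(self, tmp_path):
        m = em(["g1", "g2"], ["a", "b"], [[1.5, 0.0], [2.25, 3.0]])
        m.to_tsv(tmp_path / "e.tsv")
        back = ex.ExpressionMatrix.from_tsv(tmp_path / "e.tsv")
        assert back.gene_ids == m.gene_ids
        np.testing.assert_array_equal(back.values, m.values)


class TestTimepointMatching:
    def test_identical_column_wins(self):
        genes = [f"g{i}" for i in range(50)]
        vals = np.random.default_rng(0).lognormal(2, 1, size=(50, 3))
        ref = em(genes, ["1d", "3d", "14d"], vals)
        qry = em(genes, ["PAd"], vals[:, [1]])
        out = ex.match_timepoints_by_correlation(ref, qry, top_n=50)
        assert out["PAd"]["best_reference"] == "3d"
        assert out["PAd"]["profile"]["3d"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        genes = [f"g{i}" for i in range(40)]
        vals = np.random.default_rng(1).lognormal(2, 1, size=(40, 2))
        ref = em(genes, ["1d", "3d"], vals)
        qry = em(genes, ["q"], np.sqrt(vals[:, [0]]) * 7)
        out = ex.match_timepoints_by_correlation(ref, qry, top_n=40)
        assert out["q"]["best_reference"] == "1d"

    def test_hand_computed_spearman(self):
        genes = ["g1", "g2", "g3", "g4"]
        ref = em(genes, ["r1", "r2"], [[4, 1], [3, 2], [2, 3], [1, 4]])
        qry = em(genes, ["q"], [[4], [3], [2], [1]])
        out = ex.match_timepoints_by_correlation(ref, qry, top_n=4)
        assert out["q"]["profile"]["r1"] == pytest.approx(1.0)
        assert out["q"]["profile"]["r2"] == pytest.approx(-1.0)

    def test_no_shared_genes_errors(self):
        with pytest.raises(ValueError, match="shared"):
            ex.match_timepoints_by_correlation(
                em(["a"], ["x"], [[1.0]]), em(["b"], ["y"], [[1.0]]))


class TestClassifyGenes:
    def gene(self, gid, bait):
        return Gene(gid, iv("chr1", 0, 100), bait_fragment_id=bait)

    def test_partition(self):
        sri = make_interaction(oe_start=200_000, oe_end=204_000)
        lri = make_interaction(oe_start=1_200_000, oe_end=1_204_000)
        bait_id = sri.bait.fragment_id
        genes = [
            self.gene("sri_only", bait_id),
            self.gene("none", "other_frag"),
            self.gene("no_bait", None),
        ]
        out = {c.gene_id: c.interaction_class
               for c in ex.classify_genes_by_interaction(genes, [sri])}
        assert out == {"sri_only": "SRI-only", "none": "neither", "no_bait": "neither"}
        both = ex.classify_genes_by_interaction([self.gene("g", bait_id)], [sri, lri])
        assert both[0].interaction_class == "both"
        lri_only = ex.classify_genes_by_interaction([self.gene("g", bait_id)], [lri])
        assert lri_only[0].interaction_class == "LRI-only"

    def test_excluded_distance_ignored(self):
        far = make_interaction(oe_start=2_500_000, oe_end=2_504_000)
        g = self.gene("g", far.bait.fragment_id)
        assert ex.classify_genes_by_interaction([g], [far])[0].interaction_class == "neither"

    def test_counts_sum_to_total(self, rng):
        xs = []
        for i in range(60):
            d = int(rng.integers(50_000, 2_400_000))
            xs.append(make_interaction(bait_start=i * 10_000, bait_end=i * 10_000 + 4000,
                                       oe_start=i * 10_000 + d, oe_end=i * 10_000 + d + 4000))
        genes = [self.gene(f"g{i}", xs[i % 40].bait.fragment_id) for i in range(80)]
        out = ex.classify_genes_by_interaction(genes, xs)
        assert len(out) == 80


def classes_of(n_sri, n_lri):
    return ([ex.GeneInteractionClass(f"s{i}", "SRI-only") for i in range(n_sri)]
            + [ex.GeneInteractionClass(f"l{i}", "LRI-only") for i in range(n_lri)])


class TestExpressedFraction:
    def build_expr(self, sri_expressed, lri_expressed, n_sri, n_lri):
        genes = [f"s{i}" for i in range(n_sri)] + [f"l{i}" for i in range(n_lri)]
        vals = np.concatenate([
            np.where(np.arange(n_sri) < sri_expressed, 5.0, 0.0),
            np.where(np.arange(n_lri) < lri_expressed, 5.0, 0.0),
        ]).reshape(-1, 1)
        return em(genes, ["Adip_r1"], vals)

    def test_all_expressed_gives_degenerate_margin(self):
        expr = self.build_expr(10, 10, 10, 10)
        with pytest.raises(ValueError, match="margin"):
            ex.expressed_fraction_test(classes_of(10, 10), expr,
                                       {"Adip": "Adip_r1"}, "Adip")

    def test_hand_pearson_on_2x2(self):
        # [[90,10],[50,50]]: chi2 = sum (o-e)^2/e with margins 140/60, 100/100
        expr = self.build_expr(90, 50, 100, 100)
        res = ex.expressed_fraction_test(classes_of(100, 100), expr,
                                         {"Adip": "Adip_r1"}, "Adip")
        tab = np.array([[90, 10], [50, 50]])
        exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        chi2_hand = ((tab - exp) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2_hand)
        assert res["expressed_fraction"]["LRI-only"] == pytest.approx(0.5)

    def test_empty_class_errors(self):
        expr = self.build_expr(5, 0, 10, 0)
        with pytest.raises(ValueError, match="LRI-only"):
            ex.expressed_fraction_test(classes_of(10, 0), expr,
                                       {"Adip": "Adip_r1"}, "Adip")


class TestExpressionLevel:
    def test_identical_arms(self):
        genes = classes_of(5, 5)
        vals = np.tile(np.arange(1.0, 11.0).reshape(-1, 1), (1, 1))
        expr = {"Adip": em([c.gene_id for c in genes], ["Adip_r1"], vals)}
        # make arms identical: same values for s* and l*
        expr["Adip"].values[5:] = expr["Adip"].values[:5]
        out = ex.expression_level_test(genes, expr, {"Adip": "Adip_r1"})
        assert out["Adip"]["p_value"] == pytest.approx(1.0)
        assert out["Adip"]["t"] == pytest.approx(0.0)

    def test_bonferroni_times_three(self):
        rng = np.random.default_rng(0)
        genes = classes_of(200, 200)
        ids = [c.gene_id for c in genes]
        expr = {}
        for tp in ("PAd", "Diff", "Adip"):
            vals = np.exp2(np.concatenate([rng.normal(1, 1, 200),
                                           rng.normal(1, 1, 200)])) - 1
            expr[tp] = em(ids, [f"{tp}_r1"], vals.clip(0).reshape(-1, 1))
        out = ex.expression_level_test(genes, expr, {tp: f"{tp}_r1" for tp in expr})
        for tp in expr:
            assert out[tp]["p_adj"] == pytest.approx(min(1.0, out[tp]["p_value"] * 3))

    def test_planted_shift_detected(self):
        """N(0,1) vs N(1,1) on the log scale, n=200/arm: power ~ 1."""
        rng = np.random.default_rng(42)
        genes = classes_of(200, 200)
        ids = [c.gene_id for c in genes]
        vals = np.exp2(np.concatenate([rng.normal(2, 1, 200),
                                       rng.normal(1, 1, 200)]))
        expr = {"Adip": em(ids, ["Adip_r1"], vals.reshape(-1, 1))}
        out = ex.expression_level_test(genes, expr, {"Adip": "Adip_r1"})
        assert out["Adip"]["p_adj"] < 0.05
        assert out["Adip"]["t"] > 0  # SRI arm higher

    def test_small_arm_is_na(self):
        genes = classes_of(3, 1)
        expr = {"Adip": em([c.gene_id for c in genes], ["Adip_r1"],
                           np.ones((4, 1)))}
        out = ex.expression_level_test(genes, expr, {"Adip": "Adip_r1"})
        assert math.isnan(out["Adip"]["p_value"])


class TestBystander:
    def setup_world(self, repressed_mult, rng, n=150):
        """SRI-only genes half inside an LRI TAD, half outside."""
        tads = [ta.TADAnnotation("T0", {"Adip": True}, True, "Adip only"),
                ta.TADAnnotation("T1", {"Adip": False}, True, "none")]
        from lriscape.genomic_io import TAD
        tad_objs = [TAD(iv("chr1", 0, 1_000_000), "T0"),
                    TAD(iv("chr1", 1_000_000, 2_000_000), "T1")]
        genes, vals = [], []
        for i in range(n):
            inside = i % 2 == 0
            start = 100 + (i * 1000 if inside else 1_000_100 + i * 1000)
            genes.append(Gene(f"g{i}", iv("chr1", start, start + 500)))
            base = float(np.exp2(rng.normal(4, 1)))
            vals.append(base * (repressed_mult if inside else 1.0))
        expr = {"Adip": em([g.gene_id for g in genes], ["Adip_r1"],
                           np.array(vals).reshape(-1, 1))}
        return genes, tads, tad_objs, expr

    def test_planted_repression_detected(self, rng):
        genes, anns, tads, expr = self.setup_world(0.5, rng)
        out = ex.bystander_gene_test(genes, anns, tads, expr, {"Adip": "Adip_r1"})
        assert out["Adip"]["p_value"] < 0.01
        assert out["Adip"]["t"] < 0  # in-LRI-TAD arm lower

    def test_null_multiplier_one(self, rng):
        genes, anns, tads, expr = self.setup_world(1.0, rng)
        out = ex.bystander_gene_test(genes, anns, tads, expr, {"Adip": "Adip_r1"})
        assert out["Adip"]["p_value"] > 0.01

    def test_single_arm_errors(self, rng):
        genes, anns, tads, expr = self.setup_world(1.0, rng)
        only_inside = [g for i, g in enumerate(genes) if i % 2 == 0]
        with pytest.raises(ValueError, match="arm"):
            ex.bystander_gene_test(only_inside, anns, tads, expr, {"Adip": "Adip_r1"})
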