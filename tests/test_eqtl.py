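import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lriscape import eqtl as eq
from lriscape.expression import ExpressionMatrix
from lriscape.genomic_io import Gene, GenomicInterval
from helpers import frag, iv, make_interaction


def geno(dosages, positions=None, chrom="chr1", info=None):
    d = np.asarray(dosages, float)
    n = d.shape[0]
    return eq.GenotypeMatrix(
        snp_ids=[f"snp{i}" for i in range(n)],
        chroms=[chrom] * n,
        positions=positions or [1000 * (i + 1) for i in range(n)],
        dosages=d,
        info=np.asarray(info, float) if info is not None else None,
    )


class TestFilters:
    def test_expressed_gene_strict_threshold(self):
        vals = np.ones((3, 10))
        vals[1, 0] = 0.0   # expressed in exactly 90% -> dropped
        vals[2, :3] = 0.0
        expr = ExpressionMatrix(["a", "b", "c"], [f"i{k}" for k in range(10)], vals)
        assert eq.filter_expressed_genes(expr, 0.90) == ["a"]

    def test_monomorphic_dropped_by_maf(self):
        g = geno([np.zeros(100), np.tile([0, 1, 2, 1.0], 25)])
        kept, audit = eq.filter_snps(g)
        assert kept.snp_ids == ["snp1"]
        assert audit["maf"] == 1

    def test_hwe_no_hets_dropped(self):
        # 50 hom-ref / 50 hom-alt, no hets: chi2 = n = 100 -> p << 1e-5
        d = np.concatenate([np.zeros(50), np.full(50, 2.0)])
        kept, audit = eq.filter_snps(geno([d]))
        assert kept.snp_ids == [] and audit["hwe"] == 1

    def test_hwe_proportions_kept(self, rng):
        d = rng.binomial(2, 0.4, size=500).astype(float)
        kept, audit = eq.filter_snps(geno([d]))
        assert kept.snp_ids == ["snp0"]

    def test_info_filter_and_skip(self):
        d = [np.tile([0, 1, 2, 1.0], 25)] * 2
        kept, audit = eq.filter_snps(geno(d, info=[0.79, 0.95]))
        assert kept.snp_ids == ["snp1"] and audit["info"] == 1
        kept2, _ = eq.filter_snps(geno(d))  # no info: rule skipped
        assert len(kept2.snp_ids) == 2


class TestOLS:
    def test_exact_linear_relation(self):
        g = np.tile([0.0, 1.0, 2.0], 10)
        beta, t, p = eq.ols_association(g, 2.0 * g)
        assert beta == pytest.approx(2.0)
        assert p < 1e-50

    def test_constructed_orthogonal_dosage(self):
        g = np.array([0.0, 2.0, 0.0, 2.0, 1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])  # orthogonal to centered g
        beta, t, p = eq.ols_association(g, y)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        """beta/t/p equal an independent normal-equations solve, n=50."""
        for _ in range(20):
            g = rng.binomial(2, 0.3, 50).astype(float)
            if g.std() == 0:
                continue
            cov = rng.normal(size=(50, 2))
            y = 0.4 * g + cov @ np.array([0.5, -0.2]) + rng.normal(size=50)
            beta, t, p = eq.ols_association(g, y, cov)
            X = np.column_stack([np.ones(50), g, cov])
            bh = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bh
            s2 = resid @ resid / (50 - X.shape[1])
            se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t_ref = bh[1] / se
            p_ref = 2 * stats.t.sf(abs(t_ref), 50 - X.shape[1])
            assert beta == pytest.approx(bh[1], abs=1e-10)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_after_projection_errors(self):
        g = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            eq.ols_association(g, np.ones(4), covariates=g.reshape(-1, 1))


class TestCandidatePairs:
    def make_gene(self, start=5_000_000, end=5_020_000):
        return Gene("g", iv("chr1", start, end), bait_fragment_id="B")

    @pytest.mark.parametrize(
        "snp_pos, expected",
        [
            (4_500_000, "short"),   # 500 kb upstream
            (6_520_000, "long"),    # 1.5 Mb past the end
            (7_019_998, "long"),    # just under 2 Mb (last base is end-1)
            (7_020_000, None),      # exactly 2 Mb -> excluded
            (5_010_000, "short"),   # inside the gene body, distance 0
        ],
    )
    def test_windows(self, snp_pos, expected):
        g = geno([np.tile([0, 1, 2.0], 10)], positions=[snp_pos])
        pairs = eq.enumerate_candidate_pairs([self.make_gene()], g)
        if expected is None:
            assert pairs == []
        else:
            assert pairs[0].window_class == expected

    def test_distance_from_nearer_end(self):
        g = geno([np.tile([0, 1, 2.0], 10)], positions=[3_950_000])
        (p,) = eq.enumerate_candidate_pairs([self.make_gene()], g)
        assert p.distance == 1_050_000 and p.window_class == "long"


class TestRestrictByInteraction:
    def setup(self):
        gene = Gene("g", iv("chr1", 0, 20_000), bait_fragment_id="BAIT")
        lri = make_interaction(bait_start=0, bait_end=4000,
                               oe_start=1_500_000, oe_end=1_504_000)
        lri = type(lri)(frag("chr1", 0, 4000, "BAIT"),
                        frag("chr1", 1_500_000, 1_504_000, "OE"),
                        score=6.0)
        return gene, lri

    def test_supported_and_boundaries(self):
        gene, lri = self.setup()
        g = geno([np.tile([0, 1, 2.0], 10)] * 3,
                 positions=[1_500_000, 1_503_999, 1_504_000])
        pairs = eq.enumerate_candidate_pairs([gene], g)
        out, _ = eq.restrict_pairs_by_interaction(pairs, [lri], [gene], g)
        by_snp = {p.snp_id: p.interaction_supported for p in out}
        assert by_snp["snp0"] and by_snp["snp1"]
        assert not by_snp["snp2"]  # 1 bp outside the half-open fragment

    def test_wrong_gene_not_supported(self):
        gene, lri = self.setup()
        other = Gene("h", iv("chr1", 100_000, 120_000), bait_fragment_id="OTHER")
        g = geno([np.tile([0, 1, 2.0], 10)], positions=[1_501_000])
        pairs = eq.enumerate_candidate_pairs([other], g)
        out, _ = eq.restrict_pairs_by_interaction(pairs, [lri], [other], g)
        assert not out[0].interaction_supported

    def test_window_class_must_match(self):
        # SRI interaction cannot support a long-window pair
        gene = Gene("g", iv("chr1", 0, 20_000), bait_fragment_id="BAIT")
        sri = type(make_interaction())(frag("chr1", 0, 4000, "BAIT"),
                                       frag("chr1", 500_000, 504_000, "OE"),
                                       score=6.0)
        g = geno([np.tile([0, 1, 2.0], 10)], positions=[501_000])
        pairs = eq.enumerate_candidate_pairs([gene], g)
        out, _ = eq.restrict_pairs_by_interaction(pairs, [sri], [gene], g)
        assert out[0].window_class == "short" and out[0].interaction_supported


def results_with_p(ps, snps=None):
    snps = snps or [f"snp{i}" for i in range(len(ps))]
    return [eq.AssociationResult(s, "g", 0.1, 1.0, p, "long", True)
            for s, p in zip(snps, ps)]


class TestLDPruning:
    def ld(self, mat, snps):
        return pd.DataFrame(np.asarray(mat, float), index=snps, columns=snps)

    def test_all_correlated_counts_one(self):
        snps = ["snp0", "snp1", "snp2"]
        res, n = eq.count_independent_and_adjust(
            results_with_p([0.01, 0.02, 0.03]), self.ld(np.ones((3, 3)), snps))
        assert n == 1
        assert all(r.p_adj == pytest.approx(r.p_value) for r in res)

    def test_all_independent(self):
        snps = ["snp0", "snp1", "snp2"]
        res, n = eq.count_independent_and_adjust(
            results_with_p([0.01, 0.02, 0.03]), self.ld(np.eye(3), snps))
        assert n == 3
        assert res[0].p_adj == pytest.approx(0.03)

    def test_greedy_chain(self):
        # r2(1,2)=0.5, r2(1,3)=0.1, r2(2,3)=0.1; p order 1<2<3 -> accept {1,3}
        snps = ["snp0", "snp1", "snp2"]
        m = [[1, 0.5, 0.1], [0.5, 1, 0.1], [0.1, 0.1, 1]]
        res, n = eq.count_independent_and_adjust(
            results_with_p([0.001, 0.002, 0.003]), self.ld(m, snps))
        assert n == 2

    def test_missing_ld_entries_error(self):
        with pytest.raises(ValueError, match="missing"):
            eq.count_independent_and_adjust(
                results_with_p([0.01]), self.ld(np.eye(1), ["other"]))

    def test_count_never_exceeds_snps(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 8))
            a = rng.random((k, k))
            m = np.clip((a + a.T) / 2, 0, 1)
            np.fill_diagonal(m, 1.0)
            snps = [f"snp{i}" for i in range(k)]
            _, n = eq.count_independent_and_adjust(
                results_with_p(list(rng.random(k)), snps), self.ld(m, snps))
            assert 1 <= n <= k


class TestShortRangeFDR:
    def test_bh_hand_computation(self):
        # p = (.01,.02,.04,.5), m=4 -> q = (.04,.04,.0533,.5)
        short = results_with_p([0.01, 0.02, 0.04, 0.5])
        flags = eq.short_range_fdr_check(["snp0", "snp1", "snp2", "snp3"], short)
        qs = [r.q_value for r in short]
        np.testing.assert_allclose(qs, [0.04, 0.04, 1.6 / 30, 0.5], atol=1e-12)
        assert flags == {"snp0": True, "snp1": True, "snp2": False, "snp3": False}

    def test_unsupported_pairs_never_flag(self):
        short = [eq.AssociationResult("snp0", "g", 0.1, 1.0, 1e-6, "short", False)]
        assert eq.short_range_fdr_check(["snp0"], short) == {"snp0": False}

    def test_snp_without_short_pairs(self):
        assert eq.short_range_fdr_check(["lonely"], results_with_p([0.01])) == {
            "lonely": False}
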