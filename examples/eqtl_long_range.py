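"""Interaction-restricted long-range cis-eQTL mapping.

Simulates genotypes with LD blocks and one planted eQTL whose SNP sits
inside the other end of a planted long-range interaction looping to its
target gene's promoter. Tests only SNP-gene pairs physically supported by an
interaction, and corrects by the number of LD-independent signals
(greedy pruning at r^2 < 0.2) rather than the raw pair count.
"""

import warnings

import numpy as np

from lriscape import eqtl as eq
from lriscape import synthetic as syn
from lriscape.pipeline import fast_pair_ols, supported_pairs_from_interactions

cfg = syn.SyntheticConfig(seed=2, n_chromosomes=1, chrom_length=10_000_000,
                          n_genes_per_chrom=200, interactions_per_replicate=6_000,
                          n_individuals=300)
layout, truth = syn.generate_genome_layout(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    interactions = syn.generate_interaction_replicates(cfg, layout, truth)
    _, _, expr = syn.generate_expression(cfg, layout, truth)
    geno = syn.generate_genotypes(cfg, layout, truth, expr)

kept_genes = set(eq.filter_expressed_genes(expr, 0.90))
geno_f, audit = eq.filter_snps(geno)
print(f"SNP filters (MAF >= 5%, HWE p >= 1e-5, info >= 0.8) removed {audit} "
      f"of {len(geno.snp_ids)}; genes expressed in >90% of individuals: "
      f"{len(kept_genes)}/{len(expr.gene_ids)}")

genes_f = [g for g in layout.genes if g.gene_id in kept_genes]
union = [x for tp in syn.TIMEPOINTS for x in interactions[tp]["rep1"]
         if x.score >= 5.0]
pairs = supported_pairs_from_interactions(union, genes_f, geno_f)
long_pairs = [p for p in pairs if p.window_class == "long"]
print(f"Interaction-supported pairs: {len(pairs)} "
      f"({len(long_pairs)} in the long 1-2 Mb window)")

Y = np.log2(expr.values + 1.0)
gr = {g: i for i, g in enumerate(expr.gene_ids)}
sr = {s: i for i, s in enumerate(geno_f.snp_ids)}
beta, t, p = fast_pair_ols(
    geno_f.dosages[[sr[q.snp_id] for q in long_pairs]],
    Y[[gr[q.gene_id] for q in long_pairs]])
results = [eq.AssociationResult(q.snp_id, q.gene_id, float(b), float(tt),
                                float(pp), "long", True)
           for q, b, tt, pp in zip(long_pairs, beta, t, p)]
ld = eq.ld_r2_matrix(geno_f, sorted({r.snp_id for r in results}))
adjusted, n_ind = eq.count_independent_and_adjust(results, ld)

sig = sorted([r for r in adjusted if r.p_adj < 0.05], key=lambda r: r.p_adj)
print(f"\nIndependent signals (LD r^2 < 0.2, per gene): {n_ind}; "
      f"Bonferroni-significant long-range eQTLs at p_adj < 0.05: {len(sig)}")
for r in sig:
    print(f"  {r.snp_id} -> {r.gene_id}: beta = {r.beta:+.2f} "
          f"(log2 per dosage), p_adj = {r.p_adj:.2e}")
print(f"Planted eQTL was {truth.planted_eqtl[0]} -> {truth.planted_eqtl[1]} "
      f"with beta {truth.planted_eqtl[2]} SD; restricting tests to looping "
      "SNP-gene pairs recovers it while the hundreds of null supported pairs "
      "stay non-significant.")
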