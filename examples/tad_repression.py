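"""TAD-level repression annotation.

Classifies TADs by which time points contribute long-range interaction ends
to them, measures chromHMM state-group coverage per TAD, and tests whether
LRI TADs are more quiescent than interaction-containing TADs without LRIs.
Also runs the marker-gene category test: progenitor (PAd) markers should sit
in LRI TADs, adipocyte (Adip) markers outside them.
"""

import warnings

from lriscape import interactions as ia
from lriscape import tad_annotation as ta
from lriscape.synthetic import SyntheticConfig, TIMEPOINTS, generate_all

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ds = generate_all(SyntheticConfig(seed=3, n_chromosomes=1, chrom_length=10_000_000,
                                      n_genes_per_chrom=200,
                                      interactions_per_replicate=6_000))
    filtered = {tp: ia.filter_significant(ds.interactions[tp]["rep1"], 5.0)[0]
                for tp in TIMEPOINTS}

lri_ends = {tp: [f for x in filtered[tp] for f in (x.bait, x.other_end)
                 if ia.classify_distance(x) == "LRI"] for tp in TIMEPOINTS}
all_ends = [f for tp in TIMEPOINTS for x in filtered[tp] for f in (x.bait, x.other_end)]
anns = ta.classify_tads(lri_ends, all_ends, ds.layout.tads)

counts = {}
for a in anns:
    counts[a.category] = counts.get(a.category, 0) + 1
print("TAD categories (which time points contribute LRI ends; 'none' = "
      "interactions but no LRIs, 'excluded' = no interactions at all):")
for cat, n in sorted(counts.items()):
    print(f"  {cat:>14}: {n}")

groups = ta.StateGroupMap()
cov = {t.tad_id: ta.tad_state_coverage(t, ds.chrom_states, groups)
       for t in ds.layout.tads}
lri_cov = [cov[a.tad_id] for a in anns if a.is_lri_tad]
non_cov = [cov[a.tad_id] for a in anns if a.category == "none"]
print("\nchromHMM coverage, LRI vs non-LRI TADs (rank-sum); in the emulated "
      "study LRI TADs are quiescent-rich and depleted of active states:")
for group in ("quiescent", "active"):
    res = ta.compare_tad_coverage(lri_cov, non_cov, group)
    print(f"  {group:>9}: direction {res['direction']:<14} p = {res['p_value']:.2e}")

markers = {ct: [g for g in ds.layout.genes if g.gene_id in set(ids)]
           for ct, ids in ds.truth.marker_genes.items()}
res = ta.marker_gene_category_test(markers, anns, ds.layout.tads)
print(f"\nMarker-gene category test: chi2 = {res['chi2']:.1f}, "
      f"p = {res['p_value']:.2e} over categories {res['categories']}")
for ct, props in res["proportions"].items():
    pretty = ", ".join(f"{c}: {100 * v:.0f}%" for c, v in props.items())
    print(f"  {ct} markers: {pretty}")
print("(PAd markers concentrate in LRI TADs -- genes repressed during "
      "differentiation -- while Adip markers avoid them.)")

crossing = ta.boundary_crossing_fraction(filtered["PAd"], ds.layout.tads)
print(f"\nFraction of PAd interactions crossing a TAD boundary: {100*crossing:.1f}% "
      "(long-range pairs necessarily span boundaries in this compact genome; "
      "the study reports 5.4% for its real TAD map)")
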