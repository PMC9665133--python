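"""Distance-class statistics for promoter Capture Hi-C interactions.

Simulates two biological replicates of significant interactions per
adipogenesis time point, applies the significance filters (CHiCAGO-style
score >= 5, intra-chromosomal, < 2 Mb), and prints the short- vs long-range
breakdown, replicate concordance by distance, cross-time-point sharing and
read support.
"""

import warnings

from lriscape import interactions as ia
from lriscape.synthetic import SyntheticConfig, TIMEPOINTS, generate_genome_layout, \
    generate_interaction_replicates

cfg = SyntheticConfig(seed=11, n_chromosomes=1, chrom_length=10_000_000,
                      n_genes_per_chrom=200, interactions_per_replicate=8_000)
layout, truth = generate_genome_layout(cfg)
reps = generate_interaction_replicates(cfg, layout, truth)

filtered = {}
for tp in TIMEPOINTS:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered[tp] = {r: ia.filter_significant(rows, 5.0)[0]
                        for r, rows in reps[tp].items()}

print("LRI share of significant interactions (the long-range fraction rises "
      "sharply in the first day of differentiation):")
props = {}
for tp in TIMEPOINTS:
    classes = [ia.classify_distance(x) for x in filtered[tp]["rep1"]]
    props[tp] = classes.count("LRI") / len(classes)
    print(f"  {tp:>4}: {100 * props[tp]:.2f}%  (n = {len(classes)})")
print(f"  PAd -> Diff fold change: "
      f"{ia.proportion_fold_change(props['PAd'], props['Diff']):.2f} "
      "(the study reports 2.4-fold, from 1.1% to 2.6%)")

print("\nReplicate concordance in 50-kb distance bins (PAd); the shared "
      "fraction reflects the per-class retention planted in the simulation, "
      "and bins with a union under 10 are NA:")
bins = ia.replicate_concordance(filtered["PAd"]["rep1"], filtered["PAd"]["rep2"])
for b in bins[:3] + [b for b in bins if b.bin_start == 1_000_000][:1]:
    prop = "NA" if b.proportion != b.proportion else f"{b.proportion:.2f}"
    print(f"  [{b.bin_start//1000:>5}-{b.bin_end//1000:>5} kb] "
          f"union {b.n_union:>5}  shared {b.n_shared:>5}  proportion {prop}")

sharing = ia.timepoint_sharing({tp: filtered[tp]["rep1"] for tp in TIMEPOINTS},
                               restrict_to="LRI")
print(f"\nLRIs shared by >=2 time points: {100 * sharing.fraction_shared_2plus:.0f}% "
      "(the study reports over 40%, arguing the LRIs are not one-dataset artefacts)")

rs = ia.read_support_summary(filtered["PAd"]["rep1"])
print("\nRead support (median [Q1-Q3]); LRIs are supported by fewer reads "
      "than SRIs but well above singletons:")
for cls in ("SRI", "LRI"):
    s = rs[cls]
    print(f"  {cls}: {s['median']:.0f} [{s['q1']:.0f}-{s['q3']:.0f}]  (n = {s['n']})")
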