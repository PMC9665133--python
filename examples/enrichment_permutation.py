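"""Feature / LRI-TAD co-occurrence testing.

Counts how many features (super-enhancer stand-ins) fall in LRI-containing
TADs and tests the co-occurrence two ways: by shuffling which
interaction-containing TADs carry the LRI label (10,000 permutations), and
by a closed-form hypergeometric test. The simulated features are placed
uniformly, so neither test should report enrichment.
"""

from lriscape import enrichment as enr
from lriscape.genomic_io import GenomicInterval, TAD
import numpy as np

rng = np.random.default_rng(17)
tads = [TAD(GenomicInterval("chr1", i * 800_000, (i + 1) * 800_000), f"T{i}")
        for i in range(25)]
lri_ids = {f"T{i}" for i in rng.choice(25, size=7, replace=False)}
features = [GenomicInterval("chr1", int(p), int(p) + 20_000)
            for p in rng.integers(0, 25 * 800_000 - 20_000, 20)]

observed = enr.count_feature_tad_cooccurrence(features, tads, lri_ids)
res = enr.permutation_test(features, tads, lri_ids, n_permutations=10_000, seed=17)
hyper = enr.hypergeometric_test(observed, len(features), len(lri_ids), len(tads))

print(f"{observed} of {len(features)} features fall in the {len(lri_ids)} LRI TADs "
      f"(7/25 = 28% of TAD space)")
print(f"Permutation p (label shuffling, add-one convention): {res.p_value:.3f}")
print(f"Hypergeometric upper-tail p:                        {hyper:.3f}")
print("Both p-values are far from 0.05: uniformly placed features show no "
      "preference for LRI TADs, matching the study's non-significant "
      "super-enhancer overlap.")
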