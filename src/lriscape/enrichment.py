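"""Feature/LRI-TAD co-occurrence testing.

Two routes to the same question (do features such as super-enhancers land in
LRI-containing TADs more often than chance?): a label-shuffling permutation
null that redraws which interaction-containing TADs carry the LRI label, and
a closed-form hypergeometric test. Feature-to-TAD membership is by feature
midpoint throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genomic_io import GenomicInterval, MidpointIndex, TAD

__all__ = [
    "PermutationResult",
    "count_feature_tad_cooccurrence",
    "permutation_test",
    "hypergeometric_test",
]


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p_value: float
    n_permutations: int


def _feature_tads(features: Sequence[GenomicInterval], tads: Sequence[TAD]) -> list[str | None]:
    index = MidpointIndex([t.interval for t in tads], [t.tad_id for t in tads])
    return [index.lookup(f.chrom, f.midpoint) for f in features]


def count_feature_tad_cooccurrence(
    features: Sequence[GenomicInterval],
    tads: Sequence[TAD],
    lri_tad_ids: set[str],
) -> int:
    """Number of features whose midpoint lies inside an LRI TAD."""
    return sum(1 for tid in _feature_tads(features, tads) if tid in lri_tad_ids)


def permutation_test(
    features: Sequence[GenomicInterval],
    tads: Sequence[TAD],
    lri_tad_ids: set[str],
    eligible_tad_ids: set[str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Label-shuffling permutation null for feature/LRI-TAD co-occurrence.

    Each permutation draws a uniform subset of the eligible TAD ids (TADs
    with any interaction; defaults to all TADs) of size |lri_tad_ids| and
    recounts the co-occurrence. The p-value uses the add-one convention
    p = (1 + #{null >= observed}) / (1 + n) so it is never exactly 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    eligible = sorted(eligible_tad_ids) if eligible_tad_ids is not None else sorted(
        t.tad_id for t in tads
    )
    k = len(lri_tad_ids)
    if k > len(eligible):
        raise ValueError("more LRI TADs than eligible TADs")
    tid_index = {tid: i for i, tid in enumerate(eligible)}
    # features outside eligible TADs can never be counted, here or in any permutation
    fidx = np.array(
        [tid_index[t] for t in _feature_tads(features, tads) if t in tid_index], dtype=int
    )
    observed = int(np.isin(fidx, [tid_index[t] for t in lri_tad_ids if t in tid_index]).sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=int)
    n_eligible = len(eligible)
    for i in range(n_permutations):
        chosen = rng.choice(n_eligible, size=k, replace=False)
        mask = np.zeros(n_eligible, dtype=bool)
        mask[chosen] = True
        null_counts[i] = int(mask[fidx].sum())
    p = (1 + int((null_counts >= observed).sum())) / (1 + n_permutations)
    return PermutationResult(
        observed=observed, null_counts=null_counts, p_value=p, n_permutations=n_permutations
    )


def hypergeometric_test(
    k: int,
    n_features: int,
    n_lri_tads: int,
    n_eligible_tads: int,
) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for k of ``n_features``
    features landing in LRI TADs, with TAD counts as population/successes."""
    if not (0 <= k <= n_features):
        raise ValueError("require 0 <= k <= n_features")
    if n_lri_tads > n_eligible_tads:
        raise ValueError("more LRI TADs than eligible TADs")
    if n_features > n_eligible_tads:
        raise ValueError(
            "count-based hypergeometric model requires n_features <= eligible "
            "TADs (each draw is a feature-to-TAD assignment without "
            "replacement); use the permutation test instead"
        )
    if n_features == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_eligible_tads, n_lri_tads, n_features))
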