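"""TAD-level annotation: LRI content per time point, chromHMM state coverage,
and the marker-gene category test.

A TAD is an "LRI TAD" at a time point when at least one end of a long-range
interaction falls inside it (membership by fragment midpoint). TADs with
interaction ends but no LRI ends are "non-LRI" TADs; TADs containing no
interaction ends at all are excluded from every comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import (
    TAD,
    ChromStateSegment,
    Gene,
    GenomicInterval,
    Interaction,
    MidpointIndex,
    RestrictionFragment,
    overlap_length,
)

__all__ = [
    "DEFAULT_STATE_GROUPS",
    "GROUP_TIEBREAK_ORDER",
    "StateGroupMap",
    "TADAnnotation",
    "TADStateCoverage",
    "classify_tads",
    "fragment_state_assignment",
    "tad_state_coverage",
    "compare_tad_coverage",
    "boundary_crossing_fraction",
    "marker_gene_category_test",
    "rank_sum_compare",
]

# Default grouping of the Roadmap 25-state chromHMM model into the four
# summary groups used throughout; states not listed map to "other".
DEFAULT_STATE_GROUPS: dict[str, str] = {
    **{s: "promoter" for s in ("TssA", "PromU", "PromD1", "PromD2")},
    **{s: "active" for s in ("Tx5'", "Tx", "Tx3'", "TxWk", "TxReg",
                             "TxEnh5'", "TxEnh3'", "TxEnhW")},
    **{s: "enhancer" for s in ("EnhA1", "EnhA2", "EnhAF", "EnhW1", "EnhW2", "EnhAc")},
    "Quies": "quiescent",
}

#: deterministic tie-break when two groups cover a fragment equally
GROUP_TIEBREAK_ORDER = ("quiescent", "promoter", "enhancer", "active", "other")

GROUPS = ("active", "promoter", "enhancer", "quiescent")


class StateGroupMap:
    """chromHMM state label -> {active, promoter, enhancer, quiescent, other}."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self.mapping = dict(DEFAULT_STATE_GROUPS if mapping is None else mapping)
        bad = set(self.mapping.values()) - set(GROUP_TIEBREAK_ORDER)
        if bad:
            raise ValueError(f"unknown state groups: {sorted(bad)}")

    def group(self, state: str) -> str:
        return self.mapping.get(state, "other")


@dataclass
class TADAnnotation:
    tad_id: str
    lri_flags: dict[str, bool]
    has_any_interaction: bool
    category: str

    @property
    def is_lri_tad(self) -> bool:
        return self.has_any_interaction and any(self.lri_flags.values())


def _category(lri_flags: Mapping[str, bool], has_any: bool) -> str:
    if not has_any:
        return "excluded"
    true_tps = [tp for tp, flag in lri_flags.items() if flag]
    if not true_tps:
        return "none"
    if len(true_tps) == len(lri_flags):
        return "all"
    if len(true_tps) == 1:
        return f"{true_tps[0]} only"
    return " and ".join(true_tps)


def classify_tads(
    lri_ends_by_timepoint: Mapping[str, Sequence[RestrictionFragment]],
    all_interaction_ends: Sequence[RestrictionFragment],
    tads: Sequence[TAD],
) -> list[TADAnnotation]:
    """Label every TAD by which time points contribute LRI ends to it.

    Category is "excluded" for TADs with no interaction ends at all, "none"
    for interaction-containing TADs without LRI ends, "all" when every time
    point contributes, else the named subset (e.g., "Diff only",
    "Diff and Adip" following the given time-point order).
    """
    index = MidpointIndex([t.interval for t in tads], [t.tad_id for t in tads])
    timepoints = list(lri_ends_by_timepoint)
    flags: dict[str, dict[str, bool]] = {
        t.tad_id: {tp: False for tp in timepoints} for t in tads
    }
    has_any: dict[str, bool] = {t.tad_id: False for t in tads}
    for frag in all_interaction_ends:
        tid = index.lookup(frag.interval.chrom, frag.midpoint)
        if tid is not None:
            has_any[tid] = True
    for tp, frags in lri_ends_by_timepoint.items():
        for frag in frags:
            tid = index.lookup(frag.interval.chrom, frag.midpoint)
            if tid is not None:
                flags[tid][tp] = True
                has_any[tid] = True  # an LRI end is an interaction end
    return [
        TADAnnotation(
            tad_id=t.tad_id,
            lri_flags=flags[t.tad_id],
            has_any_interaction=has_any[t.tad_id],
            category=_category(flags[t.tad_id], has_any[t.tad_id]),
        )
        for t in tads
    ]


def _group_coverage_bp(
    target: GenomicInterval,
    segments: Sequence[ChromStateSegment],
    groups: StateGroupMap,
) -> dict[str, int]:
    cov: dict[str, int] = {}
    for seg in segments:
        bp = overlap_length(target, seg.interval)
        if bp:
            g = groups.group(seg.state)
            cov[g] = cov.get(g, 0) + bp
    return cov


def fragment_state_assignment(
    fragment: RestrictionFragment,
    segments: Sequence[ChromStateSegment],
    groups: StateGroupMap,
) -> str:
    """Assign a fragment the state group with the highest coverage of its
    length; ties break by the fixed order quiescent > promoter > enhancer >
    active > other, and zero overlap yields "other"."""
    cov = _group_coverage_bp(fragment.interval, segments, groups)
    if not cov:
        return "other"
    best = max(cov.values())
    for g in GROUP_TIEBREAK_ORDER:
        if cov.get(g, 0) == best:
            return g
    raise AssertionError("unreachable")


@dataclass
class TADStateCoverage:
    tad_id: str
    coverage: dict[str, float]  # group -> fraction of TAD length


def tad_state_coverage(
    tad: TAD,
    segments: Sequence[ChromStateSegment],
    groups: StateGroupMap,
) -> TADStateCoverage:
    """Fraction of the TAD covered by each of the four state groups."""
    length = len(tad.interval)
    cov_bp = _group_coverage_bp(tad.interval, segments, groups)
    return TADStateCoverage(
        tad_id=tad.tad_id,
        coverage={g: cov_bp.get(g, 0) / length for g in GROUPS},
    )


def rank_sum_compare(
    arm_a: Sequence[float], arm_b: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum comparison of two coverage arms.

    Returns (statistic, p, direction) where direction is 'a_higher',
    'b_higher' or 'none' based on the median difference. Identical constant
    samples give p = 1 by convention.
    """
    a = np.asarray(arm_a, dtype=float)
    b = np.asarray(arm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 0.0, 1.0, "none"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_diff = float(np.median(a) - np.median(b))
    direction = "a_higher" if med_diff > 0 else ("b_higher" if med_diff < 0 else "none")
    return float(res.statistic), float(res.pvalue), direction


def compare_tad_coverage(
    lri_tads: Sequence[TADStateCoverage],
    non_lri_tads: Sequence[TADStateCoverage],
    group: str,
) -> dict[str, float | str]:
    """Rank-sum test of one state group's coverage between LRI and non-LRI TADs."""
    a = [c.coverage[group] for c in lri_tads]
    b = [c.coverage[group] for c in non_lri_tads]
    stat, p, direction = rank_sum_compare(a, b)
    direction = {"a_higher": "lri_higher", "b_higher": "non_lri_higher"}.get(direction, "none")
    return {"group": group, "statistic": stat, "p_value": p, "direction": direction}


def boundary_crossing_fraction(
    interactions: Sequence[Interaction],
    tads: Sequence[TAD],
) -> float:
    """Fraction of interactions whose two fragment midpoints do not lie in
    the same TAD (including one-in/one-out)."""
    if not interactions:
        return math.nan
    index = MidpointIndex([t.interval for t in tads], [t.tad_id for t in tads])
    crossing = 0
    for x in interactions:
        ta = index.lookup(x.bait.interval.chrom, x.bait.midpoint)
        tb = index.lookup(x.other_end.interval.chrom, x.other_end.midpoint)
        if ta is None and tb is None:
            continue  # fully outside the TAD map: no boundary involved
        if ta != tb:
            crossing += 1
    return crossing / len(interactions)


def marker_gene_category_test(
    marker_genes: Mapping[str, Sequence[Gene]],
    annotations: Sequence[TADAnnotation],
    tads: Sequence[TAD],
    min_expected: float = 5.0,
) -> dict:
    """Chi-square test of marker-gene distribution over LRI-TAD categories.

    Each marker gene is assigned to a TAD by midpoint (genes outside the TAD
    map are dropped and counted in the audit). Categories whose expected
    count falls below ``min_expected`` in any cell-type row are removed
    before the Pearson chi-square (no continuity correction).
    """
    index = MidpointIndex([t.interval for t in tads], [t.tad_id for t in tads])
    cat_by_tad = {a.tad_id: a.category for a in annotations}
    cell_types = list(marker_genes)
    categories = sorted({a.category for a in annotations if a.category != "excluded"})
    counts = np.zeros((len(cell_types), len(categories)), dtype=float)
    dropped_outside = 0
    for r, ct in enumerate(cell_types):
        for gene in marker_genes[ct]:
            tid = index.lookup(gene.interval.chrom, gene.interval.midpoint)
            cat = cat_by_tad.get(tid) if tid is not None else None
            if cat is None or cat == "excluded":
                dropped_outside += 1
                continue
            counts[r, categories.index(cat)] += 1

    # expected counts under independence, then drop failing categories
    def expected(tab: np.ndarray) -> np.ndarray:
        return np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()

    keep = [j for j in range(len(categories)) if counts[:, j].sum() > 0]
    tab = counts[:, keep]
    kept_cats = [categories[j] for j in keep]
    while True:
        exp = expected(tab)
        bad = np.where((exp < min_expected).any(axis=0))[0]
        if bad.size == 0:
            break
        # drop the worst-offending category and recompute
        j = int(bad[np.argmin(exp[:, bad].min(axis=0))])
        tab = np.delete(tab, j, axis=1)
        kept_cats.pop(j)
        if tab.shape[1] == 0:
            break
    if tab.shape[1] < 2:
        raise ValueError("fewer than two categories survive the expected-count rule")
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    proportions = {
        ct: {cat: tab[r, j] / tab[r].sum() for j, cat in enumerate(kept_cats)}
        for r, ct in enumerate(cell_types)
    }
    return {
        "chi2": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "categories": kept_cats,
        "table": tab,
        "proportions": proportions,
        "n_genes_outside_tads": dropped_outside,
    }
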