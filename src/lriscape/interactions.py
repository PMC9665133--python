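"""Significance filtering and distance-class statistics for pCHi-C interactions.

Interactions are classed by the midpoint-to-midpoint distance between the two
restriction fragments: short-range (SRI, < 1 Mb), long-range (LRI, 1–2 Mb),
or excluded (>= 2 Mb, where replicate concordance collapses). Replicate
concordance is tallied in 50-kb distance bins as the fraction of the
bin's fragment-pair union seen in both biological replicates; bins with a
union below 10 are reported as NA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import GenomicInterval, Interaction, overlap_length

__all__ = [
    "SRI_MAX",
    "LRI_MAX",
    "FilterAudit",
    "ConcordanceBin",
    "SharingSummary",
    "filter_significant",
    "interaction_distance",
    "classify_distance",
    "replicate_concordance",
    "timepoint_sharing",
    "read_support_summary",
    "proportion_fold_change",
]

SRI_MAX = 1_000_000
LRI_MAX = 2_000_000

#: fixed application order of the significance-filter rules
FILTER_RULES = ("score", "inter_chromosomal", "exclusion", "distance")


@dataclass
class FilterAudit:
    """Per-rule removal counts, in the fixed order score -> inter-chromosomal
    -> exclusion-region -> distance."""

    removed: dict[str, int]
    n_input: int
    n_retained: int


def interaction_distance(i: Interaction) -> int:
    """Midpoint-to-midpoint distance in bp (intra-chromosomal only)."""
    if i.inter_chromosomal:
        raise ValueError("interaction distance undefined for inter-chromosomal pairs")
    return abs(i.bait.midpoint - i.other_end.midpoint)


def classify_distance(i: Interaction, sri_max: int = SRI_MAX, lri_max: int = LRI_MAX) -> str:
    """Return 'SRI' (< sri_max), 'LRI' (sri_max <= d < lri_max) or 'excluded'.

    The boundary at exactly 1 Mb is an LRI.
    """
    d = interaction_distance(i)
    if d < sri_max:
        return "SRI"
    if d < lri_max:
        return "LRI"
    return "excluded"


def filter_significant(
    interactions: Sequence[Interaction],
    score_threshold: float = 5.0,
    exclusion_regions: Sequence[GenomicInterval] = (),
    max_distance: int = LRI_MAX,
) -> tuple[list[Interaction], FilterAudit]:
    """Apply the significance/score, inter-chromosomal, exclusion-region and
    distance filters in fixed order, returning survivors plus an audit log.

    An interaction is removed by the exclusion rule when either fragment
    overlaps any exclusion region (used for outlier loci such as the
    chromosome-6 histone-gene cluster).
    """
    removed = {rule: 0 for rule in FILTER_RULES}
    kept: list[Interaction] = []
    for x in interactions:
        if x.score is None:
            raise ValueError(
                f"interaction {x.pair_id} has no score; the score filter requires one"
            )
        if x.score < score_threshold:
            removed["score"] += 1
            continue
        if x.inter_chromosomal:
            removed["inter_chromosomal"] += 1
            continue
        if any(
            overlap_length(x.bait.interval, r) > 0 or overlap_length(x.other_end.interval, r) > 0
            for r in exclusion_regions
        ):
            removed["exclusion"] += 1
            continue
        if interaction_distance(x) >= max_distance:
            removed["distance"] += 1
            continue
        kept.append(x)
    if not kept:
        warnings.warn("all interactions removed by the significance filters")
    return kept, FilterAudit(removed=removed, n_input=len(interactions), n_retained=len(kept))


# ---------------------------------------------------------------------------
# Replicate concordance


@dataclass
class ConcordanceBin:
    bin_start: int
    bin_end: int
    n_union: int
    n_shared: int
    proportion: float  # NaN when n_union < min_union


def _pair_distances(reps: Sequence[Sequence[Interaction]]) -> dict[tuple[str, str], int]:
    """Map each unordered fragment pair to its distance, checking that the
    fragment maps agree across the input collections."""
    coords: dict[str, GenomicInterval] = {}
    dist: dict[tuple[str, str], int] = {}
    for rep in reps:
        for x in rep:
            for frag in (x.bait, x.other_end):
                prev = coords.get(frag.fragment_id)
                if prev is None:
                    coords[frag.fragment_id] = frag.interval
                elif prev != frag.interval:
                    raise ValueError(
                        f"fragment {frag.fragment_id} has conflicting coordinates "
                        "across collections"
                    )
            dist[x.pair_id] = interaction_distance(x)
    return dist


def replicate_concordance(
    rep_a: Sequence[Interaction],
    rep_b: Sequence[Interaction],
    bin_width: int = 50_000,
    min_union: int = 10,
) -> list[ConcordanceBin]:
    """Distance-binned concordance between two biological replicates.

    Interactions match when they share the unordered pair of fragment ids.
    Each bin reports |A ∪ B| and |A ∩ B| restricted to pairs whose distance
    falls in the bin; the proportion shared is NA (NaN) when the union has
    fewer than ``min_union`` members. Bins run from 0 to the maximum
    observed distance.
    """
    dist = _pair_distances([rep_a, rep_b])
    set_a = {x.pair_id for x in rep_a}
    set_b = {x.pair_id for x in rep_b}
    union = set_a | set_b
    shared = set_a & set_b
    if not union:
        return []
    n_bins = max(dist[p] for p in union) // bin_width + 1
    n_union = np.zeros(n_bins, dtype=int)
    n_shared = np.zeros(n_bins, dtype=int)
    for p in union:
        b = dist[p] // bin_width
        n_union[b] += 1
        if p in shared:
            n_shared[b] += 1
    out = []
    for b in range(n_bins):
        prop = n_shared[b] / n_union[b] if n_union[b] >= min_union else math.nan
        out.append(
            ConcordanceBin(
                bin_start=b * bin_width,
                bin_end=(b + 1) * bin_width,
                n_union=int(n_union[b]),
                n_shared=int(n_shared[b]),
                proportion=prop,
            )
        )
    return out


@dataclass
class SharingSummary:
    counts: dict[int, int]  # number of time points -> interaction count
    fraction_shared_2plus: float


def timepoint_sharing(
    sets: Mapping[str, Sequence[Interaction]],
    restrict_to: str | None = None,
) -> SharingSummary:
    """Tally distinct fragment pairs by the number of time points containing
    them, optionally restricted to one distance class ('SRI'/'LRI')."""
    if len(sets) < 2:
        raise ValueError("need at least two time points")
    tallies: dict[tuple[str, str], int] = {}
    for tp, interactions in sets.items():
        seen: set[tuple[str, str]] = set()
        for x in interactions:
            if restrict_to is not None and classify_distance(x) != restrict_to:
                continue
            if x.pair_id not in seen:
                seen.add(x.pair_id)
                tallies[x.pair_id] = tallies.get(x.pair_id, 0) + 1
    counts = {k: 0 for k in range(1, len(sets) + 1)}
    for n in tallies.values():
        counts[n] += 1
    total = sum(counts.values())
    frac = sum(v for k, v in counts.items() if k >= 2) / total if total else math.nan
    return SharingSummary(counts=counts, fraction_shared_2plus=frac)


def read_support_summary(
    interactions: Sequence[Interaction],
    sri_max: int = SRI_MAX,
    lri_max: int = LRI_MAX,
) -> dict[str, dict[str, float]]:
    """Median and quartiles (linear-interpolation definition) of read support
    per distance class. Empty classes yield NaN summaries."""
    by_class: dict[str, list[int]] = {"SRI": [], "LRI": [], "excluded": []}
    for x in interactions:
        by_class[classify_distance(x, sri_max, lri_max)].append(x.read_count)
    out: dict[str, dict[str, float]] = {}
    for cls, counts in by_class.items():
        if counts:
            q1, med, q3 = np.quantile(counts, [0.25, 0.5, 0.75])
            out[cls] = {"n": len(counts), "q1": float(q1), "median": float(med), "q3": float(q3)}
        else:
            out[cls] = {"n": 0, "q1": math.nan, "median": math.nan, "q3": math.nan}
    return out


def proportion_fold_change(p_from: float, p_to: float) -> float:
    """Fold change between two proportions (e.g., the LRI share of all
    significant interactions at consecutive time points)."""
    if p_from <= 0:
        raise ValueError("p_from must be positive")
    return p_to / p_from
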