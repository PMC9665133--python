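"""A/B compartment calling from binned chromatin accessibility.

The procedure mirrors eigenvector-based compartment analysis, but on
ATAC-seq coverage instead of a Hi-C contact map: reads are counted in 100-kb
bins (blacklist-aware), normalized to bins-per-million (BPM), log2
transformed and residualized on per-sample FRiP, and a per-chromosome
Spearman correlation matrix of bins is summarized by its leading
eigenvector. Because inactive (B) chromatin is the more strongly
co-correlated compartment, the eigenvector is oriented so that it is
negatively correlated with bin connectivity (making A positive), then
smoothed with a centered 3-bin moving average. Bins are labeled A where the
smoothed eigenvector is positive and B where negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, TAD
from .tad_annotation import TADAnnotation, rank_sum_compare

__all__ = [
    "AccessibilitySampleMeta",
    "BinnedAccessibility",
    "bin_accessibility",
    "normalize_and_correct",
    "spearman_correlation_matrix",
    "leading_eigenvector",
    "orient_and_smooth",
    "call_compartments",
    "compartment_lri_tad_enrichment",
]


@dataclass(frozen=True)
class AccessibilitySampleMeta:
    sample_id: str
    timepoint: str
    frip: float
    total_reads: int

    def __post_init__(self) -> None:
        if not (0 < self.frip <= 1):
            raise ValueError("frip must be in (0, 1]")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass
class BinnedAccessibility:
    """Genome-wide bin table: one row per bin, one count column per sample.

    ``bins`` has columns chrom/start/end/excluded; ``counts`` is bins x
    samples; ``corrected``, ``eigen`` and ``label`` are filled in by the
    downstream stages.
    """

    bins: pd.DataFrame
    counts: np.ndarray
    sample_ids: list[str]
    bin_size: int
    bpm: np.ndarray | None = None
    corrected: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def bin_accessibility(
    read_positions: Mapping[str, Sequence[tuple[str, int]]],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 100_000,
    blacklist: Sequence[GenomicInterval] = (),
) -> BinnedAccessibility:
    """Count read midpoints into fixed-width bins per chromosome.

    ``read_positions`` maps sample id -> iterable of (chrom, midpoint).
    Reads whose midpoint lies in a blacklisted region are dropped; bins
    falling entirely inside the blacklist are flagged excluded. Reads beyond
    the declared chromosome length are dropped with a warning.
    """
    sample_ids = list(read_positions)
    chroms = list(chrom_lengths)
    rows = []
    for chrom in chroms:
        n = -(-chrom_lengths[chrom] // bin_size)  # ceiling division
        for b in range(n):
            start = b * bin_size
            end = min((b + 1) * bin_size, chrom_lengths[chrom])
            rows.append((chrom, start, end))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    bl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        bl_by_chrom.setdefault(iv.chrom, []).append(iv)

    def blacklisted(chrom: str, pos: int) -> bool:
        return any(iv.start <= pos < iv.end for iv in bl_by_chrom.get(chrom, ()))

    bin_index = {(c, s): i for i, (c, s) in enumerate(zip(bins["chrom"], bins["start"]))}
    counts = np.zeros((len(bins), len(sample_ids)), dtype=np.int64)
    n_dropped_oob = 0
    for j, sid in enumerate(sample_ids):
        for chrom, pos in read_positions[sid]:
            if chrom not in chrom_lengths or not (0 <= pos < chrom_lengths[chrom]):
                n_dropped_oob += 1
                continue
            if blacklisted(chrom, pos):
                continue
            counts[bin_index[(chrom, pos // bin_size * bin_size)], j] += 1
    if n_dropped_oob:
        warnings.warn(f"dropped {n_dropped_oob} reads beyond declared chromosome lengths")

    # a bin is excluded when fully covered by blacklist
    excluded = np.zeros(len(bins), dtype=bool)
    for i, (chrom, start, end) in enumerate(zip(bins["chrom"], bins["start"], bins["end"])):
        covered = 0
        for iv in bl_by_chrom.get(chrom, ()):
            covered += max(0, min(end, iv.end) - max(start, iv.start))
        excluded[i] = covered >= end - start
    bins["excluded"] = excluded
    return BinnedAccessibility(bins=bins, counts=counts, sample_ids=sample_ids, bin_size=bin_size)


def normalize_and_correct(
    data: BinnedAccessibility,
    meta: Sequence[AccessibilitySampleMeta],
    pseudocount: float = 1.0,
    correct_frip: bool = True,
) -> BinnedAccessibility:
    """BPM-normalize and FRiP-correct the bin counts.

    BPM = count / (total mapped reads / 1e6). The correction regresses each
    bin's log2(BPM + pseudocount) on sample FRiP by OLS and keeps the
    residual re-centered at the bin mean. With fewer than 3 samples the
    regression is underdetermined and skipped with a warning.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    missing = [s for s in data.sample_ids if s not in meta_by_id]
    if missing:
        raise ValueError(f"missing sample metadata for {missing}")
    totals = np.array([meta_by_id[s].total_reads for s in data.sample_ids], dtype=float)
    frip = np.array([meta_by_id[s].frip for s in data.sample_ids], dtype=float)
    data.bpm = data.counts / (totals / 1e6)
    y = np.log2(data.bpm + pseudocount)
    if len(data.sample_ids) < 3 or not correct_frip:
        if correct_frip and len(data.sample_ids) < 3:
            warnings.warn("fewer than 3 samples: FRiP correction skipped")
        data.corrected = y
        return data
    x = frip - frip.mean()
    denom = (x**2).sum()
    if denom == 0:  # constant FRiP: slope 0, correction is a no-op
        data.corrected = y
        return data
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc * x).sum(axis=1) / denom  # per-bin OLS slope
    resid = yc - slope[:, None] * x[None, :]
    data.corrected = resid + y.mean(axis=1, keepdims=True)
    return data


def spearman_correlation_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rank correlation between bins (rows of ``values``).

    Returns (corr, usable_mask); zero-variance bins are excluded from the
    matrix and reported False in the mask. Requires >=3 usable bins and >=3
    samples.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    usable = values.std(axis=1) > 0
    v = values[usable]
    if v.shape[0] < 3:
        raise ValueError("fewer than 3 usable (non-constant) bins")
    corr = stats.spearmanr(v, axis=1).statistic
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    np.fill_diagonal(corr, 1.0)
    return corr, usable


def leading_eigenvector(
    corr: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float, bool]:
    """Leading (largest-magnitude eigenvalue) eigenvector by power iteration.

    Deterministic all-ones start; returns (unit vector, eigenvalue,
    degenerate) where ``degenerate`` flags an (approximate) eigenvalue tie
    between the two largest magnitudes. The sign of the vector is arbitrary
    at this stage. Raises on non-convergence.
    """
    a = np.asarray(corr, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.all(np.isfinite(a)):
        raise ValueError("correlation matrix contains non-finite values")
    n = a.shape[0]
    if n == 1:
        return np.ones(1), float(a[0, 0]), False

    def power(mat: np.ndarray, start: np.ndarray) -> tuple[np.ndarray, float, bool]:
        v = start / np.linalg.norm(start)
        lam = 0.0
        for _ in range(max_iter):
            w = mat @ v
            norm = np.linalg.norm(w)
            if norm == 0:  # start vector annihilated: eigenvalue 0 along it
                return v, 0.0, True
            w /= norm
            lam_new = float(w @ mat @ w)
            if np.linalg.norm(w - np.sign(w @ v) * v) < tol:
                return w, lam_new, True
            v, lam = w, lam_new
        return v, lam, False

    v, lam, converged = power(a, np.ones(n))
    if not converged:
        raise RuntimeError("power iteration failed to converge")
    # estimate the runner-up eigenvalue on the deflated matrix to flag ties;
    # deterministic non-uniform start avoids exact orthogonality to lam2's space
    deflated = a - lam * np.outer(v, v)
    probe = np.cos(np.arange(n) + 1.0)
    probe -= (probe @ v) * v  # project out the leading direction
    if np.linalg.norm(probe) < 1e-12:
        probe = np.sin(np.arange(n) + 0.5)
        probe -= (probe @ v) * v
    _, lam2, conv2 = power(deflated, probe)
    degenerate = (not conv2) or abs(abs(lam) - abs(lam2)) <= 1e-8 * max(1.0, abs(lam))
    return v, lam, degenerate


def moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average, window truncated at the ends (no padding)."""
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def orient_and_smooth(
    eigvec: np.ndarray,
    corr: np.ndarray,
    window: int = 3,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orient the eigenvector against bin connectivity, then smooth.

    Connectivity_i = sum_j corr_ij (j != i). If the Pearson correlation of
    the eigenvector with connectivity is positive the sign is flipped, so
    that A compartments (positive values) end up anti-correlated with
    connectivity. Returns (smoothed vector, connectivity, flipped).
    """
    v = np.asarray(eigvec, dtype=float)
    if v.std() == 0:
        raise ValueError("eigenvector has zero variance; cannot orient")
    connectivity = corr.sum(axis=1) - np.diag(corr)
    flipped = False
    if connectivity.std() > 0 and np.corrcoef(v, connectivity)[0, 1] > 0:
        v = -v
        flipped = True
    return moving_average(v, window), connectivity, flipped


@dataclass
class CompartmentCalls:
    """Per-bin compartment results joined back onto the genome-wide bin table."""

    table: pd.DataFrame  # chrom start end eigen connectivity label
    degenerate_chroms: list[str]
    skipped_chroms: list[str]


def call_compartments(
    data: BinnedAccessibility,
    window: int = 3,
) -> CompartmentCalls:
    """Run the per-chromosome eigenvector pipeline and label bins A/B.

    Bins that are blacklist-excluded or zero-variance carry label
    'excluded', as do bins whose smoothed eigenvector is exactly 0.
    """
    if data.corrected is None:
        raise ValueError("run normalize_and_correct first")
    out = data.bins[["chrom", "start", "end"]].copy()
    out["eigen"] = np.nan
    out["connectivity"] = np.nan
    out["label"] = "excluded"
    degenerate, skipped = [], []
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        mask = ~data.bins.loc[idx, "excluded"].to_numpy()
        vals = data.corrected[idx[mask]]
        try:
            corr, usable = spearman_correlation_matrix(vals)
        except ValueError as exc:
            warnings.warn(f"{chrom}: {exc}; chromosome skipped")
            skipped.append(str(chrom))
            continue
        vec, _, degen = leading_eigenvector(corr)
        if degen:
            degenerate.append(str(chrom))
        smoothed, connectivity, _ = orient_and_smooth(vec, corr, window)
        rows = idx[mask][usable]
        out.loc[rows, "eigen"] = smoothed
        out.loc[rows, "connectivity"] = connectivity
        out.loc[rows, "label"] = np.where(smoothed > 0, "A", np.where(smoothed < 0, "B", "excluded"))
    return CompartmentCalls(table=out, degenerate_chroms=degenerate, skipped_chroms=skipped)


def compartment_lri_tad_enrichment(
    calls: CompartmentCalls,
    annotations: Sequence[TADAnnotation],
    tads: Sequence[TAD],
) -> dict:
    """Rank-sum comparison of per-TAD B-compartment coverage between LRI and
    non-LRI TADs (excluded TADs are left out)."""
    b_bins = calls.table[calls.table["label"] == "B"]
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in b_bins.iterrows():
        b_by_chrom.setdefault(row["chrom"], []).append((int(row["start"]), int(row["end"])))

    def b_coverage(tad: TAD) -> float:
        total = 0
        for s, e in b_by_chrom.get(tad.interval.chrom, ()):
            total += max(0, min(tad.interval.end, e) - max(tad.interval.start, s))
        return total / len(tad.interval)

    ann_by_id = {a.tad_id: a for a in annotations}
    lri_cov, non_cov = [], []
    for tad in tads:
        a = ann_by_id.get(tad.tad_id)
        if a is None or a.category == "excluded":
            continue
        (lri_cov if a.is_lri_tad else non_cov).append(b_coverage(tad))
    stat, p, direction = rank_sum_compare(lri_cov, non_cov)
    return {
        "statistic": stat,
        "p_value": p,
        "direction": {"a_higher": "lri_higher", "b_higher": "non_lri_higher"}.get(direction, "none"),
        "lri_mean_b_coverage": float(np.mean(lri_cov)),
        "non_lri_mean_b_coverage": float(np.mean(non_cov)),
        "n_lri": len(lri_cov),
        "n_non_lri": len(non_cov),
    }
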