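"""Interaction-restricted long-range cis-eQTL mapping.

Candidate SNP-gene pairs are windowed by the distance from the SNP to the
nearer gene end: "short" (< 1 Mb, the conventional cis window) or "long"
(1-2 Mb). Long-range pairs are tested only when physically supported by a
promoter-capture interaction: the SNP must fall inside the other-end
fragment of an interaction baited at the gene's promoter, and the
interaction's distance class must match the window. Multiple testing over
supported long-range pairs uses Bonferroni with the number of independent
signals (greedy LD pruning at r^2 < 0.2) rather than the raw test count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import Gene, Interaction
from .interactions import classify_distance
from .expression import ExpressionMatrix

__all__ = [
    "GenotypeMatrix",
    "CandidatePair",
    "AssociationResult",
    "filter_expressed_genes",
    "filter_snps",
    "ols_association",
    "enumerate_candidate_pairs",
    "restrict_pairs_by_interaction",
    "ld_r2_matrix",
    "count_independent_and_adjust",
    "short_range_fdr_check",
]

SHORT_MAX = 1_000_000
LONG_MAX = 2_000_000


@dataclass
class GenotypeMatrix:
    """SNPs x individuals dosage matrix with positional metadata."""

    snp_ids: list[str]
    chroms: list[str]
    positions: list[int]
    dosages: np.ndarray
    info: np.ndarray | None = None  # imputation quality, optional

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if self.dosages.shape[0] != len(self.snp_ids):
            raise ValueError("dosage rows must match snp_ids")
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise ValueError("dosages must lie in [0, 2]")

    def subset(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in keep],
            chroms=[self.chroms[i] for i in keep],
            positions=[self.positions[i] for i in keep],
            dosages=self.dosages[keep],
            info=self.info[keep] if self.info is not None else None,
        )

    def row(self, snp_id: str) -> np.ndarray:
        return self.dosages[self.snp_ids.index(snp_id)]


def filter_expressed_genes(expr: ExpressionMatrix, min_fraction: float = 0.90) -> list[str]:
    """Genes expressed (> 0) in strictly more than ``min_fraction`` of
    individuals."""
    frac = (expr.values > 0).mean(axis=1)
    return [g for g, f in zip(expr.gene_ids, frac) if f > min_fraction]


def _hwe_chi2_p(dosages: np.ndarray) -> float:
    """1-dof Hardy-Weinberg chi-square on dosages rounded to hard calls."""
    calls = np.clip(np.rint(dosages), 0, 2).astype(int)
    n = len(calls)
    n0, n1, n2 = np.bincount(calls, minlength=3)[:3]
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n0, n1, n2], dtype=float)
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    info_min: float = 0.8,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply MAF, Hardy-Weinberg and imputation-info filters.

    MAF is the folded mean dosage / 2; SNPs with HWE p below ``hwe_p_min``
    are removed; the info rule is skipped when no info scores are present.
    Returns the surviving subset plus a per-rule removal audit.
    """
    audit = {"info": 0, "maf": 0, "hwe": 0}
    keep = []
    for i in range(len(geno.snp_ids)):
        if geno.info is not None and geno.info[i] < info_min:
            audit["info"] += 1
            continue
        maf = geno.dosages[i].mean() / 2
        maf = min(maf, 1 - maf)
        if maf < maf_min:
            audit["maf"] += 1
            continue
        if _hwe_chi2_p(geno.dosages[i]) < hwe_p_min:
            audit["hwe"] += 1
            continue
        keep.append(i)
    return geno.subset(keep), audit


def ols_association(
    snp_dosages: np.ndarray,
    gene_expr: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """OLS of expression on dosage (+ covariates + intercept).

    Returns (beta, t, two-sided p) for the dosage term, the additive linear
    model a Matrix-eQTL-style analysis fits.
    """
    g = np.asarray(snp_dosages, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if g.shape != y.shape:
        raise ValueError("dosage and expression vectors must have equal length")
    n = len(y)
    cols = [np.ones(n), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n:
            cov = cov.T
        cols.extend(cov)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k:
        raise ValueError("not enough observations for the model")
    # check dosage variance after projecting out the other columns
    others = np.delete(X, 1, axis=1)
    resid_g = g - others @ np.linalg.lstsq(others, g, rcond=None)[0]
    if np.allclose(resid_g, 0):
        raise ValueError("zero dosage variance after covariate projection")
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * xtx_inv[1, 1])
    beta = float(beta_hat[1])
    if se == 0:
        return beta, math.inf if beta else 0.0, 0.0 if beta else 1.0
    t = beta / se
    p = 2 * float(stats.t.sf(abs(t), dof))
    return beta, float(t), p


@dataclass
class CandidatePair:
    snp_id: str
    gene_id: str
    distance: int
    window_class: str  # short | long
    interaction_supported: bool = False


@dataclass
class AssociationResult:
    snp_id: str
    gene_id: str
    beta: float
    t_stat: float
    p_value: float
    window_class: str
    interaction_supported: bool
    p_adj: float = math.nan
    n_independent: int = 0
    q_value: float = math.nan


def enumerate_candidate_pairs(
    genes: Sequence[Gene],
    geno: GenotypeMatrix,
    short_max: int = SHORT_MAX,
    long_max: int = LONG_MAX,
) -> list[CandidatePair]:
    """All SNP-gene pairs within 2 Mb of the nearer gene end, windowed as
    short (< 1 Mb) or long (1-2 Mb); SNPs inside the gene body are distance 0."""
    pairs = []
    for gene in genes:
        iv = gene.interval
        for i, (chrom, pos) in enumerate(zip(geno.chroms, geno.positions)):
            if chrom != iv.chrom:
                continue
            if iv.start <= pos < iv.end:
                d = 0
            else:
                d = min(abs(pos - iv.start), abs(pos - (iv.end - 1)))
            if d < short_max:
                wc = "short"
            elif d < long_max:
                wc = "long"
            else:
                continue
            pairs.append(CandidatePair(geno.snp_ids[i], gene.gene_id, d, wc))
    return pairs


def restrict_pairs_by_interaction(
    pairs: Sequence[CandidatePair],
    interactions: Sequence[Interaction],
    genes: Sequence[Gene],
    geno: GenotypeMatrix,
) -> tuple[list[CandidatePair], dict[str, int]]:
    """Flag pairs physically supported by an interaction.

    A pair is supported iff some interaction is baited at the gene's promoter
    fragment, the SNP position falls inside the other-end fragment
    (half-open), and the interaction's distance class matches the pair's
    window (long pairs require LRIs, short pairs SRIs).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    pos_by_snp = dict(zip(geno.snp_ids, zip(geno.chroms, geno.positions)))
    by_bait: dict[str, list[Interaction]] = {}
    for x in interactions:
        by_bait.setdefault(x.bait.fragment_id, []).append(x)
    audit = {"genes_without_bait": 0}
    wanted = {"short": "SRI", "long": "LRI"}
    out = []
    for pair in pairs:
        gene = gene_by_id[pair.gene_id]
        supported = False
        if gene.bait_fragment_id is None:
            audit["genes_without_bait"] += 1
        else:
            chrom, pos = pos_by_snp[pair.snp_id]
            for x in by_bait.get(gene.bait_fragment_id, ()):
                if (
                    x.other_end.interval.contains(chrom, pos)
                    and classify_distance(x) == wanted[pair.window_class]
                ):
                    supported = True
                    break
        out.append(
            CandidatePair(pair.snp_id, pair.gene_id, pair.distance, pair.window_class, supported)
        )
    return out, audit


def ld_r2_matrix(geno: GenotypeMatrix, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Squared Pearson correlation between dosage vectors of the given SNPs."""
    rows = np.array([geno.row(s) for s in snp_ids])
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(rows)
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=list(snp_ids), columns=list(snp_ids))


def count_independent_and_adjust(
    results: Sequence[AssociationResult],
    ld: pd.DataFrame,
    r2_max: float = 0.2,
    per_gene: bool = True,
) -> tuple[list[AssociationResult], int]:
    """Greedy LD pruning and Bonferroni adjustment of long-range results.

    An independent signal is an association of an LD-distinct locus with a
    gene: results are visited in ascending p-value order and accepted when
    their SNP has r^2 below ``r2_max`` against every previously accepted SNP
    for the same gene (with ``per_gene=False``, against every accepted SNP
    regardless of gene). The accepted count is the number of independent
    signals, and every result gets p_adj = min(1, p * n_independent).
    """
    snps = {r.snp_id for r in results}
    missing = snps - set(ld.index)
    if missing:
        raise ValueError(f"LD matrix missing SNPs: {sorted(missing)[:5]}")
    accepted: list[tuple[str, str]] = []  # (snp, gene)
    for r in sorted(results, key=lambda r: (r.p_value, r.snp_id, r.gene_id)):
        if (r.snp_id, r.gene_id) in accepted:
            continue
        conflicts = (
            a for a in accepted if per_gene is False or a[1] == r.gene_id
        )
        if all(float(ld.loc[r.snp_id, a[0]]) < r2_max for a in conflicts):
            accepted.append((r.snp_id, r.gene_id))
    n_independent = max(1, len(accepted))
    adjusted = []
    for r in results:
        adjusted.append(
            AssociationResult(
                snp_id=r.snp_id, gene_id=r.gene_id, beta=r.beta, t_stat=r.t_stat,
                p_value=r.p_value, window_class=r.window_class,
                interaction_supported=r.interaction_supported,
                p_adj=min(1.0, r.p_value * n_independent),
                n_independent=n_independent,
            )
        )
    return adjusted, n_independent


def short_range_fdr_check(
    long_snps: Sequence[str],
    short_results: Sequence[AssociationResult],
    fdr: float = 0.05,
) -> dict[str, bool]:
    """Flag long-range SNPs that also significantly regulate a gene through a
    supported short-range pair (BH q < ``fdr`` over all short-range tests)."""
    flags = {s: False for s in long_snps}
    if not short_results:
        return flags
    ps = [r.p_value for r in short_results]
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    for r, q in zip(short_results, qs):
        r.q_value = float(q)
        if r.interaction_supported and q < fdr and r.snp_id in flags:
            flags[r.snp_id] = True
    return flags
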