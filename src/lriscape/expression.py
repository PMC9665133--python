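"""Expression stratification by interaction distance class.

Genes are classed by the distance classes of the interactions baited at
their promoter fragment (SRI-only / LRI-only / both / neither); the
SRI-vs-LRI comparisons exclude "both". External RNA-seq time courses are
matched to the pCHi-C time points by Spearman correlation over the most
highly expressed genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import Gene, Interaction, MidpointIndex, TAD
from .interactions import classify_distance
from .tad_annotation import TADAnnotation

__all__ = [
    "ExpressionMatrix",
    "GeneInteractionClass",
    "match_timepoints_by_correlation",
    "classify_genes_by_interaction",
    "expressed_fraction_test",
    "expression_level_test",
    "bystander_gene_test",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values (FPKM/TPM)."""

    gene_ids: list[str]
    sample_labels: list[str]
    values: np.ndarray
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValueError("values shape does not match gene/sample labels")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.sample_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_labels)

    @classmethod
    def from_tsv(cls, path, unit: str = "FPKM") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(), unit=unit)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class GeneInteractionClass:
    gene_id: str
    interaction_class: str  # SRI-only | LRI-only | both | neither


def match_timepoints_by_correlation(
    reference: ExpressionMatrix,
    query: ExpressionMatrix,
    top_n: int = 5000,
) -> dict[str, dict]:
    """Match each query time point to the best-correlated reference time point.

    For each reference column the ``top_n`` most highly expressed genes (in
    that column, over the genes shared with the query) are selected, and the
    Spearman correlation with each query column over those genes is
    computed. Returns, per query column, the argmax reference column and the
    full correlation profile.
    """
    shared = [g for g in reference.gene_ids if g in set(query.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between reference and query")
    if len(shared) < top_n:
        warnings.warn(
            f"only {len(shared)} shared genes; lowering top_n from {top_n}"
        )
        top_n = len(shared)
    ref = reference.to_frame().loc[shared]
    qry = query.to_frame().loc[shared]
    out: dict[str, dict] = {}
    for q in qry.columns:
        profile: dict[str, float] = {}
        for r in ref.columns:
            top = ref[r].nlargest(top_n).index
            rho = stats.spearmanr(ref.loc[top, r], qry.loc[top, q]).statistic
            profile[r] = float(rho)
        best = max(profile, key=lambda k: profile[k])
        out[q] = {"best_reference": best, "profile": profile}
    return out


def classify_genes_by_interaction(
    genes: Sequence[Gene],
    interactions: Sequence[Interaction],
) -> list[GeneInteractionClass]:
    """Class each gene by the distance classes of interactions baited at its
    promoter fragment. Interactions in the excluded (>2 Mb) class are ignored."""
    classes_by_bait: dict[str, set[str]] = {}
    for x in interactions:
        cls = classify_distance(x)
        if cls == "excluded":
            continue
        classes_by_bait.setdefault(x.bait.fragment_id, set()).add(cls)
    out = []
    for gene in genes:
        seen = classes_by_bait.get(gene.bait_fragment_id or "", set())
        if seen == {"SRI"}:
            cls = "SRI-only"
        elif seen == {"LRI"}:
            cls = "LRI-only"
        elif seen == {"SRI", "LRI"}:
            cls = "both"
        else:
            cls = "neither"
        out.append(GeneInteractionClass(gene.gene_id, cls))
    return out


def _matched_values(
    gene_ids: Sequence[str],
    expr: ExpressionMatrix,
    sample_label: str,
) -> np.ndarray:
    frame = expr.to_frame()
    present = [g for g in gene_ids if g in frame.index]
    return frame.loc[present, sample_label].to_numpy()


def expressed_fraction_test(
    classes: Sequence[GeneInteractionClass],
    expr: ExpressionMatrix,
    timepoint_map: Mapping[str, str],
    timepoint: str,
    threshold: float = 0.0,
) -> dict:
    """2x2 chi-square of expressed (value > threshold) vs interaction class
    (SRI-only vs LRI-only) at one time point."""
    label = timepoint_map[timepoint]
    table = np.zeros((2, 2))
    for i, cls in enumerate(("SRI-only", "LRI-only")):
        ids = [c.gene_id for c in classes if c.interaction_class == cls]
        if not ids:
            raise ValueError(f"no genes in class {cls}")
        vals = _matched_values(ids, expr, label)
        table[i] = [(vals > threshold).sum(), (vals <= threshold).sum()]
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table (zero margin)")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {
        "table": table,
        "chi2": float(chi2),
        "p_value": float(p),
        "expressed_fraction": {
            "SRI-only": table[0, 0] / table[0].sum(),
            "LRI-only": table[1, 0] / table[1].sum(),
        },
    }


def _welch_on_log(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if np.allclose(la, la.mean()) and np.allclose(lb, la.mean()):
        return 0.0, 1.0
    res = stats.ttest_ind(la, lb, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def expression_level_test(
    classes: Sequence[GeneInteractionClass],
    expr_by_timepoint: Mapping[str, ExpressionMatrix],
    timepoint_map: Mapping[str, str],
    adjust: str = "bonferroni",
) -> dict[str, dict]:
    """Per-time-point Welch t-test of log2(x+1) expression, SRI-only vs
    LRI-only genes, with Bonferroni (default) adjustment over time points."""
    sri = [c.gene_id for c in classes if c.interaction_class == "SRI-only"]
    lri = [c.gene_id for c in classes if c.interaction_class == "LRI-only"]
    results: dict[str, dict] = {}
    m = len(expr_by_timepoint)
    for tp, expr in expr_by_timepoint.items():
        label = timepoint_map[tp]
        a = _matched_values(sri, expr, label)
        b = _matched_values(lri, expr, label)
        if len(a) < 2 or len(b) < 2:
            results[tp] = {"t": math.nan, "p_value": math.nan, "p_adj": math.nan,
                           "n_sri": len(a), "n_lri": len(b)}
            continue
        t, p = _welch_on_log(a, b)
        results[tp] = {"t": t, "p_value": p, "n_sri": len(a), "n_lri": len(b),
                       "mean_log2_sri": float(np.log2(a + 1).mean()),
                       "mean_log2_lri": float(np.log2(b + 1).mean())}
    ps = {tp: r["p_value"] for tp, r in results.items() if not math.isnan(r.get("p_value", math.nan))}
    if adjust == "bonferroni":
        for tp in ps:
            results[tp]["p_adj"] = min(1.0, ps[tp] * m)
    elif adjust == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        order = list(ps)
        _, q, _, _ = multipletests([ps[tp] for tp in order], method="fdr_bh")
        for tp, qv in zip(order, q):
            results[tp]["p_adj"] = float(qv)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def bystander_gene_test(
    sri_only_genes: Sequence[Gene],
    annotations: Sequence[TADAnnotation],
    tads: Sequence[TAD],
    expr_by_timepoint: Mapping[str, ExpressionMatrix],
    timepoint_map: Mapping[str, str],
) -> dict[str, dict]:
    """Welch t-test of expression for SRI-only genes inside vs outside LRI
    TADs, per time point (TAD membership by gene midpoint; arm assignment by
    the TAD's LRI flag at that time point)."""
    index = MidpointIndex([t.interval for t in tads], [t.tad_id for t in tads])
    ann_by_id = {a.tad_id: a for a in annotations}
    results: dict[str, dict] = {}
    for tp, expr in expr_by_timepoint.items():
        in_lri, out_lri = [], []
        for gene in sri_only_genes:
            tid = index.lookup(gene.interval.chrom, gene.interval.midpoint)
            ann = ann_by_id.get(tid) if tid is not None else None
            if ann is None or ann.category == "excluded":
                continue
            (in_lri if ann.lri_flags.get(tp, False) else out_lri).append(gene.gene_id)
        label = timepoint_map[tp]
        a = _matched_values(in_lri, expr, label)
        b = _matched_values(out_lri, expr, label)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{tp}: need >=2 genes in each arm "
                             f"(got {len(a)} in LRI TADs, {len(b)} outside)")
        t, p = _welch_on_log(a, b)
        results[tp] = {
            "t": t, "p_value": p,
            "n_in_lri_tads": len(a), "n_outside": len(b),
            "mean_log2_in_lri": float(np.log2(a + 1).mean()),
            "mean_log2_outside": float(np.log2(b + 1).mean()),
        }
    return results
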