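"""End-to-end orchestration of the analysis stages on simulated or file inputs.

`run_all` executes the stages in dependency order — interaction filtering and
distance-class statistics, TAD annotation and chromHMM coverage, A/B
compartment calling, feature enrichment, expression stratification, and the
interaction-restricted long-range eQTL analysis — writing headered TSV/JSON
outputs plus a machine-readable run report that records every threshold used
and every filter audit. Outputs carry no timestamps, so a rerun with the same
seed is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import compartments as cmp
from . import enrichment as enr
from . import eqtl as eq
from . import expression as ex
from . import interactions as ia
from . import tad_annotation as ta
from .genomic_io import Gene, Interaction, write_bed_intervals, write_interaction_table
from .synthetic import TIMEPOINTS, SyntheticConfig, SyntheticDataset, generate_all

__all__ = ["RunConfig", "run_all", "supported_pairs_from_interactions", "fast_pair_ols"]


@dataclass
class RunConfig:
    """All thresholds of the pipeline; defaults are the study's printed values."""

    seed: int = 0
    score_min: float = 5.0
    sri_max: int = 1_000_000
    lri_max: int = 2_000_000
    concordance_bin: int = 50_000
    min_union: int = 10
    compartment_bin: int = 100_000
    smoothing_window: int = 3
    n_permutations: int = 10_000
    top_n: int = 5_000
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    info_min: float = 0.8
    r2_max: float = 0.2
    fdr: float = 0.05
    expressed_fraction: float = 0.90
    expressed_threshold: float = 0.0
    min_expected: float = 5.0
    pseudocount: float = 1.0
    simulate: SyntheticConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SyntheticConfig(**sim) if isinstance(sim, dict) else SyntheticConfig()
        return cfg


def supported_pairs_from_interactions(
    interactions: Sequence[Interaction],
    genes: Sequence[Gene],
    geno: eq.GenotypeMatrix,
    sri_max: int = 1_000_000,
    lri_max: int = 2_000_000,
) -> list[eq.CandidatePair]:
    """Enumerate interaction-supported SNP-gene pairs directly.

    Walks the interactions instead of the full SNP x gene grid: for each
    interaction baited at a gene promoter, every SNP inside the other-end
    fragment forms a candidate pair, kept when the SNP-gene distance window
    (short/long) matches the interaction's distance class.
    """
    gene_by_bait: dict[str, list[Gene]] = {}
    for g in genes:
        if g.bait_fragment_id is not None:
            gene_by_bait.setdefault(g.bait_fragment_id, []).append(g)
    pos_by_chrom: dict[str, np.ndarray] = {}
    ids_by_chrom: dict[str, np.ndarray] = {}
    order_chrom = sorted(set(geno.chroms))
    for chrom in order_chrom:
        idx = [i for i, c in enumerate(geno.chroms) if c == chrom]
        pos_by_chrom[chrom] = np.array([geno.positions[i] for i in idx])
        ids_by_chrom[chrom] = np.array([geno.snp_ids[i] for i in idx], dtype=object)
    seen: set[tuple[str, str]] = set()
    out: list[eq.CandidatePair] = []
    for x in interactions:
        baited = gene_by_bait.get(x.bait.fragment_id)
        if not baited:
            continue
        cls = ia.classify_distance(x, sri_max, lri_max)
        if cls == "excluded":
            continue
        oe = x.other_end.interval
        pos = pos_by_chrom.get(oe.chrom)
        if pos is None:
            continue
        lo = int(np.searchsorted(pos, oe.start, side="left"))
        hi = int(np.searchsorted(pos, oe.end, side="left"))
        for gene in baited:
            iv = gene.interval
            for i in range(lo, hi):
                p = int(pos[i])
                if iv.start <= p < iv.end:
                    d = 0
                else:
                    d = min(abs(p - iv.start), abs(p - (iv.end - 1)))
                if d < sri_max:
                    wc = "short"
                elif d < lri_max:
                    wc = "long"
                else:
                    continue
                if (wc == "short") != (cls == "SRI"):
                    continue
                key = (str(ids_by_chrom[oe.chrom][i]), gene.gene_id)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    eq.CandidatePair(key[0], key[1], d, wc, interaction_supported=True)
                )
    return out


def fast_pair_ols(G: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple OLS (no covariates) for many (dosage, expression) pairs.

    ``G`` and ``Y`` are pairs x individuals. Algebraically identical to
    :func:`lriscape.eqtl.ols_association` with no covariates.
    """
    n = G.shape[1]
    gc = G - G.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    sgg = (gc**2).sum(axis=1)
    syy = (yc**2).sum(axis=1)
    sgy = (gc * yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sgy / sgg
        r2 = np.where((sgg > 0) & (syy > 0), sgy**2 / (sgg * syy), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        t = np.sign(beta) * np.sqrt(r2 * (n - 2) / (1 - r2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return beta, t, p


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def run_all(config: RunConfig, out_dir: str | Path, dataset: SyntheticDataset | None = None) -> dict:
    """Run every stage on a simulated dataset and write all outputs.

    ``dataset`` may be passed to reuse an already-generated simulation;
    otherwise ``config.simulate`` (or a default config seeded with
    ``config.seed``) is generated. Returns the run report, also written to
    ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        sim_cfg = config.simulate or SyntheticConfig(seed=config.seed)
        dataset = generate_all(sim_cfg)
    report: dict = {"thresholds": {k: v for k, v in asdict(config).items() if k != "simulate"},
                    "simulate": asdict(dataset.config)}

    # ---- emit the input files (also exercises the writers)
    write_bed_intervals(out / "tads.bed",
                        [t.interval for t in dataset.layout.tads],
                        [t.tad_id for t in dataset.layout.tads])
    write_bed_intervals(out / "features.bed", dataset.features)
    for tp, reps in dataset.interactions.items():
        for rep, rows in reps.items():
            write_interaction_table(out / f"interactions_{tp}_{rep}.ibed", rows)

    # ---- interactions stage
    filtered: dict[str, dict[str, list[Interaction]]] = {}
    audits = {}
    for tp, reps in dataset.interactions.items():
        filtered[tp] = {}
        for rep, rows in reps.items():
            kept, audit = ia.filter_significant(
                rows, score_threshold=config.score_min, max_distance=config.lri_max
            )
            filtered[tp][rep] = kept
            audits[f"{tp}_{rep}"] = {"removed": audit.removed, "n_input": audit.n_input,
                                     "n_retained": audit.n_retained}
    conc_rows = []
    for tp in dataset.interactions:
        for b in ia.replicate_concordance(filtered[tp]["rep1"], filtered[tp]["rep2"],
                                          bin_width=config.concordance_bin,
                                          min_union=config.min_union):
            conc_rows.append((tp, b.bin_start, b.bin_end, b.n_union, b.n_shared, b.proportion))
    pd.DataFrame(conc_rows, columns=["timepoint", "bin_start", "bin_end", "n_union",
                                     "n_shared", "proportion"]).to_csv(
        out / "concordance.tsv", sep="\t", index=False)

    lri_prop = {}
    read_support = {}
    for tp in dataset.interactions:
        classes = [ia.classify_distance(x, config.sri_max, config.lri_max)
                   for x in filtered[tp]["rep1"]]
        n = len(classes)
        lri_prop[tp] = classes.count("LRI") / n if n else math.nan
        read_support[tp] = ia.read_support_summary(filtered[tp]["rep1"],
                                                   config.sri_max, config.lri_max)
    fold_changes = {}
    tps = list(dataset.interactions)
    for a, b in zip(tps[:-1], tps[1:]):
        fold_changes[f"{a}->{b}"] = ia.proportion_fold_change(lri_prop[a], lri_prop[b])
    sharing = ia.timepoint_sharing({tp: filtered[tp]["rep1"] for tp in tps}, restrict_to="LRI")
    report["interactions"] = {
        "filter_audits": audits,
        "lri_proportion": lri_prop,
        "lri_fold_change": fold_changes,
        "read_support": read_support,
        "lri_sharing_counts": sharing.counts,
        "lri_fraction_shared_2plus": sharing.fraction_shared_2plus,
    }

    # ---- TAD annotation stage
    lri_ends = {
        tp: [f for x in filtered[tp]["rep1"]
             for f in (x.bait, x.other_end)
             if ia.classify_distance(x, config.sri_max, config.lri_max) == "LRI"]
        for tp in tps
    }
    all_ends = [f for tp in tps for x in filtered[tp]["rep1"] for f in (x.bait, x.other_end)]
    annotations = ta.classify_tads(lri_ends, all_ends, dataset.layout.tads)
    groups = ta.StateGroupMap()
    coverages = {
        t.tad_id: ta.tad_state_coverage(t, dataset.chrom_states, groups)
        for t in dataset.layout.tads
    }
    lri_cov = [coverages[a.tad_id] for a in annotations if a.is_lri_tad]
    non_cov = [coverages[a.tad_id] for a in annotations
               if a.category == "none"]
    coverage_tests = {
        g: ta.compare_tad_coverage(lri_cov, non_cov, g)
        for g in ("quiescent", "active", "promoter", "enhancer")
    }
    marker_genes = {
        ct: [g for g in dataset.layout.genes if g.gene_id in set(ids)]
        for ct, ids in dataset.truth.marker_genes.items()
    }
    try:
        marker_test = ta.marker_gene_category_test(
            marker_genes, annotations, dataset.layout.tads, min_expected=config.min_expected
        )
        marker_report = {k: _jsonable(v) for k, v in marker_test.items() if k != "table"}
    except ValueError as exc:
        marker_report = {"error": str(exc)}
    crossing = ta.boundary_crossing_fraction(filtered[tps[0]]["rep1"], dataset.layout.tads)
    pd.DataFrame(
        [(a.tad_id, a.category, a.has_any_interaction,
          *[a.lri_flags[tp] for tp in tps]) for a in annotations],
        columns=["tad_id", "category", "has_any_interaction", *[f"lri_{tp}" for tp in tps]],
    ).to_csv(out / "tad_annotations.tsv", sep="\t", index=False)
    category_counts: dict[str, int] = {}
    for a in annotations:
        category_counts[a.category] = category_counts.get(a.category, 0) + 1
    report["tads"] = {
        "category_counts": category_counts,
        "coverage_tests": coverage_tests,
        "marker_gene_test": marker_report,
        "boundary_crossing_fraction": crossing,
    }

    # ---- compartments stage
    binned = cmp.bin_accessibility(
        dataset.accessibility_reads, dataset.layout.chrom_lengths,
        bin_size=config.compartment_bin,
    )
    binned = cmp.normalize_and_correct(binned, dataset.accessibility_meta,
                                       pseudocount=config.pseudocount)
    calls = cmp.call_compartments(binned, window=config.smoothing_window)
    calls.table.to_csv(out / "compartments.tsv", sep="\t", index=False)
    truth_labels = dataset.truth.compartment_labels
    called = calls.table[calls.table["label"].isin(["A", "B"])]
    agree = sum(
        truth_labels.get((row["chrom"], int(row["start"]))) == row["label"]
        for _, row in called.iterrows()
    )
    recovery = agree / len(called) if len(called) else math.nan
    b_enrich = cmp.compartment_lri_tad_enrichment(calls, annotations, dataset.layout.tads)
    report["compartments"] = {
        "n_bins_called": int(len(called)),
        "planted_label_recovery": recovery,
        "degenerate_chroms": calls.degenerate_chroms,
        "skipped_chroms": calls.skipped_chroms,
        "b_enrichment_in_lri_tads": b_enrich,
    }

    # ---- enrichment stage
    lri_tad_ids = {a.tad_id for a in annotations if a.is_lri_tad}
    eligible = {a.tad_id for a in annotations if a.category != "excluded"}
    perm = enr.permutation_test(
        dataset.features, dataset.layout.tads, lri_tad_ids, eligible_tad_ids=eligible,
        n_permutations=config.n_permutations, seed=config.seed,
    )
    try:
        hyper_p = enr.hypergeometric_test(
            perm.observed,
            len(dataset.features),
            len(lri_tad_ids & eligible),
            len(eligible),
        )
    except ValueError:  # more features than TADs: sampling model inapplicable
        hyper_p = math.nan
    report["enrichment"] = {
        "observed": perm.observed,
        "permutation_p": perm.p_value,
        "hypergeometric_p": hyper_p,
        "n_permutations": perm.n_permutations,
    }

    # ---- expression stage
    query = ex.ExpressionMatrix(
        list(dataset.expression[tps[0]].gene_ids),
        tps,
        np.column_stack([dataset.expression[tp].values[:, 0] for tp in tps]),
    )
    matches = ex.match_timepoints_by_correlation(
        dataset.expression_reference, query, top_n=config.top_n
    )
    union_interactions = [x for tp in tps for x in filtered[tp]["rep1"]]
    classes = ex.classify_genes_by_interaction(dataset.layout.genes, union_interactions)
    timepoint_map = {tp: f"{tp}_r1" for tp in tps}
    try:
        frac_test = ex.expressed_fraction_test(
            classes, dataset.expression[tps[-1]], timepoint_map, tps[-1],
            threshold=config.expressed_threshold,
        )
        frac_report = {"chi2": frac_test["chi2"], "p_value": frac_test["p_value"],
                       "expressed_fraction": frac_test["expressed_fraction"]}
    except ValueError as exc:
        frac_report = {"error": str(exc)}
    level = ex.expression_level_test(classes, dataset.expression, timepoint_map)
    sri_only = [g for g, c in zip(dataset.layout.genes, classes)
                if c.interaction_class == "SRI-only"]
    bystander = ex.bystander_gene_test(
        sri_only, annotations, dataset.layout.tads, dataset.expression, timepoint_map
    )
    class_counts: dict[str, int] = {}
    for c in classes:
        class_counts[c.interaction_class] = class_counts.get(c.interaction_class, 0) + 1
    report["expression"] = {
        "timepoint_matches": {q: m["best_reference"] for q, m in matches.items()},
        "gene_class_counts": class_counts,
        "expressed_fraction_test": frac_report,
        "level_tests": level,
        "bystander_tests": bystander,
    }

    # ---- eQTL stage
    kept_genes = set(eq.filter_expressed_genes(dataset.expression_individuals,
                                               config.expressed_fraction))
    geno_f, snp_audit = eq.filter_snps(dataset.genotypes, maf_min=config.maf_min,
                                       hwe_p_min=config.hwe_p_min, info_min=config.info_min)
    genes_f = [g for g in dataset.layout.genes if g.gene_id in kept_genes]
    pairs = supported_pairs_from_interactions(
        union_interactions, genes_f, geno_f, config.sri_max, config.lri_max
    )
    expr_log = np.log2(dataset.expression_individuals.values + 1.0)
    gene_row = {g: i for i, g in enumerate(dataset.expression_individuals.gene_ids)}
    snp_row = {s: i for i, s in enumerate(geno_f.snp_ids)}

    def run_pairs(plist: list[eq.CandidatePair]) -> list[eq.AssociationResult]:
        if not plist:
            return []
        G = geno_f.dosages[[snp_row[p.snp_id] for p in plist]]
        Y = expr_log[[gene_row[p.gene_id] for p in plist]]
        beta, t, p = fast_pair_ols(G, Y)
        return [
            eq.AssociationResult(pr.snp_id, pr.gene_id, float(b), float(tt), float(pp),
                                 pr.window_class, pr.interaction_supported)
            for pr, b, tt, pp in zip(plist, beta, t, p)
        ]

    long_pairs = [p for p in pairs if p.window_class == "long"]
    short_pairs = [p for p in pairs if p.window_class == "short"]
    long_results = run_pairs(long_pairs)
    if long_results:
        ld = eq.ld_r2_matrix(geno_f, sorted({r.snp_id for r in long_results}))
        long_results, n_indep = eq.count_independent_and_adjust(long_results, ld, config.r2_max)
    else:
        n_indep = 0
    short_results = run_pairs(short_pairs)
    long_snps = sorted({r.snp_id for r in long_results})
    short_flags = eq.short_range_fdr_check(long_snps, short_results, fdr=config.fdr)
    rows = [
        (r.snp_id, r.gene_id, r.window_class, r.beta, r.t_stat, r.p_value, r.p_adj,
         r.n_independent, short_flags.get(r.snp_id, False))
        for r in sorted(long_results, key=lambda r: (r.p_value, r.snp_id, r.gene_id))
    ]
    pd.DataFrame(rows, columns=["snp_id", "gene_id", "window", "beta", "t", "p_value",
                                "p_adj", "n_independent", "also_short_range_fdr"]).to_csv(
        out / "eqtl_long_range.tsv", sep="\t", index=False)
    significant = [r for r in long_results if r.p_adj < 0.05]
    planted = dataset.truth.planted_eqtl
    planted_hit = None
    if planted is not None:
        planted_hit = any(r.snp_id == planted[0] and r.gene_id == planted[1]
                          for r in significant)
    report["eqtl"] = {
        "snp_filter_audit": snp_audit,
        "n_genes_expressed": len(kept_genes),
        "n_supported_long_pairs": len(long_results),
        "n_supported_short_pairs": len(short_results),
        "n_independent_signals": n_indep,
        "n_significant_long": len(significant),
        "significant_long": [(r.snp_id, r.gene_id, r.beta, r.p_adj) for r in significant],
        "planted_eqtl": list(planted) if planted else None,
        "planted_eqtl_detected": planted_hit,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
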