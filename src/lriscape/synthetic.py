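"""Synthetic miniature study with planted ground truth.

Generates every input the pipeline consumes — restriction-fragment map, TADs,
genes with promoter baits, per-time-point/per-replicate interaction tables,
chromHMM-style segmentations, expression matrices, binned accessibility
reads, genotypes — together with a :class:`SyntheticTruth` record of what was
planted, so that every stage's output can be checked against a known answer.

The stated world mirrors the study being emulated: three time points
(PAd, Diff, Adip), two biological replicates of significant interactions per
time point, an LRI share of all interactions rising 1.1% -> 2.6% -> 3.0%
across time points, LRIs planted with both ends inside "repressed" TADs
(high quiescent chromHMM coverage, lower gene expression), alternating A/B
accessibility compartments, LD-block genotypes, and one long-range eQTL
routed through a planted LRI.

Background (non-planted) interactions follow a power-law distance decay on
[20 kb, 1 Mb); interactions beyond 2 Mb are emitted at a small decoy rate so
the distance filter is exercised, as are sub-threshold score decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import (
    TAD,
    ChromStateSegment,
    Gene,
    GenomicInterval,
    Interaction,
    MidpointIndex,
    RestrictionFragment,
)
from .compartments import AccessibilitySampleMeta
from .expression import ExpressionMatrix
from .eqtl import GenotypeMatrix

__all__ = [
    "TIMEPOINTS",
    "SyntheticConfig",
    "GenomeLayout",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_genome_layout",
    "generate_interaction_replicates",
    "generate_chromatin_states",
    "generate_expression",
    "generate_accessibility",
    "generate_genotypes",
    "generate_features",
    "generate_all",
]

TIMEPOINTS = ("PAd", "Diff", "Adip")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 12_000_000
    fragment_mean_length: int = 4_000
    tad_mean_length: int = 800_000
    frac_repressed_tads: float = 0.25
    n_genes_per_chrom: int = 300
    interactions_per_replicate: int = 20_000
    distance_decay_exponent: float = 1.0
    min_interaction_distance: int = 20_000
    # LRI share of significant interactions per time point (PAd and Diff per
    # the emulated study; Adip chosen as a continued modest increase)
    lri_rate_in_repressed_tads: Mapping[str, float] = field(
        default_factory=lambda: {"PAd": 0.011, "Diff": 0.026, "Adip": 0.030}
    )
    ultra_long_decoy_rate: float = 0.004  # > 2 Mb rows, removed by distance filter
    score_decoy_rate: float = 0.10  # sub-threshold scores, removed by score filter
    lri_persistence: float = 0.6  # chance a planted LRI carries over to the next time point
    # only some repressed-TAD promoters act as LRI baits, so LRI TADs keep
    # bystander genes that are not themselves LRI-involved
    lri_bait_gene_fraction: float = 0.35
    # repressed-TAD promoters are depleted of significant short-range contacts,
    # so a fraction of LRI genes end up LRI-only (as in the emulated study)
    sri_bait_weight_repressed: float = 0.005
    replicate_retention: Mapping[str, float] = field(
        default_factory=lambda: {"SRI": 0.8, "LRI": 0.6, "excluded": 0.3}
    )
    sri_read_mean: float = 12.0
    lri_read_mean: float = 6.0
    # expression
    expr_log2_mean: float = 4.0
    expr_log2_sd: float = 1.5
    expr_noise_sd: float = 0.5
    repression_multiplier: float = 0.5
    p_unexpressed: float = 0.15
    p_unexpressed_repressed: float = 0.40
    n_expr_replicates: int = 3
    # chromatin states
    quiescent_beta_repressed: tuple[float, float] = (8.0, 2.0)
    quiescent_beta_background: tuple[float, float] = (2.0, 8.0)
    segment_mean_length: int = 20_000
    # accessibility
    compartment_block_length: int = 1_000_000
    accessibility_bin_size: int = 100_000
    n_accessibility_samples: int = 8
    a_base_reads_per_bin: float = 100.0
    b_base_reads_per_bin: float = 40.0
    a_factor_loading: float = -0.3
    b_factor_loading: float = 0.5
    block_factor_sd: float = 0.2
    bin_noise_sd: float = 0.2
    frip_loading: float = 0.5
    # genotypes / eQTL
    n_individuals: int = 300
    snp_spacing: int = 5_000
    ld_block_length: int = 200_000
    block_divergent_fraction: float = 0.8
    # low mutation keeps within-block r^2 near 1, so LD-pruned signal counts
    # remain a faithful multiple-testing denominator (intermediate LD would
    # break the Bonferroni-on-independent-signals assumption)
    haplotype_mutation_rate: float = 0.01
    eqtl_beta: float = 0.8
    eqtl_maf: float = 0.3
    # markers / features
    n_marker_pad: int = 40
    n_marker_adip: int = 60
    marker_enrichment: float = 0.85
    n_features: int = 25
    feature_length: int = 20_000
    # per-individual expression dropout (exercises the >90%-expressed filter)
    p_gene_high_dropout: float = 0.15
    dropout_low: float = 0.02
    dropout_high: float = 0.25

    def validate(self) -> None:
        probs = [
            self.frac_repressed_tads, self.ultra_long_decoy_rate, self.score_decoy_rate,
            self.p_unexpressed, self.p_unexpressed_repressed, self.marker_enrichment,
            self.haplotype_mutation_rate, self.block_divergent_fraction, self.eqtl_maf,
            *self.lri_rate_in_repressed_tads.values(), *self.replicate_retention.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        lengths = [
            self.chrom_length, self.fragment_mean_length, self.tad_mean_length,
            self.compartment_block_length, self.ld_block_length, self.segment_mean_length,
        ]
        if any(x <= 0 for x in lengths):
            raise ValueError("all lengths must be positive")


@dataclass
class GenomeLayout:
    chrom_lengths: dict[str, int]
    fragments: list[RestrictionFragment]
    tads: list[TAD]
    genes: list[Gene]
    # per-chromosome fragment boundary arrays for fast position -> fragment lookup
    frag_starts: dict[str, np.ndarray]
    frag_index_offset: dict[str, int]

    def fragment_at(self, chrom: str, pos: int) -> RestrictionFragment:
        i = int(np.searchsorted(self.frag_starts[chrom], pos, side="right")) - 1
        return self.fragments[self.frag_index_offset[chrom] + i]


@dataclass
class SyntheticTruth:
    repressed_tad_ids: set[str]
    lri_tad_ids_by_timepoint: dict[str, set[str]]
    planted_lri_pairs: dict[str, list[tuple[str, str]]]  # tp -> (bait_frag, oe_frag)
    compartment_labels: dict[tuple[str, int], str]  # (chrom, bin start) -> A/B
    planted_eqtl: tuple[str, str, float] | None
    marker_genes: dict[str, list[str]]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    layout: GenomeLayout
    truth: SyntheticTruth
    interactions: dict[str, dict[str, list[Interaction]]]  # tp -> replicate -> rows
    chrom_states: list[ChromStateSegment]
    expression: dict[str, ExpressionMatrix]  # per time point
    expression_reference: ExpressionMatrix  # external-style time course
    expression_individuals: ExpressionMatrix  # genes x individuals (eQTL)
    accessibility_reads: dict[str, list[tuple[str, int]]]
    accessibility_meta: list[AccessibilitySampleMeta]
    genotypes: GenotypeMatrix
    features: list[GenomicInterval]


def _partition(total: int, mean: int, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
    """Random segment lengths (~ mean, truncated normal) summing exactly to total."""
    n = max(1, round(total / mean))
    raw = rng.normal(mean, jitter * mean, size=n).clip(mean * 0.2, mean * 2.5)
    bounds = np.concatenate([[0.0], np.cumsum(raw)]) * (total / raw.sum())
    bounds = np.unique(np.round(bounds).astype(np.int64))
    bounds[0], bounds[-1] = 0, total
    return bounds  # boundary positions incl. 0 and total


def generate_genome_layout(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Fragments and TADs partitioning each chromosome, plus baited genes.

    Returns (layout, truth-with-repressed-TADs); repressed TADs are chosen as
    short runs of consecutive TADs so that planted 1-2 Mb LRIs can join two
    repressed TADs.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    fragments: list[RestrictionFragment] = []
    tads: list[TAD] = []
    frag_starts: dict[str, np.ndarray] = {}
    frag_offset: dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        # fragments: geometric-ish lengths around the mean
        frag_offset[chrom] = len(fragments)
        n_frag = round(length / config.fragment_mean_length)
        raw = rng.geometric(1 / config.fragment_mean_length, size=n_frag).astype(float)
        bounds = np.concatenate([[0.0], np.cumsum(raw)]) * (length / raw.sum())
        bounds = np.unique(np.round(bounds).astype(np.int64))
        bounds[0], bounds[-1] = 0, length
        frag_starts[chrom] = bounds[:-1]
        for j, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            fragments.append(
                RestrictionFragment(GenomicInterval(chrom, int(s), int(e)), f"{chrom}_F{j}")
            )
        tb = _partition(length, config.tad_mean_length, rng, jitter=0.2)
        for j, (s, e) in enumerate(zip(tb[:-1], tb[1:])):
            tads.append(TAD(GenomicInterval(chrom, int(s), int(e)), f"{chrom}_T{j}"))

    # repressed TADs: runs of 2-3 consecutive TADs per chromosome
    repressed: set[str] = set()
    target = config.frac_repressed_tads * len(tads)
    by_chrom: dict[str, list[TAD]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    chroms = sorted(by_chrom)
    guard = 0
    while len(repressed) < target and guard < 1000:
        guard += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        row = by_chrom[chrom]
        run = int(rng.integers(2, 4))
        start = int(rng.integers(0, max(1, len(row) - run)))
        for t in row[start:start + run]:
            repressed.add(t.tad_id)

    # genes: uniform distinct bait fragments, gene body extends ~20 kb from the bait
    genes: list[Gene] = []
    for chrom, length in chrom_lengths.items():
        lo, hi = frag_offset[chrom], frag_offset[chrom] + len(frag_starts[chrom])
        picks = rng.choice(np.arange(lo, hi), size=config.n_genes_per_chrom, replace=False)
        for g, fi in enumerate(sorted(int(x) for x in picks)):
            frag = fragments[fi]
            gstart = frag.interval.start
            gend = min(length, gstart + 20_000)
            genes.append(
                Gene(
                    gene_id=f"{chrom}_G{g}",
                    interval=GenomicInterval(chrom, gstart, gend),
                    strand="+" if rng.random() < 0.5 else "-",
                    bait_fragment_id=frag.fragment_id,
                )
            )
    layout = GenomeLayout(
        chrom_lengths=chrom_lengths, fragments=fragments, tads=tads, genes=genes,
        frag_starts=frag_starts, frag_index_offset=frag_offset,
    )
    truth = SyntheticTruth(
        repressed_tad_ids=repressed,
        lri_tad_ids_by_timepoint={},
        planted_lri_pairs={},
        compartment_labels={},
        planted_eqtl=None,
        marker_genes={},
    )
    return layout, truth


def _sample_decay_distance(
    rng: np.random.Generator, n: int, dmin: float, dmax: float, exponent: float
) -> np.ndarray:
    """Inverse-CDF sample of a d^-exponent density truncated to [dmin, dmax)."""
    u = rng.random(n)
    if abs(exponent - 1.0) < 1e-12:
        return dmin * (dmax / dmin) ** u
    a = 1.0 - exponent
    return (dmin**a + u * (dmax**a - dmin**a)) ** (1 / a)


def _eligible_lri_pairs(
    layout: GenomeLayout,
    repressed: set[str],
    bait_genes: set[str] | None = None,
) -> list[tuple[Gene, RestrictionFragment]]:
    """(gene, other-end fragment) pairs with both ends in repressed TADs and a
    midpoint separation of 1-2 Mb, restricted to ``bait_genes`` when given."""
    tad_index = MidpointIndex([t.interval for t in layout.tads], [t.tad_id for t in layout.tads])
    frag_by_tad: dict[str, list[RestrictionFragment]] = {}
    for frag in layout.fragments:
        tid = tad_index.lookup(frag.interval.chrom, frag.midpoint)
        if tid in repressed:
            frag_by_tad.setdefault(tid, []).append(frag)
    frag_by_id = {f.fragment_id: f for f in layout.fragments}
    out = []
    for gene in layout.genes:
        if bait_genes is not None and gene.gene_id not in bait_genes:
            continue
        g_tid = tad_index.lookup(gene.interval.chrom, gene.interval.midpoint)
        if g_tid not in repressed:
            continue
        bait = frag_by_id[gene.bait_fragment_id]
        for tid, frags in frag_by_tad.items():
            if frags[0].interval.chrom != gene.interval.chrom:
                continue
            for frag in frags:
                d = abs(bait.midpoint - frag.midpoint)
                if 1_000_000 <= d < 2_000_000 and frag.fragment_id != bait.fragment_id:
                    out.append((gene, frag))
    return out


def generate_interaction_replicates(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, list[Interaction]]]:
    """Two replicates of significant interactions per time point.

    Replicate 1 holds the full draw; replicate 2 is a thinning of replicate 1
    at the per-distance-class retention probabilities, so the planted
    concordance equals the retention. Planted LRIs (both ends inside
    repressed TADs) provide the 1-2 Mb mass at the configured per-time-point
    rates; score and >2 Mb decoys exercise the significance filters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    bait_by_gene = {g.gene_id: g.bait_fragment_id for g in layout.genes}
    frag_by_id = {f.fragment_id: f for f in layout.fragments}
    lri_bait_genes = {
        g.gene_id for g in layout.genes if rng.random() < config.lri_bait_gene_fraction
    }
    eligible = _eligible_lri_pairs(layout, truth.repressed_tad_ids, lri_bait_genes)
    if not eligible:
        raise RuntimeError("layout admits no 1-2 Mb repressed-TAD pairs; "
                           "increase chromosome length or repressed fraction")
    tad_index = MidpointIndex([t.interval for t in layout.tads], [t.tad_id for t in layout.tads])
    gene_tad = _gene_tads(layout)
    bait_weights = np.array(
        [
            config.sri_bait_weight_repressed
            if gene_tad[g.gene_id] in truth.repressed_tad_ids
            else 1.0
            for g in layout.genes
        ]
    )
    bait_weights = bait_weights / bait_weights.sum()
    out: dict[str, dict[str, list[Interaction]]] = {}
    prev_planted: list[tuple[Gene, RestrictionFragment]] = []
    for tp in TIMEPOINTS:
        n = config.interactions_per_replicate
        n_lri = round(config.lri_rate_in_repressed_tads[tp] * n)
        n_ultra = round(config.ultra_long_decoy_rate * n)
        n_bg = n - n_lri - n_ultra
        pairs: dict[tuple[str, str], Interaction] = {}

        def add(bait: RestrictionFragment, oe: RestrictionFragment, is_lri: bool,
                score: float) -> None:
            mean = config.lri_read_mean if is_lri else config.sri_read_mean
            reads = 1 + int(rng.poisson(max(0.0, mean - 1)))
            x = Interaction(bait, oe, read_count=reads, score=score, timepoint=tp, replicate="rep1")
            pairs.setdefault(x.pair_id, x)

        # background SRIs with distance decay; repressed-TAD promoters are
        # strongly depleted so LRI-only genes exist
        genes = layout.genes
        gi = rng.choice(len(genes), size=int(n_bg * 1.3), p=bait_weights)
        dists = _sample_decay_distance(
            rng, len(gi), config.min_interaction_distance, 950_000.0,
            config.distance_decay_exponent,
        )
        signs = rng.choice([-1, 1], size=len(gi))
        made = 0
        for idx, d, s in zip(gi, dists, signs):
            if made >= n_bg:
                break
            gene = genes[int(idx)]
            bait = frag_by_id[bait_by_gene[gene.gene_id]]
            pos = bait.midpoint + int(s) * int(d)
            L = layout.chrom_lengths[gene.interval.chrom]
            if not (0 <= pos < L):
                pos = bait.midpoint - int(s) * int(d)
                if not (0 <= pos < L):
                    continue
            oe = layout.fragment_at(gene.interval.chrom, pos)
            if oe.fragment_id == bait.fragment_id:
                continue
            if abs(bait.midpoint - oe.midpoint) >= 1_000_000:
                continue  # keep the background strictly short-range
            score = float(5.0 + 10.0 * rng.random())
            add(bait, oe, is_lri=False, score=score)
            made += 1

        # planted LRIs inside repressed TADs, persisting across time points
        kept = [p for p in prev_planted if rng.random() < config.lri_persistence]
        n_new = max(0, n_lri - len(kept))
        picks = rng.integers(0, len(eligible), size=n_new)
        chosen = kept + [eligible[int(i)] for i in picks]
        planted: list[tuple[str, str]] = []
        for gene, oe in chosen:
            bait = frag_by_id[bait_by_gene[gene.gene_id]]
            key = (bait.fragment_id, oe.fragment_id)
            add(bait, oe, is_lri=True, score=float(5.0 + 10.0 * rng.random()))
            planted.append(key)
        prev_planted = chosen

        # ultra-long decoys (> 2 Mb), removed by the distance filter downstream
        for _ in range(n_ultra):
            gene = genes[int(rng.integers(0, len(genes)))]
            bait = frag_by_id[bait_by_gene[gene.gene_id]]
            d = int(2_050_000 + rng.random() * 450_000)
            s = 1 if rng.random() < 0.5 else -1
            pos = bait.midpoint + s * d
            L = layout.chrom_lengths[gene.interval.chrom]
            if not (0 <= pos < L):
                pos = bait.midpoint - s * d
            if not (0 <= pos < L):
                continue
            oe = layout.fragment_at(gene.interval.chrom, pos)
            if (oe.fragment_id != bait.fragment_id
                    and abs(bait.midpoint - oe.midpoint) >= 2_000_000):
                add(bait, oe, is_lri=False, score=float(5.0 + 10.0 * rng.random()))

        rep1 = list(pairs.values())

        # sub-threshold score decoys (fail the score filter)
        n_decoy = round(config.score_decoy_rate * n)
        for _ in range(n_decoy):
            gene = genes[int(rng.integers(0, len(genes)))]
            bait = frag_by_id[bait_by_gene[gene.gene_id]]
            d = _sample_decay_distance(
                rng, 1, config.min_interaction_distance, 1_000_000.0,
                config.distance_decay_exponent,
            )[0]
            s = 1 if rng.random() < 0.5 else -1
            pos = bait.midpoint + s * int(d)
            L = layout.chrom_lengths[gene.interval.chrom]
            if not (0 <= pos < L):
                pos = bait.midpoint - s * int(d)
            if not (0 <= pos < L):
                continue
            oe = layout.fragment_at(gene.interval.chrom, pos)
            if oe.fragment_id != bait.fragment_id:
                reads = 1 + int(rng.poisson(config.sri_read_mean - 1))
                rep1.append(Interaction(bait, oe, read_count=reads,
                                        score=float(5.0 * rng.random()),
                                        timepoint=tp, replicate="rep1"))

        # replicate 2: thin replicate 1 per distance class
        rep2 = []
        for x in rep1:
            d = abs(x.bait.midpoint - x.other_end.midpoint)
            cls = "SRI" if d < 1_000_000 else ("LRI" if d < 2_000_000 else "excluded")
            if rng.random() < config.replicate_retention[cls]:
                rep2.append(
                    Interaction(x.bait, x.other_end, read_count=x.read_count,
                                score=x.score, timepoint=tp, replicate="rep2")
                )
        out[tp] = {"rep1": rep1, "rep2": rep2}
        truth.planted_lri_pairs[tp] = planted
        lri_tads: set[str] = set()
        for bait_id, oe_id in planted:
            for fid in (bait_id, oe_id):
                frag = frag_by_id[fid]
                tid = tad_index.lookup(frag.interval.chrom, frag.midpoint)
                if tid is not None:
                    lri_tads.add(tid)
        truth.lri_tad_ids_by_timepoint[tp] = lri_tads
    return out


def generate_chromatin_states(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> list[ChromStateSegment]:
    """Segments tiling each chromosome; quiescent coverage per TAD drawn from
    a high Beta inside repressed TADs and a low Beta elsewhere."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    segments: list[ChromStateSegment] = []
    non_quies = np.array(["Tx", "EnhA1", "TssA"])
    non_quies_p = np.array([0.45, 0.35, 0.20])
    for tad in layout.tads:
        a, b = (
            config.quiescent_beta_repressed
            if tad.tad_id in truth.repressed_tad_ids
            else config.quiescent_beta_background
        )
        q = float(rng.beta(a, b))
        bounds = _partition(len(tad.interval), config.segment_mean_length, rng, jitter=0.4)
        for s, e in zip(bounds[:-1], bounds[1:]):
            if rng.random() < q:
                state = "Quies"
            else:
                state = str(rng.choice(non_quies, p=non_quies_p))
            segments.append(
                ChromStateSegment(
                    GenomicInterval(tad.interval.chrom,
                                    tad.interval.start + int(s),
                                    tad.interval.start + int(e)),
                    state,
                )
            )
    return segments


def _gene_tads(layout: GenomeLayout) -> dict[str, str | None]:
    index = MidpointIndex([t.interval for t in layout.tads], [t.tad_id for t in layout.tads])
    return {
        g.gene_id: index.lookup(g.interval.chrom, g.interval.midpoint) for g in layout.genes
    }


def generate_expression(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ExpressionMatrix], ExpressionMatrix, ExpressionMatrix]:
    """Per-time-point matrices, an external-style reference time course, and a
    per-individual matrix carrying the planted eQTL effect (added later by
    :func:`generate_genotypes`, which knows the dosages).

    Genes in repressed TADs are multiplied by ``repression_multiplier`` at the
    time points where their TAD carries planted LRIs, and are unexpressed
    (exact zeros) with elevated probability there.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    genes = [g.gene_id for g in layout.genes]
    mu = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=len(genes))
    gene_tad = _gene_tads(layout)
    per_tp: dict[str, ExpressionMatrix] = {}
    ref_cols: dict[str, np.ndarray] = {}
    for tp in TIMEPOINTS:
        lri_tads = truth.lri_tad_ids_by_timepoint.get(tp, set())
        in_lri_tad = np.array([gene_tad[g] in lri_tads for g in genes])
        vals = np.zeros((len(genes), config.n_expr_replicates))
        base_log = mu[:, None] + rng.normal(
            0, config.expr_noise_sd, size=(len(genes), config.n_expr_replicates)
        )
        vals = np.exp2(base_log)
        vals[in_lri_tad] *= config.repression_multiplier
        p_zero = np.where(in_lri_tad, config.p_unexpressed_repressed, config.p_unexpressed)
        zero = rng.random(len(genes)) < p_zero
        vals[zero] = 0.0
        labels = [f"{tp}_r{i + 1}" for i in range(config.n_expr_replicates)]
        per_tp[tp] = ExpressionMatrix(list(genes), labels, vals, unit="FPKM")
        ref_cols[tp] = np.where(vals[:, 0] > 0, np.log2(vals[:, 0] + 1), 0.0)

    # external-style reference: 1d/3d/14d track PAd/Diff/Adip, 0d is a noisy decoy
    ref_map = {"1d": "PAd", "3d": "Diff", "14d": "Adip"}
    cols = {}
    cols["0d"] = np.exp2(mu + rng.normal(0, 2.0, size=len(genes))).clip(min=0)
    for label, tp in ref_map.items():
        cols[label] = np.exp2(ref_cols[tp] + rng.normal(0, 0.3, size=len(genes))).clip(min=0)
    reference = ExpressionMatrix(
        list(genes), list(cols), np.column_stack(list(cols.values())), unit="FPKM"
    )

    # per-individual baseline on log2 scale; eQTL effect added in generate_genotypes.
    # A minority of genes get heavy dropout so the >90%-expressed filter bites.
    indiv_log = mu[:, None] + rng.normal(0, 1.0, size=(len(genes), config.n_individuals))
    vals = np.exp2(indiv_log)
    dropout_rate = np.where(
        rng.random(len(genes)) < config.p_gene_high_dropout,
        config.dropout_high, config.dropout_low,
    )
    vals[rng.random(vals.shape) < dropout_rate[:, None]] = 0.0
    individuals = ExpressionMatrix(
        list(genes),
        [f"ind{i + 1}" for i in range(config.n_individuals)],
        vals,
        unit="FPKM",
    )
    return per_tp, reference, individuals


def generate_accessibility(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[tuple[str, int]]], list[AccessibilitySampleMeta]]:
    """Per-sample ATAC-like read midpoints over alternating A/B blocks.

    B blocks have lower mean counts and a stronger shared latent factor (so B
    bins are the more co-correlated compartment, as the orientation rule
    assumes); a per-sample FRiP effect concentrates reads in A bins.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    bin_size = config.accessibility_bin_size
    bins: list[tuple[str, int, str]] = []  # (chrom, start, label)
    for chrom, length in layout.chrom_lengths.items():
        for start in range(0, length, bin_size):
            block = start // config.compartment_block_length
            label = "A" if block % 2 == 0 else "B"
            bins.append((chrom, start, label))
            truth.compartment_labels[(chrom, start)] = label
    labels = np.array([b[2] for b in bins])
    is_b = labels == "B"
    base = np.where(is_b, config.b_base_reads_per_bin, config.a_base_reads_per_bin)
    loading = np.where(is_b, config.b_factor_loading, config.a_factor_loading)
    block_keys: dict[tuple[str, int], int] = {}
    block_codes = np.empty(len(bins), dtype=int)
    for i, (chrom, start, _) in enumerate(bins):
        key = (chrom, start // config.compartment_block_length)
        block_codes[i] = block_keys.setdefault(key, len(block_keys))
    n_blocks = len(block_keys)

    reads: dict[str, list[tuple[str, int]]] = {}
    meta: list[AccessibilitySampleMeta] = []
    tp_cycle = [TIMEPOINTS[i % 3] for i in range(config.n_accessibility_samples)]
    for s in range(config.n_accessibility_samples):
        sid = f"atac_s{s + 1}"
        g = rng.normal()  # global compaction factor
        frip = float(0.2 + 0.3 * rng.random())
        block_f = rng.normal(0, config.block_factor_sd, size=n_blocks)
        log_mean = (
            np.log(base)
            + loading * g
            + block_f[block_codes] * is_b  # extra within-block coherence for B
            + config.frip_loading * frip * np.where(is_b, -1.0, 1.0)
            + rng.normal(0, config.bin_noise_sd, size=len(bins))
        )
        counts = rng.poisson(np.exp(log_mean))
        positions: list[tuple[str, int]] = []
        for (chrom, start, _), c in zip(bins, counts):
            if c > 0:
                end = min(start + bin_size, layout.chrom_lengths[chrom])
                pos = rng.integers(start, end, size=int(c))
                positions.extend((chrom, int(p)) for p in pos)
        if not positions:
            raise RuntimeError(f"sample {sid} generated zero reads")
        reads[sid] = positions
        meta.append(
            AccessibilitySampleMeta(
                sample_id=sid, timepoint=tp_cycle[s], frip=frip, total_reads=len(positions)
            )
        )
    return reads, meta


def generate_genotypes(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    expression_individuals: ExpressionMatrix,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """LD-block genotypes plus one planted long-range eQTL SNP.

    Each LD block carries a founder haplotype pair; an individual's haplotype
    is a mutated copy of one founder, giving high r^2 within blocks and ~0
    across. The planted SNP sits inside a planted-LRI other-end fragment and
    its effect (``eqtl_beta`` in within-gene SD units, log2 scale) is added to
    the target gene's per-individual expression in place.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 5)
    n_ind = config.n_individuals
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    dosage_rows: list[np.ndarray] = []
    info: list[float] = []
    for chrom, length in layout.chrom_lengths.items():
        pos_all = np.arange(config.snp_spacing, length, config.snp_spacing)
        n_blocks = -(-length // config.ld_block_length)
        for b in range(n_blocks):
            lo, hi = b * config.ld_block_length, (b + 1) * config.ld_block_length
            block_pos = pos_all[(pos_all >= lo) & (pos_all < hi)]
            m = len(block_pos)
            if m == 0:
                continue
            h0 = rng.random(m) < 0.5
            divergent = rng.random(m) < config.block_divergent_fraction
            h1 = np.where(divergent, ~h0, h0)
            q = float(0.1 + 0.4 * rng.random())  # founder-1 frequency for this block
            hapA = np.where(rng.random((n_ind, 1)) < q, h1, h0)
            hapB = np.where(rng.random((n_ind, 1)) < q, h1, h0)
            mut = rng.random((n_ind, m)) < config.haplotype_mutation_rate
            hapA = np.where(mut, ~hapA, hapA)
            mut = rng.random((n_ind, m)) < config.haplotype_mutation_rate
            hapB = np.where(mut, ~hapB, hapB)
            dose = (hapA.astype(np.int8) + hapB.astype(np.int8)).T  # SNPs x individuals
            for j, p in enumerate(block_pos):
                snp_ids.append(f"{chrom}_B{b}_S{j}")
                chroms.append(chrom)
                positions.append(int(p))
                dosage_rows.append(dose[j].astype(float))
                info.append(float(0.6 + 0.4 * rng.random()) if rng.random() < 0.1
                            else float(0.85 + 0.15 * rng.random()))

    # planted eQTL: SNP inside a planted LRI other end, gene = the LRI's bait gene
    planted = None
    bait_gene = {g.bait_fragment_id: g for g in layout.genes}
    frag_by_id = {f.fragment_id: f for f in layout.fragments}
    for tp in TIMEPOINTS:
        for bait_id, oe_id in truth.planted_lri_pairs.get(tp, []):
            gene = bait_gene.get(bait_id)
            if gene is None:
                continue
            gi = expression_individuals.gene_ids.index(gene.gene_id)
            # the planted eQTL gene must itself pass the >90%-expressed filter
            if (expression_individuals.values[gi] > 0).mean() <= 0.90:
                continue
            oe = frag_by_id[oe_id]
            pos = oe.midpoint
            d = min(abs(pos - gene.interval.start), abs(pos - (gene.interval.end - 1)))
            if 1_050_000 <= d < 1_900_000:
                planted = (gene, oe, pos)
                break
        if planted:
            break
    if planted is not None:
        gene, oe, pos = planted
        dosage = rng.binomial(2, config.eqtl_maf, size=n_ind).astype(float)
        snp_id = "rs_planted_eqtl"
        snp_ids.append(snp_id)
        chroms.append(oe.interval.chrom)
        positions.append(int(pos))
        dosage_rows.append(dosage)
        info.append(1.0)
        gi = expression_individuals.gene_ids.index(gene.gene_id)
        # multiplicative on the natural scale = +beta*dosage on log2 scale
        # (beta in units of the per-individual log2 noise SD, which is 1.0)
        expression_individuals.values[gi] *= np.exp2(config.eqtl_beta * dosage)
        truth.planted_eqtl = (snp_id, gene.gene_id, config.eqtl_beta)

    order = np.lexsort((np.array(positions), np.array(chroms)))
    return GenotypeMatrix(
        snp_ids=[snp_ids[i] for i in order],
        chroms=[chroms[i] for i in order],
        positions=[positions[i] for i in order],
        dosages=np.array([dosage_rows[i] for i in order]),
        info=np.array([info[i] for i in order]),
    )


def generate_features(
    config: SyntheticConfig,
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Uniformly placed feature intervals (super-enhancer stand-ins; a null
    with respect to LRI-TAD membership)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 6)
    chroms = sorted(layout.chrom_lengths)
    out = []
    for _ in range(config.n_features):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, layout.chrom_lengths[chrom] - config.feature_length))
        out.append(GenomicInterval(chrom, start, start + config.feature_length))
    return out


def _assign_markers(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """PAd markers preferentially in repressed (LRI) TADs, Adip markers
    preferentially outside them, emulating marker-gene category structure."""
    gene_tad = _gene_tads(layout)
    in_rep = [g.gene_id for g in layout.genes if gene_tad[g.gene_id] in truth.repressed_tad_ids]
    out_rep = [g.gene_id for g in layout.genes if gene_tad[g.gene_id] not in truth.repressed_tad_ids]
    rng.shuffle(in_rep)
    rng.shuffle(out_rep)

    def pick(primary: list[str], secondary: list[str], n: int) -> list[str]:
        n_primary = min(len(primary), round(config.marker_enrichment * n))
        chosen = primary[:n_primary] + secondary[: n - n_primary]
        return sorted(chosen)

    pad = pick(in_rep, out_rep, config.n_marker_pad)
    adip = pick([g for g in out_rep if g not in set(pad)],
                [g for g in in_rep if g not in set(pad)], config.n_marker_adip)
    return {"PAd": pad, "Adip": adip}


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete miniature study. Deterministic in config.seed."""
    layout, truth = generate_genome_layout(config)
    interactions = generate_interaction_replicates(config, layout, truth)
    chrom_states = generate_chromatin_states(config, layout, truth)
    expr_tp, expr_ref, expr_ind = generate_expression(config, layout, truth)
    reads, meta = generate_accessibility(config, layout, truth)
    genotypes = generate_genotypes(config, layout, truth, expr_ind)
    features = generate_features(config, layout)
    truth.marker_genes = _assign_markers(
        config, layout, truth, np.random.default_rng(config.seed + 7)
    )
    return SyntheticDataset(
        config=config, layout=layout, truth=truth, interactions=interactions,
        chrom_states=chrom_states, expression=expr_tp, expression_reference=expr_ref,
        expression_individuals=expr_ind, accessibility_reads=reads,
        accessibility_meta=meta, genotypes=genotypes, features=features,
    )
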