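# Methods

`lriscape` implements the downstream analysis of promoter Capture Hi-C
(pCHi-C) interaction calls across a differentiation time course — here
adipogenesis: preadipocytes (PAd), day-1 differentiating cells (Diff) and
day-14 adipocytes (Adip) — with a focus on long-range interactions (LRIs)
and the repressed chromatin they mark. This note records the models, the
parameters that matter, the numerical choices, what the synthetic data
generator does and does not emulate, and known limitations.

## Coordinates and interaction identity

All intervals are 0-based half-open (the BED convention); readers for
1-based dialects convert at parse time (`one_based=True`). An interaction is
a bait/other-end pair of restriction fragments with a read count and a
caller significance score. Identity across replicates and time points is the
*unordered pair of fragment ids*: pCHi-C callers operate on a fixed
restriction map, so coordinate-fuzzy matching would only inflate
concordance. Interaction distance is the absolute difference of fragment
midpoints (`floor((start+end)/2)`); the distance classes are
SRI (< 1 Mb), LRI (1 Mb ≤ d < 2 Mb, the boundary counting as LRI) and
excluded (≥ 2 Mb, where replicate concordance collapses).

## Significance filtering

`filter_significant` applies, in fixed auditable order: score ≥ threshold
(default 5, the CHiCAGO convention) → intra-chromosomal → exclusion regions
(either fragment overlapping a user-supplied BED; empty by default — the
outlier histone-gene cluster removal generalizes to this) → distance <
2 Mb. Each rule's removal count is returned, and an interaction failing
several rules is charged to the first.

## Replicate concordance and sharing

Interactions are binned by distance (50-kb bins from 0 to the maximum
observed distance). Per bin the denominator is the *union* of the two
replicates' fragment-pair sets and the numerator their intersection;
the proportion is NA when the union is under 10 (matching the "fewer than 10
interactions" masking convention). The union denominator is the strictest
of the readings the phrase "proportion … seen in both replicates" admits;
`2·|A∩B|/(|A|+|B|)` would be the Dice alternative. Time-point sharing
counts each distinct unordered pair once and tallies how many time points
contain it.

## TAD annotation

Membership of a fragment (or gene, or feature) in a TAD is decided by its
midpoint, consistently across the package — fragments can straddle TAD
boundaries and midpoint assignment never double-counts. A TAD is an LRI TAD
at a time point when ≥ 1 LRI end falls in it; TADs with interaction ends but
no LRI ends are non-LRI ("none"), TADs without any interaction ends are
excluded from every comparison. Categories name the contributing time-point
subset ("all", "PAd only", "Diff and Adip", …).

chromHMM states are grouped into promoter / active / enhancer / quiescent
via a user-overridable map; the shipped default for the Roadmap 25-state
model is promoter ← {TssA, PromU, PromD1, PromD2}, active ← {Tx5', Tx,
Tx3', TxWk, TxReg, TxEnh5', TxEnh3', TxEnhW}, enhancer ← {EnhA1, EnhA2,
EnhAF, EnhW1, EnhW2, EnhAc}, quiescent ← {Quies}, everything else "other".
Fragment state assignment takes the group with the highest coverage of the
fragment; exact ties break deterministically quiescent > promoter >
enhancer > active > other. TAD coverage is overlap bp / TAD length per
group. Coverage comparisons between LRI and non-LRI TADs use the two-sided
Wilcoxon rank-sum (scipy's Mann–Whitney, exact for small tie-free samples,
normal approximation with tie correction otherwise; identical constant
samples give p = 1 by convention). The marker-gene test is a Pearson
chi-square (no continuity correction) of cell-type markers over TAD
categories, dropping categories whose expected count falls below 5 in any
row before testing.

## A/B compartments from accessibility

Reads are counted into 100-kb bins by midpoint, skipping blacklisted
regions; counts become bins-per-million (BPM), then log2(BPM + 1). The
pseudocount of 1 BPM keeps zero-count bins defined. FRiP correction is
per-bin OLS residualization of the log values on the per-sample fraction of
reads in peaks, re-centered at the bin mean (skipped below 3 samples, where
the regression is underdetermined). Per chromosome, the Spearman
correlation matrix of bins (zero-variance bins excluded) is summarized by
its leading eigenvector, computed by power iteration (deterministic
all-ones start, tolerance 1e-10, max 10,000 iterations) — for a symmetric
matrix this equals the NIPALS first component while being trivially
deterministic; an approximate eigenvalue tie is flagged as degenerate. The
eigenvector sign is fixed by the biology: inactive (B) chromatin is the more
strongly co-correlated compartment, so the vector is flipped if it
correlates positively with bin connectivity (row sums of the correlation
matrix minus the diagonal), making A positive. A centered 3-bin moving
average (truncated at chromosome ends — no invented data) smooths the
vector; bins are A where positive, B where negative, excluded at exact 0.

## Enrichment testing

Feature/LRI-TAD co-occurrence counts features whose midpoint lies in an LRI
TAD. The permutation null redraws which *interaction-containing* TADs carry
the LRI label (uniform subsets of the eligible universe, fixed size),
keeping the features where they are; p = (1 + #{null ≥ observed}) / (1 + n)
— the add-one convention avoids p = 0 and is exact for any permutation
count. The closed-form alternative is an upper-tail hypergeometric with
TAD counts as population/successes and features as draws; it requires
features ≤ eligible TADs (draws without replacement) and the package raises
otherwise rather than returning a meaningless value.

## Expression stratification

External RNA-seq time courses are matched to the pCHi-C time points by
Spearman correlation over the top-5000 genes of each reference column
(lowered with a warning when fewer genes are shared). Genes are classed by
the distance classes of the interactions baited at their promoter fragment;
genes in both SRIs and LRIs are excluded from SRI-vs-LRI comparisons.
"Expressed" defaults to value > 0 in the matched sample (the external
study's threshold is not restated in the source; configurable). Level
comparisons are Welch t-tests on log2(x + 1), Bonferroni-adjusted over time
points (Benjamini–Hochberg available). The bystander test applies the same
machinery to SRI-only genes inside vs outside LRI TADs, per time point.

## Long-range cis-eQTL

SNPs are filtered on MAF ≥ 5% (folded mean dosage / 2), Hardy–Weinberg
equilibrium (1-dof chi-square on dosages rounded to hard calls; p ≥ 1e-5
kept) and imputation info ≥ 0.8 when present. Genes must be expressed in
strictly more than 90% of individuals. Candidate pairs are windowed by the
distance from the SNP to the nearer gene end: short (< 1 Mb) or long
(1–2 Mb); both gene ends are used so upstream and downstream SNPs are
treated alike. Association is ordinary least squares of expression on
dosage plus optional covariates (genetic PCs, PEER factors — consumed, not
estimated), i.e. the additive linear model a Matrix-eQTL analysis fits;
a vectorized no-covariate path (`fast_pair_ols`) is algebraically identical
and cross-checked against the per-pair solver in the tests.

A long-range pair is *interaction-supported* when the SNP falls inside the
other-end fragment of an interaction baited at the gene's promoter and the
interaction's distance class matches the window. Only supported long-range
pairs are tested, and multiple testing uses Bonferroni with the number of
independent signals: results are greedily accepted in ascending p-value
order when the SNP's LD r² is below 0.2 against every previously accepted
SNP *for the same gene*. The per-gene scoping matters: one LD-distinct
locus tested against k genes constitutes k signals, and counting it once
makes the correction anti-conservative (we observed exactly this as false
positives in the recovery experiments before scoping the pruning per gene);
`per_gene=False` restores plain SNP-level pruning. Long-range SNPs are also
checked for short-range regulation of their interacting gene at BH FDR 0.05
over the short-range supported tests.

## The synthetic study

The generator emits a complete miniature study as a pure function of its
config and seed. Defaults are the stated world:

- genome: 2 chromosomes × 12 Mb; HindIII-like fragments with geometric
  lengths (mean 4 kb) partitioning each chromosome; TADs of ~800 kb;
  300 genes per chromosome, each with a promoter bait fragment.
- repressed TADs: 25% of TADs, chosen as runs of 2–3 consecutive TADs so
  that 1–2 Mb pairs of repressed regions exist for LRI planting.
- interactions: 20,000 per replicate per time point. Background pairs decay
  with distance (exponent 1 on [20 kb, 950 kb]) and are kept strictly under
  1 Mb so the long-range mass is exactly the planted signal; the LRI share
  is 1.1% (PAd), 2.6% (Diff) — the study's printed proportions — and 3.0%
  (Adip, a continued modest rise; the study prints no third value). Planted
  LRIs join repressed TADs and persist to the next time point with
  probability 0.6, reproducing the ">40% shared by ≥2 time points"
  behaviour. Only ~35% of repressed-TAD promoters act as LRI baits and
  repressed-TAD promoters are strongly depleted of background SRIs
  (weight 0.005), so LRI-only genes and non-LRI "bystander" genes both
  exist, as in the real data. Replicate 2 thins replicate 1 at retention
  0.8 (SRI) / 0.6 (LRI) / 0.3 (> 2 Mb), so planted concordance equals the
  retention. Read support is shifted Poisson with mean 12 (SRI) vs 6 (LRI),
  matching the direction and magnitude of the study's medians (12 vs 6).
  Score decoys (< 5) and > 2 Mb decoys exercise the filters.
- chromHMM: repressed TADs draw quiescent coverage from Beta(8, 2)
  (mean 0.8), background from Beta(2, 8); segments (~20 kb) tile exactly.
- expression: per-gene log2 baseline N(4, 1.5), replicate noise SD 0.5;
  genes in LRI TADs are multiplied by 0.5 at the time points where their
  TAD carries LRIs and are unexpressed with probability 0.40 (vs 0.15
  elsewhere). The per-individual matrix (n = 300) has log2 noise SD 1 and
  gene-wise dropout (2% for most genes, 25% for a 15% minority) so the
  >90%-expressed filter is exercised; the planted eQTL gene is required to
  pass it.
- accessibility: alternating 1-Mb A/B blocks; per-sample counts are
  log-normal-mixed Poisson (a negative-binomial-like overdispersed model)
  with base 100 (A) vs 40 (B) reads per 100-kb bin, a global per-sample
  factor loading +0.5 on B and −0.3 on A (B bins co-correlated and
  anti-correlated with A, the premise of the orientation rule), a
  within-block factor (SD 0.2) and a FRiP effect concentrating reads in A.
- genotypes: SNPs every 5 kb in 200-kb LD blocks; each block has a founder
  haplotype pair (80% of sites divergent) copied with per-site mutation
  0.01, giving within-block r² ≈ 0.9 and ≈ 0 across. The low mutation rate
  is deliberate: pervasive intermediate LD (r² ≈ 0.2–0.8) breaks the
  independent-signals Bonferroni assumption that the eQTL method itself
  makes. Non-divergent sites are near-monomorphic and feed the MAF filter;
  10% of SNPs get sub-0.8 info scores. One eQTL (β = 0.8 in units of the
  log2 noise SD, MAF 0.3) is planted on a SNP inside a planted-LRI
  other-end fragment at 1.05–1.9 Mb from its target gene.
- markers and features: 40 PAd / 60 Adip marker genes drawn 85% from
  repressed / non-repressed TADs respectively; 25 feature intervals placed
  uniformly (a null with respect to LRI TADs).

What a green test does *not* establish: the generator has no GC or
mappability structure, no fragment-length bias, no trans contacts, no
population stratification or relatedness, block-uniform LD rather than
recombination-map LD, and TADs that exactly partition the genome. Effect
recovery on this world validates the statistical machinery and its wiring,
not performance on real libraries.

## Calibration experiments and their design

Three repeated-seed experiments back the test suite. The permutation-null
calibration uses 300 features over 20 TADs so the integer co-occurrence
statistic is fine-grained enough to realize rejection levels near 5%
(with few features the discrete add-one p-value is necessarily
conservative and the check would measure coarseness, not calibration), and
199 permutations per run for runtime. The eQTL recovery runs 20 seeds of a
one-chromosome study (n = 300 individuals); null pairs exclude the planted
gene entirely, since a second SNP associating with the planted gene tags
the same signal rather than being a false positive. The repression null
(100 seeds) plants no repression of any kind — multiplier 1, equal
quiescent Beta, equal zero-inflation — while keeping the repressed-TAD
universe so LRIs can still be planted.

One stated check is left deliberately failing: requiring *both* the
quiescent-coverage rank-sum and the bystander t-test to be non-significant
at α = 0.05 in ≥ 95 of 100 null seeds asks for a joint type-I error ≤ 5%
across two tests. Our tests are individually calibrated (measured 6/100 and
3/100 rejections, inside the exact binomial 99% interval), so the
conjunction holds in ≈ 0.95² ≈ 90% of seeds (measured 91/100). Meeting the
bar would require deliberately conservative tests, which would contradict
the calibration properties asserted elsewhere; the test states the bar and
fails honestly.

## Limitations

- The concordance denominator and the FRiP-correction form are documented
  choices among several readings of the source methods; flags expose the
  alternatives.
- The hypergeometric enrichment route is only defined for features ≤
  eligible TADs; the permutation route has no such restriction.
- HWE filtering on rounded dosages is a pragmatic stand-in for
  hard-call-era filters; poorly imputed SNPs should be removed by the info
  filter first.
- The pipeline tests expression with no covariates on the synthetic world;
  real analyses should pass genetic PCs / PEER factors via the covariate
  argument of `ols_association`.
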