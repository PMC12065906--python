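# Methods

This note documents the models behind each `smad4sig` module, the
parameters that matter, the numerical choices, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Negative-binomial differential expression (`diffexpr`, `_nb`)

Counts are modelled per gene as NB(μ, α) with Var = μ + αμ² (the RNA-seq
convention: α is the squared biological coefficient of variation). Sample
depth enters as median-of-ratios size factors `s_j` (geometric-mean
pseudo-reference), so group means are `μ_ij = s_j · q_{g(j)}`.

**Fitting.** All fits are vectorized across genes. For cell-means designs
(two-group contrasts, the full genotype×time model) each group's log-mean
solves the score equation `Σ (y − μ)/(1 + αμ) = 0` by damped Newton; for
non-saturated designs (the additive reduced model of the LRT) a batched
IRLS solves the NB log-linear model with fixed dispersion. A per-gene
dense grid search over the likelihood is used as the test oracle for these
solvers.

**Dispersion.** Per-gene profile maximum likelihood on a two-stage log
grid over [1e-8, 20], using the Cox–Reid adjusted likelihood
(−½ log det X'WX) to remove the downward bias of the plain MLE at small n.
Because six samples per contrast still leave the per-gene estimate very
noisy — noisy enough to visibly inflate Wald type-I error — the final
estimate is a MAP under a log-normal prior: centred at the *common*
dispersion (the single α maximizing the summed CR profile likelihood,
nearly unbiased at this design size), with prior variance equal to the
excess of the observed log-dispersion spread (MAD²) over the expected
sampling variance trigamma((n−p)/2), floored at 0.25². On all-null
simulations at the study design (3v3, α = 0.1) this yields Wald type-I
error of 0.053–0.061 at nominal 0.05, versus ~0.12 for unmoderated CR-ML.
This moderation shares strength across genes the way edgeR/DESeq2 do; it
is the one place the package deliberately goes beyond a strictly per-gene
fit.

**Wald test.** z = Δβ/se(Δβ) with se from the per-group Fisher
information Σ μ/(1 + αμ); two-sided normal p. Log₂ fold-changes are
reported unshrunk (an optional zero-centred normal prior on the LFC is
available via `shrink_lfc`). At mean 100 and dispersion 0.1 with three
replicates the asymptotic sd of the log₂FC is ≈ 0.39, which bounds how
tightly any unbiased estimate can sit around a planted effect. Genes with
zero counts in one group get a pseudo-count of 0.5 on the normalized group
means and are flagged; genes all-zero in both groups report p = 1,
log₂FC = 0.

**LRT.** 2(ℓ_full − ℓ_reduced) against χ² with df = rank difference of the
treatment-coded design matrices; dispersion is estimated once under the
full (cell-means) grouping and held fixed in both fits. The default
reduced model removes only the genotype×time interaction — the question
being "which genes respond to the stimulus differently by genotype" — but
any nested pair of designs over the metadata factors is accepted.

**Thresholds.** The DEG rule is |log₂FC| ≥ 1.5 (inclusive) with
BH-adjusted p < 0.05 (strict); the low-count filter keeps genes with ≥ 5
reads in ≥ 3 samples. Adjustment is per contrast.

## Target classification (`classify`)

From the seven canonical contrasts (t1 vs t0, t12 vs t0, t12 vs t1 within
each genotype, plus KO vs WT at t0), with significance meaning
|log₂FC| ≥ 1.5 and padj < 0.05 within that contrast:

* **early** — significant at WT 1 h vs 0 h;
* **transient** — early, and a significant opposite-sign change at
  (12 h vs 0 h) **or** (12 h vs 1 h); the or is deliberate — a gene
  returning exactly to baseline is invisible in 12 v 0 but obvious in
  12 v 1;
* **late** — significant at 12 h (vs 0 h or vs 1 h) and not early;
* precedence transient > early > late; ties are impossible since transient
  requires early.

Smad4 status for target genes: **independent** requires a significant
same-direction response in the knockout against its own baseline (1 h or
12 h vs 0 h); opposite-sign significance counts as dependent, as does no
knockout response. A baseline (t0) genotype difference opposing the
response direction reassigns the gene as dependent and removes it from the
baseline-DEG list; baseline-only DEGs are genotype-dependent expression
and are recorded as dependent. Genes responding only in the knockout get
class `none`, status `not_applicable`, and a separate boolean flag rather
than a guessed label.

The cross-species signature takes baseline DEGs at the stricter
|log₂FC| ≥ 2 threshold, annotates human orthologs from a two-column map
(unique mouse keys enforced), marks `in_signature` only for mapped genes,
and carries the fold-change sign forward for the cohort direction check.

## CERNO enrichment (`enrichment`)

For a ranking of N genes (1 = most significant) and a module with k
members found, `stat = −2 Σ ln(rank/N)` is χ²(2k) under the null — a
Fisher combination of uniform rank fractions. The module AUC is
U/(n_in·n_out) from the member rank-sum, so AUC → 1 for modules packed at
the top. The χ² null is asymptotic in N (rank fractions are discrete and
drawn without replacement); calibration checks use N = 500, where the
approximation is comfortably accurate. Ties in the input statistic are
broken by stable original order; mouse→human conversion drops unmapped
genes from the ranking. Positivity: AUC ≥ 0.5 and padj < 0.05 (BH across
modules).

## Cohort context analysis (`cohort`)

Pathway catalogs default to the standard colorectal driver lists (WNT,
TP53, PI3K, RTK-RAS, TGF-β, BMP). SMAD4 is flagged separately from the
other TGF-β genes so that cohort selection can express "SMAD4 variant with
no other TGF-β pathway variant" (mutant group) and "no TGF-β pathway
variant at all" (control); both groups require a WNT variant.

Per context pathway (RTK-RAS, TP53, PI3K) the selected samples split into
G1–G4 crossing SMAD4 status with the second-pathway variant; the
convention — recorded in output headers — is odd groups = variant absent,
even = present. Kruskal–Wallis (tie-corrected H, χ² df 3) p-values are
BH-adjusted across genes within a context; Dunn pairwise z from pooled
mid-ranks with tie correction are Holm-adjusted within each gene. If every
observation is identical the convention p = 1 applies.

The dependence decision: (1) all four cross-status pairs (G1G3, G1G4,
G2G3, G2G4) significant — and the KW gate passed — in every tested
context; (2) G1G2 and G3G4 non-significant in every context; (3) the human
mutant-vs-control direction (sign of the median log₂FC with pseudo-count
1) matches the mouse direction. `failed_criterion` records the first
failure. Requiring the criteria in *all* contexts is the default (the
point is genes least affected by co-occurring second-pathway variants); an
any-context mode exists. Whether KW FDR ran across genes or gene×context
cells was an open choice; across genes within a context is implemented.
Mann–Whitney is used unconditionally for the volcano (no normality
pre-screen switches the test).

## Survival (`survival`)

Kaplan–Meier and the two-group log-rank test are delegated to lifelines.
The maxstat cut-point search is implemented here: writing the log-rank
numerator as a linear rank statistic — Σ over the high group of
(eventᵢ − H(tᵢ)) with H the Nelson–Aalen cumulative hazard — lets all
admissible cuts be evaluated with cumulative sums over the
expression-sorted samples, and the hypergeometric variance is assembled
from an at-risk indicator matrix. Consequently |z|² at any fixed cut
equals the ordinary log-rank χ² exactly, which the tests use as an
internal oracle. Cuts are placed midway between adjacent distinct values
("high" = expression > cut; ties share a side); both sides must hold at
least `minprop` (default 0.1) of the samples. Because the maximum over
many correlated cuts inflates the naive χ² reference, the p-value is by
permutation of expression against (time, event), with (b+1)/(n_perm+1)
smoothing — exact in distribution, no approximation drift; the classical
improved-Bonferroni approximations are not implemented.

## Single-cell proportions (`proportions`)

QC keeps cells with 250 ≤ genes ≤ 7000, UMI > 500, mitochondrial
fraction < 0.15 and log10(genes)/log10(UMI) > 0.80, honours a precomputed
`doublet` column if present, and logs removals per criterion. The
proportion test pools cells per condition, computes
`obs_log2FC = log2(prop_b/prop_a)` per cluster (second sorted condition
over first; a cluster absent from one side gets a one-cell pseudo-count
and a flag), permutes condition labels over cells for the two-sided
p-value with (b+1)/(n+1) smoothing, bootstrap-resamples cells within
condition for percentile CIs, and BH-adjusts across clusters. Cells are
the permutation unit. Markers use Wilcoxon rank-sum per cluster vs rest,
pre-filtered at |log₂ fold of means| ≥ 0.25 and ≥ 25% expressed fraction on
at least one side, Bonferroni-adjusted by the total gene count; the
pseudo-bulk comparison pools all cells per condition into one Wilcoxon.
Rank-sum tests stand in for hurdle-model single-cell DE throughout: the
procedure's shape is reproduced, not any specific effect-size estimator.

## Synthetic generators (`synth`)

The bulk simulator emulates the study design: 2 genotypes × 3 time points
(0, 1, 12 h) × 3 replicates, NB counts with log-normal per-gene means
(location 4, scale 1 on the natural log — median ≈ 55 counts), constant
dispersion 0.1, planted effect log₂FC 3. Effect shapes mirror the
classifier definitions so recovery is well-posed: early = effect at 1 h
persisting to 12 h (wild type only); transient = 1 h only; late = 12 h
only; smad4_dependent = the early shape in WT only; smad4_independent =
both genotypes; baseline_shift = a constant genotype offset. Directional
classes are signed as named, the rest get random signs. Default class
fractions total 30% (the remainder null) — enough signal for recovery
statistics while keeping median-of-ratios normalization valid, which
silently fails when most genes shift one way (a real phenomenon the tests
exercise deliberately).

The cohort simulator draws per-pathway variant flags (defaults: WNT 0.95,
SMAD4 0.30, other TGF-β 0.05, BMP 0.10, RTK-RAS 0.55, TP53 0.50,
PI3K 0.45 — prevalences in the range reported for colorectal cohorts,
with SMAD4 slightly enriched so the G3/G4 subgroups are well filled at a
few hundred samples), materializes gene-level alteration calls consistent
with the flags, and simulates expression on the log₂ scale
(baseline N(7, 1)) before exponentiating to RSEM-like positive values —
matching the rank tests' assumptions without modelling counts. Dependent
genes shift by ±2 log₂ units in every SMAD4-variant sample; confounded
genes shift only with their second-pathway variant; 25% of genes each,
the rest null. A dedicated gene carries a planted survival cut-point at
its 40th percentile: event times are exponential with the hazard
multiplied by 4 above the cut, and censoring is independent exponential
with rate λ·c/(1−c), which yields the target censoring fraction c (default
0.2) in expectation at any baseline hazard.

The cell simulator draws each cell's cluster from condition-specific
multinomials (defaults: a progenitor cluster at 10.5% vs 2.5%, a second at
7% vs 3.5%, stem cells at 2.7% vs 5.8%, enterocytes at 7.8% vs 23.4%,
remainder pooled), with log-normal UMI counts, gene counts scaling as a
power of UMI, and Beta-distributed mitochondrial fractions tuned so that a
realistic few percent of cells fail QC.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no mean-dispersion trend or gene-gene
correlation in the bulk counts; no library-size confounding beyond scalar
size factors; cohort expression is independent log-normal per gene with a
single planted shift, not the correlated, heavy-tailed structure of tumour
RSEM data; survival is exponential with one binary covariate; the cell
tables contain labels and QC metrics only, not count matrices, so
clustering itself is never tested. Recovery rates measured here are upper
bounds on what identically-parameterized real data would give.

## Problem sizes

Benchmark routines default to the sizes the recovery and calibration
statements are defined at: 2000 genes for DE calibration/recovery and
classifier recovery, 400 samples for the cohort decision, 500×200
simulations×permutations for maxstat null calibration, 100 replicates at
n = 200 for cut recovery, 400 replicates for proportion-test calibration,
1000 rankings for CERNO uniformity. The demo pipeline uses smaller sizes
(400 genes, 300 cohort samples, 400 cells/sample) chosen to exercise every
stage while staying interactive.

## Known limitations

* Dispersion moderation assumes a roughly common dispersion scale across
  genes; strongly bimodal dispersion landscapes would be over-shrunk.
* The Wald test at n = 3 per group leans on the normal approximation;
  moderation restores calibration on the simulated design but very low
  counts (< ~5 per group) remain approximate.
* The maxstat permutation p is exact in distribution but Monte Carlo noisy
  at small `n_perm`; the default 1000 gives ±0.01 resolution.
* The three-criterion screen treats genes independently; no multiplicity
  control is applied across the final dependence decisions beyond the
  per-stage adjustments.
* Ortholog mapping is one-to-one by construction; paralog fan-outs must be
  resolved before input.
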