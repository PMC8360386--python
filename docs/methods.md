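# Methods

`chronomics` re-implements, as a tested library, the chronological
multi-omics analysis of chemically induced rat hepatocellular carcinoma
(HCC): eleven treated stages sampled from day 1 to month 18, each
contrasted against an untreated age-matched control, with
whole-transcriptome arrays (four replicates per condition),
mitochondrial protein iBAQ intensities (three replicates) and targeted
mitochondrial metabolite concentrations (three replicates) measured on
independent animals. This note documents the statistical model of each
stage, the defaults and why they were chosen, what the synthetic study
generator does and does not emulate, and the numerical decisions taken
where the design was genuinely open.

## Study design and data model

The design is the 14-condition table built into
`datamodel.default_study_conditions()`: controls C0/C9/C18 and treated
conditions D1, D7, D11, D16, A1, N1 (vs C0), A9, N9, T9 (vs C9), A18,
T18 (vs C18). Conditions are only ever compared to their own
age-matched control; no cross-stage contrasts are formed. Because the
three omics layers come from independent animals, cross-layer
integration happens at per-condition replicate means (14-point
profiles) — the only alignment the design supports.

Feature identity is a plain string shared across layers; no gene ↔
protein mapping is imposed (the caller may pre-map identifiers).
miRNA genes live in the transcript matrix and are distinguished by an
identifier prefix (default `miR`), since array annotation, not the
pipeline, decides which probes are miRNA genes.

## Differential expression

Transcripts and proteins use an empirical-Bayes moderated t: per-feature
pooled variances s²_g (d_g df) are shrunk toward a prior s₀² with d₀
prior df, with posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)
and t = Δ/(s̃_g √(1/n₁+1/n₂)) on d₀+d_g df. The hyperparameters are
estimated by moment matching on log sample variances (digamma/trigamma
inversion); homogeneous variances yield d₀ = ∞ and a common-variance
z-test. `moderation=False` recovers the ordinary pooled t exactly.

Calls require BH-adjusted p below 0.05 **and** |log₂FC| ≥ 1 (two-fold).
"Fold change greater than one" is read on the log₂ scale, the standard
convention of the moderated-t framework; the natural-scale reading is
available via `lfc_threshold`. The protein layer uses the inclusive
threshold (p_adj ≤ 0.05), the transcript layer the strict one — the two
source conventions differ in boundary handling and both are preserved.
Metabolites (8 targeted compounds) use an ordinary equal-variance
Student t on raw concentrations with a signed natural-scale fold change
(m_t/m_c if ≥ 1, else −m_c/m_t) and no multiple-testing adjustment,
matching how small targeted panels are reported.

On pure-null data the raw moderated-t p-values reject at 5.0 % (the
acceptance suite simulates 200 × 1000 features at 4 vs 4).

## Proteomic preparation

Label-free intensities are left-censored, so two missingness mechanisms
coexist: intensity-dependent censoring (MNAR) and occasional random
dropout (MAR). The pipeline:

1. **Completeness filter** — keep proteins quantified in all replicates
   of at least one condition (default 3 of 3).
2. **Normalization** — log₂ followed by per-sample median centering. A
   deliberately simple, parameter-free normalization: it removes
   per-sample loading differences, is idempotent on centred log data,
   and makes no distributional assumption. (Variance stabilization
   would be an alternative; the difference is immaterial for iBAQ-style
   intensities spanning a few orders of magnitude.)
3. **Missingness classification** — per (protein, condition) replicate
   block: *complete* if nothing is missing; *MNAR* if the whole block
   is missing or the observed block mean falls in the lowest quartile
   of all block means (intensity dependence); *MAR* otherwise. The
   quartile threshold is configurable; on the synthetic study the rule
   recovers essentially all truly censored blocks.
4. **Split imputation** — MNAR entries are drawn from a Gaussian
   located at the q = 0.1 quantile of the sample's observed values with
   scale = tune_sigma × median per-protein observed SD (MinProb);
   MAR entries are imputed by k-nearest-neighbour regression across
   proteins (k = 11, inverse-distance weighting over mutually observed
   samples). Observed values are never altered.

Two imputation tracks feed downstream stages. Differential expression
uses the deterministic MinDet track (each missing value ← the sample's
observed minimum), which treats missingness as censoring and therefore
lets fully censored blocks produce large negative fold changes — the
behaviour wanted for a protein that disappeared. The network,
integration and classification stages use the mechanism-split
MinProb/kNN track. We deliberately do **not** use MinDet for the stage
classifier: flooring a random dropout of a well-quantified protein to
the detection limit inflates its within-group variance and can mask a
genuinely discriminative marker (on synthetic data it drops panel
ANOVA recall from 16/16 to ~5/16 and raises CV error from ~0 to ~20 %).

## Pathway over-representation and integration

ORA is the upper-tail hypergeometric test P(X ≥ k) for the overlap k of
a query list (size n) with a pathway (K members) inside a universe of N
features. The universe is the *detected* feature set of the layer (the
rows of the tested matrix), not the genome: those counts are also the
weights of the Stouffer combination, which ties the two choices
together. BH adjustment is applied within one (layer, stage, direction)
family; the q-value reported is the BH value (a Storey-style estimate
differs slightly and can be substituted). Directional ORA tests the up-
and down-called features separately; module ORA is undirected and
significant only under the conjunctive gate p < 0.05 **and** q < 0.1.

Two integration statistics are computed per (pathway, stage):

* **Enrichment status** — each level is summarized as
  none/up/down/both from its significant directional ORAs; the 16
  combinations collapse onto 11 status codes: `none`, three RNA-only,
  three protein-only, `consistent_up`, `consistent_down`, `discordant`
  (opposite single directions — the signature of post-transcriptional
  regulation), and `mixed` (any combination involving a "both" state).
  This is the unique partition of the 4 × 4 lattice into the stated
  level-significance × direction categories that yields 11 classes.
* **Weighted Stouffer Z** — z_i = Φ⁻¹(1−p_i) per level,
  z_c = Σw_i z_i/√(Σw_i²), p_c = 1−Φ(z_c), with w = the layer's
  detected-feature universe size. Raw (not adjusted) directional ORA
  p-values enter the combination; the BH family structure is not
  meaningful across layers with different universe sizes, and the
  combination is itself thresholded afterwards. A level with no test
  for a key contributes a *neutral* z = 0 rather than the −∞ that a
  literal p = 1 would give: an untested level carries no evidence
  either way, and this choice is what lets a strongly weighted
  transcriptome rescue pathways invisible to the smaller proteomic
  universe. Elsewhere p is clamped to [1e−15, 1−1e−15].

## Weighted co-expression network

Built from first principles:

* **Biweight midcorrelation** with a per-side outlier cap: u =
  (x−med)/(9·mad), and u is rescaled per side so that at most 10 % of
  samples on either side of the median get zero weight. Without the
  cap, a module whose signal is concentrated in a few stages (an acute
  day-1 response) has a noise-dominated mad, its signal samples exceed
  the Tukey cutoff, and exactly the correlations of interest are
  destroyed. Zero-mad profiles fall back to Pearson with a warning.
* **Signed soft-threshold adjacency** a = ((1+r)/2)^β with β = 24, the
  smallest power at which the study's network reached a scale-free fit
  R² > 0.85. `pick_soft_threshold` reproduces that selection rule
  (10-bin log-log regression of the connectivity distribution, signed
  fit −sign(slope)·R², smallest passing power).
* **Topological overlap** TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j)+1−a_ij),
  ℓ = shared-neighbour weight; 1−TOM is the clustering dissimilarity.
* **Module detection** — average-linkage clustering with a static cut
  at 0.95 × the maximum merge height, then clusters below 20 members
  are reassigned to grey. This is a documented simplification of the
  adaptive branch cut. The 0.95 fraction was chosen from the geometry
  of the dissimilarity: module joins complete below ~0.9 while links
  between distinct (even trajectory-correlated) modules merge above
  ~0.97, so the cut sits in the gap; a cut at 0.99 merges moderately
  correlated module pairs. Modules are named by the standard colour
  sequence in decreasing size order.
* **Module eigengene** — first right singular vector over samples of
  the feature-standardized module submatrix, sign-aligned with the
  module mean profile, unit norm.
* **Module relevance** — a (module, stage) pair is relevant when the
  median member |log₂FC| exceeds 0.9 and a two-sided Wilcoxon rank-sum
  of the stage's member fold changes against the module's pooled
  other-stage values gives p < 0.05 (exact for small samples, normal
  approximation with tie correction otherwise, via the standard
  Mann-Whitney implementation).
* **Module–feature integration** — eigengenes and molecular features
  (proteins, metabolites, miRNA genes) are reduced to 14-point
  condition-mean profiles; Pearson r with the two-sided t transform on
  n−2 df; the significance gate is p ≤ 0.001, with an additional
  |r| > 0.40 filter for the reported grid. Significant features are
  clustered on 1−Pearson distance (average linkage, k = 10, labels A…J
  in dendrogram leaf order).

## Stage classification

Proteomic samples are grouped by sampling time (1/9/18 months; 18/9/6
treated samples) regardless of tissue. Features are ranked by one-way
ANOVA F with an optional `s0` added to the pooled within-group SD
(s0 = 0 default, i.e. plain F); classification is a linear SVM with
C = 10, one-vs-one multiclass voting. Two cross-validation schemes run
250 repeats each: stratified 33 % hold-out and stratified ten-fold
(folds capped by the largest class; a class smaller than the fold count
simply misses some test folds). Feature ranking happens inside the
training portion of every split by default to avoid selection leakage;
`rank_globally=True` ranks once on all data — the optimistic variant
whose bias is the classic selection-outside-CV effect — for
comparability with workflows that rank before splitting. The error
curve over a panel-size grid reports the smallest panel with mean error
below 10 % under every scheme.

Under label permutation the CV error settles at 0.50–0.62 — chance
level for these priors, but above the 1−max-prior ≈ 0.455 heuristic,
because a hard-margin SVM with in-fold feature selection overfits the
permuted training labels instead of collapsing to the majority class.

Expression-profile biclustering uses 1−Pearson distance for stage
columns and Euclidean distance for feature rows, complete linkage both
ways, and returns leaf orders for heat-map export.

## The synthetic study generator

`emulate_study_defaults()` *is* the study design: 14 conditions, 4/3/3
replicates, 2000 genes + 60 miRNA genes, 600 mitochondrial proteins,
the 8 targeted metabolites, 9 modules, a 16-protein stage panel, and
planted pathway enrichments reproducing the qualitative integration
verdicts (a consistent-up pathway in late tumour, consistent-down
metabolic pathways at day 1, one discordant pathway with RNA up and
protein down in late tumour, plus single-level enrichments).

Module eigengene trajectories are lattice random walks (step 0.7) over
the chronological condition ordering. Walks are redrawn when the base
walk has sd < 0.7, when the spread survives trimming of the two most
extreme conditions at sd < 0.6 (robust correlation ignores isolated
extremes, so signal concentrated there would be undetectable by
design), or when the trajectory correlates above |r| = 0.6 with an
earlier module (near-collinear modules are not resolvable and would
make the planted partition ill-defined); a cornered configuration
restarts the whole set. The first module additionally receives an
acute day-1 programme (+2.1 at D1 with a decaying tail) and the second
a tumour rise (+2.1 at T9/T18, half at N9/A18); the offsets are lattice
multiples, which keeps every planted module-stage relevance median a
discrete step away from the 0.9 gate (margin ≥ 0.1 at the default
loading spread). Ground-truth relevance applies the same median +
rank-sum rule to the noiseless fold changes at a stricter α = 0.01 so
that planted truth sits clear of the detection boundary.

Gene expression is baseline + loading × trajectory + planted shifts +
N(0, 0.3²); loadings are N(1, 0.2²). Two miRNA regulators per module
follow −1.5 × trajectory + noise; the manifest records each
regulator's model correlation at condition-mean resolution (including
noise attenuation), which is the value recovery is scored against.
Planted differential expression shifts ±2 log₂ units; enriched
pathways draw 60 % of their members from planted DE features of the
stated direction. Planted protein effects go to the most abundant
non-panel members of the pathway — left-censoring makes low-abundance
planted effects unrecoverable by any method, and the panel is reserved
as a clean stage signature.

Proteins get log₂ baselines N(5, 1.5²) (panel: N(6.5, 0.5²), i.e.
reliably quantified), per-condition biological offsets N(0, 0.3²),
replicate noise N(0, 0.25²). The 16 panel proteins instead follow
their stage-group mean, a permutation of (−1, 0, +1) × 2.5 noise-SD —
a clearly discriminative biomarker panel. Censoring: entries whose
noiseless intensity falls below the per-sample 15 % quantile are
removed (MNAR), then 5 % of the survivors drop at random (MAR); the
masks are recorded before any noise-dependent step so the manifest
labels are unambiguous. Metabolites are control means (50–200 a.u.)
scaled by planted fold changes with 10 % multiplicative noise; the
planted values follow the study's chronological profile (malic ×4.63 at
day 7, ×1.59 at day 1, glutamate −3.95/+3.37 at days 1/7, citrate −12
and α-ketoglutarate −17.8 at day 1; the day-11/16 malic values 2.5 and
1.8 are representative points inside the study's 1.59–4.63 range).

What the generator does **not** emulate: probe-level microarray noise,
batch or array effects, peptide-to-protein roll-up, correlated noise
between features beyond module structure, tissue heterogeneity within
a condition, and missing metabolite replicates. Passing recovery tests
therefore demonstrates that the pipeline's statistics do what they
claim under the study's design and realistic noise — not that the
pipeline is robust to every artefact of real array/MS data.

## Numerical choices and degenerate inputs

* BH adjustment delegates to the standard step-up implementation;
  empty p-lists pass through.
* Hypergeometric tails use the survival function directly (no
  log-space tricks needed at these universe sizes); the acceptance
  suite checks exact agreement with pmf enumeration for every universe
  up to N = 30.
* Constant expression profiles are an error in the network stage
  (correlation undefined) and rank last (F = 0) in ANOVA.
* MinProb falls back to MinDet (with a warning) when the data are too
  constant to estimate a spread; kNN falls back to the feature mean
  when no candidate neighbour is observed at the target sample.
* Ties in ANOVA ranking break alphabetically by feature id; module
  colour assignment breaks size ties by cluster index; identical
  stage profiles merge at height 0 and appear adjacent in leaf order.
* All randomness flows from one root seed per run (generator,
  MinProb draws, CV splits), so reruns are bit-identical.

## Problem sizes

Defaults were sized to the study itself (2060 × 56 transcripts,
600 × 42 proteins, 8 × 42 metabolites), and the full pipeline runs in
well under a minute per study on one CPU; the acceptance sweep uses 50
seeded replicates of the network-recovery path and 250-repeat CV
curves, the same repeat count as the study protocol.

## Known limitations

* The adaptive branch cut is simplified to a static height cut; deeply
  nested module structure (modules within modules) would not be split.
* The Storey q-value is approximated by BH.
* The status lattice reconstruction (11 codes) is the unique partition
  consistent with the stated category counts, but the original coding
  table is not available, so code names need not match it.
* Cross-layer identity mapping is the caller's responsibility.
* The permutation null of the stage classifier is chance-level but not
  equal to the majority-prior heuristic (see above).
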