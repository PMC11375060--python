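# Methods

`glycoscreen` implements the computational arc of a study that links the
expression of a gene family (RAB-GAP / TBC1-domain genes) in breast cancer
to prognosis and to a glycolytic metabolic phenotype.  This note records the
models, the defaults and their rationale, the numerical choices, and what
the synthetic data do and do not establish.

## Subtype expression screen

For each gene the fold change between a target subtype (triple-negative,
TNBC) and all other samples is the ratio of **linear-scale** group means:
log2 intensities are back-transformed (`2**x`) before averaging, because
"fold change" on intensity data conventionally means a ratio of mean
abundances, not a ratio of mean logs.  A ratio-of-log-means mode
(`fc_on_log_means=True`) is provided for sensitivity analysis; for Gaussian
log-intensities with equal group variances the two differ by a fixed factor
and lead to the same ranking.  Significance is a two-sided Wilcoxon
rank-sum test; classification uses inclusive thresholds FC ≥ 1.2 /
FC ≤ 0.8 at p < 0.05, uncorrected — the screen is a candidate filter, not a
confirmatory test, so no multiplicity adjustment is applied at this stage.

Rank-sum p-values are exact (full enumeration of the U distribution) when
both groups have ≤ 10 observations and there are no ties, and otherwise use
the normal approximation with continuity and tie corrections.  When every
observation is tied the test carries no information and p = 1 is returned.

## Survival screening

**Kaplan–Meier.** Product-limit estimator reported at the distinct event
times; censored subjects leave the risk set after their recorded time.  The
implementation is a direct computation cross-checked against lifelines in
the test suite.

**Cox proportional hazards.** Fits go through lifelines' `CoxPHFitter`
(Efron tie handling; Wald p and 95% CI from the observed information; a
likelihood-ratio p is available by flag).  Breslow tie handling is not
offered because the backend implements Efron only; requesting it raises.
Degenerate designs — constant or duplicated covariates, inversion failure —
raise a typed `SingularDesignError` rather than returning a silent fit.
The engine is validated against a brute-force grid maximizer of the Efron
partial likelihood written independently in the tests (agreement to
|Δβ| < 1e-4 on all small fixtures), and its Wald intervals are calibration-
tested (95% coverage over repeated simulated cohorts; uniform null
p-values under marker permutation).

**Marker coding.** The per-gene screen uses standardized continuous
expression by default, so hazard ratios are per SD; this makes the
HR ≥ 1.2 / ≤ 0.8 screen criterion scale-free across genes.  A mean-split
(HIGH/LOW at the mean over a reference subset, ties labeled HIGH) mode is
available, as used for Kaplan–Meier displays.

**Follow-up windows.**  Early = [0, 5) years: events at or beyond 5 years
are censored at 5.  Late = 5–20 years, implemented as a landmark analysis:
subjects with follow-up shorter than 5 years are excluded, survivors enter
with the clock reset (times −5, capped at 15 years).  The landmark form is
the standard way to make "late" effects interpretable as conditional
hazards; early-window restriction is idempotent by construction.

**Multivariable model.**  Univariately significant genes are re-fit with
age (years), tumor size (mm), nodal status (0/1), hormone-receptor status
(ER or PGR positive, 0/1), HER2 (0/1) and grade.  Grade is entered as an
ordinal numeric covariate (1–3); a categorical encoding changes little at
these effect sizes and the ordinal form keeps the per-gene fits cheap and
stable.

**2×2 association.**  Odds ratio by cross-product with Haldane's +0.5
applied to every cell when any cell is zero, Woolf (log-scale) 95% CI, and
Pearson's chi-square without continuity correction.

## Monte Carlo gene-set null

The question "how often does a random set of k genes contain ≥ m flagged
genes?" is answered two ways: an empirical null drawing independent k-sets
uniformly **without replacement** (counter-based Philox stream keyed by the
seed; vectorized by taking the k smallest of N random keys per draw), and
the closed-form hypergeometric upper tail, which serves as the exact oracle
in tests.  The reported empirical p is the raw ratio `n_exceed / n_sets`; a
conservative `(n+1)/(N+1)` variant is exposed but not the default, so that
a result like 53/10,000 reads as 0.0053.  Significance flags are computed
once upstream and frozen — the null never refits survival models per draw.

## Metabolomic integration

Per gene, cell lines are ranked by expression; the bottom and top
`floor(n/3)` lines form the LOW and HIGH tertiles (ties broken by a stable
sort on value then line identifier, so constant input still yields a
deterministic labeling).  Metabolite fold changes between the HIGH and LOW
groups are computed on **linear concentrations** (back-transform of the
log10 matrix) because the target quantity is the average concentration; a
log-scale-mean mode exists.  Per (gene, metabolite) significance is a
two-sided rank-sum at α = 0.05, uncorrected; the unnamed test behind the
published filter is taken to be a nonparametric location test, matching the
screen conventions elsewhere in the pipeline.  Metabolites significant in
at least 2 gene stratifications are retained.  MID-tertile lines
participate in neither the fold change nor the test.

Ward clustering (Euclidean distance) is delegated to
`scipy.cluster.hierarchy.linkage`; merge heights are validated against a
brute-force agglomeration oracle in the tests, and dendrograms export to
Newick with branch lengths derived from merge heights.  On exactly tied
merges scipy's nearest-neighbor-chain order may differ from a smallest-
index rule, which can permute leaves but never changes heights.

## Assay metrics

Flux parameters follow the standard stress-test definitions.  Per-phase,
per-cell aggregates use a vendor-style rule: the **last** baseline
measurement, the **maximum** within stimulation phases (glucose,
oligomycin in the ECAR test; FCCP in the OCR test), and the **minimum**
within inhibition phases (2-deoxyglucose; rotenone/antimycin).  The
published analyses defer to the instrument vendor's report generator,
whose exact aggregation is not public; the rule above reproduces its
documented intent, and a plain per-phase mean mode is provided.  Then:
glycolysis = post-glucose − post-2-DG; glycolytic capacity =
post-oligomycin − post-2-DG; basal respiration = baseline − post-rot/AA;
maximal respiration = post-FCCP − post-rot/AA.  All quantities are
per-cell, hence invariant under joint scaling of rates and cell counts.

Lactate hit-calling flags a silencing condition when its control-normalized
per-cell mean drops to ≤ 70% of control **and** a two-sided rank-sum test
against control gives p < 0.05; conditions with fewer than two replicates
are marked unevaluable.  The energy map plots baseline (ECAR, OCR) relative
to a reference condition, with quadrants energetic / glycolytic / aerobic /
quiescent and the reference assigned to "energetic" by convention.  The
glucose-uptake rate is the exact formula
([2DG6P] × sample volume) / (cell number × uptake time), in fmol/cell/min.

## Image quantification

Quantification runs on average z-stack projections.  The membrane
compartment is a "corona": pixels of a cell whose exact Euclidean distance
to the nearest non-cell pixel is < `round(thickness_nm / pixel_size_nm)`
pixels (default 600 nm).  Edge pixels sit at distance exactly 1, so a
depth of 1 denotes the one-pixel edge layer; anisotropic pixels are not
supported.  The exact (not chamfer) distance transform makes the mask
bit-identical to exhaustive pixel enumeration, which the tests exploit.
For each labeled cell, the background is everything outside that cell's
label, so touching cells each keep a full corona along shared edges.  The
readouts are total marker intensity per cell and the ratio of mean corona
intensity to mean whole-cell intensity (1.0 for a uniform marker,
invariant under positive rescaling of the channel).  Cells touching the
image border are excluded by default because their coronas are truncated;
an override flag exists.  `segment_disks` (Otsu threshold + connected
components) is a deliberately simple segmenter adequate only for the
synthetic disc cells; real images should supply instance masks from a
dedicated segmentation tool.

## Regulation statistics

`direction_proportions` counts up/down genes (zero fold changes set aside)
and reports p_down at full precision.  The coordinated-downregulation
probability for a k-gene panel treats genes as independent
Bernoulli(p_down) draws and is exactly `p_down ** k`, evaluated in log
space; the direction split is taken over **all** detected genes regardless
of significance, because the question is about raw direction coincidence,
not about significant regulation.  An exact binomial-tail generalization
P(X ≥ x) is provided.  Panel summaries call a gene significantly
downregulated at |linear FC| ≥ 1.5 toward downregulation with FDR < 0.05
(two-sided mode available); panel genes missing from the table are
reported, never dropped.

## Synthetic-data generator

The generator's defaults are the study conditions: a 1904-sample cohort
with a 15.7% TNBC fraction, a 46-line cell panel, a 17,329-gene regulation
table with p_down = 0.535.  One global seed feeds independent named
sub-streams (`SeedSequence([seed, stream_id])`), so regenerating one table
never perturbs another and fixed seeds give bit-identical output.

* **Cohort.**  Log2 expression is Gaussian per gene (mean ~ N(8, 1.5),
  unit residual SD) with planted additive shifts in TNBC samples — so a
  planted shift of Δ log2 units yields a linear-mean fold change of 2^Δ in
  expectation.  Survival is exponential with per-subject rate
  `baseline_hazard · exp(Σ β_g z_g)` (z = standardized planted-gene
  expression): proportional hazards holds exactly, making planted log-HRs
  recoverable by the Cox engine.  Censoring is an independent exponential
  clock (0.05/year) capped at 20 years of follow-up.  Covariate marginals
  are fixed documented defaults (age ~ N(60,10) truncated to [25,90];
  tumor size log-normal around 22 mm; nodal status Bernoulli(0.4); grade
  1–3 at 15/45/40%; receptor status follows subtype, TNBC triple-negative
  by definition); they exist to exercise the multivariable fits, not to
  match registry distributions.
* **Cell-line panel.**  One standard-normal latent factor per line carries
  the planted axis: genes of the glycolytic module load `+√r`, FAO-module
  genes `−√r`, metabolite blocks likewise, giving each informative
  (gene, metabolite) pair correlation ±r (default 0.8).  Roughly 40/40/20%
  of genes and metabolites are glycolytic / FAO / null; ground-truth module
  labels ride along for recovery tests.
* **Regulation table.**  Direction is Bernoulli(p_down); |log2FC| is
  half-normal; FDR is drawn so that larger effects tend to smaller values
  (the exact shape is immaterial to everything downstream).
* **Images.**  Disc cells placed by rejection sampling (no overlap, no
  border contact), marker intensity split between a rim of fixed physical
  width (600 nm by default, computed with the same corona routine used for
  quantification) and the interior: rim fraction = `membrane_fraction`, so
  0 gives a uniform marker (ratio 1) and the downstream ratio is strictly
  increasing in the fraction.  Optional additive Gaussian noise (default
  off) and an optional z-stack replication for projection tests.

What the synthetic data do **not** emulate: transcriptome-wide correlation
structure, batch effects, non-proportional hazards, realistic microscopy
PSF/noise, metabolite pathway stoichiometry.  Passing recovery tests shows
the estimators are correct under their assumed models — not that real
cohorts satisfy those models.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen to make Monte
Carlo error terms small relative to the assertions: 200,000 draws for the
set-null/oracle comparison (4 SE criterion), 300–500 simulated cohorts of
120 subjects for CI calibration, 46-line panels for integration recovery,
and 192–256 px images with 3–5 cells.  The external-cohort reproduction
(the 44-gene family on the full 1904-sample freeze) runs through exactly
the same code path and is exercised end-to-end on the synthetic emulation;
the published cohort numbers require the user to supply the accession
files.

## Known limitations

* Cox fits inherit lifelines' behavior for near-separation: very large |β|
  with wide CIs rather than a refusal; complete singularities raise.
* The corona is 2-D (on the projection); no volumetric correction.
* The exact rank-sum path is limited to ≤ 10 per group; beyond that the
  corrected normal approximation is used, which is standard but not exact.
* `segment_disks` is not a general segmenter and is labeled as such.
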