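# Methods

This note documents the models and numerical choices behind `cemspipe`:
what each stage assumes, which parameters matter, what the synthetic
cohort generator does and does not emulate, and where the design was
genuinely open.

## Peak-list model

The pipeline starts from centroided CE-MS peak lists, one row per ion:
m/z (Th), charge z, intensity (arbitrary units), migration time (min),
signal-to-noise ratio, and the number of consecutive spectra in which
the ion was observed.  Inputs are assumed monoisotopic; isotopic
envelope resolution is not modelled.

**Quality filters.** Only signals with z > 1, S/N ≥ 4 and ≥ 3
consecutive spectra are kept (both numeric thresholds inclusive).
Singly charged ions are dominated by chemical noise on this kind of
platform; the spectral-count requirement removes single-scan spikes.

**Charge deconvolution.** Each signal's neutral monoisotopic mass is
M = z·(m/z − m_p) with the proton mass fixed at m_p = 1.007276 Da so
that the m/z ↔ M round trip is exact.  Two signals belong to the same
peptide when their neutral masses agree within 25 ppm — the platform's
stated mass accuracy for monoisotopically resolved peaks — *and* their
migration times within 0.1 min.  The 0.1 min co-elution tolerance is
deliberately stricter than the 0.35 min cross-sample tolerance: within
one run there is no drift between charge states of the same ion, so a
tight window costs nothing and prevents chance mergers.  Grouping is
the exact transitive closure of this pairwise relation, computed with a
union-find over a sliding window on mass-sorted signals (O(n log n)).
We chose the exact closure over a chain-then-split heuristic because it
is equally fast, order-independent by construction, and provably agrees
with the brute-force grouping oracle on *every* instance, not only
unambiguous ones.  ppm deviations are always computed relative to the
smaller mass of a pair, a convention that must simply be fixed for
reproducibility.  A feature's mass and time are intensity-weighted
means over its members; its intensity is their sum, so deconvolution
conserves total signal exactly.

## Migration-time calibration

Observed times are regressed onto the canonical times of a reference
peptide panel (the production platform uses 1770 reference peptides;
the synthetic stand-in uses 200) by LOWESS: tricube weights, local
linear fits, 2 robustifying iterations.  Matching of features to panel
entries is one-to-one and greedy by ascending ppm deviation within
50 ppm; because raw run-to-run drift can exceed the 0.35 min identity
tolerance, anchor search uses a coarser window (default 2.0 min) — the
0.35 min rule is enforced *after* calibration as the QC control, which
is exactly the role it plays on the production platform.

**Span.** The LOWESS window defaults to an adaptive fraction covering
about 30 anchors (bounded to [0.1, 0.67] of the data).  A fixed span of
0.5 was considered and rejected: with panel-scale anchor sets
(~200 anchors over a 27-minute separation window) a half-data window
smooths across the drift structure and leaves anchor residuals that can
breach the 0.35 min control, while ~30 anchors per fit is enough for a
stable robustified local line and tracks realistic drift.  Any fixed
span remains available as a parameter.  The fitted map is forced
monotone non-decreasing (cumulative maximum over fitted values) and is
extended linearly beyond the anchor range using the terminal segments.
Ties among equidistant match candidates go to the earlier-migrating
feature, then to lower indices — arbitrary, but deterministic.

Measured behaviour: an exactly linear drift is inverted to machine
precision (local linear fits are exact on linear data); monotone
piecewise-linear warps at the generator's default amplitude leave
anchor-residual SDs below 0.025 min.  The residual *maximum* for a
piecewise warp is dominated by smoothing bias at slope kinks and
plateaus near ~0.1 min for any locally weighted smoother; this is why
the QC control is the 0.35 min bound, not a near-zero one.

## Intensity normalization

Urine concentration varies widely between voids, so intensities are
rescaled per sample against a panel of 29 "housekeeping" peptides —
peptides whose abundance is stable across subjects.  The scale factor
is the **median** over detected housekeeping peptides of
(reference intensity / observed intensity); the median rather than the
mean makes one aberrant housekeeping signal harmless.  All intensities
are multiplied by the factor, making normalization scale-equivariant:
any global intensity rescaling of a run is removed exactly.  At least 3
housekeeping detections are required; fewer is a per-sample
normalization failure, reported with the sample id.  Whether the
production platform normalizes multiplicatively is not public;
median-of-ratios is this package's choice and is validated on synthetic
data (planted dilution factors recovered within 10% for ≥95% of
samples at the default housekeeping noise).

## Cross-sample matching

Samples are processed in input order.  Each feature joins the nearest
existing consensus peptide — ppm measured against the *current*
consensus mass, which stabilizes as support grows — within 50 ppm and
0.35 min, else it founds a new consensus peptide.  Within one sample at
most one feature may join a given consensus peptide; the nearer in ppm
wins and the loser founds a new peptide.  Consensus mass is an
intensity-weighted running mean, consensus time a plain running mean.
Greedy accumulation mirrors how a peptide database is built sample by
sample and is deterministic and streaming-friendly; it is not
guaranteed order-invariant in pathological overlap cases, so the tests
assert order invariance on well-separated panels (where it holds) and
exact recovery of zero-noise studies.  Missing cells stay missing in
the matrix; downstream steps decide how to treat absence.

The presence filter keeps peptides detected in **strictly more than**
half the samples (a peptide in exactly 50% is dropped).

## Classifier

The multi-peptide score is linear in log-amplitude space:
score = offset + Σ wᵢ·xᵢ with xᵢ = log10(1 + Iᵢ) for the matched panel
peptide i.  The log10(1+·) transform compresses intensities spanning
decades and is defined at zero; undetected panel peptides default to
x = 0 ("zero" missing policy) because detection-limit censoring makes
absence informative — an undetected peptide is a low-abundance one.  A
"min_observed" policy is available.  The prognostic cutoff is 0.55 with
**strict** inequality for the high-risk side; the boundary value itself
is low-risk.  The published 273-peptide panel and weights are not
public, so the model file format accepts any panel; the synthetic
studies use either the generator's planted model (weights ± w on the
marker peptides, offset placing mid-severity at the cutoff) or a model
trained on labelled synthetic data.

Training is a linear discriminant with lsqr solver and shrinkage as the
regularization parameter, fitted on log10(1+I) with missing cells
filled by the missing policy.  The trained score is the signed
discriminant value and its natural cutoff is 0 (the decision boundary);
the 0.55 prognostic cutoff belongs to applied, externally calibrated
models.  The solver is closed-form, so training is deterministic.

## Cohort statistics

* **eGFR**: simplified (abbreviated) MDRD,
  eGFR = 186 · (Scr/88.4)⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · 0.742 (female) · 1.210
  (Black), with creatinine in µmol/L.  The 186-coefficient original
  form is used rather than the later 175 re-expression, matching the
  era of the assays this pipeline targets; race defaults to false when
  unrecorded.  Dialysis patients get no eGFR (creatinine under dialysis
  does not reflect filtration) and are excluded from every eGFR-based
  analysis; they remain in clustering and outcome analyses.
* **Stage groups**: ordered bands with cutpoints 60, 30, 15 and
  inclusive upper bounds — group 1: eGFR > 60; 2: 30 < eGFR ≤ 60;
  3: 15 < eGFR ≤ 30; 4: eGFR ≤ 15 — the real-valued closure of the
  integer bands 90–61 / 60–31 / 30–16 / 15–0.  Configurable.
* **GLM/ANOVA**: one-way fixed-effects F with unequal group sizes,
  F = (SSB/(k−1))/(SSW/(N−k)); for k = 2 this equals the squared
  pooled-variance t statistic (asserted in tests).
* **Correlations**: Pearson and Spearman (average ranks on ties),
  pairwise-complete, two-sided p; constant inputs yield a flagged NaN
  rather than an exception.  OLS fits report slope, intercept and
  R² = 1 − SSres/SStot.
* **Clustering**: agglomerative average linkage on Euclidean distances
  over per-patient peptide vectors (missing cells zero-filled, log10
  transformed by default), cut to k clusters (default 4, mirroring the
  A–D pattern of real cohorts; the original cut rule is unpublished, so
  k is a parameter).  Cluster-vs-clinical comparisons use the two
  largest clusters with Welch t and two-sided Wilcoxon rank-sum per
  variable.
* **Per-peptide eGFR correlations**: Spearman per peptide with missing
  intensities as zero; direction "increased-with-CKD" for ρ < 0 and
  "decreased-with-CKD" for ρ > 0; Benjamini–Hochberg adjusted p-values
  are reported alongside raw ones, with selection at raw p < 0.05 (the
  convention of the analyses this mirrors).
* **Monotone peptides**: after the >50% presence filter, a peptide is
  kept when its group-mean signal across the ordered stage groups is
  non-strictly monotone.  Ties are allowed — "monotone" is read as
  non-increasing or non-decreasing; a strict reading would discard flat
  profiles that plainly order with stage.
* **Prognosis**: 2×2 counts of outcome against the cutoff with
  sensitivity, specificity and NPV = P(no event | score ≤ cutoff);
  samples with unknown outcome are excluded and counted.  Degenerate
  margins give NaN rates, not errors.

## Synthetic cohort generator

The generator's defaults describe the study conditions of a
single-centre CKD cohort: 53 patients, 6 on dialysis, sex ratio 33:20,
age ~N(70, 11.5²) years, follow-up 3.6 years, 4/53 (~7.5%) lost to
follow-up.  A latent severity s ~ U(0,1) drives everything:

* eGFR = 120·exp(−3s + ε), ε ~ N(0, 0.06), clipped at 4 — spanning
  stages I–V with a mean in the mid-30s mL/min/1.73 m²; serum
  creatinine is the exact MDRD inverse of that eGFR (so generated eGFR
  and MDRD(creatinine, age, sex) round-trip to <0.1);
* urine protein = exp(N(−1.5 + 3s, 0.6)) g/g creatinine;
* the combined death/dialysis endpoint is Bernoulli with a logistic
  link, p = σ(6(s − 0.65)), and **no events below s = 0.6**: the floor
  emulates cohorts in which every observed event occurred above the
  prognostic cutoff, so that the pipeline's clean cutoff separation is
  a property of the generated truth, not luck;
* the 6 most severe patients are dialysed; their creatinine is drawn
  directly (450–900 µmol/L) and their eGFR marked not applicable.

The peptide universe is a 200-entry reference panel (a scaled stand-in
for the production panel of 1770): 30 serum-protein-like markers whose
log-abundance rises with severity, 42 collagen/uromodulin-like markers
that fall (mirroring the reported 29 collagen-I + 8 collagen-III + 5
uromodulin + other down-going peptides), 29 housekeeping peptides, and
background peptides.  Panel entries are placed log-uniformly in mass
(0.8–12 kDa) and uniformly in time (18–45 min), rejection-sampled so
any two entries differ by >150 ppm in mass or >1 min in time — the
platform's own resolvability assumption.  Abundances are lognormal:
log10 A = base + d·β·(s − ½) + noise, with base ~ U(3.5, 5.5), marker
effect β = 1.2 log10-units per unit severity (≈16-fold across the
cohort, the order of magnitude seen in strongly regulated urinary
peptides), d ∈ {+1, −1, 0}, noise SD 0.15 log10 for markers/background
and 0.08 for housekeeping peptides (stable by definition).  Observed
intensity is abundance × a lognormal dilution factor (log-SD 0.5);
peptides below the detection limit (default 1500 intensity units) are
dropped — left-censoring, matching detection-limit physics, not random
dropout.  Each detectable peptide is emitted at 1–3 charge states
(z ∈ 2..6, m/z roughly 350–2500 Th, fixed intensity split), at a time
passed through a per-sample monotone piecewise-linear warp (5 knots,
offsets ±0.5 min) plus N(0, 0.02 min) jitter.  Per sample, 100
spurious noise peptides that pass the quality filters and 30 junk
signals that must be removed by them complete the peak list.  The
abundance model, effect size and noise levels are the package's own
choices — the source cohort published neither — and are therefore
documented here rather than presented as estimates.

**What the generator does not emulate**: isotopic fine structure, raw
spectra, co-elution interference, correlated marker modules (markers
are conditionally independent given severity), longitudinal sampling,
comorbidity structure, and the exact discreteness of real clinical
chemistry.  Passing recovery tests on this generator therefore shows
the pipeline correctly inverts the distortions it models — drift,
dilution, censoring, charge dispersion — not that it is robust to every
artefact of real CE-MS data.

The planted classifier weights are ±w with w = 2/(72·β) so the expected
score spans ~2 units across the severity range, and the offset places
mid-severity at the 0.55 cutoff — giving the score scale and cutoff
geometry of a CKD273-style classifier.

## Problem sizes and determinism

Default test and validation runs use the 53-patient study (~650 signals
per sample), 100 samples for dilution recovery, a 100-peptide ×
20-sample zero-noise study for matching recovery, and n = 200 cohorts
for classifier recovery — sizes chosen so the whole suite exercises
every stage end-to-end in seconds while keeping Monte-Carlo margins
comfortable.  All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning; fixed seed ⇒ bit-identical
outputs, and the acceptance script derives all sub-seeds from its
`--seed` argument.

## Known limitations

* The published 273-peptide classifier (panel, weights, training set)
  is proprietary/unpublished; this package applies or trains stand-in
  models with the same functional form and can load the real one if it
  is ever released.
* Greedy sequential matching can depend on sample order when peptide
  clouds overlap within tolerances; a global clustering would trade
  determinism and streaming for order invariance.
* The binary fixed-window endpoint model ignores censoring times; no
  survival machinery (Cox, Kaplan–Meier) is included.
* LOWESS calibration cannot reproduce sharp drift kinks exactly
  (smoothing bias ~0.1 min at a kink); the QC control accounts for
  this.
* Per-peptide correlation p-values assume independent tests; BH
  correction is reported but peptides from one parent protein are
  correlated in real data.
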