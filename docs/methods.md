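# Methods

`cardiodose` re-implements, as a tested pipeline, an analysis design that
links radiation dose to cardiac substructures with overall survival in a
lung SBRT cohort: contour-uncertainty propagation by signed physical
margins, EQD2/DVH dosimetry, ensemble variable selection by bootstrapped
elastic net and random survival forests across a 2 × 4 design of model
variations, and a resampled optimal-split dose threshold. Because no
clinical dataset ships with the package, everything is exercised on
synthetic cohorts with known ground truth; this note records the models,
the defaults, and the design choices that were genuinely open.

## Synthetic cohorts

Two generators share one statistical model.

**Voxel phantom** (`synth.generate_cohort`). Each patient gets a stylized
thorax on a 84 × 84 × 40 lattice at 2 × 2 × 3 mm (clinical planning CTs in
this setting are typically 1 × 1 × 3 mm; the coarser in-plane grid keeps a
cohort tractable while still resolving the 1.4–2.6 mm contour margins).
The four chambers are disjoint ellipsoids (per-patient heart size varies
by ±20%, chambers jitter individually), the great vessels are vertical
tubes, the whole heart (WH) is the union of the chambers with the
intracardiac vessel segments, and the lungs are large ellipsoids with the
heart and the treatment target carved out (the clinical lungs-minus-target
convention; with the target included, lung mean dose is a direct proxy of
target volume). The PTV is a random-aspect ellipsoid placed in the lung of
the recorded laterality with a surface gap to the heart drawn from
−4 … 34 mm, emulating a distance distribution whose closest targets abut
the heart. Covariate marginals follow the emulated cohort: 56.4% male,
age ≈ N(73, 9.5²) clipped to 37–92, 76.6% stage 1, 43.0% left-sided,
pathology squamous/adeno/proven/unknown at 8.6/12.1/73.7/5.6%, log-normal
PTV volume with median ≈ 20 cc, and the four SBRT schedules 3 × 18,
5 × 12, 8 × 7.5 and 12 × 5 Gy at their observed frequencies.

The dose surrogate is the prescription inside the PTV exactly, with an
isotropic exponential falloff `Rx · exp(−d/λ)` in the Euclidean distance
`d` from the PTV surface. This contract — exact plateau, deterministic
monotone falloff — is what the geometric invariant tests rely on.

**Feature-level generator** (`synth.generate_feature_cohort`). For
many-replicate experiments the voxel stage is bypassed: each patient has a
latent target–heart gap (gamma distributed, median ≈ 29 mm with a small
abutting fraction, matching the emulated cohort's target-heart distance
table); each structure's *nearest-approach* distance (plus a log-normal
hot-spot factor) produces D0.1cc and its *bulk-averaging* depth (4–28 mm
beyond the nearest approach, plus a smaller heterogeneity factor)
produces Dmean, both through the same exponential falloff and EQD2
conversion. The two latent distances model
what treatment-plan heterogeneity does in real data: they decorrelate a
structure's Dmean from its D0.1cc (Pearson ≈ 0.7–0.8 here, in the range
seen in clinical DVH tables). The idealized voxel phantom cannot produce
this decorrelation — under a deterministic isotropic kernel both features
are rank-identical functions of the patient's geometry — so benchmark
experiments that must distinguish a structure's mean from its own
near-maximum run on the feature-level cohort. This is the one feature of
real data the voxel phantom deliberately does not emulate, and passing
voxel-phantom tests accordingly says nothing about mean-versus-maximum
attribution.

**Survival.** Event times follow a Weibull baseline (shape 1.1, scale
2200 days, giving a median near the emulated cohort's 1267 days) scaled by
`exp(linear predictor)`; coefficients act on covariates centred at
reference values so the baseline keeps its interpretation. Censoring is
the minimum of a 3650-day administrative horizon and an exponential
random-censoring time (mean 6000 days), yielding roughly 60–70% events;
the event fraction of the original cohort is not published, so both knobs
are configuration. Every patient draws from an own substream of the
master seed, so growing a cohort never reshuffles earlier patients.

**Ground-truth hazards.** The cohort-emulation default gives the left
atrial mean EQD2 a per-Gy log hazard ratio ln(1.05) plus effects for age,
sex, log-PTV and pathology. The *recovery benchmark* hazard
(`recovery_hazard`) keeps the driver and the age/sex/pathology effects but
deliberately omits the PTV-volume effect: target volume determines every
dose feature at once (a bigger target irradiates everything more), so a
volume effect makes the dose-only models an ill-posed attribution problem
for any method. With dose-independent confounders the driver is
identifiable and the benchmark measures the pipeline rather than the
confounding.

## Contour uncertainty

Margins derive from segmentation-agreement statistics: expansion by
MSD + 2·SD; contraction by the same magnitude (symmetric policy, default)
or by max(0, MSD − 2·SD) (asymmetric policy, selectable) — both appear in
the literature this design follows, and the choice is surfaced in
configuration rather than silently resolved. Perturbation uses the exact
Euclidean distance transform with anisotropic sampling, so margins are in
physical millimetres: expansion keeps voxels within distance m of the
mask, contraction keeps voxels whose distance to the complement exceeds
m, guaranteeing `contract(m) ⊆ original ⊆ expand(m)`. A contraction that
empties a small structure yields an empty mask with a warning; its dose
features become missing and the modelling stage's missing-data rule (drop
the feature column if more than 5% of patients are missing, otherwise
drop the affected patients; threshold configurable) applies.

Surface metrics: boundary voxels are the 6-connectivity erosion
difference (array edges count as boundary); MSD is the mean of the two
directed mean boundary distances; HD95 is the 95th percentile of the
pooled symmetric distance set (the alternative max-of-directed-percentiles
convention was rejected for simplicity). Structures qualify for analysis
when DSC > 0.80 and MSD < 2 mm, both strict.

## Dosimetry

EQD2 is applied voxel-wise — `EQD2 = D·(d + α/β)/(2 + α/β)` with fraction
dose `d = D/n` — *before* DVH extraction; converting DVH points post hoc
differs for heterogeneous dose and the voxel-wise order matches a
conversion step that precedes extraction. α/β is 2 Gy for the whole heart
and cardiac substructures and 3 Gy for the lungs; the robustness scenario
sets 3 Gy everywhere. Dmean is the mean EQD2 over mask voxels; D0.1cc
(the maximum-dose surrogate) sorts mask voxels by descending EQD2 and
accumulates voxel volumes to 0.1 cc, reporting the crossing voxel's value
without interpolation — sub-voxel interpolation would be false precision
at 3 mm slices. A mask smaller than 0.1 cc reports its minimum EQD2,
flagged. Note the EQD2 ordering: above 2 Gy per fraction EQD2 exceeds
physical dose and *decreases* with α/β; below 2 Gy per fraction both
orderings reverse — monotonicity checks therefore condition on the
fraction dose.

## Modelling stack

Eight model runs: {contracted, original, expanded} contours under the
standard α/β map, plus all-3 Gy α/β on original contours — each with
dose-only and complete (dose + retained confounders) covariate sets.

**Confounder screen.** Marginal Cox per candidate (likelihood-ratio test
for the pathology contrast block), retaining p < 0.05 (the significance
level is not stated in the design's source and 0.05 is the convention);
PTV volume enters as log(PTV); categoricals as treatment contrasts with
the largest category as reference.

**Elastic net.** Per bootstrap (default 1000; desk-scale runs use 100):
resample patients with replacement, standardize the resample, tune the
mixing parameter over {0, 0.1, …, 1} (desk-scale {0, .25, .5, .75, 1})
and the penalty strength by K-fold cross-validated partial likelihood
(default 10 folds; desk-scale 3), refit at the chosen pair and record
nonzero coefficients. The l1-ratio-0 endpoint cannot be fit by the
coordinate-descent path solver, so a ridge-penalized Newton solver (warm
started along the penalty path, validated against lifelines) covers it;
ridge never zeroes a coefficient, so pure-ridge bootstraps select every
feature — consistent with more-ridge-like models selecting dose
parameters more often. A magnitude floor on |standardized coefficient| is
exposed (default 0, i.e. nonzero-at-numeric-zero) because the selection
rule for near-zero ridge coefficients is otherwise all-or-nothing.
Selection percentage = share of bootstraps with a nonzero coefficient.

**Random survival forests.** Per run, `n_forests` forests (default 500;
desk-scale 4) of `n_trees` log-rank-split survival trees (default 500;
desk-scale 150, leaf size 15, √p candidate features per split). VIMP is
the *tree-level out-of-bag permutation importance*: for each tree, its
OOB cases are dropped down with one feature permuted among them and the
drop in that tree's concordance index is recorded; drops are averaged
over trees, and the per-feature median over forests is compared against
the 0.01 threshold. The tree-level convention (that of the standard R
survival-forest implementations, cross-checked against `ranger` on
identical data) matters: ensemble-level permutation lets a correlated
twin feature stand in for the permuted one at prediction time, which
drives the true driver's importance toward zero under the strong
collinearity this analysis is designed around.

**Consensus.** A dose feature is consensus-influential iff its EN
selection percentage is within 5 points of the top dose feature in
*every* run and its RSF median VIMP exceeds the threshold in *every* run;
ranked by mean selection percentage. An empty intersection is a reported
outcome, not an error.

**Final model.** One multivariable Cox fit of the consensus dose feature
plus retained confounders, repeated per variation/α-β scenario; a
condition-number guard rejects degenerate designs.

## Dose threshold

The optimal split maximizes the two-sample log-rank statistic over the
unique observed feature values between the 10th and 90th percentiles with
at least 10 patients per side (guard rails configurable); ties break
toward the lower cutpoint. The criterion is log-rank maximization
(maximally selected rank statistic) — the standard choice; minimum-p and
concordance criteria were considered and rejected, and no multiple-testing
correction is applied because the split is used descriptively. Stability
comes from the median over 100 random two-thirds subsamples (simple, not
event-stratified, sampling); a repetition without an admissible candidate
is skipped and logged, and fewer than 50% successful repetitions is an
error. Kaplan–Meier medians (earliest time the survivor curve reaches
0.5; a curve that never crosses reports infinity, flagged) contrast the
strata, in days internally with months (365.25/12) at the report layer.
The log-rank scan is vectorized over candidates and is tested against
`lifelines.statistics.logrank_test` exactly.

## Pipeline

`study.run_study` executes simulate → perturb/extract (streamed per
patient; the four variant feature tables are written once and
content-addressed by a configuration hash so reruns and the eight model
runs share them) → UVA screen → 8 model runs → consensus → final Cox per
variation → threshold per variation → consolidated report (CSV + JSON +
markdown, with the EN/RSF × dose-only/complete rows against the four
variation columns). Per-run seeds derive from the master seed by spawn
keys; stage wall times go to the log only, so all written outputs are
byte-identical across reruns of the same configuration and seed.

**Falloff scale.** The e-folding length λ = 20 mm (both generators) was
fixed by a power/calibration analysis of the benchmark designs before the
test expectations were frozen: it is the dose-gradient scale at which the
driver's mean EQD2 spans the informative 0–40 Gy range (median ≈ 5 Gy, in
the regime where the analysis design places its threshold) without the
extreme-leverage tail that makes the Wald test of the univariable Cox
screen anticonservative in the null-calibration experiment. Steeper
falloffs compress the dose distribution toward zero and starve the
forests' importance signal; shallower ones re-introduce the leverage
tail.

## Problem sizes

The test and benchmark sizes are the package's own desk-scale choices:
recovery benchmarks use n = 300 patients, 100 EN bootstraps, 4 forests ×
150 trees per run, and the acceptance suite runs two replicate seeds;
null calibration uses 200 replicates for the univariable screen and 4 for
the full consensus; threshold recovery uses n = 700 with 100 resamples.
Every scientific threshold (the 0.01 VIMP flag, the 5-point consensus
band, 2-SE recovery, the 5% test level, ±10%/±15% cutpoint tolerances) is
at its designed value. Full-scale runs (n_boot = 1000, 500 forests × 500
trees) are configuration changes, not code changes.

## Known limitations

* The phantom is stylized geometry, not anatomy; only mask/dose topology
  matters downstream. No CT intensities, no motion, no plan optimization.
* The voxel dose kernel is deterministic and isotropic; mean-vs-maximum
  attribution within a structure is studied on the feature-level
  generator only (see above).
* Missing-cause-of-death, competing risks and time-varying effects are
  out of scope, as in the design this package follows.
* The elastic-net CV scorer uses the Breslow partial likelihood on the
  held-out fold; the verified-vs-lifelines agreement is exact only
  without ties (Efron vs Breslow differ on tied event times).
* Strict top-rank recovery by RSF importance is not replicable at high
  probability under strong collinearity: in roughly a quarter of
  simulated cohorts some correlated proxy (notably the whole-heart mean,
  which physically contains the driver structure) statistically ties or
  beats the driver's VIMP — a behaviour reproduced by the independent R
  implementation on identical data. The consensus rule (selection-band
  plus importance flag across all runs), not strict top rank, is what
  identifies the driver reliably.
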