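# Methods

`rtplanqa` evaluates left-breast radiotherapy plans the way a clinic audits
a deep-learning (DL) planning workflow: six dose-volume goals, an EUD-based
tumour control probability (TCP), a linear excess-risk panel for
normal-tissue endpoints, contour-similarity metrics between clinical and DL
segmentations, and a route-decision model that converts plan acceptability
into staff-time savings. Because no patient data ships with the package, a
synthetic cohort generator reproduces the statistical shape of a
101-patient cohort so that every stage is exercised end to end.

## Dose grids, masks and DVHs

Volumes are axis-aligned voxel grids (NIfTI or MetaImage via SimpleITK);
a mask voxel belongs to a structure iff its centre is inside it, and all
metrics are voxel-centre based. Cross-volume operations require identical
geometry to 1e-6 mm — there is deliberately no resampling, so a geometry
mismatch is an error, never a silent interpolation.

Cumulative DVHs are binned at 0.01 Gy by default (cGy resolution, the
precision plans are reported at). `d_mean` is computed on raw voxels and is
exact; `D98`/`D2` come from the binned curve with linear interpolation
inside the bracketing bin, which agrees with the sort-based voxel
percentile within one bin width (tested on random grids). The six protocol
goals — PTV Dmean in [39.65, 40.45] Gy, D98 ≥ 38.05 Gy, D2 ≤ 42.85 Gy for
a 15 × 2.67 Gy prescription, plus mean doses ≤ 6 / 3 / 1 Gy to lungs,
heart and contralateral breast — are compared inclusively at the
thresholds.

## Radiobiology

TCP uses the logistic EUD model: EUD = (Σ v_i D_i^a)^(1/a) over the
differential DVH, TCP = 1/(1 + (TCD50/EUD)^(4γ50)). The exponent `a` is
negative for tumours so cold spots dominate; doses below 1e-3 Gy are
clamped to that value so a cold volume at 0 Gy drives the EUD to ~0 rather
than dividing by zero. The power mean is evaluated in log-sum-exp form so
extreme |a| stays finite. An optional per-bin EQD2 conversion
(D·(D/n + α/β)/(2 + α/β)) re-expresses doses in 2-Gy-fraction equivalents;
it is off by default because all four plan setups are always scored with
identical settings, so only relative comparisons are contractual. Defaults
(a = −7.2, TCD50 = 28 Gy, γ50 = 2.5, α/β = 10 Gy) describe a steep breast
dose response of the order used in EUD-TCP reports; they are configuration
entries, not constants, and should be reviewed against local protocol —
with them, a typical intact plan (EUD ≈ 39–40 Gy) scores TCP ≈ 97 %, and a
target-coverage defect pulls it below 95 %.

NTCP is a linear, zero-anchored excess risk: value(%) = baseline(%) ×
excess-rate-per-Gy × mean organ dose, evaluated for three endpoints (acute
coronary events and cardiac-disease mortality on mean heart dose,
secondary-lung-cancer mortality on mean lung dose), each with and without
the relevant risk factor — six estimates per plan. Default rates are
0.074/Gy, 0.041/Gy and 0.11/Gy with stratum baselines (9.6/4.5, 8.0/2.0,
9.4/0.5 % lifetime risk); all reference-derived defaults, configurable.

## Contour similarity

Surfaces are the boundary member voxels under 6-connectivity (array-edge
voxels count as surface; masks are expected padded), represented by voxel
centres, with Euclidean mm distances respecting anisotropic spacing.
SDSC pools both surfaces at tolerance τ (default 3 mm); HD95 is the max of
the two directed 95th percentiles with linear interpolation between order
statistics (a pooled-distance variant exists in the literature; the
max-of-directed convention is used here). Fast KD-tree implementations are
tested against O(n²) pairwise brute force to 1e-9 mm.

## Workflow routes and time model

Route A: the fully automatic plan (DLS-DLP) meets all six goals. Route B:
it does not, but the corrected-target plan (PS-DLP) does. Route C
otherwise — the worst case of the indistinguishable C/D pair, so D is
never auto-assigned. TCP/NTCP never enter routing. Per-route times
(minutes hands-on / hours between steps): current 85/37, A 20/16, B 25/24,
C 75/36, D 70/36. The average saving is current minus the count-weighted
mean; with the published 43/26/32 split this gives 46.3 min and 12.6 h
(printed elsewhere rounded to 45 min / 12 h).

## Statistics

Per metric: Shapiro-Wilk on all pairwise setup differences as a
descriptive normality gate; the Friedman test across the four paired
setups; and only when the omnibus is significant at α = 0.05, the six
pairwise Wilcoxon signed-rank tests with Bonferroni factor 6 (the family
is the six setup pairs within one metric; configurable). Friedman uses
mid-ranks and the classic statistic with the standard tie correction; for
n ≤ 8 the p-value comes from the exact permutation null, built by
dynamic-programming convolution of per-row rank permutations (validated
against Monte Carlo permutation), otherwise from the χ² approximation with
k−1 df. The χ² approximation tracks the exact null within 0.02 where
decisions are made (p < 0.2) but can deviate by ~0.05 at mid-range p for
n = 8, because the exact null is discrete. Wilcoxon drops zero
differences, uses the exact null for n ≤ 25 without ties and the
tie-corrected normal approximation otherwise.

## Synthetic cohort

Two fidelity modes keep the suite fast: a DVH-level sampler for cohort
statistics and a voxel-level phantom for the dose/contour engines.

**DVH-level sampler.** Each of the six scored parameters is drawn per
setup from a marginal matched to a published cohort's median/Q1/Q3:
normal for PTV metrics, log-normal for the right-skewed OAR mean doses.
Printed quartiles are rounded to 0.1 Gy and sometimes collapse onto the
median; collapsed quartiles are offset by 0.03 Gy, a sub-rounding spread
chosen once so the fully automatic setup's all-goals rate calibrates to
its 43 % target. A per-patient latent factor shared across setups with
weight √ρ (ρ = 0.9 by default — four plans on one anatomy are highly
correlated) induces inter-setup correlation; PTV triples are re-drawn
until D98 ≤ Dmean ≤ D2. A configurable 23 % of patients carry a
"clinically relevant target defect": their DLS-DLP DVH receives a cold
spot (3–12 % of the volume at 12–28 Gy — the part of the true target the
DL contour missed), absent again in PS-DLP where the target was
corrected; these are the plans whose TCP drops below 95 %. TCP needs a
full DVH, so a plausible curve is synthesised from (Dmean, D98, D2): a
piecewise-linear voxel-dose quantile function through (0.02, D98) and
(0.98, D2) with an interior knot solved to match the mean.

**Voxel phantom.** Body, ipsilateral-breast CTV, lungs, heart and
contralateral breast are ellipsoids on a 3 mm grid by default (tests use
4–5 mm), with volumes of clinical magnitude (breast ~0.4 L, lungs ~3.6 L,
heart ~0.6 L). The PTV is the CTV dilated 5 mm (Euclidean) intersected
with the body eroded 5 mm, so every PTV voxel keeps the skin clearance.
Dose is a plateau inside the planning PTV with multiplicative band-limited
Gaussian texture (standardised over the PTV so the plateau mean is exact),
an exponential distance falloff outside whose length is solved by
bisection to a requested mean lung dose, and a small scatter floor
(0.6 % of plateau) so distant organs receive a realistic fraction of a Gy.
In voxel mode the fully automatic setup is planned on the *perturbed*
target and everything is evaluated on the clinical structures, so target
cold spots emerge geometrically rather than by injection.

**Contour perturbation.** DL-like contours are made by thresholding the
signed distance of the original mask against a smooth random field plus a
localised Gaussian boundary bump; the field amplitude is bisected until
the volumetric Dice lands within ±0.005 of target (±0.02 verified across
seeds), while the bump (depth ≈ the HD95 target, covering ~12 % of the
surface so the 95th percentile sees it) sets the Hausdorff scale. HD95 is
matched in scale only: it is floored by the voxel size (sub-voxel targets
such as 1.2 mm for lungs are unreachable on a 4–5 mm grid) and large
structures can overshoot by a few mm once the amplitude required by the
Dice target dominates.

Everything is a pure function of (config, seed); two runs of the full
101-patient pipeline are bit-identical.

## What the synthetic cohort does and does not show

It reproduces the marginal DVH-parameter distributions, the calibrated
all-goals rate of the automatic setup (≈43 %), the defect-driven TCP tail
(≈23 % of automatic plans below 95 % TCP, removed by target correction)
and NTCP panels at the published order of magnitude. It does **not**
reproduce joint goal-pass structure: real clinically approved plans are
tuned *toward* the goals, so their marginals hug the thresholds while
almost all plans pass (88 % in the real cohort), whereas independent
marginals matched to the same quartiles pass less often (~50–60 % here)
and over-pass the corrected-target setups, shifting some route-C patients
to route B. Cohort-level numbers other than the two workflow-time
derivations are therefore indicative, not reproductions. Passing tests
demonstrate correctness of the metric engines and pipeline on data of
realistic shape, not agreement with any particular patient cohort.

## Problem sizes

Defaults keep the whole suite desk-scale: DVH-level cohorts of 101–2000
patients, voxel phantoms at 3–5 mm spacing (≈0.2–1 M voxels), oracle
grids ≤ 16³, 20-seed perturbation batches. All are configuration, chosen
as the sizes at which the statistical checks are already stable.
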