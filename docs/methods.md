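# Methods

This note documents the models, defaults and design choices behind
`thromboflow`. The package analyses microspot flow-chamber assays of
platelet–fibrin thrombus formation: nine kinetic readouts (P1–P9) per
microspot, comparative heatmap statistics, patient-versus-control
phenotyping, condition-prediction modelling, and thrombin-generation curve
characteristics.

## Assay registry

Microspot designs (M1–M9), parameter definitions (P1–P9) and condition
semantics are pinned in a versioned JSON registry shipped with the package,
so every analysis is reproducible against one coding. Score scales are
0-based (P4: 0–5; P5, P6, P8: 0–3): a blank field at t = 0 must be
expressible as 0. The (TF, iFVIIa, CTI) intervention triple maps to a
condition class 0–7 with bit order TF = 4, iFVIIa = 2, CTI = 1; the order
is arbitrary and recorded here and in output metadata. P9 is reported as
`11 − t` min: fibrin is watched up to 10 min and an unseen onset defaults
to 11 min, so P9 = 0 means "no fibrin" and larger values mean faster
clotting.

## Synthetic data model

No raw flow-chamber recordings are publicly available, so the package
carries a first-class generator with exact ground truth.

**Kinetics.** Each channel's surface coverage follows a logistic curve
`C(t) = C_max · (s(t) − s(0)) / (1 − s(0))`, `s(t) = 1/(1+e^{−(t−t50)/τ})`
— the simplest monotone saturating form pinned to zero at t = 0. Fibrin is
gated by an onset time `T_fib` and follows its logistic in `t − T_fib`.
Defaults: platelet t50 = 1.8 min (τ = 0.9), thrombus 2.4 (1.0),
phosphatidylserine 3.0 (1.1), fibrin 1.5 (0.7) after onset — platelets
accumulate early, fibrin late.

**Surface ladder.** Per-surface plateaus implement the reactivity ordering
M1 < M2,M3 < M4,M5 < M6 ≤ M7 (platelet plateaus 3 / 20 / 22 / 33 / 36 /
52 / 55 %SAC). These numbers are plausible defaults for testing, not
measured values. Without TF, only the strongly GPVI-activating M7 forms
appreciable fibrin inside the observation window (base onsets 9.5 → 6.5
min down the ladder; none for BSA).

**TF dose–response.** Co-coated or in-medium TF shortens the fibrin onset
with a saturating law `T_fib(d) = T_min + (T_base − T_min)·K/(K + d)`,
K = 10 pM, T_min = 4.5 min, T_base ≤ 10.5 min. The response saturates at
low dose — 10 pM in-medium TF already brings the onset to ~6.5 min on
reactive collagen — and even maximal TF leaves the onset in the second
4-min interval, matching the observed early-platelet / late-fibrin
kinetic structure. TF also raises the fibrin plateau (up to +80%) and
mildly boosts thrombus and PS plateaus.

**Interventions.** iFVIIa suppresses the effective TF dose to 5% and trims
thrombus/fibrin plateaus; CTI (FXIIa block) delays the onset by 1 min
(2 min when TF is present — the intrinsic pathway contributes more once TF
has primed thrombin generation) and lowers the fibrin plateau. A TM or APC
co-coating delays fibrin by 3 min and halves-ish the PS plateau, scaled by
the subject's `tm_delay_scale` (1 = normal protein C pathway, 0 = APC
resistant). Shear 150 s⁻¹ attenuates platelet-driven plateaus by 20% and
leaves the TF effect untouched.

**Patient templates** scale plateaus and shift onsets: FXII- and
FXI-deficiency reduce thrombus/fibrin plateaus (×0.65/0.55 and ×0.75/0.65)
with a +1 min onset shift — fibrin is impaired but still present, so their
TM response remains measurable; FV-deficiency is severe (platelet ×0.85,
thrombus ×0.6, fibrin ×0.15, onset +4 min) — with almost no FVa there is
also almost nothing for the TM/APC pathway to suppress; FV-Leiden is
prothrombotic (PS ×1.3, fibrin ×1.45, onset −1.5 min) with
`tm_delay_scale = 0`, i.e. APC resistance abolishes the TM effect despite
robust fibrin formation.

**Noise.** Plateau noise is lognormal: a per-subject factor (σ = 0.12)
shared across all of a subject's runs — this produces the donor-dependent
signature that correlates across related surfaces — plus a per-run
residual (σ = 0.08); combined CV ≈ 14%, consistent with the ~15% assay
variation typical for collagen surfaces. Onset noise is additive (subject
σ = 0.4 min, residual σ = 0.3 min; intra-individual time-to-fibrin
variation of order 5–10%). Cohorts default to duplicate runs per subject ×
surface × condition, the assay's standard replication. All randomness
flows from one seed.

**Images.** Frames are 8-bit; platelets are discs (radius 4–12 px)
accreting into clusters (60% of new discs attach near an existing one),
the PS channel marks the earliest-adherent discs, fibrin is drawn as
random-walk polylines ~3 px wide anchored on platelet foreground
(fibres protruding from thrombi), and the bright-field proxy is the
inverted platelet+fibrin composite. Noise: flat background (20), tilted
illumination plane (±8), Poisson shot noise and Gaussian read noise
(σ = 5) around an object intensity of 150. Ground-truth masks and %SAC are
exact by construction. Default test frames are 256×256 (full-size frames
are supported; the default keeps test runtimes in seconds). What the
generator does **not** emulate: optical point-spread detail, focus drift,
platelet motion between captures, and human-scored morphologies — passing
tests demonstrate pipeline correctness on this model, not performance on
real microscopy.

**Thrombin curves** are gamma-shaped pulses
`T(t) = peak · (x/w)^a e^{a(1−x/w)}`, x = t − lag, peaking at x = w, with
closed-form area `peak · w · e^a Γ(a+1) / a^{a+1}` carried alongside as an
oracle; a triangular option has area `peak · w` exactly.

## Image quantification

`suppress_background` is a frequency-domain band-pass: the frame is
mirror-padded to twice its size (suppressing the wrap-around leakage a
non-periodic illumination gradient would otherwise spray across the
spectrum), a hard annular mask keeps spatial periods between
`high_period_px` (default 3 px — pixel noise) and `low_period_px` (default
200 px — image-wide structure, including the mean), and the result is
rescaled to the input range. The hard mask makes the operator idempotent
in practice.

`threshold_channel` floors an Otsu threshold with `mean + k·SD` of the
band-passed t = 0 frame of the same channel (k = 3; k = 5 for the fibrin
channel, whose baseline carries fibrinogen-binding signal that must not
count as fibrin). A frame indistinguishable from its baseline therefore
segments (almost) empty. `clean_mask` applies horizontal-then-vertical
line closings followed by the union of horizontal and vertical openings
(length 3 px): isolated pixels vanish, thin fibres survive in any
orientation. Components use 8-connectivity; %SAC is exact foreground
fraction × 100 over the full frame (an ROI can be supplied). A QC step
compares each mask against the pixels brighter than the midpoint of its
foreground/background mean intensities (Dice); below 0.5 agreement the
frame is re-thresholded once with k lowered by 1 and flagged — never more
than the configured retry count.

Measured against generator truth, mean absolute %SAC error across true
coverages of 5–80% is well below 1 %SAC at default noise (the acceptance
script reports the exact number).

## Kinetic parameters

P1–P3 and P7 are %SAC readouts (bright-field inverted first). P4–P6 and P8
were originally human visual scores against reference images; here they
are **automated surrogates** with explicit monotone rubrics, calibrated on
generator scenes and recorded as such in provenance — they are not claimed
to reproduce human scoring. Defaults: single platelet < 80 px², aggregate
tiers 80 / 500 / 2000 px² (rescaled by (0.108 µm/px)⁻² when pixel size
differs); morphology 0–5 from blank → sparse singles → extensive singles →
largest-aggregate tiers; aggregation 0–3 from the foreground fraction in
above-cutoff objects; contraction 0–3 from footprint shrinkage after the
coverage peak with non-fading mean intensity; fibrin score 0–3 from fibre
presence and coverage.

Time-to-fibrin: a frame counts when it contains a fibre-like object
(skeleton ≥ 20 px and major/minor axis ratio ≥ 4) and the signal persists
at the next frame — either fibres are still resolvable or fibrin coverage
has not receded (fibres that merge into a dense mat stop being individual
elongated objects but certainly persist). First-frame-of-series onsets are
impossible (t = 0 is blank); appearance at the final frame is accepted
since persistence cannot be checked there. Resolution is the 2-min capture
grid; sub-frame interpolation is off by default.

## Thrombin-curve characteristics

Peak = curve maximum; ETP = trapezoidal integral of the full trace
(exactly linear in the curve); lag = first grid time the concentration
exceeds `max(2 nM, 5% of peak)` for 2 consecutive points (the vendor
software's internal rule is not public; this policy is configurable);
C1 = assay cap (default 60 min) − lag, mirroring the `11 − t` convention.
An all-zero curve reports zeros rather than raising. TM suppression is the
TM/reference ratio of ETP and peak, undefined (missing) on a zero
reference.

## Heatmap analytics

Rows (parameter × time) are scaled `x → 10·(x − min)/(max − min)` across
all surface × condition × time × subject cells of the comparison set
(scaling scope is configurable; pooling across conditions matches the
published heatmap convention); constant rows scale to 0 and are flagged,
and the per-row (min, max) record makes the transform invertible.
Subtraction heatmaps are cellwise differences zeroed inside a mean ± SD
relevance band (band = replicate control statistics; centre defaults to
0). The summed scaled effect is the plain sum of retained signed values
over an **explicit** scope — which cells enter the published sums is not
stated, so the scope is a required argument. Interval kinetics compare
Δt₁ = v(4) − v(0) against Δt₂ = v(8) − v(4) on scaled values. Row
clustering is agglomerative with Euclidean distance and complete linkage
(scipy; ties break toward the lowest cluster index, and the suite verifies
agreement with a brute-force O(n³) oracle via cophenetic distances).
Cross-surface correlation pairs subjects between two surfaces and reports
Pearson r with two-sided p per parameter × time, missing on zero variance.

## Cohort phenotyping

Reference ranges are per-cell control mean and **sample** SD (n−1;
denominator choice documented because the convention was open) on the 0–10
scale, requiring ≥ 2 controls per cell. A patient's relevant-change map
keeps `Δ = patient − control mean` only where `|Δ| > SD` (red = relevant
increase, green = relevant decrease). Group integration **sums** (not
averages; a config switch exists) retained values over time points and
surfaces for the platelet (P1–2), thrombus (P3–6) and fibrin (P7–9)
groups, with TF-present and TF-absent strata reported separately. The TM
effect pairs each subject's runs on TM-co-coated collagen-I (M8, TF in
medium) against plain collagen-I under in-medium TF (the comparator choice
is recorded in output metadata) and averages the relevance-filtered
(no-TM − TM) difference over the fibrin parameters; positive = TM
suppresses fibrin. Group comparisons use the two-sided Mann–Whitney U
test: exact rank enumeration for small untied samples, tie-corrected
normal approximation otherwise, p = 1 on fully tied data.

## Prediction layer

Missing cells are kNN-imputed (k = 3): mean of the feature over the k
nearest rows by Euclidean distance on co-observed features (mean-square
normalised), ties toward the lowest row index; implemented directly
because these semantics are part of the contract. The P1–P2 contribution
to each outcome is `R²(Pi alone) / R²(full {P1,P2} model) × 100`, floored
at 0 — the "% of maximal prediction" notion is not otherwise defined, so
this ratio is the package's explicit definition; near-zero full-model R²
flags the ratio unstable. Condition classes (0–7) are predicted per
surface by a roster of distinct classifier families (decision tree, random
forest, gradient boosting, naive Bayes, logistic, ridge, RBF and linear
SVM, k-NN; configurable) under leave-one-out cross-validation with every
fold retrained from scratch; distance/margin-based members standardise
features on the training fold only; per-classifier seeds derive from one
roster seed and are recorded. Runs whose class has a single representative
are counted unpredictable and flagged. Surface pairs are compared with
paired two-sided t-tests across the roster, Benjamini–Hochberg-adjusted
across all pairs (the FDR method was unspecified; BH is fixed here);
identical accuracy vectors report p = 1 and a degeneracy flag.

## Pipeline and formats

Runs are stored as per-channel 8-bit TIFF stacks with a JSON manifest;
masks as PNG; tables as UTF-8 comma-separated CSV with '.' decimals
(decimal commas are rejected with a dialect error; floats are written with
`%.17g` and parsed with round-trip precision so tables survive
write/read exactly); configs and reports as JSON. `PipelineConfig`
rejects unknown keys and hashes itself into every provenance file, which
also records package version, seeds and inputs — enough to re-execute any
output. The CLI (`thromboflow simulate | quantify | parameters | thrombin
| heatmap | phenotype | predict | run-all`) is a thin layer over the
library; exit codes: 0 success, 2 input error, 3 stage failure.

## Problem sizes and limitations

The test suite and acceptance script use 192–256 px frames, cohorts of
10 controls + 6 patients with duplicate runs, 50-run kinetic cohorts and
20 phenotyping replicates — sizes chosen so the whole suite completes in
about a minute while leaving the statistical checks well-powered. Known
limitations: score surrogates cannot be validated against the original
visual scores without the raw images; published cohort-specific numbers
(summed scaled effects, classifier accuracies, correlation magnitudes)
depend on the original raw data and are out of scope — the corresponding
machinery is instead verified against oracles and generator ground truth;
the imaging model omits drift/registration, z-stacks and multi-spot
fields.
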