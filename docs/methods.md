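# Methods

## Problem and scope

The package analyzes craniocaudal cervical spinal cord motion measured by
cardiac-gated phase-contrast MRI in patients with monosegmental degenerative
cervical stenosis and age/gender-matched controls. Six disc levels (C2/C3 …
C7/T1) are analyzed per subject. The analysis chain is: per-segment velocity
waveform → motion parameters → intra-individual strain indices → anatomical
compromise scores → matched-pair cohort statistics. Since no clinical data
of this kind is publicly deposited, a synthetic-cohort generator provides
study-condition inputs; it is first-class, tested code, and its defaults
*are* the study conditions (group sizes 2/6/14/33/10 with the study's
male fractions, ~40 timepoints per heartbeat, heartbeat 920 ± 140 ms).

## Waveform model

One cardiac cycle of cord motion is modelled as a single short oscillation:
a caudal systolic peak and a cranial recoil lobe,

    v(t) = A · f_p(t/T),   f_p(φ) = 2[β sin(2πφ)^p]₊ − 2[(1−β)|sin 2πφ|^p]₋,

with sharpness exponent `p`, asymmetry `β` (fraction of the peak-to-peak
span carried by the caudal peak, default 0.65 so maximum velocity ≈ 0.65 ×
ptp, matching the reported ratio of peak to span), and amplitude `A` in
cm/s. The unit template has continuous span exactly 2 for every `p`, and
the rectified-lobe integral has the closed form Γ((p+1)/2)/(√π Γ(p/2+1)),
linking ptp-amplitude, heartbeat duration and total displacement
analytically. Reported total displacements (~1.5–2 mm at ptp 11–16 mm/s,
T ≈ 0.92 s) imply p ≈ 5–9, i.e. much sharper than a plain sinusoid — a
brief systolic spike. Gender enters as a shape factor multiplying the base
exponent (default 7.0): men 1.3 (sharper), women 0.8 (flattened, prolonged
sinusoid). At fixed total displacement a sharper waveform has strictly
larger ptp-amplitude, which encodes the qualitative gender difference
(similar displacement, different peaks).

## Amplitude calibration (parameter space, not ptp space)

Cohort targets are *mean pipeline-measured* ptp-amplitudes per group,
gender and segment. Because measurement takes max-minus-min of ~40 noisy
samples, it is biased upward relative to the noiseless span, and because
per-subject amplitudes are drawn log-normally (shared subject scale
σ = 0.42, matching the printed coefficient of variation ≈ 0.45; SD
agreement is reported, not asserted), the generator numerically inverts the
map {mean noiseless span → E[measured ptp]} (Gauss-Hermite quadrature over
the subject scale, fixed-seed common-random-number Monte Carlo over sample
noise) and draws waveform parameters, never measured values. The pipeline
therefore does real extraction work, and measured group means converge to
the targets over replicates.

Per-gender targets at the stenotic level and at the reference segments come
from the study's gender tables and index means (reference-segment mean =
stenosis mean / index mean); at segments adjacent to the stenosis only the
group mean is published, and the stenosis-level gender ratio is applied
within the published group mean. The control profile is a single
per-segment table with the physiological mid-cervical bump (7.2, 7.5, 7.94,
7.89, 7.2, 6.6 mm/s); the two published control values at C6/C7 (7.16 and
7.31 mm/s, from different matched groups) are split at 7.2.

A small independent per-segment jitter (log-SD 0.02) adds realism on top of
the shared subject scale. It is deliberately small: the package guarantees
that the argmax of the C2-pAI localizes the stenotic segment in ≥95% of
caudal-stenosis patients, and the published C4/C5 group separates stenosis
from its caudal neighbour by only ~10% (13.80 vs 12.46 mm/s), so larger
per-segment variation destroys localization.

## Phantom and extraction

The phantom is a sagittal velocity-map series (default 120 × 48 pixels,
row 0 cranial): cord pixels in each disc interval carry that segment's
waveform, CSF and static tissue are at rest, a global linear phase drift
(slope drawn per phantom, default SD 0.2 cm/s per cycle) is added to every
pixel plus white pixel noise (0.15 cm/s). No k-space/MRI physics or ECG
jitter is simulated. ROIs take the central third of the row interval
between consecutive vertebral-body mid-height rows intersected with the
cord label (empty intersection → missing segment, not an error). Drift is
estimated by least squares on all static-pixel samples as b₀ + b₁t
(optionally + t·row + t·col behind a switch — the published correction's
exact spatial form is not restated in this literature, so the testable
contract is "corrected static tissue has ~zero temporal slope") and
subtracted everywhere. Curves are ROI means per timepoint. Extraction is
linear and drift correction idempotent.

## Metrics and conventions

Peaks are taken over sampled points only (no interpolation). Total
displacement integrates |v| with the trapezoidal rule, closing the cycle
periodically (a rectangle-sum option exists; the original work does not
name its quadrature). Total displacement is suppressed in reports at C2/C3
(known moderate test-retest reliability); the value is still computable.
Indices propagate missingness: a missing or non-positive reference ptp
voids the whole index family with a warning, never a division error.
aMCC neighbors are the adjacent disc levels on an extended C1/C2 … T1/T2
grid, so both boundary segments are well defined.

## Anatomy generation

Canal CSAs start from a linear baseline (255 → 185 mm² across the extended
grid), whose intrinsic compromise score is exactly 1 at every interior
level, times a log-normal body-size factor (σ 0.06) and per-level jitter
(σ 0.02); the canal at the designated level is divided by a per-group
compromise target times a log-normal severity factor (σ 0.35 patients, 0.08
controls). Cord CSAs are canal × occupation ratio (per-level control
profile; patient override at the stenosis), capped at 0.97 so cord < canal
always holds. A single smooth control profile cannot satisfy all five
published per-group control compromise values at once (the implied
three-point recursion is unstable and produces non-physiological canal
areas), so controls carry their matched group's mild target at that group's
level — the matched-cohort analogue of per-group calibration.

## Statistics

Two-group comparisons are gated by Shapiro-Wilk at α = 0.05 per group
(both normal → unpaired t; otherwise Mann-Whitney U; paired variants
available — patient-vs-control tables default to unpaired, mirroring
group-level reporting, with a paired flag). Fewer than 3 values per group
yields descriptives only. Within-subject segment profiles use a
repeated-measures ANOVA (complete cases; outliers not excluded) with a
sphericity check and Greenhouse-Geisser correction when violated, followed
by paired contrasts cranial-vs-stenosis and stenosis-vs-caudal, Bonferroni
adjusted over the contrasts actually made (m recorded in the result).
Multi-group comparisons use Kruskal-Wallis; an all-tied input is reported
as a degenerate ties-only case rather than a p-value.

Prediction models are OLS (motion parameter at stenosis ~ severity score +
age + gender), constant predictors dropped with a warning. Outliers are
excluded only when flagged by BOTH Cook's distance and leverage, and the
fit is repeated once. The leverage cut-off is 2(k+1)/n; the Cook cut-off is
the classical absolute D > 1 rather than the 4/n rule of thumb: with 4/n
the conjunction fires on ~40% of clean null datasets at n = 40 and inflates
per-predictor type-I error to ~6%, whereas D > 1 keeps false exclusions
(and hence the procedure's size) at the nominal level while still removing
gross outliers. Both cut-offs are arguments. Under null simulation every
implemented test rejects at ≈ α.

## Problem sizes and numerical choices

The replicate analyses (acceptance suite and `scripts/acceptance.py`) use
50 replicate cohorts per stenosis group (C4/C5 n=14, C5/C6 n=33, C6/C7
n=10, each with matched controls), routed through phantom rendering and
extraction — enough for Monte-Carlo standard errors of pooled group means
around 1–2%, comfortably inside the ±10% comparison bands. Null
calibration uses 2000 replicates. All randomness flows through explicit
integer seeds (replicate seeds derived arithmetically, kept below 2³¹);
identical config + seed reproduces cohorts, phantoms and outputs
bit-identically. The amplitude-calibration cache is keyed on rounded
parameters and uses its own fixed seed: it is a deterministic numerical
procedure, not a data-randomness source.

## What passing tests do and do not show

The generator emulates group means, gender splits, index structure,
matching, heartbeat variation, drift and additive noise. It does not
emulate aliasing at the velocity-encoding limit, breathing or CSF-pulsation
confounds, multi-oscillation waveforms seen in severely affected patients,
segmentation errors of real CNN pipelines, or inter-scanner level shifts
(reported velocities differ ~2× between published protocols). Recovery of
the printed statistics therefore validates the pipeline's correctness and
calibration logic, not the clinical findings themselves. The C2/C3 and
C3/C4 groups are generated but, as in the study, too small for most
inference; mJOA scores are carried as inert metadata and never analyzed
against motion.
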