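# Methods

## The diagnostic model

The Dopamine Neuron Challenge (DNC) Test rests on a compensation
argument: in early Parkinson's disease the surviving nigral dopamine
neurons up-regulate release, so resting extracellular dopamine — and the
downstream metabolites DOPAC and HVA in CSF and plasma — stay in the
normal range even after a substantial fraction of neurons is gone. A
pharmacological challenge (methylphenidate 10 mg/kg + haloperidol
1 mg/kg, i.p.) drives all surviving neurons toward maximal release;
the magnitude of the evoked metabolite surge then scales with the number
of surviving neurons and separates diseased from healthy subjects.

The classifier is deliberately minimal. For one analyte the threshold is
the midpoint of the challenged-state group means,

    T = (mean_challenged_control + mean_challenged_PD) / 2,

a subject measuring strictly **below** T is called positive
(`dnctest.dnc.classify_subject`; a value exactly at T is negative, since
positivity is defined by being *smaller* than the threshold), and

    sensitivity = N_true+ / N_total_PD x 100%
    specificity = N_true- / N_total_control x 100%.

Percentages are reported as half-up-rounded integers with the unrounded
values retained. The threshold is in-sample by construction — it is
derived from the same cohort it classifies. No ROC optimisation,
cross-validation or multi-analyte combination is attempted; the package
reproduces exactly the published rule, and that limitation is inherited
deliberately.

`expected_performance` is the closed-form companion: modelling each
group as Normal(mean, SEM·√n) — the only dispersion reconstructible from
published summary statistics — the expected sensitivity is
Φ((T − μ_PD)/σ_PD) and the expected specificity Φ((μ_C − T)/σ_C). At the
published 20-week plasma parameters this predicts ≈ 81% specificity,
bracketing the published 82% (18/22). Two caveats follow directly from
the printed numbers rather than from any implementation choice: the
resting-state CSF HVA/5-HIAA parameters give an expected sensitivity of
73% (not under 70% as the DOPAC ratio's 65%), and the ultra-early
challenged CSF DOPAC/5-HIAA row gives 89.5%, a hair under 90%. The tests
assert the separation claim on the rows whose printed values support it.

## Cohort simulation

`synthetic.simulate_cohort` draws i.i.d. Normal(mean, SEM·√n) values per
(group, state, analyte) cell, parameterised by the published tables in
`dnctest.studyparams` (20-week "early" and 15-week "ultra-early"
MitoPark cohorts). This is the simplest model consistent with the
published mean ± SEM and n; no heavier-tailed alternative is modelled,
and resting/challenged cells are independent (CSF and blood were drawn
from different animals, so no within-subject correlation is available to
emulate). Consequences for interpretation: passing recovery tests shows
the classifier and its closed-form prediction are internally consistent
under normality — they cannot validate distributional assumptions about
real cohorts, for which the raw per-animal values were never published.

## Photometry

A single 473 nm laser excites both the dopamine sensor dLight1.1 (green)
and the dopamine-insensitive reference tdTomato (red); each frame's
emission spectrum is a linear mixture of the two reference shapes.
Unmixing is ordinary (unconstrained) least squares per frame
(`numpy.linalg.lstsq`, vectorised over frames), which matches a
closed-form normal-equations solution to 1e-8 and is exactly
scale-equivariant. A nonnegativity-constrained variant
(`scipy.optimize.nnls`) is available behind a flag; an optional constant
background column is off by default. Bases with condition number above a
configurable cap (default 1e8) are rejected by name.

Fading correction: dLight1.1 bleaches noticeably over a session, so an
ordinary least-squares line is fitted to the first 600 s (boundary
inclusive) of the unmixed coefficient trace and extrapolated as the
theoretical baseline F0(t); ΔF/F0% = (F − F0)/F0 × 100 per frame. The
drug injection must come after the fit window, otherwise the baseline
absorbs part of the response; a baseline that crosses zero anywhere in
the trace is rejected as an invalid fading model. Correction applies per
channel independently.

The agent-ranking metric `percent_ratio_increase` forms
r(t) = c_dLight/c_tdTomato, smooths with a centred 5 s moving average
(window configurable) and reports the post-injection maximum relative to
the pre-injection mean, in percent. Ratio first, smoothing second; the
metric is undefined (error) if the reference coefficient is ≤ 0 in any
used frame.

The session generator applies linear (not exponential) bleaching —
matching the linear-regression baseline the correction assumes — as a
fractional loss per minute on the signal channel, an exponentially
decaying transient (default decay 60–120 s) after onset, and white
Gaussian noise scaled to the peak of the clean t = 0 spectrum. Emission
shapes are single Gaussians (dLight1.1 peak 510 nm, tdTomato 581 nm, SDs
20/18 nm); published spectra are shown but not tabulated, so shapes are
configurable. Defaults: 25 Hz trigger rate as acquired; tests and the
demo run at 2–5 Hz, which changes nothing but the frame count.

## HPLC

Peak areas are trapezoidal integrals of (signal − baseline) over
user-configured retention windows. The default baseline is the straight
line through the window edges, with each edge anchored on the mean of a
short shoulder (default 5 samples) rather than the single edge sample:
a single noisy sample at each end otherwise dominates the error budget
of small peaks, while shoulder averaging leaves constant offsets and
linear drifts removed exactly and reduces to the single-sample rule at
`baseline_samples=1`. Windows are explicit configuration; the local-
maximum `detect_peaks` helper is a convenience only.

CSF analytes are reported as area ratios against 5-HIAA, the serotonin
metabolite used as an internal control: both numerator and denominator
scale identically with injection volume and dilution, so the ratio is
exactly invariant to chromatogram rescaling. Plasma HVA is converted to
ng/ml through a linear standard curve fitted (with intercept, by
default; origin-forcing behind a flag) to the eight reference
concentrations 0.5–50 ng/ml; the curve is fitted against the nominal
pre-dilution concentrations. Negative back-calculated concentrations are
clamped to zero and flagged below-detection.

The chromatogram generator sums Gaussian peaks (true area
A·w·√(2π)) on a linear drift plus white noise; peaks closer than 3σ are
flagged as overlapping rather than rejected.

## Histology

Cell counting follows a standard DAB particle-analysis recipe, in order:
green channel of the RGB scan (highest DAB contrast) → inversion (stained
somata become bright) → grayscale opening with a disk of radius 7 px
(removes bright maxima smaller than the element — the "eliminate maxima"
step) → Gaussian blur (kernel half-width 7 px, σ = 7/3, truncated at
7 px) → rolling-ball background subtraction (radius 60 px) → isodata
automatic threshold → Euclidean-distance-transform watershed with
local-maxima markers (minimum marker distance 7 px) → connected
components → count particles with area **strictly greater than** 100 px.
All sizes are configuration. Two numerical guards are package choices:
a `min_contrast` floor (default 10 gray levels after background
subtraction) short-circuits to zero cells when the image contains only
background texture, because an automatic threshold applied to pure noise
binarises it and percolating noise blobs would otherwise be counted; and
the labelled mask of counted particles is returned for audit overlays.
The interpretation of "eliminate maxima (size 7)" as opening with a
radius-7 disk, and of the blur "size" as kernel half-width, are recorded
assumptions — the source tool's semantics are not documented precisely.

Terminal density inverts the grayscale (denser staining → higher value),
selects ROI pixels inside the 45–255 intensity band, maps them through a
monotone OD calibration (identity by default; a user lookup overrides)
and reports the mean of the selected pixels only (a flag switches to
all-ROI averaging). Percent loss is (reference − test)/reference × 100;
for a unilateral lesion the whole-animal loss assumes the intact
hemisphere equals the pre-lesion count of either side, giving
(intact − lesioned)/(2·intact) × 100. No stereological correction is
applied — counts are 2-D profiles in evenly spaced sections, as in the
source protocol.

The image generator renders dark disks (default gray 60) on a light
textured background (200 ± 3) with a configurable separation margin, and
returns per-cell masks so recovery tests need no re-derivation. It does
not emulate staining gradients, section artefacts, anisotropic somata or
out-of-focus halos; exact-count results on these images demonstrate the
pipeline's bookkeeping (filters, threshold, watershed, area rule), not
robustness to real tissue variability.

## Problem sizes and numerical choices

- Unit and property tests run sessions at 2–5 Hz for 30–1000 s, images
  at 128–256 px with rolling-ball radius 30 (the 60 px default is meant
  for full-size section scans), 100 seeded chromatograms, 500 simulated
  cohorts per published row, and 50 watershed stress cases — sizes chosen
  so the whole suite completes in well under a minute of compute while
  keeping every statistical check meaningful.
- Count monotonicity (adding one disjoint cell increments the count) is
  exercised over 8 seeded placements in the unit suite; the watershed
  split-rate check runs the full 50 cases.
- Ties: classification at exactly the threshold is negative; reported
  percentages round half-up; `baseline_samples` and `marker_min_distance`
  break the remaining procedural ambiguity and are configuration.
- Determinism: every generator takes an explicit integer seed
  (`numpy.random.default_rng`); pipeline stages derive seeds from the run
  seed with fixed offsets, and rerunning a config reproduces byte-identical
  output digests.

## Known limitations

- The two thresholds published as 0.1169 and 0.1040 differ by 1e-4 from
  the midpoints of the rounded printed means (0.1170, 0.1039), implying
  unrounded underlying data; exactness is asserted only for the four
  consistent rows.
- Published sensitivities/specificities are not bit-reproducible because
  per-animal raw values were never released; the closed-form normal
  prediction plus simulation at the printed parameters is the strongest
  available check and agrees within a few percentage points.
- No motion or hemodynamic artefact correction, no isosbestic
  regression, no detector physics, no atlas registration, no
  pharmacokinetics of the challenge agents — the challenge enters only
  through the published challenged-state group means.
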