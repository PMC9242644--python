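# Methods

## Ratio–pH law and calibration

The dye response is modeled as the four-parameter logistic (4PL) in pH,

    R(pH) = r_min + (r_max − r_min) / (1 + 10^(h·(pH50 − pH))),

strictly increasing for h > 0. The base-10 slope convention is arbitrary (a
base-e sigmoid is the same family up to rescaling h); we use base 10 so that
pH50 reads directly as an apparent pKa. Generator defaults r_min = 0.2,
r_max = 2.0, pH50 = 4.8, h = 1.0 describe an Oregon-Green-like probe whose
apparent pKa (4.8) sits in the lysosomal range.

Calibration is fitted per experiment from *per-cell mean ratios* (one point
per cell per buffer, 4 cells per buffer at pH 7.0, 6.0, 5.0, 4.5, 4.0, 3.0
by default), not from individual lysosomes: cells are the experimental unit
and per-cell averaging suppresses the heavy tail of single-lysosome ratio
noise. Least squares uses `scipy.optimize.curve_fit` with initialization
r_min/r_max at the observed extremes, pH50 interpolated at the midpoint
ratio, h = 1; bounds r_min ≥ 0, h ∈ [0.1, 5]; tolerances 1e−14. The fit
fails loudly with fewer than 4 distinct buffers, fewer than 8 points, or a
non-increasing result.

Inversion is analytic. Ratios at or beyond the fitted asymptotes — where the
dye carries no pH information — are **clamped to the calibrated pH range and
flagged** rather than dropped; condition summaries report the flagged
fraction. Clamping makes the probe's insensitivity explicit instead of
silently truncating the sample.

## Synthetic imaging generator

What it emulates: fields of dye-loaded cells whose lysosomes appear as
punctate spots in two nearly simultaneous excitation images. Each lysosome
is an isotropic 2-D Gaussian (σ = `radius_px`, truncated at 3σ) with
log-normal dye amount; the 445 nm channel receives
`photon_scale·dye·G(x)` and the 488 nm channel the same times R(true pH).
This reduction — reference channel pH-independent, signal channel scaled by
the ratio law — makes the ground-truth ratio of every spot exact, which is
what downstream tests need; no attempt is made to model the dye's actual
two-excitation photophysics. Detection noise is Poisson on expected counts
(spots + constant background + planar gradient) followed by Gaussian read
noise, clipped at zero.

True pH is Normal(mean, sd) truncated to [3.0, 7.5] (the calibration span
plus margin); default sd 0.15 pH units. Lysosome count per cell is a fixed
config integer (experiment sizes in this field are quoted as exact counts);
dispersion lives in the radius, dye and pH draws. Cells are non-overlapping
ellipses on a jittered grid and serve only to group lysosomes; default
rendering is one cell per image pair (file naming
`{condition}__cell{ID}__{445|488}.tif`), with multi-cell fields supported in
memory via a label-mask assignment. Pixel size (µm/px, default 0.1 in the
configs) is an acquisition property and therefore a required `SceneConfig`
input with no internal default.

Calibration series clamp every lysosome's pH to the buffer value, emulating
ionophore equilibration.

Default study conditions (the `QuantifyConfig` defaults): control at true pH
4.32, treated at 4.02 with swollen puncta (spot σ 3.5 px vs 2.0 px);
10 cells × 30 lysosomes per condition; background 50 counts, gradient 20,
read noise 3, spot amplitudes ~3000 counts (median). The knockout-like
variant in `analysis/02_quantify_ph.py` uses a blunted treated mean of 4.19
and intermediate swelling.

What the generator does **not** reproduce: optics (no PSF, no 3-D stacks, no
chromatic offset between channels), photobleaching, autofluorescence,
touching-organelle clutter at realistic densities, or cell-to-cell loading
variability beyond the log-normal dye draw. Passing recovery tests therefore
shows the *analysis chain* is unbiased under the stated noise model, not
that any given microscope matches that model.

## Segmentation and pairing

* Local background: grayscale opening with a disk (default radius 10 px), a
  rolling-ball analog; subtraction floored at 0. Opening removes structures
  smaller than the disk from the background estimate, so puncta survive at
  full amplitude. For spots approaching the disk size (swollen condition)
  part of the spot enters the background estimate; this attenuates both
  channels equally and cancels in the ratio.
* Otsu threshold: candidates are the lower edges of a 256-bin histogram over
  [min, max]; the between-class variance w0·w1·(µ0 − µ1)² is computed from
  the exact pixel partition (≤ edge vs > edge); ties break toward the lowest
  threshold; foreground is strictly above the threshold. A brute-force
  maximizer over every distinct image value pins this behavior in the tests.
* Components: 8-connectivity and a 4 px minimum area by default (both
  configurable); centroids are unweighted pixel-coordinate means; ROI order
  is deterministic (top-left pixel, row-major).
* Pairing: maximum-cardinality, minimum-total-distance one-to-one matching
  (Hungarian algorithm on a distance matrix with disallowed entries at a
  large constant), hard gate 3 px. Optimal assignment is used because greedy
  matching is order-dependent. The low-intensity filter drops pairs whose
  ROI minimum background-subtracted intensity falls below 5 counts.
* The per-lysosome ratio is the ratio of ROI means (each channel over its
  own pixel set), not the mean of pixelwise ratios — robust to sub-pixel
  registration differences between the channels' masks. Lysosome size is the
  445-channel ROI area in µm² (the reference channel is pH-independent, so
  its area does not covary with the quantity being measured).

Biases that survive these choices (channel-dependent masks, threshold
interaction with brightness) are shared between experimental and calibration
images, so they largely cancel through the calibration inversion — the
reason calibration runs through the identical pipeline.

## Aggregation and statistics

Cell mean = unweighted mean over its lysosomes (cells with fewer than 5
measurements are excluded); condition mean and SEM are over cell means with
cells equally weighted. ΔpH = treated − control (acidification negative);
proton fold change 10^(−ΔpH). When several experiments are combined, ΔpH
and fold are computed per experiment first and then averaged — the average
of per-experiment folds is not 10^(−mean ΔpH) because the transform is
convex. ECDF reports the fraction of lysosomes at or below each observed pH.
Two-sample comparisons use Student's pooled-variance t-test (Welch available
by flag); paired designs use the paired t on differences.

## Voltage-clamp generator and fitters

The current is a minimal phenomenology of a slowly gating outward rectifier:

    I(V, t) = s · g_max · p∞(V) · (V − v_rev) · [a + (1 − a)(1 − e^(−t/τ_act(V)))]

with Boltzmann activation p∞(V) = 1/(1 + e^(−(V − v_half)/k)), voltage-
dependent activation τ_act(V) = τ0·e^(−V/v_τ), instantaneous fraction a, and
mono-exponential tail relaxation at the holding potential (τ_deact). Defaults:
g_max 10 nS, v_rev 0 mV, v_half 40 mV, k 25 mV, τ0 0.4 s, v_τ 200 mV,
τ_deact 50 ms, a 0.1; protocol: hold −60 mV, steps −80…+140 mV in 20 mV
increments, 2 s pulse, 0.5 s tail, 1 kHz sampling. This is a deliberate
self-consistent generator, not a mechanistic claim about the transporter.

Pipette dialysis of an inhibitory lipid scales the conductance by

    s(c, t) = 1 − f_max(c)·(1 − e^(−t/τ_wash)),  f_max(c) = f_ceiling·c^n/(c^n + EC50^n)

frozen at each family's break-in time (families are short relative to
τ_wash = 60 s). Tail currents carry a separate ceiling (`f_ceiling_tail`):
with the tail amplitude defined as the fitted exponential extrapolated to
repolarization onset, a single conductance scale cannot make tail inhibition
exceed steady-state inhibition, yet gating-state-dependent block does
exactly that in slowly gating transporters. The separate ceiling is the
minimal knob for this phenomenology. Defaults (f_ceiling 0.64,
f_ceiling_tail 0.94, EC50 30 µM, n 1.5, deactivation 1.67× faster under
lipid) give 3 min / 30 s ratios of 0.61 (steady state) and 0.34 (tail) at
100 µM — i.e. ~39% and ~66% inhibition. A lipid-insensitive mutant is
f_ceiling = 0.

Metrics: "maximum" current is the mean of the final 5% of the pulse (a
steady-state reading, robust to noise, rather than the pointwise maximum);
tail amplitude is the fitted decay extrapolated to repolarization onset with
the first 5 ms blanked (capacitance transient); time constants come from
single-exponential least squares initialized by log-linear regression on the
detrended signal. Degenerate traces (no relaxation) return
`converged=False` instead of raising. Inhibition ratios are late/early
within the same simulated cell, mirroring paired recordings.

Dose-response: fractional inhibition of the max-current ratio vs pipette
concentration, fitted with the 4-parameter Hill equation. The design must
bracket the midpoint (checked before and after the fit). Note two honest
biases of the late/early protocol itself: the 30 s baseline is already
partially inhibited, and the measured response is a ratio of two saturating
functions — so the apparent EC50 of the measured curve sits above the
underlying Hill midpoint (~36 µM measured for a 30 µM generator at the
default τ_wash). With one noisy response point per concentration
(sd 0.03, six concentrations), the Cramér–Rao bound places the median
relative EC50 error near 11%; recovery to better than ~10% needs replicates
(five cells per concentration suffice).

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` with explicit seeds;
scene geometry and pH draws use separate child streams so either can be
reproduced independently. Derived seeds stay below 2^31. Curve fits use
tolerance 1e−14 so that noiseless recoveries are exact to ≤ 1e−6. Output
CSVs print floats at 9 significant digits and carry a config-hash + seed
header; identical configs reproduce identical bytes.

Test and acceptance problem sizes — 256² px condition images, 160² px
calibration images, 10 cells × 30 lysosomes per condition, 5 seeds for the
end-to-end recovery, 200 replicates for calibration/EC50 Monte-Carlo, 1000
images for the Otsu oracle, 500 instances for the pairing oracle — were
chosen so the whole suite runs in about a minute on one core while keeping
Monte-Carlo standard errors well below the tolerances being asserted.

## Known limitations

* The imaging generator's simplifications listed above; in particular,
  segmentation-induced pH–size coupling is only partly cancelled by
  calibration, so weak spurious correlations (|r| ≈ 0.1 at n ≈ 250) can
  appear in single synthetic experiments.
* No watershed splitting: touching lysosomes merge into one ROI, which
  shifts the size distribution at high densities.
* The ephys model has no leak, series resistance, or capacitance artifacts
  beyond the 5 ms tail blank, and the inhibition scale is frozen within a
  family (exact only when sweeps are short relative to τ_wash).
* Out of scope by design: ANOVA/multiple-comparison corrections, recovery
  time-course fitting, any mechanistic flux model linking the transporter to
  lumenal pH.
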