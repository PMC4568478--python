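# Methods

## Signal model and concentration conversion

The scanner signal is modeled as `S(t) = S0 · exp(−k·TE·C(t))` with echo
time TE (default 30 ms), frame interval Δt (default 1.5 s) and an
arbitrary relaxivity constant `k = 1`: the analysis downstream is entirely
relative (surgical over contralateral hemisphere), so absolute
concentration calibration never enters a reported statistic. The baseline
`S0` is the mean of the first `n_baseline = 8` frames (12 s at Δt = 1.5 s;
the bolus is injected after scan start), and the brain mask keeps voxels
with `S0` above 10% of the 99th-percentile baseline. Inversion uses
`C = −ln(S/S0)/(k·TE)`. Negative concentrations from noise are *retained*
— clipping them would bias the AIF peak upward — while non-positive signal
samples are floored at `10⁻³·S0` before the logarithm and counted in a QC
field.

## Residue model and its discretization

Tissue curves obey `C(t) = F · (AIF ∗ R)(t)` with an exponential residue
`R(τ) = exp(−τ/MTT)` — the well-mixed single-compartment choice, which
makes `CBV = CBF·MTT` exact. On the frame grid the residue is
**bin-averaged**, `w[j] = (MTT/Δt)·e^(−jΔt/MTT)·(1−e^(−Δt/MTT))`, rather
than point-sampled. This keeps two properties exact at any sampling rate:
the tissue-curve area identity `∫C / ∫AIF = F·MTT = CBV`, and the impulse
limit `MTT ≪ Δt ⇒ C ≈ F·MTT·AIF`. The price is a known multiplicative
discretization factor in peak-based flow recovery: a discrete
deconvolution recovers the bin-averaged residue, whose peak is
`F·(MTT/Δt)(1−e^(−Δt/MTT)) ≈ F·(1 − Δt/(2·MTT))`. At the clinical
Δt = 1.5 s and MTT = 4 s this is a ~17% underestimation; it is shared by
both hemispheres and cancels in the relative statistics the pipeline
reports. Validation experiments that compare recovered CBF/MTT against
absolute ground truth therefore run at fine sampling (Δt = 0.25 s), where
the factor is below ~4% across the tested MTT range.

## Deconvolution operating points

Truncation thresholds default to 20% of the largest singular value for the
simple (Toeplitz) operator and 10% for the block-circulant operator, the
usual fixed operating points for noisy clinical data; both are
configurable. Circulant systems zero-pad to twice the frame count and
retain the first `n_frames` samples of the solution; CBF is the maximum of
`F·R(t)` over all retained time points (tolerant of residual delay),
negative SVD oscillations are zeroed before the CBV integral but not
before the peak, and CBV is stored as `MTT·CBF` so the central volume
identity holds to the last bit. A non-positive residue peak flags the
voxel; flagged voxels are excluded from regional means rather than
zero-filled.

The validation protocols fix these sizes:

* **Convolution oracle** — 100 random (AIF, residue) instances, operator
  application vs an explicit double-loop convolution sum.
* **Noise-free recovery** — CBF ∈ {20, 40, 60, 80} × MTT ∈ {3, 4.5, 6, 12} s,
  Δt = 0.25 s, 150 s window, circulant truncation 10⁻⁵. With no noise the
  regularization is matched to the noise level: a tiny threshold isolates
  discretization error. Worst-case recovery error is ~4% for both CBF and
  MTT (the MTT = 3 s cells dominate).
* **Noise robustness** — same grid at Δt = 0.25 s over a 90 s window,
  signal formed with a single relaxivity scaled so a mid-grid curve peaks
  at unit attenuation, Gaussian noise at baseline SNR 50, 12 replicates
  per cell, default truncation. The reported statistic is the median
  absolute CBF deviation of the noisy estimate from its noise-free
  counterpart (~2–3%): heavy truncation is precisely what buys this
  stability. The median error against *true* F at this SNR is ~15–30% for
  any fixed-threshold operating point we examined — truncation smoothing
  bias at short MTT plus noise variance at long MTT — consistent with
  published truncated-SVD simulation studies; both numbers are emitted by
  the acceptance script.
* **Delay sensitivity** — CBF 60, MTT 4 s, tissue curve delayed 0–3 frames
  at Δt = 0.25 s, default truncations. The circulant estimate is
  shift-invariant to rounding error; the simple-mode estimate decreases
  monotonically with delay. (At Δt = 1.5 s the simple-mode response still
  trends down but ripples — a truncation-projection artifact — so the
  fine-Δt protocol is the honest monotonicity regime.)

## AIF selection

Per-voxel screening features are the curve peak, time-to-peak
(`Δt·argmax`) and a first-moment width (first moment of the positive part
minus the arrival time, defined as the first frame reaching 5% of the
voxel peak). Candidates lie below the 0.1 quantile of TTP and the 0.2
quantile of the width; the 10 highest peaks among candidates (ties broken
by earlier TTP, then voxel order) are averaged into the AIF. This replaces
an interactive threshold search with a deterministic rule; the manual
plausibility check is replaced by an optional ROI restriction plus a QC
report of the selected coordinates, and by a hard guard: the selected mean
curve must peak at least 3× the median voxel peak, otherwise selection
fails rather than silently returning a tissue AIF.

## Synthetic phantom and cohort

The phantom is a 32×32×10 voxel volume, 60 frames at Δt = 1.5 s: five
territories per hemisphere as y-axis bands split left/right along x, a
4×2×2 midline artery block carrying the pure AIF, and a background rim.
The bolus is a gamma-variate `A·((t−t0)/(αβ))^α·e^(α−(t−t0)/β)` with
t0 = 12 s, α = 3, β = 1.5 s (FWHM ≈ 5.5 s, a fast antecubital injection)
and arterial amplitude 60 concentration units. Territory flows are
expressed as volume-fraction rates: CBF 0.0085–0.0105 s⁻¹ (≙ 51–63
mL/100g/min), MTT 3.8–4.6 s, hence CBV ≈ 4% — physiological gray-matter
values. Signal noise is Gaussian on magnitude with SD 0.5 at S0 = 100
(baseline SNR 200; arterial dips reach ~17% of baseline, tissue dips ~6%).
Seeds are explicit everywhere; identical specs and seeds are bit-identical.

The cohort generator draws, per subject: a baseline surgical-side
asymmetry on CBF and MTT (SD 0.10, matching the across-subject spread of
pre-surgical relative CBF in the motivating cohort), an intra-session
surgical-side CBF factor `1 + effect + N(0, 0.07)` where the effect is
+14.3% at the terminal MCA territory for CHS subjects and 0 for non-CHS,
and an intra-session surgical-side MTT jitter (SD 0.05) so that MTT and
CBV test families are non-degenerate under the null. The contralateral
hemisphere is identical across sessions. Group sizes default to 5 CHS / 9
non-CHS. `relative_truth_table()` exposes the exact relative values this
model implies — the noiseless limit of the imaging pipeline — and the
200-replicate effect-detection and 1000-replicate null-calibration
experiments run at this layer (one full imaging cohort backs the
schema and effect-cell checks); rendering a thousand full 4D cohorts would
add nothing but noise already characterized by the session-level tests.

What the generator does *not* emulate: anatomy, partial-volume mixtures,
contrast recirculation and leakage, bolus dispersion, motion, and slice
geometry (the motivating acquisition's 19 slices with gaps). Passing
tests therefore demonstrate correctness of the estimators under the
stated forward model, not robustness to those confounds.

## Statistics

Paired and independent two-tailed t-tests follow the textbook definitions
(scipy implementations behind the module surface), with explicit
degenerate contracts: all-zero paired differences report `t = 0, p = 1`;
constant nonzero differences report `p = 0` with an infinite statistic;
groups with fewer than two subjects yield not-computable (NaN) entries
while tables are still emitted. The independent test uses pooled variance
by default with a Welch flag. Benjamini–Hochberg control (statsmodels
step-up, validated in-suite against an exhaustive implementation of the
definition) runs at q = 0.2 separately per parameter over the 15-test
family {paired all-patients, across-group intra, across-group %increase}
× 5 territories; the family composition is a parameter. Group %increase
is the mean of per-subject percentage changes, not the percentage change
of group means — per-subject averaging is the only reading consistent
with the reference cohort's reported group values.

## Known limitations

* **Peak-based CBF couples to MTT at coarse sampling.** Recovered CBF is
  `F·g(MTT)` with `g` depending on Δt and truncation; side-to-side CBF
  ratios are faithful only when transit times are roughly side-symmetric.
  At the default heavy truncation a +28% MTT asymmetry can mask a −9% CBF
  asymmetry entirely. Cross-session `%increase` on one side is far more
  robust: a pure flow change scales the tissue curve linearly and survives
  any truncation exactly, up to the (small) session MTT jitter. CBV-based
  ratios are least affected.
* **Noise attenuates %increase magnitudes.** The voxelwise max-over-time
  CBF estimator has a positive noise-dependent offset, which compresses
  intra/pre ratios toward 1 at low SNR; group *contrasts* survive (the
  between-subject spread compresses by the same factor) but the absolute
  %increase printed for a noisy cohort underestimates the injected effect.
* Δt = 1.5 s absolute CBF/MTT values carry the discretization factor
  above; only relative quantities should be interpreted at that sampling.
* The pipeline assumes pre-registered inputs (series and atlas share grid
  and affine to 10⁻⁴) and NIfTI-1 throughout; no DICOM, no registration,
  no recirculation correction, and no clinical CHS threshold (none is
  established).
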