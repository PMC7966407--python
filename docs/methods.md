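# Methods

This note records the modelling choices behind `nirsdot`: the forward and
inverse models, the deconvolution statistics, what the synthetic data
emulate, and the numerical decisions a user should know before trusting
or extending the results.

## Geometry and sensitivity

The toy anatomy is a spherical-cap cortical patch (default radius 80 mm,
half-angle 50°, 250 vertices, mm units) with a radially offset scalp
layer (default +13 mm) and a contiguous region of interest (ROI) grown
around the cap apex (default radius 10 mm, minimum 5 vertices). It is a
geometric stand-in for a segmented pial surface: curved, open, with a
small target patch like the motor hand knob.

Optodes are placed greedily on scalp vertices near the ROI centroid
projection: sources first (≥ 15 mm optode spacing), then detectors chosen
to keep every source in at least two channels, preferring positions close
to the ROI. Channels are every source–detector pair with separation in
the 2.5–3.5 cm band, ordered lexicographically. This replaces a
mixed-integer optimal-montage solver; the separation and pair-density
constraints are enforced as hard invariants, the optimality is only
greedy.

Channel sensitivity at cortical vertex v is

    A[c, v] = gain(λ) · exp(−(d_s + d_d) / decay_scale)

with d_s, d_d the distances from v to the channel's source and detector
scalp positions and decay_scale = 12 mm by default. This reproduces the
qualitative structure of photon-transport sensitivities — localized,
banana-shaped, heavily overlapping, ill-conditioned — but not their
absolute magnitudes or depth profile; the two wavelengths share geometry
and differ by a gain factor (1 : 1.15). The field of view (FOV) is the
set of vertices whose best channel sensitivity reaches 10% of the global
maximum. Units: A in cm so that ΔOD (dimensionless, base e) = A · Δμa
(cm⁻¹); all mesh coordinates in mm, separations converted to cm only for
constraint checks.

## Hemodynamic response models

The HRF is a difference of two gamma-shaped lobes (main peak minus
scaled undershoot) parameterized by time-to-peak and full width at half
maximum of each lobe plus the undershoot ratio γ. The shape exponent and
scale follow the closed forms a = 8 ln2 · TTP²/FWHM², b = FWHM²/(8 ln2 ·
TTP). Four stock models:

| model | TTP1 | FWHM1 | TTP2 | FWHM2 | γ   |
|-------|------|-------|------|-------|-----|
| 1 canonical        | 6 | 5.2 | 15 | 9 | 0.1 |
| 2 short duration   | 5 | 1   | 6  | 2 | 0.1 |
| 3 long duration    | 5 | 10  | –  | – | 0   |
| 4 large undershoot | 5 | 5.2 | 15 | 9 | 0.5 |

HbO curves are scaled to a +3 μmol/L peak. HbR uses the same shape
parameters with both peak latencies delayed by 2 s, the whole
difference-of-gammas curve negated, scaled so its extremum is −1 μmol/L;
scaling is applied after the undershoot subtraction, so the undershoot
becomes a positive rebound. The closed-form TTP/FWHM parameterization is
a Gaussian-width approximation of the gamma lobe; its measured FWHM
deviates by up to ~3% when FWHM ≈ 2·TTP (model 3) and under 2%
otherwise.

## Simulated datasets

A run is 10 min at 5 Hz (N = 3000) with a rapid event-related paradigm:
30 trials of 200 ms, inter-trial intervals drawn uniformly in 2–60 s and
rescaled to fit the run after a 60 s initial rest block. The rest block
is a deliberate design choice so the channel noise covariance can be
estimated from a signal-free window, mirroring acquisitions that begin
at rest.

Every ROI vertex carries the same HbO/HbR time course (stimulus train
convolved with the model HRF, zero boundary conditions); other vertices
are silent. Concentrations are converted to absorption with base-e molar
extinction coefficients at 685/830 nm taken from the standard tabulated
hemoglobin compilation (stored base-10, multiplied by ln 10; the 685 nm
entries are interpolated from neighbouring table rows). Forward
projection gives the noise-free ΔOD.

Synthetic resting-state noise stands in for real resting runs: per
channel an AR(1) baseline (ρ = 0.8), sinusoids at cardiac 1.1 Hz,
respiratory 0.25 Hz and Mayer-wave 0.1 Hz with per-channel random
phases, white noise, and a shared "superficial" record added to all
channels (and both wavelengths) with random weights to induce spatial
correlation. One global factor τ scales the noise so that

    SNR = 10 log₁₀( ⟨ΔOD_signal⟩ / (τ² ⟨ΔOD_rest⟩) )

on the 830 nm channel with maximal summed ROI sensitivity, ⟨·⟩ the mean
sum of squares; the same τ applies to all channels and wavelengths, so
relative amplitudes are preserved. What this generator does **not**
emulate: motion artifacts, 1/f instrumental drift beyond AR(1),
heteroscedastic channel gains, nonstationary physiology, and real
spatial covariance structure from superficial layers. Passing tests
therefore demonstrate correctness and calibration under this stated
noise family, not performance on arbitrary real recordings.

## ReML inverse

The two-wavelength hierarchy is block-diagonal, so each wavelength is
solved independently with its own (h₁, h₂); whether hyperparameters
should be shared across wavelengths is genuinely open, and independence
is the simpler choice. C₁ is the sample covariance of the initial rest
window shrunk 5% toward its diagonal; C₂ is the identity (L2 minimum
norm). Hyperparameters are estimated once per run from S = Y Yᵀ/T and a
single linear operator is applied to every sample.

The free energy F(h) = −T/2·(log|Σ| + tr(Σ⁻¹S)), Σ = h₁C₁ + h₂AAᵀ, is
maximized by Newton/Fisher scoring on log h with step halving, which
makes the recorded free-energy trace monotone by construction.
Numerical details that matter:

* Steps are clipped to ±4 in log units; the Fisher system is ridged at
  1e−8 of its largest entry.
* Variance components can legitimately collapse to the h → 0 boundary
  (e.g. negligible sensor noise at very high SNR). When the likelihood
  keeps pushing a nearly extinguished component down, a direct jump to
  the boundary is offered; conversely a collapsed component whose
  gradient turns positive is offered a jump back to its initialization
  scale. Both moves are accepted only if the free energy strictly
  increases, preserving monotonicity.
* Convergence requires a relative free-energy change < 1e−6 and
  per-component stationarity (scale-invariant gradient < 1e−6, or a
  boundary-collapsed component still being pushed down); the budget is
  128 iterations, after which the result is returned with a warning and
  `converged=False`.
* Initialization h_i = tr(S)/tr(Q_i).

The minimum-norm prior biases amplitudes: overestimation at sensitivity
peaks, underestimation away from them. No depth weighting or amplitude
correction is applied; validation metrics are therefore shape-based
(normalized curves) rather than amplitude-based.

## FIR + AR(1) deconvolution

The design has K FIR columns (shifted copies of the binary stimulus
vector over a [−5, +30] s peri-stimulus window; K = 176 at 5 Hz) and M
orthonormal discrete-cosine drifts with frequencies strictly below
0.01 Hz (M = 12 for a 600 s run, counting the constant term). The
pre-stimulus samples let the fit capture anticipatory fluctuations; the
exact window is a package default since only the −5 s bound is implied
by common practice.

Estimation is deliberately the literal two-pass procedure: OLS assuming
white noise, Yule–Walker lag-1 coefficient from the OLS residuals
(clipped to ±0.99), then exact GLS by the analytic AR(1) whitening
transform (first sample scaled by √(1−ρ²), then y[n] − ρy[n−1]) — O(N)
and mathematically identical to dense Ω⁻¹ weighting. ρ is not iterated
further, and one ρ is estimated per vertex and chromophore. σ̂² uses the
maximum-likelihood 1/N normalization; the (N−L)/N factor in the partial
F statistic restores the unbiased scale, and F is referred to F(K, N−L).

Per-vertex mapping over the FOV uses a batched implementation: the OLS
pass is one shared pseudoinverse, and each vertex's whitened normal
equations are assembled from precomputed Gram pieces (a quadratic
polynomial in ρ), with the HRF-block quadratic form obtained through the
Schur complement of the small drift block. This path agrees with the
single-series implementation to machine precision and is unit-tested at
1e−10. F-maps are Bonferroni-thresholded at α/|FOV|; an empty
significant set is a valid outcome at low SNR. Effect-size maps are read
at the FIR sample nearest the canonical first-peak latency (6 s HbO,
8 s HbR) regardless of the simulated model, matching common reporting
practice.

## Validation metrics

Accuracy is evaluated at the peak vertex: maximal |β̂| at the first-peak
sample among significant vertices, falling back to the whole FOV (with a
`not_significant` flag) when nothing passes threshold, so that low-SNR
behaviour can still be reported for comparison. The shape error is the
MSE between the estimated and true curves after each is divided by its
own extremum magnitude with sign preserved (HbO maps to +1, HbR to −1,
treating the chromophores symmetrically). MSE uses the full FIR window
including the pre-stimulus segment.

Timing parameters are recovered by bounded nonlinear least squares on
the normalized curve, initialized at the true parameters, with TTP/FWHM
in (0.1 s, window] and γ in [0, 2]; the model curve is renormalized at
every evaluation so amplitude is not a parameter. The undershoot latency
is parameterized as TTP2 = TTP1 + dTTP with dTTP ≥ 0.5 s: the
unconstrained five-parameter fit admits a degenerate optimum in which
two coincident lobes nearly cancel (γ → 1) while mimicking the curve
shape, and the offset — which encodes the physiological ordering true of
all four stock models — removes it. For the single-lobe model 3 only
TTP1 and FWHM1 are free and no undershoot metrics are reported.
Replicates (fresh seeded anatomy, paradigm and noise) play the role of
subject-specific head models.

## Benchmark problem sizes

The packaged benchmarks (`nirsdot.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use 1000 null series
for the false-positive-rate experiment; 10 replicates for the canonical
model at 0 dB; and 5 replicates per cell for the long-duration model at
−8/−4/0 dB and the short-duration and large-undershoot models at 0 dB.
These sizes keep a full benchmark run under a minute on one CPU while
leaving the replicate means' sampling error small relative to the
bounds they are compared against; TTP2 for the short-duration model is
the most variable quantity (its undershoot amplitude is small), and
occasional noisy replicates can move that cell mean noticeably.

## Known limitations

* The sensitivity model is parametric, not photon-transport-based;
  absolute reconstruction amplitudes are not physically calibrated.
* Only AR(1) serial correlation is modelled; higher-order or
  oscillatory noise inside the stimulus band would miscalibrate the
  F-test (the null experiment keeps its sinusoids below the drift
  cutoff for exactly this reason).
* Multi-condition paradigms are supported structurally (stacked FIR
  blocks) but only single-condition behaviour is validated.
* The greedy montage is not optimal; it only satisfies the hard
  constraints.
* Block designs, motion artifacts and their correction, wavelet
  whitening, FDR/random-field corrections and depth-weighted or smooth
  source priors are out of scope.
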