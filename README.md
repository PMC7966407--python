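# nirsdot

Surface-based diffuse optical tomography (DOT) and hemodynamic-response
deconvolution for functional near-infrared spectroscopy (fNIRS).

Continuous-wave fNIRS measures base-e optical-density changes ΔOD on
scalp source–detector channels at two wavelengths (685 and 830 nm).
`nirsdot` reconstructs the underlying cortical absorption changes Δμa and
hemoglobin concentration changes Δ[HbO], Δ[HbR], then estimates the
hemodynamic response function (HRF) at every cortical vertex without
assuming its shape — the setting of personalized optimal-montage fNIRS,
where a small montage (e.g. 4 sources, 8 detectors) targets one cortical
region such as the motor hand knob. It is aimed at methods researchers
who need a controlled, fully synthetic test bed for DOT + deconvolution
pipelines with known ground truth.

## Model

**Forward model.** Per wavelength λ, ΔOD^λ = A^λ Δμa^λ, with A^λ the
channels × vertices sensitivity matrix (units cm, so Δμa in cm⁻¹ gives
dimensionless OD). Vertices whose best channel sensitivity exceeds 10% of
the global maximum form the montage field of view (FOV). The packaged
sensitivity generator is a parametric exponential-product stand-in for
photon-transport modelling.

**Inverse.** A two-level Gaussian hierarchy per wavelength,

    ΔOD = A μ + E₁,  E₁ ~ N(0, h₁C₁)       (sensor noise)
    μ   = E₂,        E₂ ~ N(0, h₂I)        (minimum-norm prior)

with C₁ the channel covariance estimated from the initial rest period.
The hyperparameters (h₁, h₂) maximize the restricted likelihood (free
energy) of the temporal second-moment matrix by Fisher-scored Newton
iterations on log-hyperparameters; the posterior-mean operator
h₂AᵀΣ⁻¹ (Σ = h₁C₁ + h₂AAᵀ) is then applied to all samples. Hemoglobin
follows by a per-vertex 2×2 extinction-coefficient solve.

**Deconvolution.** Each vertex time series y is fit with a finite impulse
response (FIR) basis — one free coefficient per peri-stimulus sample over
a [−5, +30] s window — plus orthonormal discrete-cosine drift regressors
below 0.01 Hz:

    y = Xβ + e,   e ~ N(0, σ²Ω),   Ω_ij = ρ^|i−j|  (AR(1))

Estimation is the two-pass AR(1)-MLE: OLS, Yule–Walker ρ̂ from the
residuals, then exact generalized least squares via the analytic AR(1)
whitening filter. The K HRF coefficients are tested jointly with the
partial F statistic

    F = (N−L)/N · (β̂ₕᵀ Θₕ⁻¹ β̂ₕ) / (K σ̂²)  ~  F(K, N−L)

and cortical F-maps are thresholded at α = 0.05 with Bonferroni
correction over the FOV size.

**Simulation.** Ground-truth HRFs are differences of two gamma functions
parameterized by time-to-peak and width (TTP1, FWHM1, TTP2, FWHM2, γ);
four stock models cover canonical, short, long-duration and
large-undershoot responses. HbO peaks at +3 μmol/L, HbR at −1 μmol/L with
a 2 s latency lag. Simulated runs add synthetic resting-state noise
(AR(1) + cardiac/respiratory/Mayer oscillations + a shared superficial
component) scaled by a single factor τ to a target SNR defined on the
most ROI-sensitive 830 nm channel.

## Worked example

```python
import nirsdot as nd
from nirsdot.metrics import evaluate_map

surface  = nd.generate_toy_anatomy(seed=1)
montage  = nd.generate_montage(surface, 4, 8, seed=1)
sens     = nd.compute_synthetic_sensitivity(surface, montage)
paradigm = nd.generate_paradigm(seed=1)           # 30 x 200 ms, ITI 2-60 s
ds = nd.simulate_dataset(surface, montage, sens, model_id=1,
                         paradigm=paradigm, target_snr_db=0.0, seed=1)

c1  = nd.estimate_channel_covariance(ds.od_sim, (0.0, float(paradigm.onsets_s[0])))
rec = nd.reml_reconstruct(ds.od_sim, sens, c1)
hbo, hbr = nd.absorption_to_hemoglobin(rec.dmua)
dmap = nd.map_deconvolution({"HbO": hbo, "HbR": hbr}, paradigm, sens.fov_vertices)
m = evaluate_map(dmap, 1, "HbO")
```

which prints, with the intermediate quantities shown:

```
channels: 15, FOV vertices: 94, tau: 2.373e-04
ReML hyperparameters (830 nm): h1=1.107e+00, h2=3.743e-06
F threshold (Bonferroni over 94 vertices): 1.40
significant vertices: HbO 51, HbR 35
peak vertex: 4, shape MSE: 0.0029
recovered TTP1: 5.80 s (truth 6.0), FWHM1: 4.74 s (truth 5.2)
```

Read: at 0 dB SNR the evoked response is detected over roughly half the
FOV; the nonparametric HRF at the peak vertex matches the simulated
canonical shape to a normalized MSE of 0.003, and the difference-of-gammas
refit recovers the first-peak latency within 0.2 s.

A CLI mirrors the library: `nirsdot pipeline --seed 1 --out artifacts/`
runs simulate → reconstruct → deconvolve → evaluate and writes CSV/JSON
artifacts; `nirsdot deconvolve --input series.csv --paradigm events.csv
--window -5 30 --alpha 0.05 --out out/` deconvolves an existing
vertices × samples matrix. Channel data can be exported to a minimal
SNIRF (HDF5) file with `nirsdot.export_snirf`.

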