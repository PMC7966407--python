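"""Event paradigms, hemoglobin/absorption spectroscopy and SNR-controlled
simulated two-wavelength optical-density datasets.

A simulated run is assembled as

    OD_sim = OD_noise_free + tau * OD_rest

where the noise-free part is the forward projection of a homogeneous
ROI hemodynamic response (stimulus train convolved with an HbO/HbR HRF,
converted to absorption via extinction coefficients) and OD_rest is a
synthetic resting-state record with serial correlation, physiological
oscillations and a shared superficial component.  A single global factor
tau sets the signal-to-noise ratio, defined on the 830 nm channel most
sensitive to the ROI as

    SNR = 10 log10( <OD_roi> / (tau^2 <OD_rest>) )

with <.> the mean sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import CorticalSurface, Montage, SensitivityModel, forward_project
from .hrf import HRFCurve, make_hemoglobin_hrfs
from .timeseries import ODTimeSeries

__all__ = [
    "Paradigm",
    "ExtinctionTable",
    "DEFAULT_EXTINCTION",
    "NoiseConfig",
    "SimulatedDataset",
    "generate_paradigm",
    "hemoglobin_to_absorption",
    "generate_resting_noise",
    "scale_noise_to_snr",
    "compute_snr_db",
    "simulate_dataset",
]


@dataclass
class Paradigm:
    """Event timing plus its binary stimulus vector at the sampling rate."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    run_length_s: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, float)
        self.durations_s = np.asarray(self.durations_s, float)
        if np.any(self.onsets_s + self.durations_s > self.run_length_s + 1e-9):
            raise ValueError("an event extends past the end of the run")
        if np.any(np.diff(self.onsets_s) < 0):
            raise ValueError("onsets must be sorted")

    @property
    def n_samples(self) -> int:
        return int(round(self.run_length_s * self.sampling_rate))

    @property
    def n_trials(self) -> int:
        return len(self.onsets_s)

    @property
    def stimulus_vector(self) -> np.ndarray:
        """Binary vector s[n]; each event occupies round(duration*fs)
        samples (at least one) starting at its onset sample."""
        s = np.zeros(self.n_samples)
        fs = self.sampling_rate
        for on, dur in zip(self.onsets_s, self.durations_s):
            i0 = int(round(on * fs))
            n = max(1, int(round(dur * fs)))
            s[i0 : min(i0 + n, self.n_samples)] = 1.0
        return s

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"onset_s": self.onsets_s, "duration_s": self.durations_s}
        ).to_csv(path, index=False)


def generate_paradigm(
    n_trials: int = 30,
    trial_duration_s: float = 0.2,
    iti_range_s: tuple[float, float] = (2.0, 60.0),
    run_length_s: float = 600.0,
    fs: float = 5.0,
    seed: int = 0,
    initial_rest_s: float = 60.0,
) -> Paradigm:
    """Rapid event-related paradigm with uniformly drawn inter-trial
    intervals, rescaled to fit the run after an initial rest block.

    The initial rest (default 60 s) keeps a clean window for estimating
    the channel noise covariance, mirroring acquisitions that start at
    rest.  Infeasible when even minimum ITIs cannot pack into the run.
    """
    lo, hi = iti_range_s
    if not (0 < lo <= hi):
        raise ValueError("invalid ITI range")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    min_needed = initial_rest_s + n_trials * (lo + trial_duration_s)
    if min_needed > run_length_s:
        raise ValueError(
            f"infeasible paradigm: minimum packing needs {min_needed:.0f} s "
            f"but the run is {run_length_s:.0f} s"
        )
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(lo, hi, n_trials)
    available = run_length_s - initial_rest_s - n_trials * trial_duration_s
    if gaps.sum() > available:
        gaps = gaps * (available / gaps.sum())
    onsets = initial_rest_s + np.cumsum(gaps) + trial_duration_s * np.arange(n_trials)
    durations = np.full(n_trials, trial_duration_s)
    return Paradigm(onsets, durations, run_length_s, fs)


@dataclass(frozen=True)
class ExtinctionTable:
    """Base-e molar absorption coefficients, cm^-1 M^-1, per wavelength.

    Stored as wavelength -> (alpha_HbO, alpha_HbR).  Values derive from the
    standard tabulated compilation of hemoglobin spectra (base-10 molar
    extinction), converted to base e by multiplying by ln 10.
    """

    coefficients: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFS)
    )

    def __post_init__(self) -> None:
        m = self.matrix()
        if np.linalg.cond(m) >= 100:
            raise ValueError("extinction matrix too ill-conditioned to invert")

    def alpha(self, wavelength: float) -> tuple[float, float]:
        if wavelength not in self.coefficients:
            raise KeyError(f"no extinction coefficients for {wavelength} nm")
        return self.coefficients[wavelength]

    def matrix(self) -> np.ndarray:
        """2x2 matrix [[aHbR_l1, aHbO_l1], [aHbR_l2, aHbO_l2]] with rows in
        ascending wavelength order (the spectroscopic unmixing matrix)."""
        rows = []
        for lam in sorted(self.coefficients):
            hbo, hbr = self.coefficients[lam]
            rows.append([hbr, hbo])
        return np.asarray(rows)

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.coefficients))


_LN10 = np.log(10.0)
# base-10 molar extinction (cm^-1 M^-1): 830 nm from the standard table,
# 685 nm interpolated from its neighbouring entries.
_DEFAULT_COEFFS = {
    685.0: (287.6 * _LN10, 2170.2 * _LN10),  # (HbO, HbR)
    830.0: (974.0 * _LN10, 693.04 * _LN10),
}

DEFAULT_EXTINCTION = ExtinctionTable()


def hemoglobin_to_absorption(
    dhbo_um, dhbr_um, table: ExtinctionTable = DEFAULT_EXTINCTION
) -> dict[float, np.ndarray]:
    """Absorption change (1/cm) per wavelength from concentration changes
    in umol/L: mu_a = alpha_HbO * [HbO] + alpha_HbR * [HbR] (molar)."""
    dhbo = np.asarray(dhbo_um, float) * 1e-6
    dhbr = np.asarray(dhbr_um, float) * 1e-6
    if dhbo.shape != dhbr.shape:
        raise ValueError("HbO and HbR series must have equal shapes")
    out = {}
    for lam in table.wavelengths:
        a_hbo, a_hbr = table.alpha(lam)
        out[lam] = a_hbo * dhbo + a_hbr * dhbr
    return out


@dataclass(frozen=True)
class NoiseConfig:
    """Resting-state noise model: AR(1) baseline + cardiac/respiratory/
    Mayer-wave oscillations + white noise + a shared superficial component.

    Amplitudes are in arbitrary OD units; the SNR scaling factor tau makes
    the absolute scale irrelevant.
    """

    ar_rho: float = 0.8
    ar_sigma: float = 1.0  # innovation SD of the AR baseline
    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.6
    respiratory_amp: float = 0.8
    mayer_amp: float = 1.0
    white_sigma: float = 0.3
    shared_weight_sigma: float = 0.5


def _ar1(rng: np.random.Generator, rho: float, sigma: float, n: int) -> np.ndarray:
    from scipy.signal import lfilter

    e = rng.normal(0.0, sigma, n)
    e[0] /= np.sqrt(1.0 - rho**2)  # stationary start
    return lfilter([1.0], [1.0, -rho], e)


def generate_resting_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    config: NoiseConfig | None = None,
    seed: int = 0,
    wavelengths: tuple[float, ...] = (685.0, 830.0),
    channel_ids: list[tuple[int, int]] | None = None,
) -> ODTimeSeries:
    """Seed-reproducible stationary surrogate for resting-state OD data."""
    if n_samples < 2 or fs <= 0:
        raise ValueError("need n_samples >= 2 and fs > 0")
    cfg = config or NoiseConfig()
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    freqs = (cfg.cardiac_hz, cfg.respiratory_hz, cfg.mayer_hz)
    amps = (cfg.cardiac_amp, cfg.respiratory_amp, cfg.mayer_amp)

    # one superficial record shared by every channel (and both wavelengths)
    shared = _ar1(rng, cfg.ar_rho, cfg.ar_sigma, n_samples)
    for f, a in zip(freqs, amps):
        shared += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    out: dict[float, np.ndarray] = {}
    for lam in wavelengths:
        block = np.empty((n_channels, n_samples))
        for c in range(n_channels):
            x = _ar1(rng, cfg.ar_rho, cfg.ar_sigma, n_samples)
            for f, a in zip(freqs, amps):
                x += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x += rng.normal(0.0, cfg.white_sigma, n_samples)
            x += rng.normal(0.0, cfg.shared_weight_sigma) * shared
            block[c] = x
        out[lam] = block
    return ODTimeSeries(out, fs, channel_ids or [])


def compute_snr_db(
    noise_free: ODTimeSeries, scaled_noise: ODTimeSeries, channel: int,
    wavelength: float = 830.0,
) -> float:
    """SNR (dB) of a channel: evoked power over (already scaled) noise power."""
    p_sig = float(np.mean(noise_free.values[wavelength][channel] ** 2))
    p_noise = float(np.mean(scaled_noise.values[wavelength][channel] ** 2))
    return 10.0 * np.log10(p_sig / p_noise)


def scale_noise_to_snr(
    noise_free: ODTimeSeries,
    noise: ODTimeSeries,
    target_snr_db: float,
    sens: SensitivityModel,
    roi: np.ndarray,
    wavelength: float = 830.0,
) -> tuple[float, ODTimeSeries, int]:
    """Single global noise scaling achieving the target SNR on the 830 nm
    channel with maximal summed ROI sensitivity.  Returns (tau, OD_sim,
    best_channel)."""
    roi = np.asarray(roi, int)
    if roi.size == 0:
        raise ValueError("ROI is empty")
    best = int(np.argmax(sens.roi_sensitivity(wavelength, roi)))
    p_sig = float(np.mean(noise_free.values[wavelength][best] ** 2))
    p_noise = float(np.mean(noise.values[wavelength][best] ** 2))
    if p_noise == 0:
        raise ValueError("noise record has zero power on the best channel")
    tau = float(np.sqrt(p_sig / (p_noise * 10.0 ** (target_snr_db / 10.0))))
    od_sim = ODTimeSeries(
        {
            lam: noise_free.values[lam] + tau * noise.values[lam]
            for lam in noise_free.values
        },
        noise_free.sampling_rate,
        list(noise_free.channel_ids),
    )
    return tau, od_sim, best


@dataclass
class SimulatedDataset:
    od_sim: ODTimeSeries
    od_noise_free: ODTimeSeries
    od_rest: ODTimeSeries  # unscaled noise record
    ground_truth_hbo: HRFCurve
    ground_truth_hbr: HRFCurve
    roi_vertices: np.ndarray
    paradigm: Paradigm
    tau: float
    target_snr_db: float
    best_channel: int
    model_id: int
    seed: int


def simulate_dataset(
    surface: CorticalSurface,
    montage: Montage,
    sens: SensitivityModel,
    model_id: int,
    paradigm: Paradigm,
    target_snr_db: float,
    seed: int = 0,
    noise_config: NoiseConfig | None = None,
    extinction: ExtinctionTable = DEFAULT_EXTINCTION,
) -> SimulatedDataset:
    """Full simulated two-wavelength run for one HRF model and SNR level.

    Every ROI vertex carries the same HbO/HbR time course (stimulus train
    convolved with the model HRF); vertices outside the ROI are silent.
    """
    roi = np.asarray(surface.roi_vertices, int)
    if roi.size == 0:
        raise ValueError("surface has an empty ROI")
    fs = paradigm.sampling_rate
    n = paradigm.n_samples
    hbo, hbr = make_hemoglobin_hrfs(model_id, fs=fs)
    s = paradigm.stimulus_vector
    dhbo = np.convolve(s, hbo.values)[:n]
    dhbr = np.convolve(s, hbr.values)[:n]

    dmua_roi = hemoglobin_to_absorption(dhbo, dhbr, extinction)
    V = surface.n_vertices
    dmua = {}
    for lam, series in dmua_roi.items():
        block = np.zeros((V, n))
        block[roi] = series
        dmua[lam] = block
    noise_free = forward_project(sens, dmua, sampling_rate=fs)

    noise = generate_resting_noise(
        noise_free.n_channels, n, fs, noise_config, seed=seed,
        wavelengths=tuple(noise_free.values), channel_ids=list(noise_free.channel_ids),
    )
    tau, od_sim, best = scale_noise_to_snr(
        noise_free, noise, target_snr_db, sens, roi
    )
    return SimulatedDataset(
        od_sim=od_sim,
        od_noise_free=noise_free,
        od_rest=noise,
        ground_truth_hbo=hbo,
        ground_truth_hbr=hbr,
        roi_vertices=roi,
        paradigm=paradigm,
        tau=tau,
        target_snr_db=target_snr_db,
        best_channel=best,
        model_id=model_id,
        seed=seed,
    )
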