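"""Difference-of-two-gammas hemodynamic response functions.

The HRF is modelled as a main gamma-shaped lobe minus a scaled second gamma
for the post-stimulus undershoot:

    HRF(t) = (t/TTP1)^a1 * exp(-(t-TTP1)/b1) - gamma * (t/TTP2)^a2 * exp(-(t-TTP2)/b2)

Each lobe is parameterized directly by its time-to-peak (TTP, s) and full
width at half maximum (FWHM, s); the shape exponent and scale follow from

    a_i = 8 ln2 * TTPi^2 / FWHMi^2,     b_i = FWHMi^2 / (8 ln2 * TTPi).

Four stock parameter sets are provided (canonical, short-duration,
long-duration without undershoot, large-undershoot).  HbO curves are scaled
to a +3 umol/L peak; HbR curves use the same shape with both peak latencies
delayed by 2 s, sign-inverted, and scaled to a -1 umol/L trough.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GammaHRFParams",
    "HRFCurve",
    "HRF_MODELS",
    "gamma_shape_params",
    "evaluate_hrf",
    "make_hemoglobin_hrfs",
]

_8LN2 = 8.0 * np.log(2.0)

#: Peak amplitude conventions, umol/L.
HBO_PEAK_UM = 3.0
HBR_PEAK_UM = -1.0
#: HbR peak latencies lag HbO by this many seconds.
HBR_DELAY_S = 2.0


def gamma_shape_params(ttp: float, fwhm: float) -> tuple[float, float]:
    """Closed-form gamma shape/scale for a lobe with given TTP and FWHM.

    Returns ``(a, b)`` with ``a`` unitless and ``b`` in seconds.
    """
    if ttp <= 0 or fwhm <= 0:
        raise ValueError(f"TTP and FWHM must be positive, got {ttp}, {fwhm}")
    a = _8LN2 * ttp**2 / fwhm**2
    b = fwhm**2 / (_8LN2 * ttp)
    return a, b


@dataclass(frozen=True)
class GammaHRFParams:
    """Five shape parameters of the difference-of-gammas HRF.

    ``ttp2``/``fwhm2`` may be ``None`` when ``gamma_ratio`` is 0 (no
    undershoot lobe).
    """

    ttp1: float
    fwhm1: float
    ttp2: float | None
    fwhm2: float | None
    gamma_ratio: float

    def __post_init__(self) -> None:
        if self.ttp1 <= 0 or self.fwhm1 <= 0:
            raise ValueError("ttp1 and fwhm1 must be positive")
        if self.gamma_ratio < 0:
            raise ValueError("gamma_ratio must be >= 0")
        if self.gamma_ratio > 0 and (self.ttp2 is None or self.fwhm2 is None):
            raise ValueError("undershoot lobe requires ttp2 and fwhm2")

    @property
    def a1(self) -> float:
        return gamma_shape_params(self.ttp1, self.fwhm1)[0]

    @property
    def b1(self) -> float:
        return gamma_shape_params(self.ttp1, self.fwhm1)[1]

    @property
    def a2(self) -> float | None:
        if self.ttp2 is None or self.fwhm2 is None:
            return None
        return gamma_shape_params(self.ttp2, self.fwhm2)[0]

    @property
    def b2(self) -> float | None:
        if self.ttp2 is None or self.fwhm2 is None:
            return None
        return gamma_shape_params(self.ttp2, self.fwhm2)[1]

    def delayed(self, delay_s: float) -> "GammaHRFParams":
        """Copy with both peak latencies shifted by ``delay_s`` seconds."""
        return replace(
            self,
            ttp1=self.ttp1 + delay_s,
            ttp2=None if self.ttp2 is None else self.ttp2 + delay_s,
        )


#: Stock HbO parameter sets: canonical, short duration, long duration
#: (single lobe), large undershoot.
HRF_MODELS: dict[int, GammaHRFParams] = {
    1: GammaHRFParams(ttp1=6.0, fwhm1=5.2, ttp2=15.0, fwhm2=9.0, gamma_ratio=0.1),
    2: GammaHRFParams(ttp1=5.0, fwhm1=1.0, ttp2=6.0, fwhm2=2.0, gamma_ratio=0.1),
    3: GammaHRFParams(ttp1=5.0, fwhm1=10.0, ttp2=None, fwhm2=None, gamma_ratio=0.0),
    4: GammaHRFParams(ttp1=5.0, fwhm1=5.2, ttp2=15.0, fwhm2=9.0, gamma_ratio=0.5),
}

HRF_MODEL_NAMES = {
    1: "canonical",
    2: "short duration",
    3: "long duration",
    4: "large undershoot",
}


def evaluate_hrf(params: GammaHRFParams, time_grid) -> np.ndarray:
    """Evaluate the unscaled difference-of-gammas HRF on ``time_grid`` (s).

    The curve is 0 for t <= 0.  With ``gamma_ratio == 0`` the single lobe
    peaks at exactly 1.0 at t = TTP1.
    """
    t = np.asarray(time_grid, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def lobe(ttp, a, b):
        # log-space evaluation avoids 0 * inf for extreme shape exponents
        return np.exp(a * np.log(tp / ttp) - (tp - ttp) / b)

    out[pos] = lobe(params.ttp1, params.a1, params.b1)
    if params.gamma_ratio > 0:
        out[pos] -= params.gamma_ratio * lobe(params.ttp2, params.a2, params.b2)
    return out


@dataclass(frozen=True)
class HRFCurve:
    """A sampled HRF in concentration units (umol/L)."""

    time_s: np.ndarray
    values: np.ndarray
    chromophore: str  # "HbO" | "HbR"
    model_id: int
    params: GammaHRFParams

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("time grid must be a 1-D array of >= 2 samples")
        dt = np.diff(t)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("time grid must be strictly increasing and uniform")
        if len(self.values) != len(t):
            raise ValueError("time grid and values length mismatch")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


def make_hemoglobin_hrfs(
    model_id: int, fs: float = 5.0, window_s: float = 40.0
) -> tuple[HRFCurve, HRFCurve]:
    """Scaled (HbO, HbR) curves for one of the four stock HRF models.

    HbO: stock parameters, positive peak normalized to +3 umol/L.
    HbR: same parameters with TTP1/TTP2 delayed by 2 s, complete curve
    negated and scaled so its extremum is -1 umol/L (the undershoot thus
    becomes a positive rebound).
    """
    if model_id not in HRF_MODELS:
        raise ValueError(f"unknown HRF model id {model_id}; choose from 1-4")
    p_hbo = HRF_MODELS[model_id]
    p_hbr = p_hbo.delayed(HBR_DELAY_S)
    t = np.arange(0.0, window_s, 1.0 / fs)

    raw_o = evaluate_hrf(p_hbo, t)
    raw_r = -evaluate_hrf(p_hbr, t)
    v_hbo = raw_o * (HBO_PEAK_UM / np.max(np.abs(raw_o)))
    v_hbr = raw_r * (abs(HBR_PEAK_UM) / np.max(np.abs(raw_r)))

    hbo = HRFCurve(t, v_hbo, "HbO", model_id, p_hbo)
    hbr = HRFCurve(t, v_hbr, "HbR", model_id, p_hbr)
    return hbo, hbr
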