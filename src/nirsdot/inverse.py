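"""Hierarchical ReML reconstruction of cortical absorption changes.

Per wavelength the measurements follow a two-level Gaussian model

    OD = A mu + E1,   E1 ~ N(0, h1 C1)        (sensor level)
    mu = 0 + E2,      E2 ~ N(0, h2 C2),  C2 = I (minimum-norm prior)

so the marginal covariance of one OD sample is Sigma = h1 C1 + h2 A A^T.
The two hyperparameters are estimated by maximizing the restricted
log-likelihood (free energy) of the temporal second-moment matrix

    F(h1, h2) = -T/2 [ log|Sigma| + tr(Sigma^-1 S) ] + const,
    S = OD OD^T / T,

with Newton/Fisher scoring on log-hyperparameters and step halving, which
keeps the free-energy trace monotone.  At convergence the posterior-mean
inverse operator h2 A^T Sigma^-1 is applied to every time sample.  The two
wavelengths are block-diagonal in the fusion model and therefore solved
independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anatomy import SensitivityModel
from .simulate import DEFAULT_EXTINCTION, ExtinctionTable
from .timeseries import ODTimeSeries, SurfaceTimeSeries

__all__ = [
    "NoiseCovariance",
    "ReMLResult",
    "estimate_channel_covariance",
    "reml_reconstruct",
    "absorption_to_hemoglobin",
]


@dataclass
class NoiseCovariance:
    """Channel-space noise covariance per wavelength (symmetric PSD)."""

    C1: dict[float, np.ndarray]
    window_s: tuple[float, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        for lam, c in self.C1.items():
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"covariance at {lam} nm is not symmetric")
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-8 * max(1.0, abs(w.max())):
                raise ValueError(f"covariance at {lam} nm is not PSD")


def estimate_channel_covariance(
    od_rest: ODTimeSeries,
    window_s: tuple[float, float] = (0.0, 60.0),
    shrinkage: float = 0.05,
) -> NoiseCovariance:
    """Sample covariance over a rest window, shrunk toward its diagonal.

    Shrinkage ``s`` replaces C with ``(1-s) C + s diag(C)``, which keeps the
    estimate positive semi-definite and well conditioned for short windows.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    fs = od_rest.sampling_rate
    i0, i1 = int(round(window_s[0] * fs)), int(round(window_s[1] * fs))
    i1 = min(i1, od_rest.n_samples)
    n = i1 - i0
    if n < 2 * od_rest.n_channels:
        raise ValueError(
            f"rest window has {n} samples; need at least twice the channel "
            f"count ({2 * od_rest.n_channels})"
        )
    out, degenerate = {}, False
    for lam, block in od_rest.values.items():
        x = block[:, i0:i1]
        x = x - x.mean(axis=1, keepdims=True)
        c = x @ x.T / (n - 1)
        c = (1.0 - shrinkage) * c + shrinkage * np.diag(np.diag(c))
        if np.allclose(c, 0.0):
            degenerate = True
        out[lam] = c
    return NoiseCovariance(out, window_s, degenerate=degenerate)


@dataclass
class ReMLResult:
    dmua: dict[float, SurfaceTimeSeries]
    hyperparameters: dict[float, tuple[float, float]]
    free_energy_trace: dict[float, list[float]]
    iterations: dict[float, int]
    converged: bool


def _free_energy_terms(sigma: np.ndarray, S: np.ndarray, T: int):
    """Free energy (up to a constant) plus the solve factor of Sigma."""
    cho = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    sig_inv = np.linalg.inv(sigma)
    f = -0.5 * T * (logdet + np.trace(sig_inv @ S))
    return f, sig_inv


def _reml_single(
    Y: np.ndarray,
    A: np.ndarray,
    C1: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 128,
    fixed: tuple[float, float] | None = None,
):
    """ReML for one wavelength.  Returns (x, (h1,h2), trace, iters, ok)."""
    P, T = Y.shape
    S = Y @ Y.T / T
    Q1 = C1 + 1e-12 * np.trace(C1) / P * np.eye(P)  # numerical floor
    Q2 = A @ A.T

    if fixed is not None:
        h = np.array(fixed, float)
        sigma = h[0] * Q1 + h[1] * Q2
        f, sig_inv = _free_energy_terms(sigma, S, T)
        x = h[1] * A.T @ (sig_inv @ Y)
        return x, tuple(h), [f], 0, True

    h = np.array([np.trace(S) / np.trace(Q1), np.trace(S) / np.trace(Q2)])
    h = np.maximum(h, 1e-300)
    trace: list[float] = []
    converged = False
    sigma = h[0] * Q1 + h[1] * Q2
    f, sig_inv = _free_energy_terms(sigma, S, T)
    trace.append(f)
    it = 0
    for it in range(1, max_iter + 1):
        M = sig_inv @ S @ sig_inv  # Sigma^-1 S Sigma^-1
        raw = np.array(
            [np.trace((sig_inv - M) @ Q1), np.trace((sig_inv - M) @ Q2)]
        )
        grad = -0.5 * T * raw * h  # d F / d log h
        fisher = np.empty((2, 2))
        for i, Qi in enumerate((Q1, Q2)):
            for j, Qj in enumerate((Q1, Q2)):
                fisher[i, j] = (
                    0.5 * T * np.trace(sig_inv @ Qi @ sig_inv @ Qj) * h[i] * h[j]
                )
        # per-component stationarity: either the scale-invariant gradient is
        # tiny, or the component has collapsed toward the h -> 0 boundary
        # with the likelihood still pushing it down (a boundary optimum)
        denom = np.array([np.trace(sig_inv @ Q1), np.trace(sig_inv @ Q2)])
        rel_grad = np.abs(raw) / np.maximum(denom, 1e-300)
        share = np.array(
            [h[0] * np.trace(Q1), h[1] * np.trace(Q2)]
        ) / max(np.trace(sigma), 1e-300)
        stationary = (rel_grad < 1e-6) | ((share < 1e-7) & (raw > 0))

        newton = np.linalg.solve(fisher + 1e-8 * np.eye(2) * fisher.max(), grad)
        gnorm = np.linalg.norm(grad)
        directions = [np.clip(newton, -4.0, 4.0)]
        h_init = np.array([np.trace(S) / np.trace(Q1), np.trace(S) / np.trace(Q2)])
        for i in range(2):
            # a variance component the likelihood keeps pushing downward sits
            # at a boundary optimum; offer a direct jump toward h_i -> 0,
            # first when the component is already nearly extinguished
            if grad[i] < 0:
                crush = np.zeros(2)
                crush[i] = -30.0
                if share[i] < 1e-3 and raw[i] > 0:
                    directions.insert(0, crush)
                else:
                    directions.append(crush)
            elif share[i] < 1e-6 and h_init[i] > 0:
                # rescue: a collapsed component the gradient wants to grow
                # climbs back to its initialization scale in one jump
                rescue = np.zeros(2)
                rescue[i] = np.log(max(h_init[i], 1e-300)) - np.log(h[i])
                directions.insert(0, rescue)
        if gnorm > 0:
            directions.append(4.0 * grad / gnorm)
        # step halving keeps the free-energy trace monotone
        accepted = False
        for step in directions:
            for _ in range(40):
                h_new = np.maximum(h * np.exp(step), 1e-300)
                sigma_new = h_new[0] * Q1 + h_new[1] * Q2
                try:
                    f_new, sig_inv_new = _free_energy_terms(sigma_new, S, T)
                except np.linalg.LinAlgError:
                    step = step * 0.5
                    continue
                if f_new > f:  # strict: a no-op step must not mask fallbacks
                    accepted = True
                    break
                step = step * 0.5
            if accepted:
                break
        if not accepted:
            converged = bool(np.all(stationary))
            break
        rel_df = abs(f_new - f) / max(abs(f), 1e-300)
        h, sigma, f, sig_inv = h_new, sigma_new, f_new, sig_inv_new
        trace.append(f)
        if rel_df < tol and np.all(stationary):
            converged = True
            break
    x = h[1] * A.T @ (sig_inv @ Y)
    return x, (float(h[0]), float(h[1])), trace, it, converged


def reml_reconstruct(
    od: ODTimeSeries,
    sens: SensitivityModel,
    c1: NoiseCovariance,
    c2_mode: str = "identity",
    fixed_hyperparameters: dict[float, tuple[float, float]] | None = None,
    tol: float = 1e-6,
    max_iter: int = 128,
) -> ReMLResult:
    """Reconstruct absorption changes on the cortex per wavelength.

    ``fixed_hyperparameters`` bypasses estimation (used to cross-check the
    operator against the closed-form Tikhonov/minimum-norm solution).
    """
    if c2_mode != "identity":
        raise ValueError("only the identity source prior is supported")
    dmua, hypers, traces, iters = {}, {}, {}, {}
    all_ok = True
    for lam in od.wavelengths:
        A = sens.A_per_wavelength[lam]
        Y = od.values[lam]
        if Y.shape[0] != A.shape[0]:
            raise ValueError("channel count mismatch between OD and sensitivity")
        fixed = None if fixed_hyperparameters is None else fixed_hyperparameters[lam]
        x, h, tr, it, ok = _reml_single(
            Y, A, c1.C1[lam], tol=tol, max_iter=max_iter, fixed=fixed
        )
        dmua[lam] = SurfaceTimeSeries(x, "dmua", od.sampling_rate)
        hypers[lam] = h
        traces[lam] = tr
        iters[lam] = it
        all_ok &= ok
    if not all_ok:
        warnings.warn("ReML did not converge within the iteration budget")
    return ReMLResult(dmua, hypers, traces, iters, all_ok)


def absorption_to_hemoglobin(
    dmua_by_wavelength: dict[float, SurfaceTimeSeries],
    table: ExtinctionTable = DEFAULT_EXTINCTION,
) -> tuple[SurfaceTimeSeries, SurfaceTimeSeries]:
    """Spectroscopic unmixing: per-vertex 2x2 solve from absorption (1/cm)
    at both wavelengths to (HbO, HbR) concentration changes in umol/L."""
    lams = sorted(dmua_by_wavelength)
    if tuple(lams) != table.wavelengths:
        raise ValueError("wavelengths do not match the extinction table")
    a, b = (dmua_by_wavelength[lam] for lam in lams)
    if a.values.shape != b.values.shape:
        raise ValueError("absorption blocks must share shape")
    E = table.matrix()  # rows: wavelengths; cols: (HbR, HbO)
    stacked = np.stack([a.values.ravel(), b.values.ravel()])
    sol = np.linalg.solve(E, stacked) * 1e6  # mol/L -> umol/L
    shape = a.values.shape
    hbr = SurfaceTimeSeries(sol[0].reshape(shape), "HbR", a.sampling_rate)
    hbo = SurfaceTimeSeries(sol[1].reshape(shape), "HbO", a.sampling_rate)
    return hbo, hbr
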