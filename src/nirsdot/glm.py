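"""FIR deconvolution GLM with AR(1) generalized least squares.

The hemodynamic response at a vertex is modelled nonparametrically with one
free coefficient per peri-stimulus sample (FIR basis over a [k0, k1] sample
window, k0 typically negative), plus a block of orthonormal discrete-cosine
drift regressors below a cutoff frequency.  The noise is AR(1); estimation
is the literal two-pass procedure: an ordinary least-squares pass, Yule-
Walker estimation of the lag-1 coefficient from its residuals, then exact
generalized least squares through the analytic AR(1) whitening transform
(first sample scaled by sqrt(1 - rho^2), then first differences y[n] -
rho y[n-1]).  The HRF coefficient block is tested jointly with a partial
F statistic

    F = (N - L)/N * (bh' Theta_h^-1 bh) / (K sigma2_hat) ~ F(K, N - L)

where sigma2_hat uses the maximum-likelihood 1/N normalization and Theta_h
is the HRF sub-block of (X' Omega^-1 X)^-1; the (N - L)/N factor restores
the unbiased error scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .simulate import Paradigm
from .timeseries import SurfaceTimeSeries

__all__ = [
    "DesignMatrix",
    "ARModel",
    "GLMFit",
    "DeconvolutionMap",
    "build_design_matrix",
    "estimate_ar1",
    "fit_gls",
    "deconvolve_ar1_mle",
    "partial_f_test",
    "map_deconvolution",
    "estimate_sensor_snr",
]

#: Canonical first-peak latencies (s) used for effect-size extraction.
EFFECT_SIZE_TTP1_S = {"HbO": 6.0, "HbR": 8.0}


@dataclass
class DesignMatrix:
    """FIR + cosine-drift design.  First K columns: shifted stimulus copies
    (Toeplitz); last M columns: orthonormal DCT drifts."""

    X: np.ndarray  # (N, L)
    K: int
    k0: int  # samples (may be negative: pre-stimulus coefficients)
    k1: int
    M: int
    fs: float
    rank_deficient: bool = False

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    @property
    def fir_times_s(self) -> np.ndarray:
        """Peri-stimulus time of each FIR coefficient."""
        return np.arange(self.k0, self.k1 + 1) / self.fs


def _dct_drifts(N: int, M: int) -> np.ndarray:
    n = np.arange(N)
    D = np.empty((N, M))
    D[:, 0] = np.sqrt(1.0 / N)
    for m in range(2, M + 1):
        D[:, m - 1] = np.sqrt(2.0 / N) * np.cos(
            np.pi * (2 * n + 1) * (m - 1) / (2 * N)
        )
    return D


def build_design_matrix(
    paradigm: Paradigm,
    window_s: tuple[float, float] = (-5.0, 30.0),
    drift_cutoff_hz: float = 0.01,
) -> DesignMatrix:
    """Assemble the N x (K + M) design for a paradigm.

    The number of drift cosines M counts every basis function whose
    frequency (m - 1)/(2 T) lies strictly below the cutoff (T = run length
    in seconds); the constant term (m = 1, zero frequency) always counts.
    """
    if drift_cutoff_hz <= 0:
        raise ValueError("drift cutoff must be positive")
    fs = paradigm.sampling_rate
    k0 = int(round(window_s[0] * fs))
    k1 = int(round(window_s[1] * fs))
    if k1 < k0:
        raise ValueError("window upper bound below lower bound")
    K = k1 - k0 + 1
    s = paradigm.stimulus_vector
    N = len(s)

    X_fir = np.zeros((N, K))
    for j, shift in enumerate(range(k0, k1 + 1)):
        # column j holds s delayed by `shift` samples, zero outside the run
        if shift >= 0:
            X_fir[shift:, j] = s[: N - shift] if shift else s
        else:
            X_fir[: N + shift, j] = s[-shift:]

    T = N / fs
    M = int(np.sum((np.arange(1, N + 1) - 1) / (2.0 * T) < drift_cutoff_hz))
    X = np.hstack([X_fir, _dct_drifts(N, M)])

    rank_deficient = s.sum() == 0 or np.linalg.matrix_rank(X) < X.shape[1]
    return DesignMatrix(X, K, k0, k1, M, fs, rank_deficient=rank_deficient)


@dataclass(frozen=True)
class ARModel:
    """AR(1) serial-correlation model, Omega_ij = rho^|i-j|.

    Omega is never materialized; whitening uses the analytic transform.
    """

    rho: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


def estimate_ar1(residuals) -> ARModel:
    """Yule-Walker lag-1 coefficient of a residual series, clipped to
    (-0.99, 0.99)."""
    r = np.asarray(residuals, float)
    if r.ndim != 1 or len(r) < 3:
        raise ValueError("need a 1-D residual series of length >= 3")
    r = r - r.mean()
    c0 = float(r @ r)
    if c0 == 0.0:
        return ARModel(0.0, degenerate=True)
    rho = float(r[1:] @ r[:-1]) / c0
    return ARModel(float(np.clip(rho, -0.99, 0.99)))


@dataclass
class GLMFit:
    beta_hat: np.ndarray  # (L,): K HRF samples then M drifts
    sigma2_hat: float  # ML scale (1/N normalization)
    theta_h: np.ndarray  # (K, K) HRF block of (X' Omega^-1 X)^-1
    F_stat: float
    p_value: float
    dof: tuple[int, int]  # (K, N - L)
    residuals: np.ndarray  # unwhitened y - X beta_hat
    rho_used: float
    design: DesignMatrix = field(repr=False)

    @property
    def hrf_estimate(self) -> np.ndarray:
        return self.beta_hat[: self.design.K]


def _whiten(arr: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening (rows = samples)."""
    out = np.empty_like(arr)
    out[0] = np.sqrt(1.0 - rho**2) * arr[0]
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def fit_gls(y, X: DesignMatrix, ar: ARModel) -> GLMFit:
    """Exact GLS under AR(1) noise via the analytic whitening transform."""
    y = np.asarray(y, float)
    if len(y) != X.N:
        raise ValueError("data length does not match the design")
    if X.rank_deficient:
        raise ValueError("design matrix is rank deficient (no events?)")
    rho = ar.rho
    Xw = _whiten(X.X, rho)
    yw = _whiten(y, rho)
    G = Xw.T @ Xw  # = (1 - rho^2) X' Omega^-1 X
    c, low = cho_factor(G)
    beta = cho_solve((c, low), Xw.T @ yw)
    rss_w = float(yw @ yw - beta @ (Xw.T @ yw))
    one_m = 1.0 - rho**2
    sigma2 = max(rss_w, 0.0) / (one_m * X.N)
    theta_h = np.linalg.inv(G)[: X.K, : X.K] * one_m
    resid = y - X.X @ beta

    fit = GLMFit(
        beta_hat=beta,
        sigma2_hat=sigma2,
        theta_h=theta_h,
        F_stat=np.nan,
        p_value=np.nan,
        dof=(X.K, X.N - X.L),
        residuals=resid,
        rho_used=rho,
        design=X,
    )
    fit.F_stat, fit.p_value = partial_f_test(fit)
    return fit


def partial_f_test(fit: GLMFit) -> tuple[float, float]:
    """Joint test that the K HRF coefficients are zero."""
    K, dof2 = fit.dof
    if dof2 < 1:
        raise ValueError("insufficient residual degrees of freedom")
    bh = fit.beta_hat[:K]
    if fit.sigma2_hat == 0.0:
        if np.allclose(bh, 0.0):
            return 0.0, 1.0
        return np.inf, 0.0
    N = fit.design.N
    quad = float(bh @ np.linalg.solve(fit.theta_h, bh))
    F = (dof2 / N) * quad / (K * fit.sigma2_hat)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, K, dof2))
    return F, p


def deconvolve_ar1_mle(y, X: DesignMatrix) -> GLMFit:
    """Two-pass AR(1)-MLE: OLS assuming white noise, Yule-Walker on the
    residuals, then GLS with the estimated lag-1 coefficient."""
    first = fit_gls(y, X, ARModel(0.0))
    ar = estimate_ar1(first.residuals)
    return fit_gls(y, X, ar)


class _BatchDeconvolver:
    """Vectorized two-pass AR(1)-MLE over many series sharing one design.

    Pass 1 (OLS) is a single batched least-squares solve; pass 2 assembles
    each series' whitened normal equations from precomputed Gram pieces, so
    the N x L design is never re-whitened per series.  Agrees with
    ``deconvolve_ar1_mle`` to machine precision.
    """

    def __init__(self, design: DesignMatrix):
        if design.rank_deficient:
            raise ValueError("design matrix is rank deficient")
        self.design = design
        X = design.X
        self.G0 = X.T @ X
        G1 = X[1:].T @ X[:-1]
        self.G1s = G1 + G1.T
        x0 = X[0]
        xl = X[-1]
        # sum over n <= N-2 of x_n x_n' minus the first-row correction
        self.G2c = self.G0 - np.outer(xl, xl) - np.outer(x0, x0)
        self.x0 = x0
        self.pinv = np.linalg.pinv(X)

    def fit(self, Y: np.ndarray):
        """Y: (N, V).  Returns dict of per-series arrays."""
        X = self.design.X
        N, L = X.shape
        K = self.design.K
        V = Y.shape[1]

        B0 = self.pinv @ Y
        R = Y - X @ B0
        Rc = R - R.mean(axis=0)
        c0 = np.einsum("nv,nv->v", Rc, Rc)
        c1 = np.einsum("nv,nv->v", Rc[1:], Rc[:-1])
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(c0 > 0, c1 / np.where(c0 > 0, c0, 1.0), 0.0)
        rho = np.clip(rho, -0.99, 0.99)

        C0 = X.T @ Y
        C1a = X[1:].T @ Y[:-1]
        C1b = X[:-1].T @ Y[1:]
        y0 = Y[0]
        yl = Y[-1]
        C2c = C0 - np.outer(X[-1], yl) - np.outer(self.x0, y0)
        s0 = np.einsum("nv,nv->v", Y, Y)
        s1 = np.einsum("nv,nv->v", Y[1:], Y[:-1])
        s2 = s0 - yl**2 - y0**2

        betas = np.empty((L, V))
        F = np.empty(V)
        p = np.empty(V)
        sigma2 = np.empty(V)
        dof2 = N - L
        for v in range(V):
            r = rho[v]
            M = self.G0 - r * self.G1s + r**2 * self.G2c
            cvec = (
                C0[:, v]
                - r * (C1a[:, v] + C1b[:, v])
                + r**2 * C2c[:, v]
            )
            yy = s0[v] - 2.0 * r * s1[v] + r**2 * s2[v]
            c, low = cho_factor(M)
            b = cho_solve((c, low), cvec)
            rss = max(float(yy - b @ cvec), 0.0)
            # Schur complement of the drift block gives Theta_h^-1 directly
            Mkk = M[:K, :K]
            Mkd = M[:K, K:]
            Mdd = M[K:, K:]
            Sch = Mkk - Mkd @ np.linalg.solve(Mdd, Mkd.T)
            quad = float(b[:K] @ Sch @ b[:K])
            if rss == 0.0:
                Fv = 0.0 if np.allclose(b[:K], 0.0) else np.inf
            else:
                Fv = dof2 * quad / (K * rss)
            betas[:, v] = b
            F[v] = max(Fv, 0.0)
            p[v] = float(stats.f.sf(F[v], K, dof2))
            sigma2[v] = rss / ((1.0 - r**2) * N)
        return {
            "beta": betas,
            "F": F,
            "p": p,
            "rho": rho,
            "sigma2": sigma2,
            "dof": (K, dof2),
        }


@dataclass
class DeconvolutionMap:
    """Per-vertex FIR deconvolution over the montage FOV for both
    chromophores, with the Bonferroni-thresholded F map and the effect-size
    map at the canonical first-peak latency."""

    fov_vertices: np.ndarray
    design: DesignMatrix
    beta_h: dict[str, np.ndarray]  # chromophore -> (K, |FOV|)
    F_map: dict[str, np.ndarray]
    p_map: dict[str, np.ndarray]
    rho: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]  # boolean over FOV
    effect_size: dict[str, np.ndarray]  # beta at the TTP1-nearest sample
    effect_size_index: dict[str, int]
    F_threshold: float
    alpha: float

    def significant_vertices(self, chromophore: str) -> np.ndarray:
        return self.fov_vertices[self.significant[chromophore]]


def map_deconvolution(
    hb: dict[str, SurfaceTimeSeries],
    paradigm: Paradigm,
    fov_vertices: np.ndarray,
    alpha: float = 0.05,
    window_s: tuple[float, float] = (-5.0, 30.0),
    drift_cutoff_hz: float = 0.01,
) -> DeconvolutionMap:
    """Two-pass AR(1)-MLE deconvolution at every FOV vertex.

    The F maps are thresholded at ``alpha`` with Bonferroni correction over
    the FOV size; an empty significant set is a valid outcome.
    """
    fov = np.asarray(fov_vertices, int)
    if fov.size == 0:
        raise ValueError("FOV is empty")
    design = build_design_matrix(paradigm, window_s, drift_cutoff_hz)
    engine = _BatchDeconvolver(design)
    m = len(fov)
    K, dof2 = design.K, design.N - design.L
    f_thr = float(stats.f.ppf(1.0 - alpha / m, K, dof2))
    fir_t = design.fir_times_s

    beta_h, Fm, pm, rho, sig, eff, eff_idx = {}, {}, {}, {}, {}, {}, {}
    for chrom, series in hb.items():
        res = engine.fit(series.values[fov].T)
        beta_h[chrom] = res["beta"][:K]
        Fm[chrom] = res["F"]
        pm[chrom] = res["p"]
        rho[chrom] = res["rho"]
        sig[chrom] = res["F"] > f_thr
        idx = int(np.argmin(np.abs(fir_t - EFFECT_SIZE_TTP1_S.get(chrom, 6.0))))
        eff_idx[chrom] = idx
        eff[chrom] = res["beta"][idx]
    return DeconvolutionMap(
        fov_vertices=fov,
        design=design,
        beta_h=beta_h,
        F_map=Fm,
        p_map=pm,
        rho=rho,
        significant=sig,
        effect_size=eff,
        effect_size_index=eff_idx,
        F_threshold=f_thr,
        alpha=alpha,
    )


def estimate_sensor_snr(
    od_channel,
    paradigm: Paradigm,
    window_s: tuple[float, float] = (-5.0, 30.0),
    drift_cutoff_hz: float = 0.01,
) -> float:
    """Sensor-level SNR (dB): log ratio of the deconvolution-predicted
    evoked response power to the residual power."""
    design = build_design_matrix(paradigm, window_s, drift_cutoff_hz)
    fit = deconvolve_ar1_mle(np.asarray(od_channel, float), design)
    pred = design.X[:, : design.K] @ fit.hrf_estimate
    p_pred = float(np.mean(pred**2))
    p_res = float(np.mean(fit.residuals**2))
    if p_res == 0.0:
        return np.inf
    return 10.0 * np.log10(p_pred / p_res)
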