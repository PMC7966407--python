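"""Toy head geometry, optode montages and synthetic sensitivity matrices.

The cortical surface is a jittered spherical-cap patch (mm units) with a
radially offset scalp layer and a contiguous target region of interest
(ROI).  Optodes are placed greedily on scalp vertices near the ROI subject
to the usual continuous-wave constraints: source-detector separation within
2.5-3.5 cm and every source measured by at least two detectors.

Channel sensitivity is a parametric stand-in for photon-transport
modelling: for a channel (s, d) the sensitivity at cortical vertex v is
``gain(lambda) * exp(-dist(v, s)/decay) * exp(-dist(v, d)/decay)``, which
reproduces the banana-shaped, overlapping, ill-conditioned structure of
measured profiles.  Vertices whose best channel sensitivity exceeds 10% of
the global maximum form the montage field of view (FOV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .timeseries import ODTimeSeries, SurfaceTimeSeries

__all__ = [
    "CorticalSurface",
    "Montage",
    "SensitivityModel",
    "MontageInfeasibleError",
    "generate_toy_anatomy",
    "generate_montage",
    "compute_synthetic_sensitivity",
    "forward_project",
    "compute_fov",
]

#: Source-detector separation limits, mm.
MIN_SEPARATION_MM = 25.0
MAX_SEPARATION_MM = 35.0
#: Minimum spacing between any two optodes, mm.
MIN_OPTODE_SPACING_MM = 15.0

DEFAULT_WAVELENGTHS = (685.0, 830.0)


class MontageInfeasibleError(RuntimeError):
    """Raised when no optode placement satisfies the montage constraints."""


@dataclass
class CorticalSurface:
    vertex_positions: np.ndarray  # (V, 3) mm
    triangle_faces: np.ndarray  # (F, 3) int
    scalp_positions: np.ndarray  # (V, 3) mm, radially offset
    roi_vertices: np.ndarray  # int indices

    def __post_init__(self) -> None:
        V = self.vertex_positions.shape[0]
        if V < 50:
            raise ValueError("mesh must have at least 50 vertices")
        if self.triangle_faces.min() < 0 or self.triangle_faces.max() >= V:
            raise ValueError("face indices out of range")
        if len(self.roi_vertices) and (
            self.roi_vertices.min() < 0 or self.roi_vertices.max() >= V
        ):
            raise ValueError("ROI indices out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_vertices)}
        for a, b, c in self.triangle_faces:
            adj[a] |= {b, c}
            adj[b] |= {a, c}
            adj[c] |= {a, b}
        return adj

    def to_ply(self, path) -> None:
        """Write the cortical mesh as ascii PLY plus a JSON manifest."""
        v, f = self.vertex_positions, self.triangle_faces
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(v)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                f"element face {len(f)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for p in v:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        manifest = {
            "roi_vertices": [int(i) for i in self.roi_vertices],
            "scalp_positions": self.scalp_positions.tolist(),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh)


@dataclass
class Montage:
    source_positions: np.ndarray  # (S, 3) mm on scalp
    detector_positions: np.ndarray  # (D, 3) mm on scalp
    channels: list[tuple[int, int]]  # (source index, detector index)
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in montage")
        for s, d in self.channels:
            sep = self.channel_separation_mm(s, d)
            if not (MIN_SEPARATION_MM - 1e-9 <= sep <= MAX_SEPARATION_MM + 1e-9):
                raise ValueError(
                    f"channel ({s},{d}) separation {sep:.1f} mm outside "
                    f"[{MIN_SEPARATION_MM}, {MAX_SEPARATION_MM}] mm"
                )
        counts = np.zeros(len(self.source_positions), dtype=int)
        for s, _ in self.channels:
            counts[s] += 1
        if np.any(counts < 2):
            raise ValueError("every source must appear in at least two channels")

    def channel_separation_mm(self, s: int, d: int) -> float:
        return float(
            np.linalg.norm(self.source_positions[s] - self.detector_positions[d])
        )

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class SensitivityModel:
    """Per-wavelength channels x vertices sensitivity with its FOV.

    Entries are in cm so that dimensionless base-e OD changes follow from
    absorption changes in 1/cm via a plain matrix product.
    """

    A_per_wavelength: dict[float, np.ndarray]
    fov_vertices: np.ndarray
    fov_threshold_fraction: float = 0.1
    channels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lam, A in self.A_per_wavelength.items():
            if np.any(A < 0):
                raise ValueError(f"negative sensitivity entries at {lam} nm")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.A_per_wavelength))

    @property
    def n_vertices(self) -> int:
        return next(iter(self.A_per_wavelength.values())).shape[1]

    def roi_sensitivity(self, wavelength: float, roi: np.ndarray) -> np.ndarray:
        """Summed sensitivity over ROI vertices, per channel."""
        return self.A_per_wavelength[wavelength][:, np.asarray(roi, int)].sum(axis=1)


def _cap_points(n: int, half_angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform unit directions on a spherical cap around +z (Fibonacci
    spiral with a small seeded jitter)."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    zmin = np.cos(half_angle_rad)
    z = 1.0 - (i + 0.5) / n * (1.0 - zmin)
    phi = golden * i + rng.uniform(0, 2 * np.pi)
    # jitter keeps the triangulation generic without destroying uniformity
    z = np.clip(z + rng.normal(0, 0.25 * (1 - zmin) / n, n), zmin, 1.0)
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_toy_anatomy(
    n_vertices: int = 250,
    roi_radius_mm: float = 10.0,
    seed: int = 0,
    sphere_radius_mm: float = 80.0,
    cap_half_angle_deg: float = 50.0,
    scalp_offset_mm: float = 13.0,
) -> CorticalSurface:
    """Curved open cortical patch with contiguous ROI and offset scalp layer.

    Deterministic for a fixed seed.  The ROI is grown around the cap apex:
    all vertices within ``roi_radius_mm``, topped up to at least 5 with the
    next-nearest vertices so a minimal analysis target always exists.
    """
    if n_vertices < 50:
        raise ValueError("n_vertices must be >= 50")
    if roi_radius_mm < 1.0:
        raise ValueError(
            "roi_radius_mm below 1 mm is degenerate relative to mesh resolution"
        )
    if scalp_offset_mm < 10.0:
        raise ValueError("scalp offset must be >= 10 mm")
    rng = np.random.default_rng(seed)
    dirs = _cap_points(n_vertices, np.deg2rad(cap_half_angle_deg), rng)
    verts = dirs * sphere_radius_mm
    # triangulate in the tangent plane of the cap (gnomonic-like projection)
    uv = dirs[:, :2] / (1.0 + dirs[:, 2:3])
    faces = Delaunay(uv).simplices.astype(int)
    scalp = dirs * (sphere_radius_mm + scalp_offset_mm)

    apex = np.array([0.0, 0.0, sphere_radius_mm])
    dist = np.linalg.norm(verts - apex, axis=1)
    order = np.argsort(dist, kind="stable")
    in_radius = int(np.sum(dist <= roi_radius_mm))
    roi = order[: max(5, in_radius)]
    return CorticalSurface(verts, faces, scalp, np.sort(roi))


def generate_montage(
    surface: CorticalSurface,
    n_sources: int = 4,
    n_detectors: int = 8,
    seed: int = 0,
) -> Montage:
    """Greedy ROI-targeted optode placement on the scalp layer.

    Sources are packed as close to the ROI centroid projection as spacing
    allows; detectors are then chosen to keep every source in at least two
    channels within the 2.5-3.5 cm separation band, preferring positions
    close to the ROI.  Channels are every in-band source-detector pair,
    ordered lexicographically.
    """
    if n_sources < 1:
        raise MontageInfeasibleError("need at least one source")
    if n_detectors < 2:
        raise MontageInfeasibleError(
            "need at least two detectors so each source has two channels"
        )
    rng = np.random.default_rng(seed)
    scalp = surface.scalp_positions
    roi_centroid = surface.vertex_positions[surface.roi_vertices].mean(axis=0)
    # project centroid radially onto the scalp shell
    scalp_radius = np.linalg.norm(scalp, axis=1).mean()
    center = roi_centroid / np.linalg.norm(roi_centroid) * scalp_radius
    closeness = np.linalg.norm(scalp - center, axis=1)
    closeness = closeness + rng.normal(0.0, 1e-6, len(closeness))  # seeded tie-break
    order = np.argsort(closeness, kind="stable")

    src_idx: list[int] = []
    for cand in order:
        if len(src_idx) == n_sources:
            break
        if all(
            np.linalg.norm(scalp[cand] - scalp[j]) >= MIN_OPTODE_SPACING_MM
            for j in src_idx
        ):
            src_idx.append(int(cand))
    if len(src_idx) < n_sources:
        raise MontageInfeasibleError(
            f"could only place {len(src_idx)}/{n_sources} sources with "
            f">= {MIN_OPTODE_SPACING_MM} mm spacing"
        )
    src_pos = scalp[src_idx]

    det_idx: list[int] = []
    taken = set(src_idx)
    for _ in range(n_detectors):
        best, best_score = None, None
        for cand in order:
            if int(cand) in taken or int(cand) in det_idx:
                continue
            p = scalp[cand]
            spacing_ok = all(
                np.linalg.norm(p - scalp[j]) >= MIN_OPTODE_SPACING_MM
                for j in list(taken) + det_idx
            )
            if not spacing_ok:
                continue
            seps = np.linalg.norm(src_pos - p, axis=1)
            in_band = (seps >= MIN_SEPARATION_MM) & (seps <= MAX_SEPARATION_MM)
            if not np.any(in_band):
                continue
            # how many under-covered sources would this detector help?
            cover = _source_coverage(src_pos, scalp[det_idx]) if det_idx else np.zeros(
                len(src_pos), int
            )
            helps = int(np.sum(in_band & (cover < 2)))
            score = (helps, -closeness[cand])
            if best_score is None or score > best_score:
                best, best_score = int(cand), score
        if best is None:
            raise MontageInfeasibleError(
                "no admissible detector position left on this scalp"
            )
        det_idx.append(best)
    det_pos = scalp[det_idx]

    channels = [
        (s, d)
        for s in range(n_sources)
        for d in range(n_detectors)
        if MIN_SEPARATION_MM
        <= np.linalg.norm(src_pos[s] - det_pos[d])
        <= MAX_SEPARATION_MM
    ]
    cover = _source_coverage(src_pos, det_pos)
    if np.any(cover < 2):
        raise MontageInfeasibleError(
            "placement leaves a source with fewer than two channels"
        )
    return Montage(src_pos, det_pos, channels)


def _source_coverage(src_pos: np.ndarray, det_pos: np.ndarray) -> np.ndarray:
    if len(det_pos) == 0:
        return np.zeros(len(src_pos), int)
    d = np.linalg.norm(src_pos[:, None, :] - det_pos[None, :, :], axis=2)
    return ((d >= MIN_SEPARATION_MM) & (d <= MAX_SEPARATION_MM)).sum(axis=1)


def compute_fov(
    A_per_wavelength: dict[float, np.ndarray], threshold_fraction: float = 0.1
) -> np.ndarray:
    """Vertices whose best channel sensitivity reaches the stated fraction
    of the global maximum (over all channels and wavelengths)."""
    stacked = np.vstack(list(A_per_wavelength.values()))
    best = stacked.max(axis=0)
    return np.flatnonzero(best >= threshold_fraction * stacked.max())


def compute_synthetic_sensitivity(
    surface: CorticalSurface,
    montage: Montage,
    decay_scale_mm: float = 12.0,
    wavelength_gain: dict[float, float] | None = None,
    fov_threshold_fraction: float = 0.1,
) -> SensitivityModel:
    """Exponential-product sensitivity profile per channel.

    ``A[c, v] = gain(lambda) * exp(-(|v-s| + |v-d|)/decay_scale_mm)`` with
    distances from cortical vertex v to the channel's source and detector
    scalp positions.  Symmetric in source/detector by construction.
    """
    if decay_scale_mm <= 0:
        raise ValueError("decay_scale_mm must be positive")
    if wavelength_gain is None:
        wavelength_gain = {montage.wavelengths[0]: 1.0, montage.wavelengths[1]: 1.15}
    verts = surface.vertex_positions
    base = np.empty((len(montage.channels), len(verts)))
    for c, (s, d) in enumerate(montage.channels):
        ds = np.linalg.norm(verts - montage.source_positions[s], axis=1)
        dd = np.linalg.norm(verts - montage.detector_positions[d], axis=1)
        base[c] = np.exp(-(ds + dd) / decay_scale_mm)
    A = {lam: g * base for lam, g in wavelength_gain.items()}
    fov = compute_fov(A, fov_threshold_fraction)
    if len(fov) == 0:
        raise ValueError(
            "empty field of view; increase decay_scale_mm or mesh density"
        )
    if not np.any(np.isin(surface.roi_vertices, fov)):
        raise ValueError("no ROI vertex falls inside the FOV; montage off target")
    return SensitivityModel(A, fov, fov_threshold_fraction, list(montage.channels))


def forward_project(
    sens: SensitivityModel, dmua: dict[float, np.ndarray | SurfaceTimeSeries],
    sampling_rate: float = 1.0,
) -> ODTimeSeries:
    """Linear forward model: OD change = sensitivity x absorption change."""
    out: dict[float, np.ndarray] = {}
    fs = sampling_rate
    for lam, A in sens.A_per_wavelength.items():
        if lam not in dmua:
            raise ValueError(f"missing absorption block for {lam} nm")
        x = dmua[lam]
        if isinstance(x, SurfaceTimeSeries):
            fs = x.sampling_rate
            x = x.values
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[0] != A.shape[1]:
            raise ValueError(
                f"vertex dimension {x.shape[0]} does not match sensitivity "
                f"columns {A.shape[1]}"
            )
        out[lam] = A @ x
    return ODTimeSeries(out, fs, list(sens.channels))
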