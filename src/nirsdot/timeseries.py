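"""In-memory containers for channel-space and surface-space time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ODTimeSeries", "SurfaceTimeSeries"]


@dataclass
class ODTimeSeries:
    """Channel-space optical-density change (base-e), one block per wavelength.

    ``values`` maps wavelength (nm) to a channels x samples array.  All
    wavelength blocks share the channel list and sample count.
    """

    values: dict[float, np.ndarray]
    sampling_rate: float
    channel_ids: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("at least one wavelength block required")
        shapes = {lam: np.asarray(v).shape for lam, v in self.values.items()}
        first = next(iter(shapes.values()))
        for lam, shp in shapes.items():
            if len(shp) != 2 or shp != first:
                raise ValueError(f"inconsistent block shape for {lam} nm: {shp}")
            if not np.all(np.isfinite(self.values[lam])):
                raise ValueError(f"non-finite values in {lam} nm block")
        if self.channel_ids and len(self.channel_ids) != first[0]:
            raise ValueError("channel_ids length does not match value rows")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.values))

    @property
    def n_channels(self) -> int:
        return next(iter(self.values.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.values.values())).shape[1]

    def copy(self) -> "ODTimeSeries":
        return ODTimeSeries(
            {lam: v.copy() for lam, v in self.values.items()},
            self.sampling_rate,
            list(self.channel_ids),
        )


@dataclass
class SurfaceTimeSeries:
    """Vertex-space time series (absorption in 1/cm or hemoglobin in umol/L)."""

    values: np.ndarray  # vertices x samples
    quantity: str  # "dmua" | "HbO" | "HbR"
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a vertices x samples matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in surface time series")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]
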