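"""Minimal SNIRF (HDF5) export/import for channel-space OD data.

Writes the subset of the SNIRF layout needed for interoperability: probe
geometry, wavelengths, and a processed time series whose measurement list
maps each row to a (source, detector, wavelength) triple.
"""

from __future__ import annotations

import numpy as np
import h5py

from .anatomy import Montage
from .timeseries import ODTimeSeries

__all__ = ["export_snirf", "import_snirf"]


def export_snirf(od: ODTimeSeries, montage: Montage, path) -> None:
    if od.n_channels != len(montage.channels):
        raise ValueError(
            f"OD has {od.n_channels} channels but the montage defines "
            f"{len(montage.channels)}"
        )
    lams = list(od.wavelengths)
    n = od.n_samples
    t = np.arange(n) / od.sampling_rate
    # stack wavelength blocks: columns ordered (wavelength-major)
    data = np.vstack([od.values[lam] for lam in lams]).T  # time x measurements

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(lams, float))
        probe.create_dataset("sourcePos3D", data=montage.source_positions)
        probe.create_dataset("detectorPos3D", data=montage.detector_positions)
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=t)
        k = 1
        for wi, lam in enumerate(lams, start=1):
            for s, d in montage.channels:
                ml = d1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=s + 1)
                ml.create_dataset("detectorIndex", data=d + 1)
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=99999)  # processed
                ml.create_dataset("dataTypeLabel", data="dOD")
                k += 1


def import_snirf(path) -> tuple[ODTimeSeries, np.ndarray, np.ndarray]:
    """Read back an exported file.  Returns (od, source_pos, detector_pos)."""
    with h5py.File(path, "r") as f:
        probe = f["nirs/probe"]
        lams = [float(x) for x in probe["wavelengths"][()]]
        src = probe["sourcePos3D"][()]
        det = probe["detectorPos3D"][()]
        d1 = f["nirs/data1"]
        data = d1["dataTimeSeries"][()]
        t = d1["time"][()]
        n_meas = data.shape[1]
        triples = []
        for k in range(1, n_meas + 1):
            ml = d1[f"measurementList{k}"]
            triples.append(
                (
                    int(ml["sourceIndex"][()]) - 1,
                    int(ml["detectorIndex"][()]) - 1,
                    int(ml["wavelengthIndex"][()]) - 1,
                )
            )
    fs = 1.0 / float(t[1] - t[0])
    per_lam = len(triples) // len(lams)
    values = {}
    channel_ids = [(s, d) for s, d, wi in triples[:per_lam]]
    for wi, lam in enumerate(lams):
        cols = [k for k, (_, _, w) in enumerate(triples) if w == wi]
        values[lam] = data[:, cols].T
    od = ODTimeSeries(values, fs, channel_ids)
    return od, src, det
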