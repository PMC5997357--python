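"""Serialization: rasters and graphs as CSV, time series and spectra as HDF5.

One results container per run; every writer stamps the package version so a
result file identifies the code that produced it.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import SpikeRaster
from .lfp import LFPRecord
from .spectral import SaccadeLockedSpectra


def save_raster_csv(raster: SpikeRaster, path) -> None:
    """Two-column CSV (neuron_id, time_ms)."""
    raster.to_frame().to_csv(path, index=False)


def load_raster_csv(path, duration: float, n_neurons: int) -> SpikeRaster:
    df = pd.read_csv(path)
    return SpikeRaster(
        df["neuron_id"].to_numpy(), df["time_ms"].to_numpy(), duration, n_neurons
    )


def save_graph_csv(graph, path) -> None:
    """Edge-list CSV (pre, post, weight)."""
    graph.to_edge_frame().to_csv(path, index=False)


def _stamp(group) -> None:
    from . import __version__

    group.attrs["msping_version"] = __version__


def save_run_h5(
    path,
    raster: SpikeRaster | None = None,
    lfp: LFPRecord | None = None,
    spectra: SaccadeLockedSpectra | None = None,
    onsets: np.ndarray | None = None,
    extra: dict | None = None,
) -> None:
    """Write a results container with raster, LFP, spectra and onsets."""
    with h5py.File(path, "w") as fh:
        _stamp(fh)
        if raster is not None:
            g = fh.create_group("raster")
            g.create_dataset("neuron_id", data=raster.neuron_ids)
            g.create_dataset("time_ms", data=raster.times)
            g.attrs["duration_ms"] = raster.duration
            g.attrs["n_neurons"] = raster.n_neurons
        if lfp is not None:
            g = fh.create_group("lfp")
            g.create_dataset("data", data=lfp.data, compression="gzip")
            g.create_dataset("positions", data=lfp.grid.positions())
            g.attrs["dt_ms"] = lfp.dt
        if spectra is not None:
            g = fh.create_group("plv")
            g.create_dataset("plv", data=spectra.plv, compression="gzip")
            g.create_dataset("theta", data=spectra.theta, compression="gzip")
            g.create_dataset("freqs_hz", data=spectra.freqs)
            g.create_dataset("times_ms", data=spectra.times)
            g.create_dataset("pairs", data=spectra.pairs)
            g.attrs["n_saccades"] = spectra.n_saccades
        if onsets is not None:
            fh.create_dataset("ms_onsets_ms", data=np.asarray(onsets))
        if extra:
            g = fh.create_group("extra")
            for key, value in extra.items():
                g.create_dataset(key, data=np.asarray(value))


def load_lfp_h5(path) -> LFPRecord:
    from .lfp import ElectrodeGrid

    with h5py.File(path, "r") as fh:
        data = fh["lfp/data"][()]
        dt = float(fh["lfp"].attrs["dt_ms"])
    return LFPRecord(data=data, dt=dt, grid=ElectrodeGrid())


def save_patch(patch: np.ndarray, path) -> None:
    """Grayscale patch as plain numeric CSV grid (or PNG by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".png", ".pgm"):
        import imageio.v3 as iio

        iio.imwrite(path, (np.clip(patch, 0, 1) * 255).astype(np.uint8))
    else:
        np.savetxt(path, patch, delimiter=",")


def load_patch(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".png", ".pgm"):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=float)
    return np.loadtxt(path, delimiter=",")
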