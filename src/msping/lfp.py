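"""Virtual-electrode LFP proxy.

The model LFP at an electrode is the Gaussian-distance-weighted sum of
excitatory membrane potentials, w(D) = exp(-D^2 / 2 sigma_lfp^2) with
toroidal distance D and sigma_lfp = 1 E-cell spacing by default.  Weights
are deliberately not normalised (the absolute LFP scale is arbitrary; every
downstream measure — phase, PLV, correlation — is scale invariant).  A
10 x 10 electrode grid covers the 40 x 40 E grid, giving an inter-electrode
spacing of 4 E-cell spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .connectivity import GridGeometry, torus_distance

__all__ = ["ElectrodeGrid", "LFPRecord", "compute_lfp", "electrode_pair_table"]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular grid of virtual electrodes over the excitatory sheet."""

    n_side: int = 10
    sigma_lfp: float = 1.0
    geometry: GridGeometry = field(default_factory=GridGeometry)
    cutoff_sigmas: float = 5.0

    @property
    def n_channels(self) -> int:
        return self.n_side * self.n_side

    @property
    def spacing(self) -> float:
        return self.geometry.extent / self.n_side

    def positions(self) -> np.ndarray:
        g = np.arange(self.n_side, dtype=float) * self.spacing
        xx, yy = np.meshgrid(g, g, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def weights(self) -> sp.csr_matrix:
        """Sparse (n_channels x n_exc) Gaussian weight matrix.

        Weights beyond ``cutoff_sigmas`` standard deviations are dropped;
        with the default cutoff the discarded mass is < 4e-6 per channel.
        """
        pos_e = self.geometry.e_positions()
        d = torus_distance(
            self.positions()[:, None, :], pos_e[None, :, :], self.geometry.extent
        )
        w = np.exp(-(d**2) / (2.0 * self.sigma_lfp**2))
        w[d > self.cutoff_sigmas * self.sigma_lfp] = 0.0
        return sp.csr_matrix(w)


@dataclass
class LFPRecord:
    """Multichannel virtual-electrode time series."""

    data: np.ndarray  # (n_channels, n_samples)
    dt: float
    grid: ElectrodeGrid
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("LFP contains non-finite samples")
        if self.times is None:
            self.times = (np.arange(self.data.shape[1]) + 1) * self.dt

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt


def compute_lfp(
    v_traces: np.ndarray,
    grid: ElectrodeGrid,
    dt: float = 0.5,
) -> LFPRecord:
    """LFP_k(t) = sum_i w(D_ik) V_i(t) over all excitatory cells.

    ``v_traces`` must contain the membrane potential of every V1 excitatory
    cell (rows in grid order); the LFP is undefined with any cell missing.
    """
    v_traces = np.asarray(v_traces)
    if v_traces.shape[0] != grid.geometry.n_exc:
        raise ValueError(
            f"need traces for all {grid.geometry.n_exc} excitatory cells, "
            f"got {v_traces.shape[0]}"
        )
    data = grid.weights() @ v_traces
    return LFPRecord(data=np.asarray(data), dt=dt, grid=grid)


def electrode_pair_table(grid: ElectrodeGrid) -> pd.DataFrame:
    """All unordered channel pairs with toroidal distances.

    Columns: ``a``, ``b`` (channel indices), ``distance`` (E-cell units),
    ``is_neighbor`` (minimal distance = grid spacing) and ``is_max``
    (maximal toroidal distance, half-period along both axes).
    """
    pos = grid.positions()
    n = grid.n_channels
    a, b = np.triu_indices(n, k=1)
    d = torus_distance(pos[a], pos[b], grid.geometry.extent)
    d = np.round(d, 9)
    return pd.DataFrame(
        {
            "a": a,
            "b": b,
            "distance": d,
            "is_neighbor": np.isclose(d, d.min()),
            "is_max": np.isclose(d, d.max()),
        }
    )
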