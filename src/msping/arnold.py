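"""Arnold-tongue reconstruction from simulated synchronization data.

For weakly coupled oscillators, the region of phase locking in the
(detuning, coupling) plane is triangular: at larger coupling the
synchronized region tolerates larger detuning (the Arnold tongue), and
within the locked region the mean phase difference grows with detuning
(Adler's equation: sin(theta*) = detuning / coupling).  Here both axes are
operational proxies measured on electrode pairs of the simulated network:
detuning as the absolute difference of the drive under the two electrodes
(input drives the local oscillation frequency), coupling as the summed
reciprocal synaptic weight between the electrodes' neuron neighbourhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.stats

from .connectivity import ConnectivityGraph
from .lfp import ElectrodeGrid

__all__ = [
    "TongueMap",
    "electrode_drive",
    "pair_detuning",
    "pair_interaction_strength",
    "tongue_map",
    "tongue_statistic",
    "flatness_statistic",
]


def electrode_drive(j_e: np.ndarray, grid: ElectrodeGrid) -> np.ndarray:
    """LFP-kernel-weighted mean static drive under each electrode."""
    w = grid.weights()
    j = np.asarray(j_e, dtype=float).ravel()
    num = w @ j
    den = np.asarray(w.sum(axis=1)).ravel()
    return num / den


def pair_detuning(
    electrode_values: np.ndarray, pair_table
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair detuning proxy from an electrode-level drive (or rate) map.

    Returns ``(absolute, signed)`` differences; the signed variant (b minus
    a) is kept for mean-phase analysis, and is antisymmetric under pair
    order swap by construction.
    """
    a = pair_table["a"].to_numpy()
    b = pair_table["b"].to_numpy()
    signed = electrode_values[b] - electrode_values[a]
    return np.abs(signed), signed


def pair_interaction_strength(
    graph: ConnectivityGraph,
    grid: ElectrodeGrid,
    pair_table,
) -> np.ndarray:
    """Reciprocal synaptic weight between electrode neighbourhoods.

    For electrodes x, y with LFP kernels K_x, K_y over V1 E cells, the proxy
    is sum_ij K_x(i) (W_ij + W_ji) K_y(j), normalised by the kernel masses —
    symmetric in pair order and linear in the synaptic weights.
    """
    k = grid.weights()  # (n_ch, n_e)
    v1e = graph.v1_exc_indices()
    w_ee = graph.weights[v1e][:, v1e]
    w_sym = (w_ee + w_ee.T).tocsr()
    m = k @ w_sym @ k.T
    if sp.issparse(m):
        m = m.toarray()
    m = np.asarray(m)
    mass = np.asarray(k.sum(axis=1)).ravel()
    norm = np.outer(mass, mass)
    m = m / norm
    a = pair_table["a"].to_numpy()
    b = pair_table["b"].to_numpy()
    return m[a, b]


@dataclass
class TongueMap:
    """Binned synchronization map over (detuning, coupling) space.

    ``plv`` and ``theta`` are (n_coupling_bins, n_detuning_bins) bin means;
    bins with zero occupancy are NaN (missing), never zero.
    """

    plv: np.ndarray
    theta: np.ndarray
    counts: np.ndarray
    detuning_edges: np.ndarray
    coupling_edges: np.ndarray
    period_label: str = ""

    @property
    def detuning_centers(self) -> np.ndarray:
        return 0.5 * (self.detuning_edges[:-1] + self.detuning_edges[1:])

    @property
    def coupling_centers(self) -> np.ndarray:
        return 0.5 * (self.coupling_edges[:-1] + self.coupling_edges[1:])


def tongue_map(
    pair_plv: np.ndarray,
    pair_theta: np.ndarray,
    detuning: np.ndarray,
    coupling: np.ndarray,
    n_detuning_bins: int = 8,
    n_coupling_bins: int = 6,
    period_label: str = "",
    min_count: int = 1,
) -> TongueMap:
    """Bin per-pair window-averaged PLV and mean phase on the 2D proxy grid.

    Coupling bins are quantile based (equal occupancy along that axis, since
    the coupling proxy is heavily skewed by the distance-dependent wiring);
    detuning bins are equal width.
    """
    detuning = np.asarray(detuning, dtype=float)
    coupling = np.asarray(coupling, dtype=float)
    d_edges = np.linspace(detuning.min(), detuning.max(), n_detuning_bins + 1)
    c_edges = np.quantile(coupling, np.linspace(0, 1, n_coupling_bins + 1))
    c_edges = np.unique(c_edges)
    di = np.clip(np.digitize(detuning, d_edges) - 1, 0, n_detuning_bins - 1)
    ci = np.clip(np.digitize(coupling, c_edges) - 1, 0, len(c_edges) - 2)
    shape = (len(c_edges) - 1, n_detuning_bins)
    plv = np.full(shape, np.nan)
    theta = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    for c in range(shape[0]):
        for d in range(shape[1]):
            sel = (ci == c) & (di == d)
            counts[c, d] = sel.sum()
            if counts[c, d] >= min_count:
                plv[c, d] = pair_plv[sel].mean()
                z = np.exp(1j * pair_theta[sel]).mean()
                theta[c, d] = np.angle(z)
    return TongueMap(plv, theta, counts, d_edges, c_edges, period_label)


def _half_widths(tmap: TongueMap, level: float) -> np.ndarray:
    """Detuning half-width of the PLV >= level region per coupling bin.

    Scanning outward from zero detuning, the half-width is the detuning bin
    centre of the last contiguous bin with mean PLV >= level (NaN bins stop
    the scan); coupling rows whose lowest-detuning bin is unlocked get
    width 0.
    """
    centers = tmap.detuning_centers
    widths = np.zeros(tmap.plv.shape[0])
    for c in range(tmap.plv.shape[0]):
        w = 0.0
        for d in range(tmap.plv.shape[1]):
            v = tmap.plv[c, d]
            if np.isnan(v) or v < level:
                break
            w = centers[d]
        widths[c] = w
    return widths


def tongue_statistic(tmap: TongueMap, level: float = 0.5) -> tuple[float, np.ndarray]:
    """Spearman correlation between coupling bin and locking half-width.

    A positive value means the locked region widens with coupling — the
    Arnold-tongue signature.  Returns (rho, half_widths); rho is NaN when
    the half-widths are constant (e.g. a saturated or empty map).
    """
    widths = _half_widths(tmap, level)
    if np.all(widths == widths[0]):
        return float("nan"), widths
    rho = scipy.stats.spearmanr(np.arange(widths.size), widths).statistic
    return float(rho), widths


def tongue_summary(tmap: TongueMap, level: float = 0.5, min_rho: float = 0.5) -> dict:
    """Classify a synchronization map as Arnold tongue vs uniform locking.

    A map *has a tongue* when the locked (PLV >= level) region widens with
    coupling (Spearman rho >= ``min_rho``) *and* shows an apex — at least
    one weak-coupling bin with zero locked width, so locking genuinely
    vanishes for weak interaction.  A map is *uniformly locked* when every
    coupling bin keeps a nonzero locked width: synchrony is present for any
    combination of coupling and detuning, which is the opposite of a
    tongue.
    """
    rho, widths = tongue_statistic(tmap, level)
    has_apex = bool(np.any(widths == 0.0))
    locked_everywhere = bool(np.all(widths > 0.0))
    return {
        "rho": rho,
        "half_widths": widths,
        "has_apex": has_apex,
        "locked_everywhere": locked_everywhere,
        "has_tongue": bool(rho >= min_rho) and has_apex,
        "flatness": flatness_statistic(tmap),
    }


def flatness_statistic(tmap: TongueMap) -> dict:
    """Flatness of the map: relative range and variance of the bin means.

    A transient-period map is expected to be uniformly high (locking for any
    proxy combination), hence a small relative range.
    """
    vals = tmap.plv[np.isfinite(tmap.plv)]
    mean = float(vals.mean())
    return {
        "mean": mean,
        "relative_range": float((vals.max() - vals.min()) / mean) if mean > 0 else np.inf,
        "variance": float(vals.var()),
    }
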