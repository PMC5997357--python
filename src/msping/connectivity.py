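"""Network construction: toroidal V1 grids and the V1->V2 feedforward net.

Excitatory (RS) cells sit on an ``n_e x n_e`` square grid, inhibitory (FS)
cells on a coarser ``n_i x n_i`` grid spanning the same physical extent (I
coordinates are scaled so both grids cover [0, L)).  All distances are
Euclidean with periodic wrap-around (the network lives on a torus).

Connections are drawn per *receiving* neuron: the Gaussian connection
probability P(D) ~ exp(-D^2 / 2 sigma_S^2) over candidate senders (self
excluded) is sampled exactly N_S times with replacement, so every receiver
has total incoming weight N_S * g_S; repeated draws accumulate integer
multiples of g_S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GridGeometry",
    "ProjectionParams",
    "ConnectivityGraph",
    "torus_delta",
    "torus_distance",
    "sample_gaussian_connections",
    "build_v1_network",
    "apply_anisotropy",
    "build_v1_v2_network",
]


def torus_delta(a: np.ndarray, b: np.ndarray, extent: float) -> np.ndarray:
    """Signed per-axis displacement b - a wrapped to [-extent/2, extent/2)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return (d + extent / 2.0) % extent - extent / 2.0


def torus_distance(a: np.ndarray, b: np.ndarray, extent: float) -> np.ndarray:
    """Euclidean distance between points on a square torus of side ``extent``.

    ``a`` and ``b`` are (..., 2) coordinate arrays; broadcasting applies.
    """
    d = torus_delta(a, b, extent)
    return np.sqrt((d**2).sum(axis=-1))


@dataclass(frozen=True)
class GridGeometry:
    """E and I grid layout on a common torus.

    ``n_e`` is the side of the excitatory grid (spacing 1, the distance
    unit); ``n_i`` the side of the inhibitory grid, registered by scaling its
    coordinates by ``n_e / n_i`` so both grids span [0, n_e).
    """

    n_e: int = 40
    n_i: int = 20
    periodic: bool = True

    @property
    def extent(self) -> float:
        return float(self.n_e)

    @property
    def n_exc(self) -> int:
        return self.n_e * self.n_e

    @property
    def n_inh(self) -> int:
        return self.n_i * self.n_i

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def e_positions(self) -> np.ndarray:
        g = np.arange(self.n_e, dtype=float)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def i_positions(self) -> np.ndarray:
        scale = self.n_e / self.n_i
        g = np.arange(self.n_i, dtype=float) * scale
        xx, yy = np.meshgrid(g, g, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def all_positions(self) -> np.ndarray:
        return np.vstack([self.e_positions(), self.i_positions()])

    def center_e_index(self) -> int:
        c = self.n_e // 2
        return c * self.n_e + c


@dataclass(frozen=True)
class ProjectionParams:
    """Per-projection wiring parameters: in-degree, unit weight, reach."""

    n_s: int
    g_s: float
    sigma_s: float

    def __post_init__(self) -> None:
        if self.n_s <= 0:
            raise ValueError("N_S must be positive")
        if self.sigma_s <= 0:
            raise ValueError("sigma_S must be positive")


# In-degrees and unit synaptic strengths per projection (sender->receiver).
# Excitatory projections reach sigma_E = sqrt(20) ~ 4.47 grid units (the
# Gaussian footprint variance is 20 squared grid units), inhibitory
# projections sigma = 1: excitatory wiring reaches several times further
# than inhibitory wiring, and the resulting gamma coherence length of a few
# electrode spacings is what makes sustained synchrony distance selective.
# N_S and g_S are not constrained by closed-form theory; these values come
# from the calibrate_gamma grid search (see experiments module) selecting
# sustained-period population gamma in the 25-40 Hz band at physiological
# E rates, with distance- and input-selective sustained locking.
SIGMA_E = 20.0 ** 0.5
DEFAULT_V1_PROJECTIONS: dict[str, ProjectionParams] = {
    "EE": ProjectionParams(n_s=40, g_s=0.006, sigma_s=SIGMA_E),
    "EI": ProjectionParams(n_s=40, g_s=0.012, sigma_s=SIGMA_E),
    "IE": ProjectionParams(n_s=20, g_s=0.04, sigma_s=1.0),
    "II": ProjectionParams(n_s=10, g_s=0.02, sigma_s=1.0),
}


@dataclass
class ConnectivityGraph:
    """Weighted, directed, typed adjacency for the whole simulated network.

    ``weights[post, pre]`` is the total synaptic strength of the pre -> post
    connection (integer multiple of the projection's g_S).  ``is_exc`` and
    ``area`` (0 = V1, 1 = V2) type each neuron; ``positions`` are torus
    coordinates for V1 neurons (V2 carries no spatial geometry and reuses the
    grid centre as a placeholder coordinate).
    """

    weights: sp.csr_matrix
    is_exc: np.ndarray
    area: np.ndarray
    positions: np.ndarray
    geometry: GridGeometry
    projections: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def exc_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_exc)

    def v1_exc_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_exc & (self.area == 0))

    def in_weight(self, receivers: np.ndarray, senders: np.ndarray) -> np.ndarray:
        """Total incoming weight to each receiver from the sender set."""
        sub = self.weights[receivers][:, senders]
        return np.asarray(sub.sum(axis=1)).ravel()

    def to_edge_frame(self):
        """Edge list as a pandas DataFrame (pre, post, weight)."""
        import pandas as pd

        coo = self.weights.tocoo()
        return pd.DataFrame({"pre": coo.col, "post": coo.row, "weight": coo.data})


def sample_gaussian_connections(
    receiver_positions: np.ndarray,
    sender_positions: np.ndarray,
    n_s: int,
    sigma_s: float,
    extent: float,
    rng: np.random.Generator,
    self_pairs: tuple[np.ndarray, np.ndarray] | None = None,
    footprint: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample fixed-in-degree Gaussian connections.

    For every receiver, ``n_s`` senders are drawn with replacement with
    probability proportional to exp(-D^2 / 2 sigma_s^2) (toroidal D); or,
    when ``footprint`` (receivers x senders nonnegative weights) is given,
    proportional to that footprint instead.  ``self_pairs`` maps receiver row
    -> sender column of the same physical neuron, excluded from sampling.

    Returns COO triplets ``(sender_idx, receiver_idx, multiplicity)``.
    """
    if n_s <= 0:
        raise ValueError("N_S must be positive")
    n_recv = receiver_positions.shape[0]
    n_send = sender_positions.shape[0]
    if n_send == 0:
        raise ValueError("empty candidate sender set")
    if footprint is None:
        d = torus_distance(
            receiver_positions[:, None, :], sender_positions[None, :, :], extent
        )
        prob = np.exp(-(d**2) / (2.0 * sigma_s**2))
    else:
        prob = np.array(footprint, dtype=float)
    if self_pairs is not None:
        prob[self_pairs] = 0.0
    row_sums = prob.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("a receiver has no available senders")
    prob /= row_sums[:, None]
    pre, post, mult = [], [], []
    for r in range(n_recv):
        draws = rng.choice(n_send, size=n_s, replace=True, p=prob[r])
        senders, counts = np.unique(draws, return_counts=True)
        pre.append(senders)
        post.append(np.full(senders.size, r))
        mult.append(counts)
    return np.concatenate(pre), np.concatenate(post), np.concatenate(mult)


def _self_pairs_identity(n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    return idx, idx


def build_v1_network(
    geometry: GridGeometry,
    projections: dict[str, ProjectionParams] | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectivityGraph:
    """Build the four-projection (EE, EI, IE, II) toroidal V1 network.

    Neuron ordering: E cells 0 .. n_exc-1, then I cells.
    """
    if projections is None:
        projections = DEFAULT_V1_PROJECTIONS
    if rng is None:
        rng = np.random.default_rng()
    pos_e = geometry.e_positions()
    pos_i = geometry.i_positions()
    n_e, n_i = geometry.n_exc, geometry.n_inh
    n = n_e + n_i
    rows, cols, vals = [], [], []

    blocks = {
        # projection -> (receiver positions, sender positions, row/col offsets)
        "EE": (pos_e, pos_e, 0, 0, True),
        "EI": (pos_i, pos_e, n_e, 0, False),  # E -> I
        "IE": (pos_e, pos_i, 0, n_e, False),  # I -> E
        "II": (pos_i, pos_i, n_e, n_e, True),
    }
    for name, (rpos, spos, roff, coff, same) in blocks.items():
        p = projections[name]
        self_pairs = _self_pairs_identity(rpos.shape[0]) if same else None
        pre, post, mult = sample_gaussian_connections(
            rpos, spos, p.n_s, p.sigma_s, geometry.extent, rng, self_pairs
        )
        rows.append(post + roff)
        cols.append(pre + coff)
        vals.append(mult * p.g_s)

    w = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_e] = True
    return ConnectivityGraph(
        weights=w,
        is_exc=is_exc,
        area=np.zeros(n, dtype=np.int8),
        positions=np.vstack([pos_e, pos_i]),
        geometry=geometry,
        projections=dict(projections),
    )


def bar_footprint(
    center: np.ndarray,
    sender_positions: np.ndarray,
    extent: float,
    orientation: str,
    sigma_long: float = 10.0,
    sigma_short: float = 2.0,
) -> np.ndarray:
    """Oriented bar-like connection footprint around ``center``.

    An anisotropic Gaussian over toroidal offsets, elongated along the first
    axis for ``"horizontal"`` and along the second for ``"vertical"``.
    The widths are calibration choices that make the footprint resemble the
    oriented-bar drive map.
    """
    d = torus_delta(center[None, :], sender_positions, extent)
    if orientation == "horizontal":
        sx, sy = sigma_long, sigma_short
    elif orientation == "vertical":
        sx, sy = sigma_short, sigma_long
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    return np.exp(-(d[:, 0] ** 2) / (2 * sx**2) - (d[:, 1] ** 2) / (2 * sy**2))


def apply_anisotropy(
    graph: ConnectivityGraph,
    orientation: str,
    scale: float = 3.0,
    center_neuron: int | None = None,
    n_draws: int | None = None,
    sigma_long: float = 10.0,
    sigma_short: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ConnectivityGraph:
    """Anisotropic-connectivity variant: keep only EE connections emerging
    from the centre neuron, redrawn from an oriented bar-like footprint with
    strength scaled by ``scale``; all other projections are untouched.
    """
    if rng is None:
        rng = np.random.default_rng()
    geom = graph.geometry
    n_e = geom.n_exc
    if center_neuron is None:
        center_neuron = geom.center_e_index()
    if not (0 <= center_neuron < n_e):
        raise ValueError("center neuron index out of the excitatory range")
    if n_draws is None:
        n_draws = graph.projections["EE"].n_s
    # drop every EE edge (E senders are columns < n_e, E receivers rows < n_e)
    coo = graph.weights.tocoo()
    keep = ~((coo.row < n_e) & (coo.col < n_e))
    rows = [coo.row[keep]]
    cols = [coo.col[keep]]
    vals = [coo.data[keep]]
    pos_e = geom.e_positions()
    fp = bar_footprint(
        pos_e[center_neuron], pos_e, geom.extent, orientation, sigma_long, sigma_short
    )
    fp[center_neuron] = 0.0
    fp = fp / fp.sum()
    draws = rng.choice(n_e, size=n_draws, replace=True, p=fp)
    targets, counts = np.unique(draws, return_counts=True)
    g_ee = graph.projections["EE"].g_s
    rows.append(targets)
    cols.append(np.full(targets.size, center_neuron))
    vals.append(counts * scale * g_ee)
    w = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=graph.weights.shape,
    ).tocsr()
    out = ConnectivityGraph(
        weights=w,
        is_exc=graph.is_exc.copy(),
        area=graph.area.copy(),
        positions=graph.positions.copy(),
        geometry=geom,
        projections=dict(graph.projections),
    )
    out.projections["EE_anisotropic"] = {
        "orientation": orientation,
        "scale": scale,
        "center": center_neuron,
        "sigma_long": sigma_long,
        "sigma_short": sigma_short,
    }
    return out


@dataclass(frozen=True)
class FeedforwardSpec:
    """V1 -> V2 feedforward wiring.

    ``footprint`` is ``"gaussian"`` (convergent isotropic Gaussian over V1 E
    cells, all V2 neurons sharing the receptive-field centre at the grid
    centre) or ``"uniform"``.
    """

    footprint: str = "gaussian"
    sigma: float = 6.0
    n_s: int = 40
    g_s: float = 0.004
    rf_center: tuple[float, float] | None = None


DEFAULT_V2_PROJECTIONS: dict[str, ProjectionParams] = {
    # local V2 wiring, sampled uniformly (no V2 geometry); sigma unused
    "EE": ProjectionParams(n_s=20, g_s=0.002, sigma_s=1.0),
    "EI": ProjectionParams(n_s=20, g_s=0.004, sigma_s=1.0),
    "IE": ProjectionParams(n_s=10, g_s=0.02, sigma_s=1.0),
    "II": ProjectionParams(n_s=5, g_s=0.01, sigma_s=1.0),
}


def build_v1_v2_network(
    v1_graph: ConnectivityGraph,
    feedforward: FeedforwardSpec | None = None,
    v2_n_e: int = 100,
    v2_n_i: int = 25,
    v2_projections: dict[str, ProjectionParams] | None = None,
    i_feedforward_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> ConnectivityGraph:
    """Append an unstructured V2 population fed by V1 excitatory cells.

    V2 E cells receive convergent feedforward input from V1 E cells (Gaussian
    footprint around a shared RF centre, or uniform); V2 I cells receive a
    ``i_feedforward_fraction`` scaled copy of the same footprint.  V2 wires
    locally with uniform sampling.  There are no V2 -> V1 edges.
    """
    if feedforward is None:
        feedforward = FeedforwardSpec()
    if v2_projections is None:
        v2_projections = DEFAULT_V2_PROJECTIONS
    if rng is None:
        rng = np.random.default_rng()
    geom = v1_graph.geometry
    n1 = v1_graph.n_neurons
    n_v1e = geom.n_exc
    n2 = v2_n_e + v2_n_i
    n = n1 + n2
    pos_e = geom.e_positions()
    if feedforward.rf_center is None:
        center = np.array([geom.extent / 2.0, geom.extent / 2.0])
    else:
        center = np.asarray(feedforward.rf_center, dtype=float)
    if feedforward.footprint == "gaussian":
        if feedforward.sigma > geom.extent / 2.0:
            import warnings

            warnings.warn(
                "feedforward footprint wider than the grid half-period; "
                "wrap-around makes it near-uniform"
            )
        d = torus_distance(center[None, :], pos_e, geom.extent)
        fp_row = np.exp(-(d**2) / (2 * feedforward.sigma**2))
    elif feedforward.footprint == "uniform":
        fp_row = np.ones(n_v1e)
    else:
        raise ValueError("footprint must be 'gaussian' or 'uniform'")
    fp_row = fp_row / fp_row.sum()

    rows, cols, vals = [], [], []
    # feedforward V1 E -> V2 (E then I)
    for k in range(n2):
        draws = rng.choice(n_v1e, size=feedforward.n_s, replace=True, p=fp_row)
        senders, counts = np.unique(draws, return_counts=True)
        g = feedforward.g_s * (1.0 if k < v2_n_e else i_feedforward_fraction)
        rows.append(np.full(senders.size, n1 + k))
        cols.append(senders)
        vals.append(counts * g)
    # local V2 wiring, uniform sampling
    v2e = np.arange(v2_n_e)
    v2i = np.arange(v2_n_i)
    local = {
        "EE": (v2e, v2e, 0, 0, True),
        "EI": (v2i, v2e, v2_n_e, 0, False),
        "IE": (v2e, v2i, 0, v2_n_e, False),
        "II": (v2i, v2i, v2_n_e, v2_n_e, True),
    }
    for name, (recv, send, roff, coff, same) in local.items():
        p = v2_projections[name]
        for r in recv:
            candidates = send.copy()
            if same:
                candidates = candidates[candidates != r]
            draws = rng.choice(candidates, size=p.n_s, replace=True)
            senders, counts = np.unique(draws, return_counts=True)
            rows.append(np.full(senders.size, n1 + roff + r))
            cols.append(n1 + coff + senders)
            vals.append(counts * p.g_s)

    v1_coo = v1_graph.weights.tocoo()
    rows.append(v1_coo.row)
    cols.append(v1_coo.col)
    vals.append(v1_coo.data)
    w = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    is_exc = np.concatenate(
        [
            v1_graph.is_exc,
            np.ones(v2_n_e, dtype=bool),
            np.zeros(v2_n_i, dtype=bool),
        ]
    )
    area = np.concatenate([v1_graph.area, np.ones(n2, dtype=np.int8)])
    positions = np.vstack([v1_graph.positions, np.tile(center, (n2, 1))])
    projections = dict(v1_graph.projections)
    projections["FF"] = feedforward
    projections["V2"] = dict(v2_projections)
    return ConnectivityGraph(
        weights=w,
        is_exc=is_exc,
        area=area,
        positions=positions,
        geometry=geom,
        projections=projections,
    )


def membership_matrix(graph: ConnectivityGraph) -> sp.csr_matrix:
    """Binary S[i, j] = 1 iff V1 E neuron j is presynaptic to V2 neuron i.

    Rows are V2 neurons (E then I, in graph order), columns V1 E neurons.
    """
    v2 = np.flatnonzero(graph.area == 1)
    v1e = graph.v1_exc_indices()
    sub = graph.weights[v2][:, v1e]
    return (sub > 0).astype(np.int8).tocsr()
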