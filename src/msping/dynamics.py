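"""Izhikevich RS/FS network integration with exponential synapses.

Membrane dynamics per neuron i (all in the standard dimensionless Izhikevich
units: V, c, V_rev in mV; time in ms):

    dV/dt = 0.04 V^2 + 5 V + 140 - u + I(t)
    du/dt = a (b V - u)
    ds/dt = -s / tau_syn

with reset on V >= 30 mV: V <- c, u <- u + d, s <- 1.  The total input is
the synaptic current  sum_j s_j g_ij (V_rev,j - V_i)  plus the imposed drive
and a per-step Gaussian noise current with std sqrt(I_imp / SNR).

Integration is classical 4th-order Runge-Kutta at dt = 0.5 ms; the noise
current is sampled once per step and applied to V after the deterministic
update (the noise term is specified as a per-step sample, not a
continuous-time process).  A spike sets the presynaptic gate s <- 1 at the
end of the step, so its postsynaptic effect becomes visible one step later
(a one-step synaptic latency; there are no axonal delays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .connectivity import ConnectivityGraph
from .stimulus import DriveSpec

__all__ = [
    "NeuronParams",
    "NoiseSpec",
    "NetworkState",
    "SpikeRaster",
    "SimulationResult",
    "step_network",
    "run_simulation",
]

V_PEAK = 30.0  # spike detection threshold, mV


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters plus synapse constants for one cell class."""

    a: float
    b: float
    c: float
    d: float
    tau_syn: float
    v_rev: float
    cell_class: str

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")

    @staticmethod
    def rs() -> "NeuronParams":
        """Regular-spiking excitatory cell (AMPA-type synapse, V_rev +50 mV)."""
        return NeuronParams(0.02, 0.2, -65.0, 8.0, 10.0, 50.0, "RS")

    @staticmethod
    def fs() -> "NeuronParams":
        """Fast-spiking inhibitory cell (GABA-A-type synapse, V_rev -90 mV)."""
        return NeuronParams(0.1, 0.2, -65.0, 2.0, 5.0, -90.0, "FS")


@dataclass
class NoiseSpec:
    """Per-step Gaussian current noise on the imposed input.

    ``snr_factor`` scales the noise down (std = sqrt(max(I_imp, 0) /
    snr_factor) under the default ``variant="variance"``); ``np.inf``
    disables noise.  ``variant="amplitude"`` uses the alternative reading
    std = sqrt(max(I_imp, 0)) / snr_factor.
    """

    snr_factor: float = 2.0
    rng_seed: int | None = None
    variant: str = "variance"

    def __post_init__(self) -> None:
        if not self.snr_factor > 0:
            raise ValueError("snr_factor must be positive")
        if self.variant not in ("variance", "amplitude"):
            raise ValueError("variant must be 'variance' or 'amplitude'")

    def std(self, i_imp: np.ndarray) -> np.ndarray:
        if np.isinf(self.snr_factor):
            return np.zeros_like(i_imp)
        pos = np.maximum(i_imp, 0.0)
        if self.variant == "variance":
            return np.sqrt(pos / self.snr_factor)
        return np.sqrt(pos) / self.snr_factor


@dataclass
class NetworkState:
    """Instantaneous state of every neuron."""

    v: np.ndarray
    u: np.ndarray
    s: np.ndarray
    t: float = 0.0

    @staticmethod
    def resting(graph: ConnectivityGraph) -> "NetworkState":
        rs, fs = NeuronParams.rs(), NeuronParams.fs()
        n = graph.n_neurons
        v = np.full(n, rs.c)
        b = np.where(graph.is_exc, rs.b, fs.b)
        return NetworkState(v=v, u=b * v, s=np.zeros(n), t=0.0)


@dataclass
class SpikeRaster:
    """Spike events as parallel (neuron_id, time) arrays."""

    neuron_ids: np.ndarray
    times: np.ndarray
    duration: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if self.times.min() <= 0 or self.times.max() > self.duration:
                raise ValueError("spike times must lie strictly within (0, duration]")
            if self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n_neurons:
                raise ValueError("neuron id out of range")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def subset(self, neuron_indices: np.ndarray) -> "SpikeRaster":
        """Raster restricted to a neuron subset, ids renumbered to 0..k-1."""
        neuron_indices = np.asarray(neuron_indices)
        lookup = -np.ones(self.n_neurons, dtype=np.int64)
        lookup[neuron_indices] = np.arange(neuron_indices.size)
        keep = lookup[self.neuron_ids] >= 0
        return SpikeRaster(
            lookup[self.neuron_ids[keep]],
            self.times[keep],
            self.duration,
            neuron_indices.size,
        )

    def counts(self, dt: float) -> np.ndarray:
        """Spike-count matrix (n_neurons, n_bins) with bin width dt ms."""
        n_bins = int(round(self.duration / dt))
        bins = np.minimum((self.times / dt - 1e-9).astype(np.int64), n_bins - 1)
        mat = np.zeros((self.n_neurons, n_bins), dtype=np.float32)
        np.add.at(mat, (self.neuron_ids, bins), 1.0)
        return mat

    def rates(self, t_start: float = 0.0, t_stop: float | None = None) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over [t_start, t_stop]."""
        if t_stop is None:
            t_stop = self.duration
        mask = (self.times > t_start) & (self.times <= t_stop)
        out = np.bincount(self.neuron_ids[mask], minlength=self.n_neurons)
        return out / ((t_stop - t_start) / 1000.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.neuron_ids, "time_ms": self.times})


class _CompiledNetwork:
    """Per-neuron parameter arrays and class-split weight matrices.

    The synaptic reversal potential depends only on the presynaptic class, so
    the synaptic current factorises into an excitatory and an inhibitory
    conductance term, each a single sparse mat-vec per RK stage.
    """

    def __init__(self, graph: ConnectivityGraph):
        rs, fs = NeuronParams.rs(), NeuronParams.fs()
        e = graph.is_exc
        self.n = graph.n_neurons
        self.a = np.where(e, rs.a, fs.a)
        self.b = np.where(e, rs.b, fs.b)
        self.c = np.where(e, rs.c, fs.c)
        self.d = np.where(e, rs.d, fs.d)
        self.inv_tau = np.where(e, 1.0 / rs.tau_syn, 1.0 / fs.tau_syn)
        self.v_rev_e = rs.v_rev
        self.v_rev_i = fs.v_rev
        self.exc_idx = np.flatnonzero(e)
        self.inh_idx = np.flatnonzero(~e)
        w = graph.weights.tocsc()
        self.w_exc = w[:, self.exc_idx].tocsr()
        self.w_inh = w[:, self.inh_idx].tocsr()

    def syn_current(self, v: np.ndarray, s: np.ndarray) -> np.ndarray:
        ge = self.w_exc @ s[self.exc_idx]
        gi = self.w_inh @ s[self.inh_idx]
        return ge * (self.v_rev_e - v) + gi * (self.v_rev_i - v)

    def deriv(self, v, u, s, i_imp):
        i_total = self.syn_current(v, s) + i_imp
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_total
        du = self.a * (self.b * v - u)
        ds = -s * self.inv_tau
        return dv, du, ds


def _get_compiled(graph: ConnectivityGraph) -> _CompiledNetwork:
    cached = getattr(graph, "_compiled", None)
    if cached is None:
        cached = _CompiledNetwork(graph)
        graph._compiled = cached
    return cached


def step_network(
    state: NetworkState,
    graph: ConnectivityGraph,
    drive_current: np.ndarray,
    noise: NoiseSpec | None = None,
    dt: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the network one RK4 step; returns (new state, spiker indices).

    ``drive_current`` is the full imposed current J_i * sigma(t) for this
    step.  Spike detection (V >= 30 mV) happens after the step completes;
    spikers are reset (V <- c, u <- u + d, s <- 1) and their gate update is
    seen by postsynaptic targets from the next step on.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    net = _get_compiled(graph)
    v, u, s = state.v, state.u, state.s
    i_imp = np.asarray(drive_current, dtype=float)

    k1 = net.deriv(v, u, s, i_imp)
    k2 = net.deriv(v + 0.5 * dt * k1[0], u + 0.5 * dt * k1[1], s + 0.5 * dt * k1[2], i_imp)
    k3 = net.deriv(v + 0.5 * dt * k2[0], u + 0.5 * dt * k2[1], s + 0.5 * dt * k2[2], i_imp)
    k4 = net.deriv(v + dt * k3[0], u + dt * k3[1], s + dt * k3[2], i_imp)
    v_new = v + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    u_new = u + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    s_new = s + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

    if noise is not None and not np.isinf(noise.snr_factor):
        if rng is None:
            rng = np.random.default_rng(noise.rng_seed)
        v_new = v_new + noise.std(i_imp) * rng.standard_normal(v.size) * dt

    spiked = np.flatnonzero(v_new >= V_PEAK)
    if spiked.size:
        v_new[spiked] = net.c[spiked]
        u_new[spiked] = u_new[spiked] + net.d[spiked]
        s_new[spiked] = 1.0
    if not (np.all(np.isfinite(v_new)) and np.all(np.isfinite(u_new))):
        raise RuntimeError(
            "integration blow-up: non-finite membrane state "
            f"at t = {state.t + dt:.2f} ms"
        )
    return NetworkState(v=v_new, u=u_new, s=s_new, t=state.t + dt), spiked


@dataclass
class SimulationResult:
    raster: SpikeRaster
    times: np.ndarray
    traces: np.ndarray | None = None
    trace_ids: np.ndarray | None = None
    lfp: np.ndarray | None = None
    n_resets: int = 0
    meta: dict = field(default_factory=dict)


def run_simulation(
    graph: ConnectivityGraph,
    drive: DriveSpec,
    duration: float,
    noise: NoiseSpec | None = None,
    dt: float = 0.5,
    record: np.ndarray | str | None = None,
    lfp_weights: sp.spmatrix | None = None,
    state: NetworkState | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration`` ms.

    ``record`` selects membrane-potential traces: ``"exc"`` for all V1
    excitatory cells, an index array, or None.  ``lfp_weights`` (n_channels x
    n_recorded_exc sparse) accumulates the virtual-electrode LFP online so
    full traces need not be stored.  Deterministic given (graph, drive, seed,
    dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = graph.n_neurons
    n_steps = int(round(duration / dt))
    if drive.j.size != n:
        raise ValueError("drive J length does not match network size")
    if drive.modulation.size < n_steps:
        raise ValueError("modulation series shorter than the simulation")
    if state is None:
        state = NetworkState.resting(graph)
    if isinstance(record, str):
        if record != "exc":
            raise ValueError("record must be 'exc', an index array, or None")
        record_ids = graph.v1_exc_indices()
    elif record is not None:
        record_ids = np.asarray(record, dtype=np.int64)
        if record_ids.size and (record_ids.min() < 0 or record_ids.max() >= n):
            raise ValueError("recording channel out of range")
    else:
        record_ids = None
    if rng is None and noise is not None:
        rng = np.random.default_rng(noise.rng_seed)

    traces = (
        np.empty((record_ids.size, n_steps), dtype=np.float32)
        if record_ids is not None
        else None
    )
    lfp = None
    lfp_exc = None
    if lfp_weights is not None:
        lfp_weights = sp.csr_matrix(lfp_weights)
        lfp_exc = graph.v1_exc_indices()
        if lfp_weights.shape[1] != lfp_exc.size:
            raise ValueError("lfp_weights column count must match V1 E population")
        lfp = np.empty((lfp_weights.shape[0], n_steps), dtype=np.float32)

    spike_ids: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []
    n_resets = 0
    for step in range(n_steps):
        i_imp = drive.current_at(step)
        state, spiked = step_network(state, graph, i_imp, noise, dt, rng)
        if spiked.size:
            spike_ids.append(spiked.astype(np.int32))
            spike_steps.append(np.full(spiked.size, step, dtype=np.int64))
            n_resets += spiked.size
        if traces is not None:
            traces[:, step] = state.v[record_ids]
        if lfp is not None:
            lfp[:, step] = lfp_weights @ state.v[lfp_exc]

    if spike_ids:
        ids = np.concatenate(spike_ids)
        times = (np.concatenate(spike_steps) + 1) * dt
    else:
        ids = np.empty(0, dtype=np.int32)
        times = np.empty(0)
    raster = SpikeRaster(ids, times, duration, n)
    return SimulationResult(
        raster=raster,
        times=(np.arange(n_steps) + 1) * dt,
        traces=traces,
        trace_ids=record_ids,
        lfp=lfp,
        n_resets=n_resets,
        meta={"dt": dt, "duration": duration},
    )
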