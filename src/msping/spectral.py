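"""MS-triggered spectral analysis: time-frequency power, phase extraction,
across-saccade phase locking (PLV) and its correlates.

All analyses are event locked: the LFP is cut into epochs around each MS
onset and short-time Fourier transforms (Hann window, zero padded) are
evaluated on a sliding grid of window centres expressed in time relative to
MS onset.  The PLV between channels x and y at a (frequency, time) bin is

    PLV = | (1/N) sum_n exp(i (phi_n,y - phi_n,x)) |

over the N saccades, i.e. the modulus of the mean unit phasor of the
per-saccade phase differences; the mean phase difference is the argument of
the same sum.  PLV is 0 for inconsistent and 1 for perfectly consistent
phase differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .lfp import LFPRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TFR",
    "SaccadeLockedSpectra",
    "ms_triggered_tfr",
    "stft_epochs",
    "extract_phase",
    "plv_across_saccades",
    "pairwise_plv",
    "plv_vs_distance",
    "plv_vs_input_difference",
    "window_average",
    "correlation_map",
    "window_correlation_test",
]

TRANSIENT_WINDOW = (0.0, 100.0)  # ms post-MS
SUSTAINED_WINDOW = (150.0, 350.0)
GAMMA_BAND = (25.0, 40.0)  # Hz


@dataclass
class TFR:
    """MS-triggered time-frequency power, averaged across saccades."""

    power: np.ndarray  # (n_channels, n_freq, n_time)
    freqs: np.ndarray
    times: np.ndarray  # ms relative to MS onset
    window_ms: float
    n_saccades: int

    def band_time_average(self, band: tuple, window: tuple) -> np.ndarray:
        """Mean power per channel in a frequency band x time window."""
        fsel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        tsel = (self.times >= window[0]) & (self.times <= window[1])
        return self.power[:, fsel][:, :, tsel].mean(axis=(1, 2))

    def ridge_frequency(self, window: tuple | None = None) -> np.ndarray:
        """Frequency of maximal channel-averaged power per time bin."""
        p = self.power.mean(axis=0)
        if window is not None:
            tsel = (self.times >= window[0]) & (self.times <= window[1])
            p = p[:, tsel]
        return self.freqs[np.argmax(p, axis=0)]


@dataclass
class SaccadeLockedSpectra:
    """Per-pair, per-frequency, per-time PLV and mean phase difference."""

    plv: np.ndarray  # (n_pairs, n_freq, n_time)
    theta: np.ndarray  # mean phase difference, (-pi, pi]
    freqs: np.ndarray
    times: np.ndarray
    pairs: np.ndarray  # (n_pairs, 2) channel indices
    n_saccades: int


def _epoch_matrix(
    signal: np.ndarray,
    onsets: np.ndarray,
    dt: float,
    start_ms: float,
    stop_ms: float,
) -> np.ndarray:
    """Cut (n_sacc, n_samp) epochs; epochs outside the recording are dropped."""
    n = signal.shape[-1]
    i0 = np.round(np.asarray(onsets) / dt).astype(int) + int(round(start_ms / dt))
    n_samp = int(round((stop_ms - start_ms) / dt))
    keep = (i0 >= 0) & (i0 + n_samp <= n)
    dropped = np.count_nonzero(~keep)
    if dropped:
        logger.info("dropped %d epochs extending beyond the recording", dropped)
    idx = i0[keep][:, None] + np.arange(n_samp)[None, :]
    return signal[..., idx] if signal.ndim > 1 else signal[idx]


def stft_epochs(
    signal: np.ndarray,
    onsets: np.ndarray,
    dt: float,
    window_ms: float = 150.0,
    hop_ms: float = 10.0,
    pad_to: int = 1024,
    freq_range: tuple = (5.0, 80.0),
    t_pre: float = 50.0,
    t_post: float = 400.0,
    demean_evoked: bool = False,
    detrend: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-locked sliding-window Fourier coefficients of one channel.

    Returns ``(coeffs, freqs, times)`` with ``coeffs`` complex of shape
    (n_saccades, n_freq, n_time); ``times`` are window centres in ms
    relative to MS onset, covering [-t_pre, t_post].  ``demean_evoked``
    subtracts the across-saccade mean epoch (the deterministic MS-locked
    evoked component) before the transform, leaving induced activity.
    ``detrend`` removes a linear fit from every window segment before
    tapering, so the large slow MS-evoked depolarisation does not leak
    through the window mainlobe into the oscillation bands.
    """
    fs = 1000.0 / dt
    w_samp = int(round(window_ms / dt))
    if pad_to < w_samp:
        raise ValueError("pad_to shorter than the window")
    freqs_all = np.fft.rfftfreq(pad_to, d=1.0 / fs)
    fsel = (freqs_all >= freq_range[0]) & (freqs_all <= freq_range[1])
    if not np.any(fsel):
        raise ValueError("frequency range outside the resolvable band")
    centers = np.arange(-t_pre, t_post + hop_ms / 2, hop_ms)
    # epochs with margin so every window is fully supported
    margin = window_ms / 2.0
    epochs = _epoch_matrix(signal, onsets, dt, -t_pre - margin, t_post + margin)
    if epochs.shape[0] < 2:
        raise ValueError("need at least 2 usable saccade epochs")
    if demean_evoked:
        epochs = epochs - epochs.mean(axis=0, keepdims=True)
    # sliding windows: start index of each centre within the padded epoch
    starts = np.round((centers + t_pre + margin - window_ms / 2.0) / dt).astype(int)
    win = scipy.signal.windows.hann(w_samp, sym=False)
    segs = epochs[:, starts[:, None] + np.arange(w_samp)[None, :]]  # (n_sacc, n_t, w)
    if detrend:
        segs = scipy.signal.detrend(segs, axis=-1, type="linear")
    spec = np.fft.rfft(segs * win, n=pad_to, axis=-1)[..., fsel]
    coeffs = np.transpose(spec, (0, 2, 1)).astype(np.complex64)
    return coeffs, freqs_all[fsel], centers


def bandpoint_coeffs(
    signals: np.ndarray,
    onsets: np.ndarray,
    dt: float,
    freq: float,
    window_ms: float = 50.0,
    hop_ms: float = 10.0,
    t_pre: float = 50.0,
    t_post: float = 400.0,
    detrend: bool = True,
    chunk: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked Hann-windowed Fourier coefficient at one frequency.

    Vectorised over many signals (rows): returns ``(coeffs, times)`` with
    ``coeffs`` complex of shape (n_signals, n_saccades, n_time).  Used for
    dense per-neuron phase maps where a full spectrum per channel would be
    wasteful.
    """
    signals = np.atleast_2d(signals)
    w_samp = int(round(window_ms / dt))
    centers = np.arange(-t_pre, t_post + hop_ms / 2, hop_ms)
    margin = window_ms / 2.0
    win = scipy.signal.windows.hann(w_samp, sym=False)
    phasor = win * np.exp(-2j * np.pi * freq * np.arange(w_samp) * dt / 1000.0)
    starts = np.round((centers + t_pre + margin - window_ms / 2.0) / dt).astype(int)
    sl = starts[:, None] + np.arange(w_samp)[None, :]
    out = None
    for lo in range(0, signals.shape[0], chunk):
        epochs = _epoch_matrix(signals[lo : lo + chunk], onsets, dt,
                               -t_pre - margin, t_post + margin)
        segs = epochs[:, :, sl]  # (chunk, n_sacc, n_t, w)
        if detrend:
            segs = scipy.signal.detrend(segs, axis=-1, type="linear")
        c = segs @ phasor
        if out is None:
            out = np.empty((signals.shape[0],) + c.shape[1:], dtype=np.complex64)
        out[lo : lo + chunk] = c
    return out, centers


def ms_triggered_tfr(
    lfp: LFPRecord,
    onsets: np.ndarray,
    window_ms: float = 150.0,
    hop_ms: float = 10.0,
    pad_to: int = 1024,
    freq_range: tuple = (5.0, 80.0),
    t_pre: float = 50.0,
    t_post: float = 400.0,
    channels: np.ndarray | None = None,
) -> TFR:
    """MS-triggered TFR: per-channel spectral power averaged across saccades."""
    if channels is None:
        channels = np.arange(lfp.n_channels)
    power = None
    n_sacc = 0
    for k, ch in enumerate(channels):
        coeffs, freqs, times = stft_epochs(
            lfp.data[ch], onsets, lfp.dt, window_ms, hop_ms, pad_to,
            freq_range, t_pre, t_post,
        )
        n_sacc = coeffs.shape[0]
        p = (np.abs(coeffs) ** 2).mean(axis=0)
        if power is None:
            power = np.empty((len(channels),) + p.shape, dtype=np.float64)
        power[k] = p
    return TFR(power=power, freqs=freqs, times=times, window_ms=window_ms,
               n_saccades=n_sacc)


def extract_phase(
    signal: np.ndarray,
    dt: float,
    onsets: np.ndarray | None = None,
    method: str = "stft",
    band: tuple = GAMMA_BAND,
    **kwargs,
) -> np.ndarray:
    """Instantaneous phase in (-pi, pi].

    ``method="stft"`` returns per-frequency phases of event-locked sliding
    Fourier coefficients (requires ``onsets``); ``method="analytic"``
    band-passes the whole signal (4th-order Butterworth, zero phase) and
    returns the analytic-signal phase on the raw time grid.
    """
    fs = 1000.0 / dt
    if method == "stft":
        if onsets is None:
            raise ValueError("stft phase extraction requires MS onsets")
        coeffs, _, _ = stft_epochs(signal, onsets, dt, **kwargs)
        return np.angle(coeffs)
    if method == "analytic":
        nyq = fs / 2.0
        if band[1] >= nyq:
            raise ValueError("band edge at or above Nyquist")
        sos = scipy.signal.butter(4, [band[0] / nyq, band[1] / nyq],
                                  btype="band", output="sos")
        filtered = scipy.signal.sosfiltfilt(sos, signal)
        return np.angle(scipy.signal.hilbert(filtered))
    raise ValueError("method must be 'stft' or 'analytic'")


def _unit(z: np.ndarray) -> np.ndarray:
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    return z / mag


def plv_across_saccades(
    phases_x: np.ndarray,
    phases_y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """PLV and mean phase difference across saccades for one channel pair.

    Inputs are per-saccade phase arrays of identical shape with saccades on
    axis 0.  Returns (plv, theta) over the remaining axes; PLV in [0, 1],
    theta = arg of the mean phasor in (-pi, pi].
    """
    phases_x = np.asarray(phases_x)
    phases_y = np.asarray(phases_y)
    if phases_x.shape != phases_y.shape:
        raise ValueError("phase arrays must have identical shapes")
    if phases_x.shape[0] < 2:
        raise ValueError("PLV requires at least 2 saccades")
    z = np.exp(1j * (phases_y - phases_x)).mean(axis=0)
    return np.abs(z), np.angle(z)


def pairwise_plv(
    coeffs: np.ndarray,
    pairs: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    chunk: int = 256,
) -> SaccadeLockedSpectra:
    """Across-saccade PLV for many channel pairs from complex coefficients.

    ``coeffs`` is (n_channels, n_saccades, n_freq, n_time) complex; ``pairs``
    an (n_pairs, 2) index array.  Phase differences use the unit phasors of
    the coefficients, so amplitude plays no role.
    """
    pairs = np.asarray(pairs)
    if coeffs.shape[1] < 2:
        raise ValueError("PLV requires at least 2 saccades")
    u = _unit(coeffs)
    n_pairs = pairs.shape[0]
    plv = np.empty((n_pairs,) + coeffs.shape[2:], dtype=np.float32)
    theta = np.empty_like(plv)
    for lo in range(0, n_pairs, chunk):
        sel = pairs[lo : lo + chunk]
        z = (u[sel[:, 1]] * np.conj(u[sel[:, 0]])).mean(axis=1)
        plv[lo : lo + chunk] = np.abs(z)
        theta[lo : lo + chunk] = np.angle(z)
    return SaccadeLockedSpectra(
        plv=plv, theta=theta, freqs=np.asarray(freqs), times=np.asarray(times),
        pairs=pairs, n_saccades=coeffs.shape[1],
    )


def window_average(
    spectra: SaccadeLockedSpectra,
    band: tuple = GAMMA_BAND,
    window: tuple = SUSTAINED_WINDOW,
    what: str = "plv",
) -> np.ndarray:
    """Per-pair mean PLV (or circular-mean phase) in a band x time window."""
    fsel = (spectra.freqs >= band[0]) & (spectra.freqs <= band[1])
    tsel = (spectra.times >= window[0]) & (spectra.times <= window[1])
    if what == "plv":
        return spectra.plv[:, fsel][:, :, tsel].mean(axis=(1, 2))
    if what == "theta":
        z = np.exp(1j * spectra.theta[:, fsel][:, :, tsel]).mean(axis=(1, 2))
        return np.angle(z)
    raise ValueError("what must be 'plv' or 'theta'")


def correlation_map(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson correlation across pairs for every (freq, time) bin.

    ``values`` is (n_pairs, n_freq, n_time), ``x`` a per-pair covariate.
    Bins where the values are constant across pairs return 0.
    """
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValueError("degenerate covariate: no variance across pairs")
    xc = x - x.mean()
    v = values - values.mean(axis=0, keepdims=True)
    num = np.tensordot(xc, v, axes=(0, 0))
    den = np.sqrt((xc**2).sum()) * np.sqrt((v**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def plv_vs_distance(
    spectra: SaccadeLockedSpectra,
    pair_table,
) -> np.ndarray:
    """Correlation between electrode distance and PLV per (freq, time) bin."""
    d = pair_table["distance"].to_numpy()
    return correlation_map(spectra.plv, d)


def plv_vs_input_difference(
    spectra: SaccadeLockedSpectra,
    electrode_input: np.ndarray,
    pair_table,
    max_pair_distance: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation between per-pair input difference and PLV.

    ``electrode_input`` is the LFP-kernel-weighted mean drive under each
    electrode; the per-pair input difference is its absolute difference.
    Only pairs within ``max_pair_distance`` E-cell units are used (the
    default, 8 units, is 4 inter-I-neuron distances); beyond that sustained
    synchrony is absent and the pair carries no usable signal.

    Returns ``(corr_map, pair_mask)``.
    """
    plv = spectra.plv if hasattr(spectra, "plv") else np.asarray(spectra)
    d = pair_table["distance"].to_numpy()
    mask = d <= max_pair_distance
    if not np.any(mask):
        raise ValueError("all pairs filtered out by the distance cut")
    a = pair_table["a"].to_numpy()[mask]
    b = pair_table["b"].to_numpy()[mask]
    dj = np.abs(electrode_input[a] - electrode_input[b])
    if np.std(dj) == 0:
        warnings.warn("uniform input: input differences all zero, returning zeros")
        return np.zeros(plv.shape[1:]), mask
    return correlation_map(plv[mask], dj), mask


def window_correlation_test(
    values: np.ndarray,
    x: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    alternative: str = "less",
) -> tuple[float, float]:
    """Permutation test for the across-pair correlation of a window average.

    ``values`` is a per-pair scalar (e.g. gamma-band sustained-window mean
    PLV); pair labels of ``x`` are permuted.  Returns (r, p).
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.std(x) == 0 or np.std(values) == 0:
        return 0.0, 1.0
    r_obs = float(np.corrcoef(x, values)[0, 1])
    perm = np.empty(n_permutations)
    for k in range(n_permutations):
        perm[k] = np.corrcoef(rng.permutation(x), values)[0, 1]
    if alternative == "less":
        p = (1 + np.count_nonzero(perm <= r_obs)) / (n_permutations + 1)
    elif alternative == "greater":
        p = (1 + np.count_nonzero(perm >= r_obs)) / (n_permutations + 1)
    else:
        p = (1 + np.count_nonzero(np.abs(perm) >= abs(r_obs))) / (n_permutations + 1)
    return r_obs, float(p)
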