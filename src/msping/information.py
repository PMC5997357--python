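"""Feedforward information transfer: synaptically confined spike-triggered
averages (synSTA) and the mutual-information decomposition of what predicts
them.

The synSTA estimates the effective (functional) receptive field of a V2
neuron: using V2 spikes as triggers, it measures the probability that each
*anatomically presynaptic* V1 neuron spiked in a short pre-trigger lag
window ([-8, -2] ms by default), normalised by the trigger count and
averaged over the lag bins.  A shuffle correction — the same statistic with
an equal number of random trigger times drawn in the same analysis period —
removes the rate-driven baseline, so independent pre/post activity gives a
corrected synSTA of 0 in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dynamics import SpikeRaster

__all__ = [
    "SynSTAMap",
    "syn_sta",
    "shuffle_correct",
    "mutual_information",
    "mi_bias_threshold",
    "coding_scheme_analysis",
]

LAG_WINDOW = (-8.0, -2.0)  # ms, pre-trigger


@dataclass
class SynSTAMap:
    """Shuffle-corrected pre-spike V1 spike probability per (V2, V1) pair.

    ``values[i, j]`` is defined only where ``mask[i, j]`` (V1 neuron j
    presynaptic to V2 neuron i); other entries are NaN.  ``raw`` and
    ``shuffled`` keep the uncorrected components.
    """

    values: np.ndarray
    raw: np.ndarray
    shuffled: np.ndarray
    mask: np.ndarray
    n_triggers: np.ndarray
    lag_window: tuple
    period_label: str = ""

    def neuron_profile(self, v2_weights: np.ndarray | None = None) -> np.ndarray:
        """Per-V1-neuron synSTA pooled over V2 neurons (trigger-weighted)."""
        w = self.n_triggers if v2_weights is None else v2_weights
        num = np.nansum(self.values * self.mask * w[:, None], axis=0)
        den = (self.mask * w[:, None]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def _windowed_counts(
    counts: np.ndarray, dt: float, lag_window: tuple
) -> tuple[np.ndarray, int]:
    """Mean pre-trigger spike count per lag bin, aligned to trigger bins.

    ``out[j, t]`` is the average of ``counts[j, t + lag]`` over the discrete
    lags spanning ``lag_window`` (inclusive ends on the dt grid).
    """
    lo = int(round(lag_window[0] / dt))
    hi = int(round(lag_window[1] / dt))
    lags = np.arange(lo, hi + 1)  # negative offsets
    n_lags = lags.size
    out = np.zeros_like(counts, dtype=np.float64)
    n_bins = counts.shape[1]
    for lag in lags:
        # counts at t + lag contribute to trigger bin t
        out[:, -lag:] += counts[:, : n_bins + lag]
    return out / n_lags, n_lags


def _sta_from_triggers(
    windowed: np.ndarray, triggers: np.ndarray, n_triggers: np.ndarray
) -> np.ndarray:
    """STA matrix (n_v2, n_v1) from trigger-count matrix (n_v2, n_bins)."""
    num = triggers @ windowed.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_triggers[:, None] > 0, num / np.maximum(n_triggers, 1)[:, None], np.nan)


def syn_sta(
    v1_raster: SpikeRaster,
    v2_raster: SpikeRaster,
    presyn_mask: np.ndarray | sp.spmatrix,
    period_mask: np.ndarray,
    dt: float = 0.5,
    lag_window: tuple = LAG_WINDOW,
    shuffle: bool = True,
    n_shuffles: int = 10,
    rng: np.random.Generator | None = None,
    period_label: str = "",
) -> SynSTAMap:
    """Shuffle-corrected synaptically confined STA.

    ``presyn_mask[i, j]`` flags V1 neuron j as presynaptic to V2 neuron i;
    ``period_mask`` is a boolean over time bins restricting the triggers
    (e.g. the sustained windows of every MS interval).  V2 neurons without
    any trigger in the mask yield NaN rows.
    """
    if sp.issparse(presyn_mask):
        presyn_mask = np.asarray(presyn_mask.todense())
    presyn_mask = np.asarray(presyn_mask, dtype=bool)
    n_v2, n_v1 = presyn_mask.shape
    if n_v1 != v1_raster.n_neurons or n_v2 != v2_raster.n_neurons:
        raise ValueError("presyn mask shape does not match the rasters")
    counts1 = v1_raster.counts(dt)
    counts2 = v2_raster.counts(dt)
    period_mask = np.asarray(period_mask, dtype=bool)
    if period_mask.size != counts1.shape[1]:
        raise ValueError("period mask length does not match the time axis")
    windowed, _ = _windowed_counts(counts1, dt, lag_window)

    triggers = counts2 * period_mask[None, :]
    n_trig = triggers.sum(axis=1)
    raw = _sta_from_triggers(windowed, triggers, n_trig)

    if shuffle:
        shuffled = shuffle_correct(
            windowed, n_trig, period_mask, n_shuffles=n_shuffles, rng=rng
        )
    else:
        shuffled = np.zeros_like(raw)
    values = raw - shuffled
    values[~presyn_mask] = np.nan
    return SynSTAMap(
        values=values,
        raw=raw,
        shuffled=shuffled,
        mask=presyn_mask,
        n_triggers=n_trig,
        lag_window=lag_window,
        period_label=period_label,
    )


def shuffle_correct(
    windowed: np.ndarray,
    n_triggers: np.ndarray,
    period_mask: np.ndarray,
    n_shuffles: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expected STA under random triggers drawn inside the period mask.

    For each V2 neuron the same number of triggers as real spikes is drawn
    uniformly (with replacement) from the masked bins, ``n_shuffles`` times,
    and the resulting STA is averaged.  Deterministic under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng()
    allowed = np.flatnonzero(period_mask)
    n_v2 = n_triggers.size
    out = np.zeros((n_v2, windowed.shape[0]))
    for _ in range(n_shuffles):
        trig = np.zeros((n_v2, windowed.shape[1]), dtype=np.float32)
        for i, k in enumerate(n_triggers.astype(int)):
            if k > 0:
                bins = rng.choice(allowed, size=k, replace=True)
                np.add.at(trig[i], bins, 1.0)
        out += _sta_from_triggers(windowed, trig, n_triggers)
    return out / n_shuffles


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a normalised histogram."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 8,
) -> tuple[float, float]:
    """Histogram mutual information I(X;Y) in bits and normalised by H(X).

    Equal-width binning over the observed range of each variable.  A
    constant series has zero entropy; the normalised MI is then defined
    as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        return 0.0, 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    h_x = entropy_bits(px)
    h_y = entropy_bits(py)
    h_xy = entropy_bits(joint.ravel())
    mi = max(h_x + h_y - h_xy, 0.0)
    return mi, (mi / h_x if h_x > 0 else 0.0)


def mi_bias_threshold(n_samples: int, n_bins: int) -> float:
    """First-order small-sample bias of histogram MI, (B-1)^2 / (2 N ln 2)."""
    return (n_bins - 1) ** 2 / (2.0 * n_samples * np.log(2))


def coding_scheme_analysis(
    records: pd.DataFrame,
    predictors: tuple = ("rate", "synchrony", "phase"),
    target: str = "synsta",
    n_bins: int = 8,
) -> pd.DataFrame:
    """Normalised MI between the synSTA and each candidate coding variable.

    ``records`` pools per-(stimulus, V1 neuron) rows with columns for the
    target and the predictors, plus a ``period`` column ({"transient",
    "sustained"}).  Returns a tidy table with MI, normalised MI, sample
    count and the small-sample bias threshold.
    """
    if "period" not in records:
        raise ValueError("records must carry a 'period' column")
    n_stimuli = records["stimulus"].nunique() if "stimulus" in records else 1
    if n_stimuli < 2:
        import warnings

        warnings.warn("fewer than 2 stimuli: MI estimates may be unreliable")
    rows = []
    for period, sub in records.groupby("period"):
        x = sub[target].to_numpy()
        for pred in predictors:
            if pred not in sub:
                continue
            mi, nmi = mutual_information(x, sub[pred].to_numpy(), n_bins)
            rows.append(
                {
                    "period": period,
                    "predictor": pred,
                    "mi_bits": mi,
                    "normalized_mi": nmi,
                    "n": len(sub),
                    "bias_threshold": mi_bias_threshold(len(sub), n_bins),
                }
            )
    return pd.DataFrame(rows)
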