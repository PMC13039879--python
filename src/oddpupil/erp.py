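"""Epoch-level ERP feature extraction: MMN and P3a.

MMN is the negative peak of the fronto-central cluster (FC1, FC2, FCz,
Fz) in 100-150 ms post-onset; P3a is the positive peak of the central
cluster (Cz, FCz) in 150-250 ms.  Amplitude is the mean within +/-4 ms
of the peak sample; latency is the peak time.  Epochs carry a 500 ms
pre-stimulus baseline and are low-pass filtered at 30 Hz with a
zero-phase Butterworth filter before extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

MMN_CLUSTER = ("FC1", "FC2", "FCz", "Fz")
P3A_CLUSTER = ("Cz", "FCz")
MMN_WINDOW_MS = (100.0, 150.0)
P3A_WINDOW_MS = (150.0, 250.0)
PEAK_MEAN_HALFWIDTH_MS = 4.0


@dataclass
class Epoch:
    """Channels x time segment of EEG around one stimulus."""

    channels: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples), microvolts
    rate: float  # Hz
    tmin_ms: float = -500.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.tmin_ms + np.arange(self.data.shape[1]) * 1000.0 / self.rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


@dataclass
class ErpFeatures:
    mmn_amp: float
    mmn_lat: float
    p3a_amp: float
    p3a_lat: float


@lru_cache(maxsize=16)
def _butter_sos(order: int, cutoff_hz: float, rate: float) -> np.ndarray:
    return signal.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")


def lowpass_epoch(epoch: Epoch, cutoff_hz: float = 30.0, order: int = 4) -> Epoch:
    """Zero-phase Butterworth low-pass per channel (forward-backward)."""
    if cutoff_hz >= epoch.rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({epoch.rate / 2} Hz)"
        )
    sos = _butter_sos(order, float(cutoff_hz), float(epoch.rate))
    filtered = signal.sosfiltfilt(sos, epoch.data, axis=-1)
    return Epoch(epoch.channels, filtered, epoch.rate, epoch.tmin_ms)


def baseline_epoch(
    epoch: Epoch, window_ms: tuple[float, float] = (-500.0, 0.0)
) -> Epoch:
    """Subtract the per-channel mean over the pre-stimulus window."""
    t = epoch.t
    mask = (t >= window_ms[0]) & (t < window_ms[1])
    if not mask.any():
        raise ValueError("baseline window not covered by epoch")
    baseline = epoch.data[:, mask].mean(axis=1, keepdims=True)
    return Epoch(epoch.channels, epoch.data - baseline, epoch.rate, epoch.tmin_ms)


def cluster_waveform(epoch: Epoch, channels: tuple[str, ...]) -> np.ndarray:
    """Pointwise mean over the named channels."""
    missing = [c for c in channels if c not in epoch.channels]
    if missing:
        raise KeyError(f"channels not present in epoch: {missing}")
    idx = [epoch.channels.index(c) for c in channels]
    return epoch.data[idx].mean(axis=0)


def _windowed_peak(
    waveform: np.ndarray,
    rate: float,
    tmin_ms: float,
    window_ms: tuple[float, float],
    polarity: int,
    mean_halfwidth_ms: float = PEAK_MEAN_HALFWIDTH_MS,
) -> tuple[float, float]:
    waveform = np.asarray(waveform, dtype=float)
    t = tmin_ms + np.arange(len(waveform)) * 1000.0 / rate
    lo, hi = window_ms
    if t[0] > lo - mean_halfwidth_ms or t[-1] < hi + mean_halfwidth_ms:
        raise ValueError(
            f"waveform does not cover [{lo - mean_halfwidth_ms},"
            f" {hi + mean_halfwidth_ms}] ms"
        )
    win = np.flatnonzero((t >= lo) & (t <= hi))
    seg = waveform[win] * polarity
    i_peak = win[int(np.argmax(seg))]  # argmax -> earliest tie wins
    lat = float(t[i_peak])
    half = int(round(mean_halfwidth_ms * rate / 1000.0))
    a = max(0, i_peak - half)
    b = min(len(waveform), i_peak + half + 1)
    amp = float(np.mean(waveform[a:b]))
    return amp, lat


def extract_mmn(
    waveform: np.ndarray,
    rate: float,
    tmin_ms: float = -500.0,
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
) -> tuple[float, float]:
    """Negative-peak amplitude (mean of +/-4 ms) and latency in ``window_ms``."""
    return _windowed_peak(waveform, rate, tmin_ms, window_ms, polarity=-1)


def extract_p3a(
    waveform: np.ndarray,
    rate: float,
    tmin_ms: float = -500.0,
    window_ms: tuple[float, float] = P3A_WINDOW_MS,
) -> tuple[float, float]:
    """Positive-peak amplitude (mean of +/-4 ms) and latency in ``window_ms``."""
    return _windowed_peak(waveform, rate, tmin_ms, window_ms, polarity=+1)


def difference_wave(
    oddball_mean: np.ndarray, standard_mean: np.ndarray
) -> np.ndarray:
    """Pointwise oddball minus standard average waveform."""
    oddball_mean = np.asarray(oddball_mean, dtype=float)
    standard_mean = np.asarray(standard_mean, dtype=float)
    if oddball_mean.shape != standard_mean.shape:
        raise ValueError("waveform shapes differ")
    return oddball_mean - standard_mean


def block_thresholds(scheduled: tuple[int, int] = (20, 80)) -> tuple[int, int]:
    """Two-thirds inclusion thresholds (floor) for (oddball, standard)."""
    return tuple(math.floor(2 * s / 3) for s in scheduled)  # type: ignore[return-value]


def block_inclusion(
    valid_oddball: int,
    valid_standard: int,
    scheduled: tuple[int, int] = (20, 80),
) -> bool:
    """Whether a block retains at least two thirds of both trial types."""
    if valid_oddball < 0 or valid_standard < 0:
        raise ValueError("counts must be non-negative")
    if valid_oddball > scheduled[0] or valid_standard > scheduled[1]:
        raise ValueError("valid counts exceed scheduled counts")
    thr_odd, thr_std = block_thresholds(scheduled)
    return valid_oddball >= thr_odd and valid_standard >= thr_std


def extract_trial_features(
    epoch: Epoch,
    *,
    lowpass_hz: float | None = 30.0,
    mmn_cluster: tuple[str, ...] = MMN_CLUSTER,
    p3a_cluster: tuple[str, ...] = P3A_CLUSTER,
) -> ErpFeatures:
    """Filter, baseline and extract MMN/P3a features from one epoch."""
    ep = lowpass_epoch(epoch, lowpass_hz) if lowpass_hz else epoch
    ep = baseline_epoch(ep)
    mmn_amp, mmn_lat = extract_mmn(
        cluster_waveform(ep, mmn_cluster), ep.rate, ep.tmin_ms
    )
    p3a_amp, p3a_lat = extract_p3a(
        cluster_waveform(ep, p3a_cluster), ep.rate, ep.tmin_ms
    )
    return ErpFeatures(mmn_amp, mmn_lat, p3a_amp, p3a_lat)


def _batch_peak(
    waves: np.ndarray,
    t: np.ndarray,
    window_ms: tuple[float, float],
    polarity: int,
    half: int,
) -> tuple[np.ndarray, np.ndarray]:
    win = np.flatnonzero((t >= window_ms[0]) & (t <= window_ms[1]))
    seg = waves[:, win] * polarity
    i_peak = win[np.argmax(seg, axis=1)]
    lat = t[i_peak]
    idx = np.clip(
        i_peak[:, None] + np.arange(-half, half + 1)[None, :], 0, waves.shape[1] - 1
    )
    amp = np.take_along_axis(waves, idx, axis=1).mean(axis=1)
    return amp, lat


def extract_features_batch(
    epochs: list[Epoch],
    *,
    lowpass_hz: float | None = 30.0,
    mmn_cluster: tuple[str, ...] = MMN_CLUSTER,
    p3a_cluster: tuple[str, ...] = P3A_CLUSTER,
    chunk: int = 512,
) -> list[ErpFeatures]:
    """Vectorized equivalent of :func:`extract_trial_features` for epochs
    sharing layout (channels, rate, window); falls back to the per-epoch
    path otherwise."""
    if not epochs:
        return []
    first = epochs[0]
    same = all(
        e.channels == first.channels
        and e.rate == first.rate
        and e.tmin_ms == first.tmin_ms
        and e.data.shape == first.data.shape
        for e in epochs
    )
    if not same:
        return [
            extract_trial_features(
                e, lowpass_hz=lowpass_hz,
                mmn_cluster=mmn_cluster, p3a_cluster=p3a_cluster,
            )
            for e in epochs
        ]
    t = first.t
    rate = first.rate
    half = int(round(PEAK_MEAN_HALFWIDTH_MS * rate / 1000.0))
    mmn_idx = [first.channels.index(c) for c in mmn_cluster]
    p3a_idx = [first.channels.index(c) for c in p3a_cluster]
    base_mask = (t >= -500.0) & (t < 0.0)
    out: list[ErpFeatures] = []
    for start in range(0, len(epochs), chunk):
        block = np.stack([e.data for e in epochs[start:start + chunk]])
        if lowpass_hz:
            sos = _butter_sos(4, float(lowpass_hz), float(rate))
            block = signal.sosfiltfilt(sos, block, axis=-1)
        block = block - block[:, :, base_mask].mean(axis=2, keepdims=True)
        mmn_wave = block[:, mmn_idx].mean(axis=1)
        p3a_wave = block[:, p3a_idx].mean(axis=1)
        m_amp, m_lat = _batch_peak(mmn_wave, t, MMN_WINDOW_MS, -1, half)
        p_amp, p_lat = _batch_peak(p3a_wave, t, P3A_WINDOW_MS, +1, half)
        out.extend(
            ErpFeatures(float(a), float(l), float(pa), float(pl))
            for a, l, pa, pl in zip(m_amp, m_lat, p_amp, p_lat)
        )
    return out
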