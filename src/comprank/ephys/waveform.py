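"""Averaged-waveform selection and shape features.

The three features used for unit typing are the trough-to-peak latency,
the width of the trough at half its depth, and the area under the
absolute waveform (uV*ms). A valid extracellular averaged waveform is
biphasic: a negative trough followed by a positive peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveformFeatures", "average_waveform", "extract_features"]


@dataclass
class WaveformFeatures:
    unit_id: str | None
    tp_latency_ms: float
    half_width_ms: float
    auc: float


def average_waveform(site_waveforms: dict) -> np.ndarray:
    """Mean waveform at the recording site with maximum amplitude.

    Parameters
    ----------
    site_waveforms : mapping site -> array (n_spikes, n_samples) of
        per-spike waveform snippets. All sites must share the sample
        count.

    The per-site mean waveforms are compared by peak-to-trough amplitude
    and the largest one is returned.
    """
    if not site_waveforms:
        raise ValueError("no recording sites")
    means = {}
    n_samples = None
    for site, w in site_waveforms.items():
        w = np.atleast_2d(np.asarray(w, dtype=float))
        if w.shape[0] < 1:
            raise ValueError(f"site {site!r} has no spikes")
        if n_samples is None:
            n_samples = w.shape[1]
        elif w.shape[1] != n_samples:
            raise ValueError("sites disagree on sample count")
        means[site] = w.mean(axis=0)
    amplitudes = {s: m.max() - m.min() for s, m in means.items()}
    if max(amplitudes.values()) == 0:
        raise ValueError("all-zero waveforms")
    best = max(sorted(amplitudes), key=lambda s: amplitudes[s])
    return means[best]


def _cross_time(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    """Linear interpolation of the time at which v crosses level."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def extract_features(
    waveform: np.ndarray, sampling_rate_hz: float, unit_id: str | None = None
) -> WaveformFeatures:
    """Trough-to-peak latency, trough half-width and absolute-area AUC.

    tp_latency is the time from the (global) trough to the largest
    positive peak after it; half_width is the width of the trough at
    half its depth, with sub-sample linear interpolation; auc is the
    trapezoidal integral of |amplitude| in uV*ms.

    Raises ValueError for monophasic waveforms (no trough below zero or
    no positive deflection after the trough).
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise ValueError("waveform must be a 1-D array of >= 3 samples")
    dt_ms = 1e3 / sampling_rate_hz
    i_trough = int(np.argmin(w))
    trough = w[i_trough]
    if trough >= 0:
        raise ValueError("monophasic waveform: no negative trough")
    after = w[i_trough + 1 :]
    if after.size == 0 or after.max() <= 0:
        raise ValueError("monophasic waveform: no positive peak after trough")
    i_peak = i_trough + 1 + int(np.argmax(after))
    tp_latency_ms = (i_peak - i_trough) * dt_ms

    level = trough / 2.0
    # walk outward from the trough to the half-depth crossings
    i = i_trough
    while i > 0 and w[i] < level:
        i -= 1
    if w[i] < level:  # trough starts below half depth at the first sample
        t_left = 0.0
    else:
        t_left = _cross_time(i * dt_ms, w[i], (i + 1) * dt_ms, w[i + 1], level)
    j = i_trough
    while j < w.size - 1 and w[j] < level:
        j += 1
    if w[j] < level:
        t_right = (w.size - 1) * dt_ms
    else:
        t_right = _cross_time((j - 1) * dt_ms, w[j - 1], j * dt_ms, w[j], level)
    half_width_ms = t_right - t_left

    auc = float(np.trapezoid(np.abs(w), dx=dt_ms))
    return WaveformFeatures(unit_id, float(tp_latency_ms), float(half_width_ms), auc)
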