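"""Brute-force reference extraction, independent of the package internals.

Everything here is deliberately naive: explicit loops, two-pass statistics,
dense-grid interpolation scans.  Used only to cross-check the production
implementation.
"""

import math

import numpy as np

DENSE_STEP_MS = 0.01


def ref_threshold(wave, window=(-200.0, 0.0)):
    vals = [
        v for t, v in zip(wave.t_axis, wave.samples) if window[0] <= t < window[1]
    ]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean - math.sqrt(var)


def ref_peak(wave, window=(100.0, 300.0)):
    best_t, best_v = None, math.inf
    for t, v in zip(wave.t_axis, wave.samples):
        if window[0] <= t < window[1] and v < best_v:
            best_t, best_v = t, v
    return best_t, best_v


def ref_ampavg(wave, peak_latency, half_width=20.0):
    vals = [
        v
        for t, v in zip(wave.t_axis, wave.samples)
        if peak_latency - half_width - 1e-9 <= t <= peak_latency + half_width + 1e-9
    ]
    return sum(vals) / len(vals)


def _dense(wave):
    t = np.arange(wave.t_axis[0], wave.t_axis[-1] + DENSE_STEP_MS / 2, DENSE_STEP_MS)
    return t, np.interp(t, wave.t_axis, wave.samples)


def ref_onset_offset(wave, th, peak_latency):
    """Dense-interpolation scan outward from the peak."""
    t, v = _dense(wave)
    i_pk = int(np.argmin(np.abs(t - peak_latency)))
    i = i_pk
    while i > 0 and v[i - 1] < th:
        i -= 1
    onset = t[0] if i == 0 else t[i]
    onset_clipped = i == 0
    j = i_pk
    while j < len(v) - 1 and v[j + 1] < th:
        j += 1
    offset = t[-1] if j == len(v) - 1 else t[j]
    offset_clipped = j == len(v) - 1
    return float(onset), float(offset), onset_clipped, offset_clipped


def ref_all_crossings(wave, th):
    """Every sub-sample threshold crossing time, in order."""
    t, v = wave.t_axis, wave.samples
    out = []
    for i in range(len(v) - 1):
        below0, below1 = v[i] < th, v[i + 1] < th
        if below0 != below1:
            frac = (th - v[i]) / (v[i + 1] - v[i])
            out.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return out


def ref_area(wave, onset, offset):
    t, v = _dense(wave)
    mask = (t >= onset) & (t <= offset)
    return abs(float(np.trapezoid(v[mask], t[mask])))


def ref_slopes(wave, onset, peak_latency, offset):
    t, v = wave.t_axis, wave.samples
    derivs = []
    for i in range(len(v)):
        if i == 0:
            d = (v[1] - v[0]) / (t[1] - t[0])
        elif i == len(v) - 1:
            d = (v[-1] - v[-2]) / (t[-1] - t[-2])
        else:
            d = (v[i + 1] - v[i - 1]) / (t[i + 1] - t[i - 1])
        derivs.append(d)
    up = [
        abs(d)
        for i, d in enumerate(derivs)
        if onset - 1e-9 <= t[i] <= peak_latency + 1e-9 and d < 0
    ]
    down = [
        abs(d)
        for i, d in enumerate(derivs)
        if peak_latency - 1e-9 <= t[i] <= offset + 1e-9 and d > 0
    ]
    return (max(up) if up else None, max(down) if down else None)
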