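"""Nine-parameter characterization of one averaged difference wave.

For each wave a rejection threshold is computed from the pre-stimulus
baseline as ``mean - SD``; waves that never dip strictly below it within
the 100–300 ms component window are flagged invalid and excluded from all
downstream statistics.  For valid waves we measure:

amplitude, ampavg, onset, offset, peak latency, duration, area,
upslope, downslope

Conventions (documented choices where the measuring criteria are
ambiguous):

- threshold SD uses the sample (n-1) estimator;
- validity is judged inside the peak-search window only;
- onset/offset are the sub-sample (linearly interpolated) threshold
  crossings of the contiguous sub-threshold excursion containing the peak;
  if the excursion runs into an epoch edge the time is clamped there and an
  edge flag is set;
- area is the absolute trapezoidal integral relative to 0 µV between onset
  and offset (a config switch integrates relative to the threshold
  instead);
- slopes are maxima of central finite differences, sign-restricted so only
  descent toward the peak counts for the upslope and only the return
  toward baseline counts for the downslope; both are reported unsigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .waveforms import MMNWave, _window_mask, DEFAULT_BASELINE_WINDOW

#: The nine extracted parameters, in reporting order.
PARAMETER_NAMES = (
    "amplitude",
    "ampavg",
    "onset",
    "offset",
    "peak_latency",
    "duration",
    "area",
    "upslope",
    "downslope",
)

DEFAULT_PEAK_WINDOW = (100.0, 300.0)
DEFAULT_AMPAVG_HALF_WIDTH = 20.0


class ExtractionError(RuntimeError):
    """Extraction failed for one wave; message carries the wave identity."""


@dataclass
class ExtractionConfig:
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW
    ampavg_half_width_ms: float = DEFAULT_AMPAVG_HALF_WIDTH
    area_reference: str = "zero"  # or "threshold"

    def validate(self) -> None:
        if self.area_reference not in ("zero", "threshold"):
            raise ValueError("area_reference must be 'zero' or 'threshold'")
        if self.ampavg_half_width_ms <= 0:
            raise ValueError("ampavg_half_width_ms must be positive")
        for name in ("baseline_window", "peak_window"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must satisfy start < end")


@dataclass
class MMNParameters:
    """Nine parameters + threshold and validity for one wave."""

    subject_id: int
    isi_s: float
    channel: str
    amplitude: float = math.nan  # µV, signed (negative for a valid wave)
    ampavg: float = math.nan  # µV, signed
    onset: float = math.nan  # ms
    offset: float = math.nan  # ms
    peak_latency: float = math.nan  # ms
    duration: float = math.nan  # ms
    area: float = math.nan  # µV·ms, absolute
    upslope: float = math.nan  # µV/ms, absolute
    downslope: float = math.nan  # µV/ms, absolute
    threshold: float = math.nan  # µV
    valid: bool = False
    onset_clipped: bool = False
    offset_clipped: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def compute_threshold(
    wave: MMNWave, baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
) -> float:
    """Rejection threshold: baseline mean minus baseline sample SD."""
    samples = wave.samples[_window_mask(wave.t_axis, baseline_window)]
    if samples.size < 2:
        raise ValueError(
            f"baseline window {baseline_window} has {samples.size} sample(s); "
            "need >= 2 for an SD"
        )
    return float(samples.mean() - samples.std(ddof=1))


def validate_mmn(
    wave: MMNWave,
    threshold: float,
    search_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
) -> bool:
    """True iff the wave dips strictly below the threshold in the window."""
    samples = wave.samples[_window_mask(wave.t_axis, search_window)]
    return bool(samples.min() < threshold)


def find_peak(
    wave: MMNWave, window: tuple[float, float] = DEFAULT_PEAK_WINDOW
) -> tuple[float, float]:
    """(peak_latency, amplitude): most negative sample in the window.

    Ties are broken by the earliest time (``argmin`` on the sorted axis).
    """
    mask = _window_mask(wave.t_axis, window)
    t = wave.t_axis[mask]
    v = wave.samples[mask]
    i = int(np.argmin(v))
    return float(t[i]), float(v[i])


def compute_ampavg(
    wave: MMNWave,
    peak_latency: float,
    half_width_ms: float = DEFAULT_AMPAVG_HALF_WIDTH,
) -> tuple[float, bool]:
    """Mean over [peak - hw, peak + hw], endpoints inclusive on the grid.

    Returns ``(ampavg, clipped)`` where ``clipped`` flags a window truncated
    by an epoch edge.
    """
    eps = 1e-9
    lo, hi = peak_latency - half_width_ms, peak_latency + half_width_ms
    mask = (wave.t_axis >= lo - eps) & (wave.t_axis <= hi + eps)
    clipped = bool(lo < wave.t_axis[0] - eps or hi > wave.t_axis[-1] + eps)
    return float(wave.samples[mask].mean()), clipped


def find_onset_offset(
    wave: MMNWave, threshold: float, peak_latency: float
) -> tuple[float, float, bool, bool]:
    """Interpolated threshold crossings bounding the peak's excursion.

    Scans outward from the peak sample while the wave stays strictly below
    the threshold, then linearly interpolates the exact crossing time within
    the straddling sample pair.  If the excursion reaches an epoch edge the
    crossing is clamped there and the corresponding flag set.

    Returns ``(onset, offset, onset_clipped, offset_clipped)``.
    """
    t = wave.t_axis
    v = wave.samples
    i_pk = int(np.argmin(np.abs(t - peak_latency)))
    if not v[i_pk] < threshold:
        raise ValueError(
            f"peak sample at {t[i_pk]} ms is not below the threshold "
            f"({v[i_pk]:.4g} >= {threshold:.4g}); wave should have been "
            "rejected as invalid"
        )

    # backward: first sample at/above threshold before the excursion
    i = i_pk
    while i > 0 and v[i - 1] < threshold:
        i -= 1
    if i == 0:
        onset, onset_clipped = float(t[0]), True
    else:
        onset = _interp_crossing(t[i - 1], v[i - 1], t[i], v[i], threshold)
        onset_clipped = False

    j = i_pk
    n = v.size
    while j < n - 1 and v[j + 1] < threshold:
        j += 1
    if j == n - 1:
        offset, offset_clipped = float(t[-1]), True
    else:
        offset = _interp_crossing(t[j], v[j], t[j + 1], v[j + 1], threshold)
        offset_clipped = False
    return onset, offset, onset_clipped, offset_clipped


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, th: float) -> float:
    """Time where the segment (t0, v0)→(t1, v1) equals th; one side is >= th."""
    if v1 == v0:
        return float(t0)
    return float(t0 + (th - v0) / (v1 - v0) * (t1 - t0))


def compute_duration_area(
    wave: MMNWave,
    onset: float,
    offset: float,
    *,
    area_reference: str = "zero",
    threshold: float = 0.0,
) -> tuple[float, float]:
    """Duration and absolute trapezoidal area between onset and offset.

    The integral runs over the sample grid with linearly interpolated
    fractional segments at both ends; the integrand is the wave relative to
    0 µV (default) or relative to the threshold.
    """
    if onset > offset:
        raise ValueError(f"onset {onset} after offset {offset}")
    duration = offset - onset
    if duration == 0.0:
        return 0.0, 0.0

    t = wave.t_axis
    v = wave.samples
    inner = (t > onset) & (t < offset)
    knots_t = np.concatenate(([onset], t[inner], [offset]))
    knots_v = np.interp(knots_t, t, v)
    if area_reference == "threshold":
        knots_v = knots_v - threshold
    area = abs(float(np.trapezoid(knots_v, knots_t)))
    return float(duration), area


def compute_slopes(
    wave: MMNWave, onset: float, peak_latency: float, offset: float
) -> tuple[float, float]:
    """(upslope, downslope): largest |dV/dt| on each side of the peak.

    Derivatives are central finite differences on the (already low-passed)
    wave.  On the ascending side only samples heading toward the negative
    peak (dV/dt < 0) count; on the descending side only the return toward
    baseline (dV/dt > 0).  Sides with fewer than 3 samples fall back to the
    two-point secant.  Both values are absolute.
    """
    if not onset < peak_latency < offset:
        raise ValueError(
            f"require onset < peak < offset, got ({onset}, {peak_latency}, {offset})"
        )
    t = wave.t_axis
    v = wave.samples
    deriv = np.gradient(v, t)

    eps = 1e-9
    up_mask = (t >= onset - eps) & (t <= peak_latency + eps)
    down_mask = (t >= peak_latency - eps) & (t <= offset + eps)

    upslope = _side_slope(deriv[up_mask], negative=True)
    if upslope is None:
        upslope = abs(_secant(wave, onset, peak_latency))
    downslope = _side_slope(deriv[down_mask], negative=False)
    if downslope is None:
        downslope = abs(_secant(wave, peak_latency, offset))
    return float(upslope), float(downslope)


def _side_slope(deriv: np.ndarray, negative: bool) -> float | None:
    if deriv.size < 3:
        return None
    selected = deriv[deriv < 0] if negative else deriv[deriv > 0]
    if selected.size == 0:
        return None
    return float(np.abs(selected).max())


def _secant(wave: MMNWave, t0: float, t1: float) -> float:
    v0 = float(np.interp(t0, wave.t_axis, wave.samples))
    v1 = float(np.interp(t1, wave.t_axis, wave.samples))
    return (v1 - v0) / (t1 - t0)


def extract_all(wave: MMNWave, config: ExtractionConfig | None = None) -> MMNParameters:
    """Run the full per-wave measurement chain.

    Invalid waves (never strictly below threshold inside the peak window)
    return ``valid=False`` with every parameter missing.
    """
    cfg = config or ExtractionConfig()
    cfg.validate()
    out = MMNParameters(
        subject_id=wave.subject_id, isi_s=wave.isi_s, channel=wave.channel
    )
    try:
        th = compute_threshold(wave, cfg.baseline_window)
        out.threshold = th
        if not validate_mmn(wave, th, cfg.peak_window):
            return out
        out.valid = True
        out.peak_latency, out.amplitude = find_peak(wave, cfg.peak_window)
        out.ampavg, _ampavg_clipped = compute_ampavg(
            wave, out.peak_latency, cfg.ampavg_half_width_ms
        )
        out.onset, out.offset, out.onset_clipped, out.offset_clipped = (
            find_onset_offset(wave, th, out.peak_latency)
        )
        out.duration, out.area = compute_duration_area(
            wave, out.onset, out.offset,
            area_reference=cfg.area_reference, threshold=th,
        )
        out.upslope, out.downslope = compute_slopes(
            wave, out.onset, out.peak_latency, out.offset
        )
    except Exception as exc:  # attach wave identity for debuggability
        raise ExtractionError(
            f"extraction failed for subject {wave.subject_id}, "
            f"ISI {wave.isi_s} s, channel {wave.channel}: {exc}"
        ) from exc
    return out


def extract_table(
    waves: Iterable[MMNWave], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """One row per wave: identity, nine parameters, threshold, flags."""
    rows = [extract_all(w, config).to_dict() for w in waves]
    return pd.DataFrame(rows)
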