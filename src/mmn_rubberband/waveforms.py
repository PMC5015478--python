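"""Epochs → averaged, baseline-corrected, low-passed difference waves.

Processing order: baseline-correct single epochs, average per condition,
subtract standard from deviant, then zero-phase low-pass the averaged
difference.  The filter is linear, so filtering averages is equivalent to
averaging filtered epochs and much cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .channels import DEFAULT_REGIONS
from .synth.epochs import EpochSet

DEFAULT_BASELINE_WINDOW = (-200.0, 0.0)
DEFAULT_CUTOFF_HZ = 25.0


class MissingConditionError(KeyError):
    """A required condition is absent for some subject/ISI/electrode cell."""


@dataclass
class MMNWave:
    """One averaged deviant-minus-standard difference wave."""

    subject_id: int
    isi_s: float
    channel: str  # electrode label or ROI name
    t_axis: np.ndarray = field(repr=False)
    samples: np.ndarray = field(repr=False)

    def baseline_mean(self, window: tuple[float, float] = DEFAULT_BASELINE_WINDOW) -> float:
        mask = _window_mask(self.t_axis, window)
        return float(self.samples[mask].mean())

    def copy_with(self, **changes) -> "MMNWave":
        kwargs = {
            "subject_id": self.subject_id,
            "isi_s": self.isi_s,
            "channel": self.channel,
            "t_axis": self.t_axis,
            "samples": self.samples,
        }
        kwargs.update(changes)
        return MMNWave(**kwargs)


def _window_mask(t_axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Half-open [start, end) mask on the time axis."""
    start, end = window
    mask = (t_axis >= start) & (t_axis < end)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples of the epoch")
    return mask


def baseline_correct(
    epochs: np.ndarray,
    t_axis: np.ndarray,
    window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> np.ndarray:
    """Subtract the mean over ``window`` (last axis is time)."""
    epochs = np.asarray(epochs, dtype=float)
    mask = _window_mask(t_axis, window)
    return epochs - epochs[..., mask].mean(axis=-1, keepdims=True)


def lowpass(
    samples: np.ndarray,
    sampling_rate_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, last axis is time)."""
    if sampling_rate_hz <= 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz too low for a {cutoff_hz} Hz cutoff"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate_hz, output="sos")
    samples = np.asarray(samples, dtype=float)
    # sosfiltfilt needs some warm-up length; surface a clear error for stubs
    min_len = 3 * (2 * order + 1)
    if samples.shape[-1] <= min_len:
        raise ValueError(
            f"epoch of {samples.shape[-1]} samples is shorter than the filter "
            f"warm-up ({min_len} samples)"
        )
    return signal.sosfiltfilt(sos, samples, axis=-1)


def average_difference(
    epochs: EpochSet,
    subject_id: int,
    isi_s: float,
    electrode: str,
    *,
    baseline_window: tuple[float, float] | None = DEFAULT_BASELINE_WINDOW,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
) -> MMNWave:
    """Averaged deviant minus averaged standard for one cell.

    ``baseline_window=None`` skips baseline correction and ``cutoff_hz=None``
    skips filtering (useful for arithmetic-level tests).
    """
    arrays = {}
    for condition in ("deviant", "standard"):
        key = (subject_id, isi_s, condition, electrode)
        if key not in epochs.data:
            raise MissingConditionError(
                f"no {condition} epochs for subject {subject_id}, "
                f"ISI {isi_s} s, electrode {electrode}"
            )
        arr = epochs.data[key]
        if arr.shape[0] < 2:
            raise ValueError(
                f"need >= 2 {condition} epochs for subject {subject_id}, "
                f"ISI {isi_s} s, electrode {electrode}; got {arr.shape[0]}"
            )
        if baseline_window is not None:
            arr = baseline_correct(arr, epochs.t_axis, baseline_window)
        arrays[condition] = arr.mean(axis=0)

    diff = arrays["deviant"] - arrays["standard"]
    if cutoff_hz is not None:
        diff = lowpass(diff, epochs.sampling_rate_hz, cutoff_hz)
    return MMNWave(
        subject_id=subject_id,
        isi_s=isi_s,
        channel=electrode,
        t_axis=epochs.t_axis,
        samples=diff,
    )


def difference_waves(epochs: EpochSet, **kwargs) -> list[MMNWave]:
    """``average_difference`` for every (subject, ISI, electrode) cell present."""
    cells = sorted({(k[0], k[1], k[3]) for k in epochs.data})
    return [average_difference(epochs, s, i, e, **kwargs) for s, i, e in cells]


def roi_average(
    waves: Iterable[MMNWave],
    regions: Mapping[str, Sequence[str]] = DEFAULT_REGIONS,
) -> list[MMNWave]:
    """Unweighted per-sample mean across each region's electrodes.

    One output wave per (subject, ISI, region).  Raises ``KeyError`` if a
    region electrode has no wave in the input.
    """
    by_cell: dict[tuple[int, float], dict[str, MMNWave]] = {}
    for w in waves:
        by_cell.setdefault((w.subject_id, w.isi_s), {})[w.channel] = w

    out = []
    for (subject, isi), chans in sorted(by_cell.items()):
        for region, members in regions.items():
            missing = [m for m in members if m not in chans]
            if missing:
                raise KeyError(
                    f"region {region!r}: electrode(s) {missing} missing for "
                    f"subject {subject}, ISI {isi} s"
                )
            stack = np.stack([chans[m].samples for m in members])
            ref = chans[members[0]]
            out.append(
                MMNWave(
                    subject_id=subject,
                    isi_s=isi,
                    channel=region,
                    t_axis=ref.t_axis,
                    samples=stack.mean(axis=0),
                )
            )
    return out


def waves_to_frame(waves: Iterable[MMNWave]) -> pd.DataFrame:
    """Long format: subject_id, isi_s, channel, time_ms, amplitude_uv."""
    parts = []
    for w in waves:
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": w.subject_id,
                    "isi_s": w.isi_s,
                    "channel": w.channel,
                    "time_ms": w.t_axis,
                    "amplitude_uv": w.samples,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def waves_from_frame(frame: pd.DataFrame) -> list[MMNWave]:
    out = []
    for (subject, isi, channel), grp in frame.groupby(
        ["subject_id", "isi_s", "channel"], sort=True
    ):
        grp = grp.sort_values("time_ms")
        out.append(
            MMNWave(
                subject_id=int(subject),
                isi_s=float(isi),
                channel=str(channel),
                t_axis=grp["time_ms"].to_numpy(),
                samples=grp["amplitude_uv"].to_numpy(),
            )
        )
    return out
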