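"""Deterministic waveform building blocks for synthetic epochs.

The deviance-response component is a single negative deflection: zero
outside ``[t_on, t_off]``, reaching ``-A`` at ``t_pk``.  The default shape
joins two half-raised-cosine segments (smooth, C1 at the peak); a
piecewise-linear option exists because its slopes are exactly constant,
which makes analytic slope tests trivial.
"""

from __future__ import annotations

import math

import numpy as np

SHAPES = ("cosine", "linear")


def _check_times(t_on: float, t_pk: float, t_off: float) -> None:
    if not (t_on < t_pk < t_off):
        raise ValueError(
            f"require t_on < t_pk < t_off, got ({t_on}, {t_pk}, {t_off})"
        )


def mmn_component(
    t_axis: np.ndarray,
    amplitude: float,
    t_on: float,
    t_pk: float,
    t_off: float,
    shape: str = "cosine",
) -> np.ndarray:
    """Sample the negative deflection on ``t_axis`` (ms), returning µV.

    ``amplitude`` is the positive peak magnitude; the sampled wave dips to
    ``-amplitude`` at ``t_pk``.  ``amplitude == 0`` yields all zeros.
    """
    if shape not in SHAPES:
        raise ValueError(f"shape must be one of {SHAPES}, got {shape!r}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    t = np.asarray(t_axis, dtype=float)
    out = np.zeros_like(t)
    if amplitude == 0.0:
        return out
    _check_times(t_on, t_pk, t_off)

    rising = (t >= t_on) & (t <= t_pk)
    falling = (t > t_pk) & (t <= t_off)
    if shape == "cosine":
        out[rising] = -amplitude * 0.5 * (
            1.0 - np.cos(np.pi * (t[rising] - t_on) / (t_pk - t_on))
        )
        out[falling] = -amplitude * 0.5 * (
            1.0 + np.cos(np.pi * (t[falling] - t_pk) / (t_off - t_pk))
        )
    else:  # linear
        out[rising] = -amplitude * (t[rising] - t_on) / (t_pk - t_on)
        out[falling] = -amplitude * (t_off - t[falling]) / (t_off - t_pk)
    return out


def max_rise_slope(amplitude: float, t_on: float, t_pk: float, shape: str = "cosine") -> float:
    """Largest |dV/dt| (µV/ms) on the onset→peak segment, in closed form."""
    _check_times(t_on, t_pk, t_pk + 1.0)
    seg = t_pk - t_on
    if shape == "cosine":
        return amplitude * math.pi / (2.0 * seg)
    return amplitude / seg


def max_descent_slope(amplitude: float, t_pk: float, t_off: float, shape: str = "cosine") -> float:
    """Largest |dV/dt| (µV/ms) on the peak→offset segment, in closed form."""
    _check_times(t_pk - 1.0, t_pk, t_off)
    seg = t_off - t_pk
    if shape == "cosine":
        return amplitude * math.pi / (2.0 * seg)
    return amplitude / seg


def _bump(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine bump of unit height on [center - hw, center + hw]."""
    x = (t - center) / half_width
    inside = np.abs(x) <= 1.0
    out = np.zeros_like(t)
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside]))
    return out


def obligatory_template(t_axis: np.ndarray) -> np.ndarray:
    """Shared stimulus-evoked response added to standard AND deviant trials.

    An N1-like trough followed by a P2-like crest.  It cancels exactly in
    the deviant-minus-standard difference, so its precise shape is
    inconsequential; it exists so single-condition averages look like ERPs.
    """
    t = np.asarray(t_axis, dtype=float)
    return -2.0 * _bump(t, 100.0, 50.0) + 1.5 * _bump(t, 195.0, 70.0)
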