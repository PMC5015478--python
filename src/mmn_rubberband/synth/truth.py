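"""Ground-truth parameter draws for the synthetic cohort.

Two generator modes encode the hypothesis contrast the pipeline is meant to
detect:

``rubberband``
    The return-to-baseline window ``t_off - t_pk`` is a fixed constant, so
    the descent rate is proportional to the amplitude (large responses come
    back faster).

``null``
    The descent rate is drawn independently of the amplitude, so the
    return time varies with amplitude instead (what a fixed decay process
    would produce).

In both modes the rise rate is drawn independently of the amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ..channels import DEFAULT_TOPOGRAPHY

MODES = ("rubberband", "null")

DEFAULT_ISIS = (1.5, 3.0, 4.5, 6.0)


def descent_rate_for(amplitude: float, return_window_ms: float) -> float:
    """Descent rate (µV/ms) implied by a fixed return window: ``A / T_ret``."""
    if return_window_ms <= 0:
        raise ValueError("return window must be positive")
    return amplitude / return_window_ms


@dataclass
class GroundTruthParams:
    """Hyperparameters of the ground-truth draw.

    Amplitudes are lognormal (median ``amplitude_median_uv``, log-sd
    ``amplitude_sigma``); peak latency is normal, clipped to the
    conventional 100–300 ms component window; rise and (null-mode) descent
    rates are lognormal and independent of amplitude.
    """

    amplitude_median_uv: float = 3.0
    amplitude_sigma: float = 0.3
    peak_latency_mean_ms: float = 170.0
    peak_latency_sd_ms: float = 15.0
    peak_latency_bounds_ms: tuple[float, float] = (110.0, 290.0)
    rise_rate_median_uv_ms: float = 0.0353
    rise_rate_sigma: float = 0.3
    rise_time_bounds_ms: tuple[float, float] = (40.0, 165.0)
    return_window_ms: float = 120.0  # rubberband mode
    descent_rate_median_uv_ms: float = 0.025  # null mode
    descent_rate_sigma: float = 0.3
    return_time_bounds_ms: tuple[float, float] = (50.0, 480.0)
    max_offset_ms: float = 780.0
    topography_jitter_sigma: float = 0.0
    isi_amplitude_scale: dict[float, float] = field(default_factory=dict)
    topography: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOPOGRAPHY)
    )

    def validate(self) -> None:
        if self.amplitude_median_uv <= 0:
            raise ValueError("amplitude_median_uv must be positive")
        if self.amplitude_sigma < 0 or self.rise_rate_sigma < 0 or self.descent_rate_sigma < 0:
            raise ValueError("distribution sigmas must be non-negative")
        if self.return_window_ms <= 0:
            raise ValueError("return_window_ms must be positive")
        if self.topography_jitter_sigma < 0:
            raise ValueError("topography_jitter_sigma must be non-negative")
        if self.rise_rate_median_uv_ms <= 0 or self.descent_rate_median_uv_ms <= 0:
            raise ValueError("rate medians must be positive")
        for name in ("peak_latency_bounds_ms", "rise_time_bounds_ms", "return_time_bounds_ms"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi")
        for w in self.topography.values():
            if w <= 0:
                raise ValueError("topography weights must be positive")
        for s in self.isi_amplitude_scale.values():
            if s <= 0:
                raise ValueError("ISI amplitude scales must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def draw_ground_truth(
    mode: str,
    n_subjects: int,
    hyperparams: GroundTruthParams | None = None,
    seed: int | None = None,
    *,
    isis: tuple[float, ...] = DEFAULT_ISIS,
    electrodes: tuple[str, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-(subject, ISI, electrode) ground truth as a long table.

    Amplitude, peak latency and rise time are drawn once per subject × ISI;
    electrode rows share the timing and scale the amplitude (and hence both
    rates) by the electrode's topography weight.

    Returns a DataFrame with columns ``subject_id, isi_s, electrode,
    amplitude_uv, t_on_ms, t_pk_ms, t_off_ms, rise_rate_uv_ms,
    descent_rate_uv_ms, topography_weight``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    hp = hyperparams or GroundTruthParams()
    hp.validate()
    if electrodes is None:
        electrodes = tuple(hp.topography)
    unknown = [e for e in electrodes if e not in hp.topography]
    if unknown:
        raise ValueError(f"electrodes missing a topography weight: {unknown}")
    if rng is None:
        rng = np.random.default_rng(seed)

    mu_amp = math.log(hp.amplitude_median_uv)
    rows = []
    for subject in range(n_subjects):
        for isi in isis:
            a = float(rng.lognormal(mu_amp, hp.amplitude_sigma))
            a *= hp.isi_amplitude_scale.get(isi, 1.0)
            t_pk = float(
                np.clip(
                    rng.normal(hp.peak_latency_mean_ms, hp.peak_latency_sd_ms),
                    *hp.peak_latency_bounds_ms,
                )
            )
            rise_rate = float(
                rng.lognormal(math.log(hp.rise_rate_median_uv_ms), hp.rise_rate_sigma)
            )
            lo, hi = hp.rise_time_bounds_ms
            rise_time = float(np.clip(a / rise_rate, lo, min(hi, t_pk - 10.0)))
            t_on = t_pk - rise_time

            if mode == "rubberband":
                ret = hp.return_window_ms
            else:
                rate = float(
                    rng.lognormal(
                        math.log(hp.descent_rate_median_uv_ms), hp.descent_rate_sigma
                    )
                )
                lo, hi = hp.return_time_bounds_ms
                ret = float(np.clip(a / rate, lo, min(hi, hp.max_offset_ms - t_pk)))
            t_off = t_pk + ret

            for electrode in electrodes:
                # per-subject topography jitter: individual scalp maps differ,
                # so an electrode's gain is not rank-identical across subjects.
                # The jittered weight scales amplitude AND both rates, leaving
                # the within-electrode amplitude-descent coupling intact.
                w = hp.topography[electrode]
                if hp.topography_jitter_sigma > 0:
                    w *= float(rng.lognormal(0.0, hp.topography_jitter_sigma))
                rows.append(
                    {
                        "subject_id": subject,
                        "isi_s": isi,
                        "electrode": electrode,
                        "amplitude_uv": w * a,
                        "t_on_ms": t_on,
                        "t_pk_ms": t_pk,
                        "t_off_ms": t_off,
                        "rise_rate_uv_ms": w * a / rise_time,
                        "descent_rate_uv_ms": w * a / ret,
                        "topography_weight": w,
                    }
                )
    return pd.DataFrame(rows)
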