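"""Epoched EEG synthesis: obligatory template + deviance component + noise."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .components import mmn_component, obligatory_template
from .sequences import StimulusSequence, DEVIANT

EPOCH_START_MS = -400.0
EPOCH_END_MS = 800.0
DEFAULT_SAMPLING_RATE_HZ = 500.0

CONDITIONS = ("standard", "deviant")

#: (subject_id, isi_s, condition, electrode)
CellKey = tuple[int, float, str, str]


def default_t_axis(
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    start_ms: float = EPOCH_START_MS,
    end_ms: float = EPOCH_END_MS,
) -> np.ndarray:
    """Half-open sample grid [start, end) in ms; t = 0 is stimulus onset."""
    step = 1000.0 / sampling_rate_hz
    return np.arange(start_ms, end_ms, step)


@dataclass
class EpochSet:
    """Per (subject, ISI, condition, electrode) trial × time voltage arrays."""

    t_axis: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    data: dict[CellKey, np.ndarray] = field(default_factory=dict)

    def add(self, key: CellKey, epochs: np.ndarray) -> None:
        epochs = np.asarray(epochs, dtype=float)
        if epochs.ndim != 2 or epochs.shape[1] != self.t_axis.size:
            raise ValueError(
                f"epochs for {key} must be (n_trials, {self.t_axis.size}), "
                f"got {epochs.shape}"
            )
        self.data[key] = epochs

    def get(self, subject_id: int, isi_s: float, condition: str, electrode: str) -> np.ndarray:
        return self.data[(subject_id, isi_s, condition, electrode)]

    def keys(self):
        return self.data.keys()

    @property
    def subjects(self) -> tuple[int, ...]:
        return tuple(sorted({k[0] for k in self.data}))

    @property
    def isis(self) -> tuple[float, ...]:
        return tuple(sorted({k[1] for k in self.data}))

    @property
    def electrodes(self) -> tuple[str, ...]:
        return tuple(sorted({k[3] for k in self.data}))

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject_id, isi_s, condition, electrode, trial, time_ms, amplitude_uv."""
        parts = []
        nt = self.t_axis.size
        for (subject, isi, condition, electrode), arr in self.data.items():
            n_trials = arr.shape[0]
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": subject,
                        "isi_s": isi,
                        "condition": condition,
                        "electrode": electrode,
                        "trial": np.repeat(np.arange(n_trials), nt),
                        "time_ms": np.tile(self.t_axis, n_trials),
                        "amplitude_uv": arr.ravel(),
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ) -> "EpochSet":
        t_axis = np.sort(frame["time_ms"].unique())
        out = cls(t_axis=t_axis, sampling_rate_hz=sampling_rate_hz)
        group_cols = ["subject_id", "isi_s", "condition", "electrode"]
        for key, grp in frame.groupby(group_cols, sort=True):
            grp = grp.sort_values(["trial", "time_ms"])
            n_trials = grp["trial"].nunique()
            arr = grp["amplitude_uv"].to_numpy().reshape(n_trials, t_axis.size)
            out.add((int(key[0]), float(key[1]), str(key[2]), str(key[3])), arr)
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sidecar(self, **extra) -> dict:
        meta = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "epoch_window_ms": [float(self.t_axis[0]), float(self.t_axis[-1])],
            "electrodes": list(self.electrodes),
            "subjects": list(self.subjects),
            "isis_s": list(self.isis),
        }
        meta.update(extra)
        return meta

    def write_sidecar(self, path: str | Path, **extra) -> None:
        Path(path).write_text(json.dumps(self.sidecar(**extra), indent=2))


def trial_counts_from_sequences(sequences: list[StimulusSequence]) -> tuple[int, int]:
    """(n_deviant, n_standard) trials pooled over a list of blocks."""
    n_dev = sum(s.n_deviants for s in sequences)
    n_std = sum(s.n_stimuli - s.n_deviants for s in sequences)
    return n_dev, n_std


def synthesize_epochs(
    truth: pd.DataFrame,
    n_deviant_trials: int = 60,
    n_standard_trials: int = 240,
    noise_sd_uv: float = 8.0,
    seed: int | None = None,
    *,
    sequences: list[StimulusSequence] | None = None,
    t_axis: np.ndarray | None = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    shape: str = "cosine",
    include_template: bool = True,
    pink_noise_sd_uv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Simulate single-trial epochs for every row of a ground-truth table.

    Standard trials carry the shared obligatory template; deviant trials add
    the deflection component of the matching ground-truth row.  Noise is
    i.i.d. Gaussian per sample (optionally plus a 1/f surrogate), so the
    deviant-minus-standard average recovers the component with residual
    noise SD ≈ ``noise_sd_uv * sqrt(1/n_dev + 1/n_std)``.

    If ``sequences`` is given, the pooled per-condition trial counts are
    taken from the blocks instead of the explicit arguments.
    """
    if sequences is not None:
        n_deviant_trials, n_standard_trials = trial_counts_from_sequences(sequences)
    if n_deviant_trials < 2 or n_standard_trials < 2:
        raise ValueError(
            "need at least 2 trials per condition to define an average "
            f"(got deviant={n_deviant_trials}, standard={n_standard_trials})"
        )
    if noise_sd_uv < 0 or pink_noise_sd_uv < 0:
        raise ValueError("noise SDs must be non-negative")
    if t_axis is None:
        t_axis = default_t_axis(sampling_rate_hz)
    if rng is None:
        rng = np.random.default_rng(seed)

    template = obligatory_template(t_axis) if include_template else np.zeros_like(t_axis)
    out = EpochSet(t_axis=t_axis, sampling_rate_hz=sampling_rate_hz)

    counts = {"standard": n_standard_trials, "deviant": n_deviant_trials}
    for row in truth.itertuples(index=False):
        component = mmn_component(
            t_axis, row.amplitude_uv, row.t_on_ms, row.t_pk_ms, row.t_off_ms, shape=shape
        )
        for condition in CONDITIONS:
            n = counts[condition]
            signal = template + (component if condition == "deviant" else 0.0)
            epochs = signal + rng.normal(0.0, noise_sd_uv, size=(n, t_axis.size))
            if pink_noise_sd_uv > 0:
                epochs += _pink_noise(rng, (n, t_axis.size), pink_noise_sd_uv)
            out.add(
                (int(row.subject_id), float(row.isi_s), condition, str(row.electrode)),
                epochs,
            )
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise, per trial."""
    n = shape[1]
    white = rng.normal(size=shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return sd * pink
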