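"""Electrode montage constants and region-of-interest groupings.

Only labels matter here: the analysis is electrode-wise and never uses
scalp coordinates.
"""

from __future__ import annotations

#: The 13 fronto-central / temporal electrodes entering the correlation stage.
ELECTRODES: tuple[str, ...] = (
    "FPZ", "FZ", "FCZ", "CZ", "CPZ",
    "F1", "F3", "F2", "F4",
    "FT7", "FT8", "T7", "T8",
)

#: Electrode groups averaged before ROI-level parameter extraction.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("FZ", "FPZ", "F1", "F2", "F3", "F4"),
    "central": ("FCZ", "CZ", "CPZ"),
    "left_temporal": ("T7", "FT7"),
    "right_temporal": ("T8", "FT8"),
}

_TEMPORAL = {"FT7", "FT8", "T7", "T8"}

#: Per-electrode scaling of the deviance-response component.  Temporal sites
#: sit close to the (reference) mastoids and carry a smaller response.
DEFAULT_TOPOGRAPHY: dict[str, float] = {
    e: (0.4 if e in _TEMPORAL else 1.0) for e in ELECTRODES
}


def validate_regions(regions: dict[str, tuple[str, ...]], electrodes) -> None:
    """Raise ``ValueError`` if any region references an unknown electrode."""
    known = set(electrodes)
    for name, members in regions.items():
        missing = [m for m in members if m not in known]
        if missing:
            raise ValueError(
                f"region {name!r} references unknown electrode(s): {missing}"
            )
        if not members:
            raise ValueError(f"region {name!r} is empty")
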