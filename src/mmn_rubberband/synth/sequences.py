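"""Oddball stimulus sequences with exact deviant counts and spacing rules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD = "standard"
DEVIANT = "deviant"


class SequenceInfeasibleError(ValueError):
    """Requested deviant count cannot be placed under the spacing constraints."""


@dataclass(frozen=True)
class StimulusSequence:
    """One block of ordered standard/deviant labels.

    Parameters
    ----------
    block_id : int
        Index of the block within a session.
    isi_s : float
        Inter-stimulus interval of the block, in seconds.
    labels : tuple of str
        Ordered ``"standard"`` / ``"deviant"`` labels.
    """

    block_id: int
    isi_s: float
    labels: tuple[str, ...] = field(repr=False)

    @property
    def n_stimuli(self) -> int:
        return len(self.labels)

    @property
    def n_deviants(self) -> int:
        return sum(1 for lab in self.labels if lab == DEVIANT)

    @property
    def n_standards(self) -> int:
        return self.n_stimuli - self.n_deviants

    @property
    def deviant_positions(self) -> tuple[int, ...]:
        return tuple(i for i, lab in enumerate(self.labels) if lab == DEVIANT)


def n_deviants_for(n_stimuli: int, deviant_prob: float) -> int:
    """Exact deviant count for a block: ``round(prob * n)``, not Bernoulli."""
    if not 0.0 <= deviant_prob <= 1.0:
        raise ValueError(f"deviant_prob must be in [0, 1], got {deviant_prob}")
    return int(round(deviant_prob * n_stimuli))


def generate_stimulus_sequence(
    n_stimuli: int = 150,
    deviant_prob: float = 0.20,
    min_sep: int = 2,
    n_lead: int = 5,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    block_id: int = 0,
    isi_s: float = float("nan"),
) -> StimulusSequence:
    """Generate one oddball block.

    Deviant positions are drawn uniformly at random among all placements
    that satisfy the constraints: exactly ``round(deviant_prob * n_stimuli)``
    deviants, consecutive deviants separated by at least ``min_sep``
    standards, and the first ``n_lead`` stimuli all standard.

    Uniformity uses the classic gap bijection: choosing ``k`` positions with
    pairwise spacing ``> min_sep`` from ``m`` slots is equivalent to choosing
    ``k`` unconstrained slots from ``m - (k - 1) * min_sep``.

    Raises
    ------
    SequenceInfeasibleError
        If the deviants cannot be placed under the constraints.
    """
    if n_stimuli < 0 or min_sep < 0 or n_lead < 0:
        raise ValueError("n_stimuli, min_sep and n_lead must be non-negative")
    if n_lead > n_stimuli:
        raise ValueError("n_lead cannot exceed n_stimuli")
    k = n_deviants_for(n_stimuli, deviant_prob)

    labels = np.full(n_stimuli, STANDARD, dtype=object)
    if k > 0:
        m = n_stimuli - n_lead  # slots available to deviants
        reduced = m - (k - 1) * min_sep
        if reduced < k:
            raise SequenceInfeasibleError(
                f"cannot place {k} deviants in {n_stimuli} stimuli with "
                f"min_sep={min_sep} and n_lead={n_lead}"
            )
        if rng is None:
            rng = np.random.default_rng(seed)
        picked = np.sort(rng.choice(reduced, size=k, replace=False))
        positions = n_lead + picked + min_sep * np.arange(k)
        labels[positions] = DEVIANT

    return StimulusSequence(block_id=block_id, isi_s=isi_s, labels=tuple(labels))


def check_sequence(
    seq: StimulusSequence, *, n_deviants: int, min_sep: int, n_lead: int
) -> None:
    """Assert the three block invariants; raise ``AssertionError`` on failure."""
    pos = np.asarray(seq.deviant_positions)
    assert len(pos) == n_deviants, f"expected {n_deviants} deviants, got {len(pos)}"
    if len(pos) > 0:
        assert pos.min() >= n_lead, "deviant within the all-standard lead-in"
        if len(pos) > 1:
            gaps = np.diff(pos) - 1
            assert gaps.min() >= min_sep, "deviants closer than min_sep standards"
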