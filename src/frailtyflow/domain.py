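"""Core vocabulary: age bands, frailty states, subgroup indexing and eFI scoring.

The population is stratified into four age bands (50-64, 65-74, 75-84, 85+)
and four ordered frailty states derived from the electronic frailty index
(eFI), a cumulative-deficit score: number of recorded deficits divided by the
total deficit count (36 by default). The 16 (band, state) pairs are the
model's indexing backbone; everything downstream addresses compartments by
the canonical band-major subgroup index 0-15.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Optional

__all__ = [
    "FrailtyState",
    "AgeBand",
    "Subgroup",
    "EfiScore",
    "DEFAULT_TOTAL_DEFICITS",
    "efi_score",
    "categorise_efi",
    "subgroup_of",
    "next_band",
    "next_state",
    "iter_subgroups",
    "N_BANDS",
    "N_STATES",
    "N_SUBGROUPS",
    "FRAIL_STATES",
]

DEFAULT_TOTAL_DEFICITS = 36

N_BANDS = 4
N_STATES = 4
N_SUBGROUPS = N_BANDS * N_STATES


class FrailtyState(enum.IntEnum):
    """Ordered frailty category; progression is one-directional (Fit is best)."""

    FIT = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return _STATE_LABELS[self]

    @property
    def efi_lower(self) -> float:
        """Lower eFI bound; exclusive except for Fit (which includes 0)."""
        return _STATE_CUTS[self.value]

    @property
    def efi_upper(self) -> float:
        """Upper eFI bound, inclusive."""
        return _STATE_CUTS[self.value + 1]

    @classmethod
    def from_label(cls, label: str) -> "FrailtyState":
        try:
            return _STATE_BY_LABEL[label]
        except KeyError:
            raise ValueError(f"unknown frailty state label {label!r}") from None


_STATE_LABELS = {
    FrailtyState.FIT: "Fit",
    FrailtyState.MILD: "Mild",
    FrailtyState.MODERATE: "Moderate",
    FrailtyState.SEVERE: "Severe",
}
_STATE_BY_LABEL = {v: k for k, v in _STATE_LABELS.items()}

# Interval edges: Fit = [0, 0.12], Mild = (0.12, 0.24], Moderate = (0.24, 0.36],
# Severe = (0.36, 1]. Half-open-above so the printed category cut-offs are
# reproduced on every k/36 grid value while leaving no gaps for arbitrary
# fractions.
_STATE_CUTS = (0.0, 0.12, 0.24, 0.36, 1.0)

FRAIL_STATES = (FrailtyState.MILD, FrailtyState.MODERATE, FrailtyState.SEVERE)


class AgeBand(enum.IntEnum):
    """Age band in the ageing chain; the last band has no ageing outflow."""

    B50_64 = 0
    B65_74 = 1
    B75_84 = 2
    B85_PLUS = 3

    @property
    def label(self) -> str:
        return _BAND_LABELS[self]

    @property
    def lower_age(self) -> int:
        return _BAND_BOUNDS[self.value][0]

    @property
    def upper_age(self) -> Optional[int]:
        """Upper age (inclusive), or None for the open-ended last band."""
        return _BAND_BOUNDS[self.value][1]

    @property
    def width(self) -> Optional[int]:
        upper = self.upper_age
        return None if upper is None else upper - self.lower_age + 1

    @classmethod
    def from_label(cls, label: str) -> "AgeBand":
        try:
            return _BAND_BY_LABEL[label]
        except KeyError:
            raise ValueError(f"unknown age band label {label!r}") from None


_BAND_LABELS = {
    AgeBand.B50_64: "50-64",
    AgeBand.B65_74: "65-74",
    AgeBand.B75_84: "75-84",
    AgeBand.B85_PLUS: "85+",
}
_BAND_BY_LABEL = {v: k for k, v in _BAND_LABELS.items()}
_BAND_BOUNDS = {0: (50, 64), 1: (65, 74), 2: (75, 84), 3: (85, None)}


@dataclass(frozen=True)
class Subgroup:
    """One of the 16 (age band, frailty state) compartments."""

    band: AgeBand
    state: FrailtyState

    @property
    def index(self) -> int:
        """Canonical band-major index: (50-64, Fit) = 0 ... (85+, Severe) = 15."""
        return self.band.value * N_STATES + self.state.value

    @classmethod
    def from_index(cls, index: int) -> "Subgroup":
        if not 0 <= index < N_SUBGROUPS:
            raise ValueError(f"subgroup index {index} outside 0..{N_SUBGROUPS - 1}")
        return cls(AgeBand(index // N_STATES), FrailtyState(index % N_STATES))

    @property
    def label(self) -> str:
        return f"{self.band.label}/{self.state.label}"


def iter_subgroups() -> Iterator[Subgroup]:
    """All 16 subgroups in canonical band-major order."""
    for index in range(N_SUBGROUPS):
        yield Subgroup.from_index(index)


@dataclass(frozen=True)
class EfiScore:
    """Cumulative-deficit score: n_deficits / total_deficits, exact."""

    n_deficits: int
    total_deficits: int = DEFAULT_TOTAL_DEFICITS

    def __post_init__(self) -> None:
        if self.total_deficits <= 0:
            raise ValueError("total_deficits must be positive")
        if not 0 <= self.n_deficits <= self.total_deficits:
            raise ValueError(
                f"n_deficits {self.n_deficits} outside 0..{self.total_deficits}"
            )

    @property
    def value(self) -> Fraction:
        return Fraction(self.n_deficits, self.total_deficits)

    def __float__(self) -> float:
        return float(self.value)


def efi_score(n_deficits: int, total_deficits: int = DEFAULT_TOTAL_DEFICITS) -> EfiScore:
    """Build an eFI score from a deficit count.

    Raises ``ValueError`` when the count falls outside 0..total_deficits.
    """
    return EfiScore(n_deficits, total_deficits)


def categorise_efi(score) -> FrailtyState:
    """Map an eFI score (``EfiScore``, ``Fraction`` or float in [0, 1]) to a state."""
    value = float(score)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"eFI score {value} outside [0, 1]")
    for state in FrailtyState:
        if value <= _STATE_CUTS[state.value + 1]:
            return state
    return FrailtyState.SEVERE  # unreachable; value <= 1.0 always hits the loop


def subgroup_of(band: AgeBand, state: FrailtyState) -> Subgroup:
    return Subgroup(band, state)


def next_band(band: AgeBand) -> Optional[AgeBand]:
    """Band people age into, or None for the open-ended 85+ band."""
    if band is AgeBand.B85_PLUS:
        return None
    return AgeBand(band.value + 1)


def next_state(state: FrailtyState) -> Optional[FrailtyState]:
    """Adjacent worse frailty state, or None for Severe (absorbing)."""
    if state is FrailtyState.SEVERE:
        return None
    return FrailtyState(state.value + 1)
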