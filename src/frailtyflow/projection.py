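"""National scale-up: closed population with entries only at age 50.

The national model removes de-registration and within-cohort entries: people
enter only by reaching age 50 (driven by official population projections)
and leave only by dying. Summaries mirror the published reporting layout:
per-subgroup counts and percentages of the over-50 total, the frail share,
and the age-band composition of the frail population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .domain import (
    AgeBand,
    FRAIL_STATES,
    FrailtyState,
    N_BANDS,
    N_STATES,
    iter_subgroups,
)
from .engine import (
    ConfigurationError,
    EntrySpec,
    FlowSpec,
    ModelParameters,
    PopulationState,
    Trajectory,
    step,
)

__all__ = [
    "PopulationProjection",
    "EntryFrailtySplit",
    "ProjectionSummary",
    "national_parameters",
    "project",
    "summarise",
    "prevalence_percent",
    "percent_change",
]


@dataclass(frozen=True)
class PopulationProjection:
    """Annual counts of people reaching age 50, plus optional band totals.

    ``entrants_50`` maps calendar year -> persons turning 50 that year.
    ``band_population`` optionally carries per-band population estimates
    (keyed by band label) for initialising the national run.
    """

    entrants_50: Mapping[int, float]
    band_population: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        for year, count in self.entrants_50.items():
            if count < 0:
                raise ValueError(f"entrants_50 for {year} is negative: {count}")
        years = sorted(self.entrants_50)
        if years and years != list(range(years[0], years[-1] + 1)):
            missing = sorted(set(range(years[0], years[-1] + 1)) - set(years))
            raise ConfigurationError(f"projection years not contiguous; missing {missing}")

    def years(self) -> Sequence[int]:
        return sorted(self.entrants_50)


@dataclass(frozen=True)
class EntryFrailtySplit:
    """Frailty-state shares for new 50-year-old entrants (sum to 1)."""

    shares: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.shares) != N_STATES:
            raise ValueError(f"need {N_STATES} shares, got {len(self.shares)}")
        if any(s < 0 for s in self.shares):
            raise ValueError(f"negative share in {self.shares}")
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {sum(self.shares)}")

    @classmethod
    def all_fit(cls) -> "EntryFrailtySplit":
        return cls((1.0, 0.0, 0.0, 0.0))

    @classmethod
    def from_state(cls, state: PopulationState, band: int = 0) -> "EntryFrailtySplit":
        """Shares matching the current frailty mix of one band's alive stocks."""
        counts = state.alive[band]
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"band {band} has no alive population to derive shares")
        return cls(tuple(float(c / total) for c in counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.shares, dtype=float)


def national_parameters(params: ModelParameters) -> ModelParameters:
    """Close the model: zero every de-registration and entry spec.

    The age-50 inflow is supplied separately by :func:`project`; death,
    ageing and progression specs pass through untouched. Idempotent.
    """
    zero_p = FlowSpec(kind="constant", p=0.0)
    zero_e = EntrySpec(kind="constant", rate=0.0)
    return ModelParameters(
        death=dict(params.death),
        dereg={key: zero_p for key in params.dereg},
        entry={key: zero_e for key in params.entry},
        ageing=dict(params.ageing),
        progression=dict(params.progression),
        n_bands=params.n_bands,
        n_states=params.n_states,
    )


def project(
    initial: PopulationState,
    projection: PopulationProjection,
    params: ModelParameters,
    split: EntryFrailtySplit,
    horizon: int,
    start_year: int,
) -> Trajectory:
    """Run the national model: inject age-50 entrants, then step each year.

    Each year's entrants (entrants_50 x split) join the youngest band's
    stocks before the synchronous annual update, so they are exposed to that
    year's flows. Raises a configuration error if the projection table does
    not cover every simulated year.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    needed = list(range(start_year, start_year + horizon))
    missing = [y for y in needed if y not in projection.entrants_50]
    if missing:
        raise ConfigurationError(f"projection table missing years {missing}")
    params.validate()

    states = [initial.copy()]
    flows = []
    for k, year in enumerate(needed):
        current = states[-1].copy()
        entrants = float(projection.entrants_50[year]) * split.as_array()
        current.alive[0, :] += entrants
        current.entered_cum[0, :] += entrants
        nxt, rec = step(current, params)
        rec.entries[0, :] += entrants
        states.append(nxt)
        flows.append(rec)
    return Trajectory(states=states, flows=flows, start_year=start_year)


def prevalence_percent(count: float, total: float) -> float:
    """Simple prevalence: count / total x 100."""
    if total <= 0:
        raise ValueError("total must be positive")
    return count / total * 100.0


def percent_change(before: float, after: float) -> float:
    """Relative change from ``before`` to ``after``, in percent."""
    if before == 0:
        raise ValueError("undefined percent change from zero")
    return (after / before - 1.0) * 100.0


@dataclass(frozen=True)
class ProjectionSummary:
    """Prevalence summary of one year's 16 subgroup counts."""

    counts: Mapping[Tuple[str, str], float]  # (band label, state label) -> persons
    total: float
    subgroup_percent: Mapping[Tuple[str, str], float]
    frail_count: float
    frail_percent: float
    moderate_severe_count: float
    band_frail_share: Mapping[str, float]  # band label -> % of total frail

    @property
    def total_thousands(self) -> float:
        """Total rounded to the nearest thousand persons."""
        return float(round(self.total / 1000.0) * 1000)

    @property
    def frail_percent_1dp(self) -> float:
        return round(self.frail_percent, 1)


def summarise(counts: Union[np.ndarray, Mapping[Tuple[str, str], float]]) -> ProjectionSummary:
    """Aggregate 16 subgroup counts into the standard prevalence summary.

    Accepts either an (n_bands, n_states) array or a mapping keyed by
    (band label, state label). Frail = Mild + Moderate + Severe.
    """
    grid = np.zeros((N_BANDS, N_STATES))
    if isinstance(counts, Mapping):
        for (band_label, state_label), value in counts.items():
            b = AgeBand.from_label(band_label).value
            s = FrailtyState.from_label(state_label).value
            grid[b, s] = value
    else:
        arr = np.asarray(counts, dtype=float)
        if arr.shape != (N_BANDS, N_STATES):
            raise ValueError(f"expected shape {(N_BANDS, N_STATES)}, got {arr.shape}")
        grid = arr.copy()
    if np.any(grid < 0):
        raise ValueError("subgroup counts must be non-negative")
    total = float(grid.sum())
    if total == 0:
        raise ValueError("all subgroup counts are zero; nothing to summarise")

    count_map = {}
    pct_map = {}
    for sg in iter_subgroups():
        key = (sg.band.label, sg.state.label)
        count_map[key] = float(grid[sg.band, sg.state])
        pct_map[key] = float(grid[sg.band, sg.state] / total * 100.0)

    frail_idx = [s.value for s in FRAIL_STATES]
    frail_grid = grid[:, frail_idx]
    frail = float(frail_grid.sum())
    mod_sev = float(
        grid[:, [FrailtyState.MODERATE.value, FrailtyState.SEVERE.value]].sum()
    )
    band_share = {}
    for band in AgeBand:
        band_share[band.label] = (
            float(frail_grid[band.value].sum() / frail * 100.0) if frail > 0 else 0.0
        )
    return ProjectionSummary(
        counts=count_map,
        total=total,
        subgroup_percent=pct_map,
        frail_count=frail,
        frail_percent=frail / total * 100.0,
        moderate_severe_count=mod_sev,
        band_frail_share=band_share,
    )
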