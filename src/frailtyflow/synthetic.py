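"""Stochastic synthetic cohorts with known ground truth.

Generates annual observation tables that mimic the structure of the primary
care cohort data: per subgroup-year, competing outcomes (die / de-register /
progress / age / stay) are drawn from a single multinomial on the
start-of-year alive count, and entries are Poisson. The true parameters are
returned alongside, so calibration and validation can be tested end to end
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .domain import N_BANDS, N_STATES, iter_subgroups
from .engine import (
    ConfigurationError,
    EntrySpec,
    FlowSpec,
    ModelParameters,
    PopulationState,
    annual_proportions,
)
from .calibration import CohortObservations, FLOW_COLUMNS
from .datasets import table1_shares

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "table1_initial_state",
    "example_parameters",
    "largest_remainder_counts",
]


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic cohort run; the seed fixes everything."""

    years: int
    initial_counts: np.ndarray  # (n_bands, n_states) persons at start
    true_params: ModelParameters
    seed: int
    start_year: int = 2006

    def __post_init__(self) -> None:
        self.initial_counts = np.asarray(self.initial_counts)
        if self.initial_counts.shape != (N_BANDS, N_STATES):
            raise ValueError(
                f"initial_counts must have shape {(N_BANDS, N_STATES)}, "
                f"got {self.initial_counts.shape}"
            )
        if np.any(self.initial_counts < 0):
            raise ValueError("initial_counts must be non-negative")
        if self.years < 1:
            raise ValueError("years must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """The true parameters echoed with the generated observations."""

    params: ModelParameters
    seed: int
    start_year: int


def generate(config: SyntheticConfig) -> Tuple[CohortObservations, GroundTruth]:
    """Draw a full observation table from the configured ground truth.

    All per-year outcome proportions are checked to sum to <= 1 in every
    subgroup before any random draw; violations raise a configuration error.
    """
    params = config.true_params
    params.validate()
    # pre-flight: proportions must form a valid multinomial in every year
    for t in range(config.years):
        props = annual_proportions(params, t)
        total = props["death"] + props["dereg"] + props["progression"] + props["ageing"]
        if np.any(total > 1.0 + 1e-12):
            b, s = np.argwhere(total > 1.0 + 1e-12)[0]
            raise ConfigurationError(
                f"outcome proportions sum to {total[b, s]:.4g} > 1 for subgroup "
                f"({b},{s}) at t={t}"
            )

    rng = np.random.default_rng(config.seed)
    shape = (config.years, N_BANDS, N_STATES)
    data: Dict[str, np.ndarray] = {
        name: np.zeros(shape) for name in ("alive_start",) + FLOW_COLUMNS
    }
    alive = np.round(config.initial_counts).astype(np.int64)

    for t in range(config.years):
        props = annual_proportions(params, t)
        data["alive_start"][t] = alive
        deaths = np.zeros((N_BANDS, N_STATES), dtype=np.int64)
        deregs = np.zeros_like(deaths)
        prog = np.zeros_like(deaths)
        ageing = np.zeros_like(deaths)
        for sg in iter_subgroups():
            b, s = sg.band.value, sg.state.value
            p = [
                props["death"][b, s],
                props["dereg"][b, s],
                props["progression"][b, s],
                props["ageing"][b, s],
            ]
            p.append(max(1.0 - sum(p), 0.0))
            draw = rng.multinomial(alive[b, s], p)
            deaths[b, s], deregs[b, s], prog[b, s], ageing[b, s] = draw[:4]
        entries = rng.poisson(props["entry"])
        data["deaths"][t] = deaths
        data["deregs"][t] = deregs
        data["progression_out"][t] = prog
        data["ageing_out"][t] = ageing
        data["entries"][t] = entries

        alive = alive - deaths - deregs - prog - ageing
        alive[:, 1:] += prog[:, :-1]
        alive[1:, :] += ageing[:-1, :]
        alive = alive + entries

    years = [config.start_year + t for t in range(config.years)]
    obs = CohortObservations(years, data)
    return obs, GroundTruth(params=params, seed=config.seed, start_year=config.start_year)


def largest_remainder_counts(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment with an exact-sum guarantee.

    ``quotas`` are real-valued cell targets (they need not sum exactly to
    ``total``). Quotas are floored and the residual units are assigned to the
    cells with the largest fractional parts (ties broken by cell order), so
    the result always sums to ``total`` exactly.
    """
    quotas = np.asarray(quotas, dtype=float)
    if np.any(quotas < 0):
        raise ValueError("quotas must be non-negative")
    floors = np.floor(quotas).astype(np.int64)
    residual = int(total - floors.sum())
    remainders = (quotas - floors).ravel()
    order = np.lexsort((np.arange(remainders.size), -remainders))
    counts = floors.copy().ravel()
    if residual >= 0:
        base, extra = divmod(residual, counts.size)
        counts += base
        counts[order[:extra]] += 1
    else:
        # over-allocation: strip units from the smallest remainders first
        deficit = -residual
        while deficit > 0:
            stripped = False
            for idx in order[::-1]:
                if deficit == 0:
                    break
                if counts[idx] > 0:
                    counts[idx] -= 1
                    deficit -= 1
                    stripped = True
            if not stripped:
                raise ValueError(f"cannot apportion negative total {total}")
    return counts.reshape(quotas.shape)


def table1_initial_state(cohort_size: int, cohort: str = "RCGP") -> PopulationState:
    """Initial population with the published per-subgroup shares of a cohort.

    ``cohort`` is "RCGP" or "SAIL". Counts are apportioned by largest
    remainder so they sum exactly to ``cohort_size``.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    shares = table1_shares(cohort)  # (n_bands, n_states) percentages
    counts = largest_remainder_counts(shares / 100.0 * cohort_size, cohort_size)
    shape = (N_BANDS, N_STATES)
    return PopulationState(
        alive=counts.astype(float),
        died_cum=np.zeros(shape),
        left_cum=np.zeros(shape),
        entered_cum=np.zeros(shape),
        t=0,
    )


def example_parameters(
    entry_rate: float = 400.0,
    seed: Optional[int] = None,
) -> ModelParameters:
    """Plausible constant ground-truth parameters for demos and tests.

    Death risk rises with band and state; progression and ageing decline with
    state/band size. If ``seed`` is given, rates are jittered reproducibly.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    death = {}
    dereg = {}
    entry = {}
    ageing = {}
    progression = {}
    for b in range(N_BANDS):
        for s in range(N_STATES):
            p_death = 0.005 * (1 + b) * (1 + 0.8 * s)
            p_dereg = 0.03
            if rng is not None:
                p_death *= rng.uniform(0.8, 1.2)
                p_dereg *= rng.uniform(0.8, 1.2)
            death[(b, s)] = FlowSpec(kind="constant", p=min(p_death, 1.0))
            dereg[(b, s)] = FlowSpec(kind="constant", p=min(p_dereg, 1.0))
            rate = entry_rate
            if rng is not None:
                rate *= rng.uniform(0.8, 1.2)
            entry[(b, s)] = EntrySpec(kind="constant", rate=rate)
            if b < N_BANDS - 1:
                p_age = {0: 1 / 15, 1: 1 / 10, 2: 1 / 10}[b]
                ageing[(b, s)] = FlowSpec(kind="constant", p=p_age)
            if s < N_STATES - 1:
                p_prog = 0.02 * (1 + 0.5 * b)
                if rng is not None:
                    p_prog *= rng.uniform(0.8, 1.2)
                progression[(b, s)] = FlowSpec(kind="constant", p=min(p_prog, 1.0))
    return ModelParameters(
        death=death, dereg=dereg, entry=entry, ageing=ageing, progression=progression
    )
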