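"""Stock-flow engine: build the compartment grid and simulate annual dynamics.

For an ``n_bands x n_states`` grid there are three stocks per subgroup (alive,
cumulatively died, cumulatively left) and five flow families: exogenous entry,
death, de-registration, adjacent frailty progression (not from the worst
state) and ageing to the next band (not from the last band). At the default
4 x 4 configuration this yields 48 stocks and 72 flows.

The clock is a discrete annual update. Within a year all outflows compete
synchronously on the start-of-year alive stock; entries are added afterwards.
Frailty progression and ageing are strictly one-directional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .domain import N_BANDS, N_STATES

__all__ = [
    "ConfigurationError",
    "FlowSpec",
    "EntrySpec",
    "ModelParameters",
    "Model",
    "PopulationState",
    "FlowRecord",
    "Trajectory",
    "build_model",
    "annual_proportions",
    "step",
    "simulate",
    "zero_state",
]

Key = Tuple[int, int]  # (band index, state index)


class ConfigurationError(ValueError):
    """A parameter set or input file is structurally invalid."""


def _eval_poly(beta: Sequence[float], t: float, t_max: Optional[float]) -> float:
    if t_max is not None:
        t = min(t, t_max)
    return float(sum(b * t**k for k, b in enumerate(beta)))


@dataclass(frozen=True)
class FlowSpec:
    """A per-year transition proportion: constant or polynomial in time.

    Polynomial form: proportion(t) = beta0 + beta1*t + beta2*t^2 + beta3*t^3,
    evaluated at min(t, t_max) so rates freeze at the end of the calibration
    window, then clamped to [0, 1].
    """

    kind: str  # "constant" | "polynomial"
    p: Optional[float] = None
    beta: Optional[Tuple[float, ...]] = None
    t_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.p is None:
                raise ConfigurationError("constant FlowSpec requires p")
            if not 0.0 <= self.p <= 1.0:
                raise ConfigurationError(f"constant proportion {self.p} outside [0, 1]")
        elif self.kind == "polynomial":
            if self.beta is None or len(self.beta) == 0:
                raise ConfigurationError("polynomial FlowSpec requires beta")
            object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        else:
            raise ConfigurationError(f"unknown FlowSpec kind {self.kind!r}")

    def proportion_at(self, t: float) -> float:
        if self.kind == "constant":
            return float(self.p)
        raw = _eval_poly(self.beta, t, self.t_max)
        if raw < 0.0 or raw > 1.0:
            warnings.warn(
                f"flow proportion {raw:.4g} at t={t} clamped to [0, 1]",
                stacklevel=2,
            )
        return min(max(raw, 0.0), 1.0)

    def scaled(self, factor: float) -> "FlowSpec":
        """Multiply the proportion through by a non-negative factor."""
        if factor < 0:
            raise ValueError(f"scaling factor {factor} must be non-negative")
        if self.kind == "constant":
            p = self.p * factor
            if p > 1.0:
                warnings.warn(f"scaled constant proportion {p:.4g} clamped to 1")
                p = 1.0
            return replace(self, p=p)
        return replace(self, beta=tuple(b * factor for b in self.beta))


@dataclass(frozen=True)
class EntrySpec:
    """Expected entrants per year (persons/year, not a proportion)."""

    kind: str  # "constant" | "polynomial"
    rate: Optional[float] = None
    beta: Optional[Tuple[float, ...]] = None
    t_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.rate is None:
                raise ConfigurationError("constant EntrySpec requires rate")
            if self.rate < 0:
                raise ConfigurationError(f"entry rate {self.rate} must be >= 0")
        elif self.kind == "polynomial":
            if self.beta is None or len(self.beta) == 0:
                raise ConfigurationError("polynomial EntrySpec requires beta")
            object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        else:
            raise ConfigurationError(f"unknown EntrySpec kind {self.kind!r}")

    def rate_at(self, t: float) -> float:
        if self.kind == "constant":
            return float(self.rate)
        raw = _eval_poly(self.beta, t, self.t_max)
        if raw < 0.0:
            warnings.warn(f"entry rate {raw:.4g} at t={t} clamped to 0", stacklevel=2)
        return max(raw, 0.0)

    def scaled(self, factor: float) -> "EntrySpec":
        if factor < 0:
            raise ValueError(f"scaling factor {factor} must be non-negative")
        if self.kind == "constant":
            return replace(self, rate=self.rate * factor)
        return replace(self, beta=tuple(b * factor for b in self.beta))


@dataclass
class ModelParameters:
    """Complete flow specification for an ``n_bands x n_states`` grid.

    ``death``, ``dereg`` and ``entry`` are keyed by every (band, state) pair;
    ``ageing`` omits the last band and ``progression`` omits the last state.
    """

    death: Dict[Key, FlowSpec]
    dereg: Dict[Key, FlowSpec]
    entry: Dict[Key, EntrySpec]
    ageing: Dict[Key, FlowSpec]
    progression: Dict[Key, FlowSpec]
    n_bands: int = N_BANDS
    n_states: int = N_STATES

    def validate(self) -> None:
        nb, ns = self.n_bands, self.n_states
        full = {(b, s) for b in range(nb) for s in range(ns)}
        ageing_keys = {(b, s) for b in range(nb - 1) for s in range(ns)}
        prog_keys = {(b, s) for b in range(nb) for s in range(ns - 1)}
        for name, specs, expected in (
            ("death", self.death, full),
            ("dereg", self.dereg, full),
            ("entry", self.entry, full),
            ("ageing", self.ageing, ageing_keys),
            ("progression", self.progression, prog_keys),
        ):
            missing = expected - set(specs)
            if missing:
                b, s = min(missing)
                raise ConfigurationError(
                    f"missing {name} spec for subgroup (band {b}, state {s})"
                )
            extra = set(specs) - expected
            if extra:
                b, s = min(extra)
                raise ConfigurationError(
                    f"unexpected {name} spec for subgroup (band {b}, state {s})"
                )


@dataclass(frozen=True)
class Model:
    """A validated parameter grid plus its structural stock/flow inventory."""

    params: ModelParameters
    n_bands: int
    n_states: int

    @property
    def n_stocks(self) -> int:
        return self.n_bands * self.n_states * 3

    @property
    def n_flows(self) -> int:
        nb, ns = self.n_bands, self.n_states
        return 3 * nb * ns + nb * (ns - 1) + (nb - 1) * ns

    def flow_edges(self) -> List[Tuple[str, Optional[Key], Optional[Key]]]:
        """All flows as (name, source subgroup or None, target subgroup or None)."""
        edges: List[Tuple[str, Optional[Key], Optional[Key]]] = []
        for b in range(self.n_bands):
            for s in range(self.n_states):
                edges.append(("entry", None, (b, s)))
                edges.append(("death", (b, s), None))
                edges.append(("dereg", (b, s), None))
                if s < self.n_states - 1:
                    edges.append(("progression", (b, s), (b, s + 1)))
                if b < self.n_bands - 1:
                    edges.append(("ageing", (b, s), (b + 1, s)))
        return edges


def build_model(
    n_bands: int = N_BANDS,
    n_states: int = N_STATES,
    params: Optional[ModelParameters] = None,
) -> Model:
    """Assemble and validate the stock-flow model for the requested grid."""
    if n_bands < 1 or n_states < 1:
        raise ConfigurationError("grid must have at least one band and one state")
    if params is None:
        params = zero_parameters(n_bands, n_states)
    if (params.n_bands, params.n_states) != (n_bands, n_states):
        raise ConfigurationError(
            f"parameters are for a {params.n_bands}x{params.n_states} grid, "
            f"not {n_bands}x{n_states}"
        )
    params.validate()
    return Model(params=params, n_bands=n_bands, n_states=n_states)


def zero_parameters(n_bands: int = N_BANDS, n_states: int = N_STATES) -> ModelParameters:
    """All-zero parameter grid (useful as a template)."""
    zero = FlowSpec(kind="constant", p=0.0)
    zentry = EntrySpec(kind="constant", rate=0.0)
    return ModelParameters(
        death={(b, s): zero for b in range(n_bands) for s in range(n_states)},
        dereg={(b, s): zero for b in range(n_bands) for s in range(n_states)},
        entry={(b, s): zentry for b in range(n_bands) for s in range(n_states)},
        ageing={(b, s): zero for b in range(n_bands - 1) for s in range(n_states)},
        progression={(b, s): zero for b in range(n_bands) for s in range(n_states - 1)},
        n_bands=n_bands,
        n_states=n_states,
    )


@dataclass
class PopulationState:
    """Alive stocks plus cumulative accounting stocks, per subgroup.

    Arrays have shape (n_bands, n_states); ``t`` counts years since the
    simulation origin.
    """

    alive: np.ndarray
    died_cum: np.ndarray
    left_cum: np.ndarray
    entered_cum: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.alive = np.asarray(self.alive, dtype=float)
        self.died_cum = np.asarray(self.died_cum, dtype=float)
        self.left_cum = np.asarray(self.left_cum, dtype=float)
        self.entered_cum = np.asarray(self.entered_cum, dtype=float)
        if np.any(self.alive < 0):
            raise ValueError("alive stocks must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.alive.shape

    def copy(self) -> "PopulationState":
        return PopulationState(
            alive=self.alive.copy(),
            died_cum=self.died_cum.copy(),
            left_cum=self.left_cum.copy(),
            entered_cum=self.entered_cum.copy(),
            t=self.t,
        )

    def total_alive(self) -> float:
        return float(self.alive.sum())


def zero_state(n_bands: int = N_BANDS, n_states: int = N_STATES) -> PopulationState:
    shape = (n_bands, n_states)
    return PopulationState(
        alive=np.zeros(shape),
        died_cum=np.zeros(shape),
        left_cum=np.zeros(shape),
        entered_cum=np.zeros(shape),
        t=0,
    )


@dataclass
class FlowRecord:
    """Realised flows during one simulated year, per subgroup (persons/year)."""

    deaths: np.ndarray
    deregs: np.ndarray
    entries: np.ndarray
    ageing_out: np.ndarray
    progression_out: np.ndarray

    def copy(self) -> "FlowRecord":
        return FlowRecord(
            deaths=self.deaths.copy(),
            deregs=self.deregs.copy(),
            entries=self.entries.copy(),
            ageing_out=self.ageing_out.copy(),
            progression_out=self.progression_out.copy(),
        )


def annual_proportions(params: ModelParameters, t: float) -> Dict[str, np.ndarray]:
    """Evaluate every flow spec at model time ``t``.

    Returns arrays of shape (n_bands, n_states): proportions for death, dereg,
    progression (zero in the last state) and ageing (zero in the last band),
    plus expected entries in persons/year.
    """
    if t < 0:
        raise ValueError("model time must be >= 0")
    nb, ns = params.n_bands, params.n_states
    out = {
        name: np.zeros((nb, ns))
        for name in ("death", "dereg", "progression", "ageing", "entry")
    }
    for (b, s), spec in params.death.items():
        out["death"][b, s] = spec.proportion_at(t)
    for (b, s), spec in params.dereg.items():
        out["dereg"][b, s] = spec.proportion_at(t)
    for (b, s), spec in params.progression.items():
        out["progression"][b, s] = spec.proportion_at(t)
    for (b, s), spec in params.ageing.items():
        out["ageing"][b, s] = spec.proportion_at(t)
    for (b, s), spec in params.entry.items():
        out["entry"][b, s] = spec.rate_at(t)
    return out


def step(
    state: PopulationState,
    params: ModelParameters,
    substeps: int = 1,
) -> Tuple[PopulationState, FlowRecord]:
    """Advance the population by one year.

    All outflows compete synchronously on the start-of-(sub)step alive stock:
    deaths = p_death*N, de-registrations = p_dereg*N, progression to the next
    frailty state = p_prog*N, ageing to the next band = p_age*N. If the four
    proportions jointly exceed 1 they are rescaled proportionally (with a
    warning). Entries are exogenous and added after the outflows.

    ``substeps > 1`` enables a sub-annual Euler mode: each of the k substeps
    applies proportion 1 - (1-p)^(1/k) and 1/k of the annual entry rate.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if np.any(state.alive < 0):
        raise ValueError("alive stocks must be non-negative")

    props = annual_proportions(params, state.t)
    new = state.copy()
    rec = FlowRecord(
        deaths=np.zeros(state.shape),
        deregs=np.zeros(state.shape),
        entries=np.zeros(state.shape),
        ageing_out=np.zeros(state.shape),
        progression_out=np.zeros(state.shape),
    )

    dt = 1.0 / substeps
    if substeps == 1:
        p_death = props["death"]
        p_dereg = props["dereg"]
        p_prog = props["progression"]
        p_age = props["ageing"]
    else:
        conv = lambda p: 1.0 - (1.0 - p) ** dt  # noqa: E731
        p_death, p_dereg, p_prog, p_age = (
            conv(props[k]) for k in ("death", "dereg", "progression", "ageing")
        )
    total = p_death + p_dereg + p_prog + p_age
    if np.any(total > 1.0 + 1e-12):
        warnings.warn(
            "total outflow proportion exceeds 1 in some subgroup; "
            "rescaling all outflows proportionally",
            stacklevel=2,
        )
        scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
        p_death, p_dereg, p_prog, p_age = (
            p * scale for p in (p_death, p_dereg, p_prog, p_age)
        )

    for _ in range(substeps):
        n0 = new.alive
        deaths = p_death * n0
        deregs = p_dereg * n0
        prog_out = p_prog * n0
        age_out = p_age * n0
        entries = props["entry"] * dt

        alive = n0 - deaths - deregs - prog_out - age_out
        # outflows never exceed the stock after rescaling, so any negative
        # residual is pure floating-point noise
        alive = np.clip(alive, 0.0, None)
        # arrivals: progression shifts along the state axis, ageing along bands
        alive[:, 1:] += prog_out[:, :-1]
        alive[1:, :] += age_out[:-1, :]
        alive += entries

        new.alive = alive
        new.died_cum = new.died_cum + deaths
        new.left_cum = new.left_cum + deregs
        new.entered_cum = new.entered_cum + entries
        rec.deaths += deaths
        rec.deregs += deregs
        rec.entries += entries
        rec.ageing_out += age_out
        rec.progression_out += prog_out

    new.t = state.t + 1
    return new, rec


@dataclass
class Trajectory:
    """Annual states (horizon + 1 of them) and the flows of each elapsed year."""

    states: List[PopulationState]
    flows: List[FlowRecord]
    start_year: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.states) != len(self.flows) + 1:
            raise ValueError("trajectory needs exactly one more state than flow record")

    @property
    def horizon(self) -> int:
        return len(self.flows)

    def years(self) -> List[int]:
        y0 = 0 if self.start_year is None else self.start_year
        return [y0 + k for k in range(len(self.states))]

    def alive_series(self, band: int, state: int) -> np.ndarray:
        return np.array([s.alive[band, state] for s in self.states])

    def flow_series(self, name: str, band: int, state: int) -> np.ndarray:
        return np.array([getattr(f, name)[band, state] for f in self.flows])


def simulate(
    initial: PopulationState,
    params: ModelParameters,
    horizon: int,
    substeps: int = 1,
    start_year: Optional[int] = None,
) -> Trajectory:
    """Run the annual update ``horizon`` times; deterministic given inputs."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    params.validate()
    states = [initial.copy()]
    flows: List[FlowRecord] = []
    for _ in range(horizon):
        nxt, rec = step(states[-1], params, substeps=substeps)
        states.append(nxt)
        flows.append(rec)
    return Trajectory(states=states, flows=flows, start_year=start_year)
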