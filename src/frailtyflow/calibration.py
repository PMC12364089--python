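"""Estimate flow specifications from annual cohort observation tables.

Transition proportions are the per-year ratio of a flow count to the
start-of-year alive stock of its source subgroup. Each flow is fitted by
ordinary least squares on polynomials of time (degree 0..3), the degree being
chosen by forward nested F-tests; entry flows are fitted on the raw counts
(persons/year) rather than proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .domain import (
    AgeBand,
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
)

__all__ = [
    "CohortObservations",
    "FittedFlow",
    "FLOW_COLUMNS",
    "yearly_proportions",
    "fit_flow",
    "fit_entry",
    "calibrate",
    "initial_state_from",
]

FLOW_COLUMNS = ("deaths", "deregs", "entries", "ageing_out", "progression_out")

#: observation CSV columns, in canonical order
OBS_COLUMNS = ("year", "band", "state", "alive_start") + FLOW_COLUMNS


class CohortObservations:
    """Annual observed stocks and flow counts for the 4x4 subgroup grid.

    Holds, for each observation year, the start-of-year alive count and the
    within-year flow counts of every subgroup, as arrays of shape
    (n_years, n_bands, n_states).
    """

    def __init__(self, years: Sequence[int], data: Dict[str, np.ndarray]):
        self.years = [int(y) for y in years]
        if len(self.years) == 0:
            raise ValueError("observations need at least one year")
        if self.years != sorted(self.years):
            raise ValueError("observation years must be sorted")
        if len(set(self.years)) != len(self.years):
            raise ValueError("duplicate observation years")
        expected = ("alive_start",) + FLOW_COLUMNS
        missing = set(expected) - set(data)
        if missing:
            raise ValueError(f"missing observation arrays: {sorted(missing)}")
        shape = (len(self.years), N_BANDS, N_STATES)
        self.data = {}
        for name in expected:
            arr = np.asarray(data[name], dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"array {name!r} has shape {arr.shape}, expected {shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"array {name!r} contains negative counts")
            self.data[name] = arr
        outflow = sum(
            self.data[c] for c in ("deaths", "deregs", "ageing_out", "progression_out")
        )
        if np.any(outflow > self.data["alive_start"] + 1e-9):
            warnings.warn(
                "some subgroup-years have outflows exceeding the start-of-year "
                "alive count; proceeding (real-data noise tolerated)"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def start_year(self) -> int:
        return self.years[0]

    def series(self, name: str, band: int, state: int) -> np.ndarray:
        return self.data[name][:, band, state]

    def to_frame(self) -> pd.DataFrame:
        """Long/tidy table, one row per (year, band, state)."""
        rows = []
        for yi, year in enumerate(self.years):
            for sg in iter_subgroups():
                row = {
                    "year": year,
                    "band": sg.band.label,
                    "state": sg.state.label,
                    "alive_start": self.data["alive_start"][yi, sg.band, sg.state],
                }
                for col in FLOW_COLUMNS:
                    row[col] = self.data[col][yi, sg.band, sg.state]
                rows.append(row)
        return pd.DataFrame(rows, columns=list(OBS_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortObservations":
        missing = set(OBS_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"observations table missing columns: {sorted(missing)}")
        years = sorted(int(y) for y in frame["year"].unique())
        shape = (len(years), N_BANDS, N_STATES)
        data = {name: np.full(shape, np.nan) for name in ("alive_start",) + FLOW_COLUMNS}
        year_index = {y: i for i, y in enumerate(years)}
        for _, row in frame.iterrows():
            yi = year_index[int(row["year"])]
            b = AgeBand.from_label(str(row["band"])).value
            s = FrailtyState.from_label(str(row["state"])).value
            for name in ("alive_start",) + FLOW_COLUMNS:
                data[name][yi, b, s] = float(row[name])
        for name, arr in data.items():
            if np.any(np.isnan(arr)):
                yi, b, s = np.argwhere(np.isnan(arr))[0]
                raise ValueError(
                    f"observations missing row for year {years[yi]}, "
                    f"band {AgeBand(b).label!r}, state {FrailtyState(s).label!r}"
                )
        return cls(years, data)


@dataclass
class FittedFlow:
    """Result of polynomial least-squares fitting with degree selection."""

    spec: FlowSpec
    degree: int
    rss: float
    #: (degree tested, p-value of the added term) for each forward step
    selection_trace: List[Tuple[int, float]] = field(default_factory=list)
    coefficients: Tuple[float, ...] = ()


def yearly_proportions(
    observations: CohortObservations,
    band: int,
    state: int,
    flow_name: str,
) -> List[Tuple[float, float]]:
    """Per-year (t, flow count / start-of-year alive) for one subgroup flow.

    ``t`` counts years since the first observation year. Years with a zero
    alive denominator are excluded with a warning.
    """
    if flow_name not in FLOW_COLUMNS:
        raise ValueError(f"unknown flow {flow_name!r}")
    alive = observations.series("alive_start", band, state)
    flow = observations.series(flow_name, band, state)
    points = []
    for yi, year in enumerate(observations.years):
        if alive[yi] <= 0:
            warnings.warn(
                f"year {year}: zero alive count in subgroup ({band},{state}); "
                "excluded from proportion series"
            )
            continue
        points.append((float(yi), float(flow[yi] / alive[yi])))
    if not points:
        raise ValueError(
            f"no usable observation years for subgroup ({band},{state}) {flow_name}"
        )
    return points


def _ols_poly(t: np.ndarray, y: np.ndarray, degree: int) -> Tuple[np.ndarray, float]:
    """Least-squares polynomial fit; returns (coefficients low->high, RSS)."""
    X = np.vander(t, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _select_degree(
    t: np.ndarray,
    y: np.ndarray,
    max_degree: int,
    alpha: float,
) -> Tuple[int, Dict[int, Tuple[np.ndarray, float]], List[Tuple[int, float]]]:
    """Forward nested F-tests: raise the degree while the added term helps."""
    n = len(t)
    max_degree = min(max_degree, max(n - 2, 0), len(np.unique(t)) - 1)
    fits = {d: _ols_poly(t, y, d) for d in range(max_degree + 1)}
    trace: List[Tuple[int, float]] = []
    chosen = 0
    tol = 1e-12 * max(1.0, float(y @ y))
    for d in range(1, max_degree + 1):
        rss0 = fits[d - 1][1]
        rss1 = fits[d][1]
        dof = n - (d + 1)
        if dof <= 0:
            break
        if rss1 <= tol:
            # an exact (noiseless) fit: accept iff it actually reduced the RSS
            pval = 0.0 if rss0 > tol else 1.0
        else:
            f_stat = (rss0 - rss1) / (rss1 / dof)
            pval = float(stats.f.sf(max(f_stat, 0.0), 1, dof))
        trace.append((d, pval))
        if pval < alpha:
            chosen = d
        else:
            break
    return chosen, fits, trace


def fit_flow(
    points: Sequence[Tuple[float, float]],
    max_degree: int = 3,
    alpha: float = 0.05,
) -> FittedFlow:
    """Fit a proportion series with polynomial OLS and nested-F degree selection.

    With fewer than two points, returns a constant spec equal to the mean with
    a warning. The returned spec freezes at t_max = max observed t.
    """
    pts = [(float(t), float(p)) for t, p in points]
    if len(pts) < 2:
        warnings.warn("fewer than 2 points; returning constant mean spec")
        mean = pts[0][1] if pts else 0.0
        spec = FlowSpec(kind="constant", p=min(max(mean, 0.0), 1.0))
        return FittedFlow(spec=spec, degree=0, rss=0.0, coefficients=(mean,))
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    degree, fits, trace = _select_degree(t, y, max_degree, alpha)
    coef, rss = fits[degree]
    t_max = float(t.max())
    if degree == 0:
        mean = float(coef[0])
        spec = FlowSpec(kind="constant", p=min(max(mean, 0.0), 1.0))
    else:
        beta = tuple(float(c) for c in coef) + (0.0,) * (4 - len(coef))
        spec = FlowSpec(kind="polynomial", beta=beta[:4], t_max=t_max)
    return FittedFlow(
        spec=spec,
        degree=degree,
        rss=rss,
        selection_trace=trace,
        coefficients=tuple(float(c) for c in coef),
    )


def fit_entry(
    observations: CohortObservations,
    band: int,
    state: int,
    max_degree: int = 3,
    alpha: float = 0.05,
) -> Tuple[EntrySpec, FittedFlow]:
    """Fit the entry count series (persons/year) for one subgroup."""
    counts = observations.series("entries", band, state)
    t = np.arange(len(observations.years), dtype=float)
    if len(t) < 2:
        warnings.warn("fewer than 2 points; returning constant mean entry spec")
        spec = EntrySpec(kind="constant", rate=max(float(counts.mean()), 0.0))
        return spec, FittedFlow(
            spec=FlowSpec(kind="constant", p=0.0), degree=0, rss=0.0
        )
    degree, fits, trace = _select_degree(t, counts, max_degree, alpha)
    coef, rss = fits[degree]
    if degree == 0:
        spec = EntrySpec(kind="constant", rate=max(float(coef[0]), 0.0))
    else:
        beta = tuple(float(c) for c in coef) + (0.0,) * (4 - len(coef))
        spec = EntrySpec(kind="polynomial", beta=beta[:4], t_max=float(t.max()))
    fitted = FittedFlow(
        spec=FlowSpec(kind="constant", p=0.0),  # placeholder; entry uses EntrySpec
        degree=degree,
        rss=rss,
        selection_trace=trace,
        coefficients=tuple(float(c) for c in coef),
    )
    return spec, fitted


#: flow column -> (parameter slot, applicability predicate)
_PROPORTION_FLOWS = {
    "deaths": "death",
    "deregs": "dereg",
    "ageing_out": "ageing",
    "progression_out": "progression",
}


def calibrate(
    observations: CohortObservations,
    max_degree: int = 3,
    alpha: float = 0.05,
) -> ModelParameters:
    """Fit one spec per required flow (16 death + 16 dereg + 16 entry +
    12 ageing + 12 progression) from the observation table."""
    if observations.n_years < 2:
        raise ConfigurationError("calibration needs at least 2 observation years")
    death: Dict[Tuple[int, int], FlowSpec] = {}
    dereg: Dict[Tuple[int, int], FlowSpec] = {}
    ageing: Dict[Tuple[int, int], FlowSpec] = {}
    progression: Dict[Tuple[int, int], FlowSpec] = {}
    entry: Dict[Tuple[int, int], EntrySpec] = {}
    slots = {"death": death, "dereg": dereg, "ageing": ageing, "progression": progression}
    for sg in iter_subgroups():
        b, s = sg.band.value, sg.state.value
        for column, slot in _PROPORTION_FLOWS.items():
            if slot == "ageing" and b == N_BANDS - 1:
                continue
            if slot == "progression" and s == N_STATES - 1:
                continue
            points = yearly_proportions(observations, b, s, column)
            slots[slot][(b, s)] = fit_flow(points, max_degree, alpha).spec
        entry[(b, s)], _ = fit_entry(observations, b, s, max_degree, alpha)
    params = ModelParameters(
        death=death, dereg=dereg, entry=entry, ageing=ageing, progression=progression
    )
    params.validate()
    return params


def calibration_report(
    observations: CohortObservations,
    max_degree: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-flow table of chosen degree, coefficients, RSS and F-test trace."""
    rows = []
    for sg in iter_subgroups():
        b, s = sg.band.value, sg.state.value
        for column, slot in _PROPORTION_FLOWS.items():
            if slot == "ageing" and b == N_BANDS - 1:
                continue
            if slot == "progression" and s == N_STATES - 1:
                continue
            fitted = fit_flow(
                yearly_proportions(observations, b, s, column), max_degree, alpha
            )
            rows.append(_report_row(sg, slot, fitted))
        _, fitted = fit_entry(observations, b, s, max_degree, alpha)
        rows.append(_report_row(sg, "entry", fitted))
    return pd.DataFrame(rows)


def _report_row(sg, flow: str, fitted: FittedFlow) -> dict:
    return {
        "band": sg.band.label,
        "state": sg.state.label,
        "flow": flow,
        "degree": fitted.degree,
        "coefficients": ";".join(f"{c:.12g}" for c in fitted.coefficients),
        "rss": fitted.rss,
        "f_test_trace": ";".join(f"d{d}:p={p:.4g}" for d, p in fitted.selection_trace),
    }


def initial_state_from(
    observations: CohortObservations, year: Optional[int] = None
) -> PopulationState:
    """Population state whose alive stocks copy one observation year."""
    if year is None:
        year = observations.start_year
    if year not in observations.years:
        raise ValueError(
            f"year {year} not in observations ({observations.years[0]}.."
            f"{observations.years[-1]})"
        )
    yi = observations.years.index(year)
    shape = (N_BANDS, N_STATES)
    return PopulationState(
        alive=observations.data["alive_start"][yi].copy(),
        died_cum=np.zeros(shape),
        left_cum=np.zeros(shape),
        entered_cum=np.zeros(shape),
        t=0,
    )
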