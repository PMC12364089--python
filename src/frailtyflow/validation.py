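"""Model-fit assessment via MAPE tables, and cross-cohort rescaling.

The fit statistic is the mean absolute percentage error between an observed
and a simulated annual series, tabulated per subgroup for six variables:
Alive, Entering, Dying, Deregistration, Ageing and FrailtyTransition (the
last two only where the flow exists), 88 cells in all for the 4x4 grid. The
overall figure is the equal-weighted mean of the cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .domain import (
    AgeBand,
    FrailtyState,
    N_BANDS,
    N_STATES,
    iter_subgroups,
)
from .engine import ModelParameters, PopulationState, Trajectory

__all__ = [
    "UndefinedMapeError",
    "MAPE_VARIABLES",
    "MapeTable",
    "ScalingFactors",
    "mape",
    "build_mape_table",
    "rescale_parameters",
    "scale_initial_prevalence",
]

MAPE_VARIABLES = (
    "Alive",
    "Entering",
    "Dying",
    "Deregistration",
    "Ageing",
    "FrailtyTransition",
)

CellKey = Tuple[str, str, str]  # (band label, state label, variable)


class UndefinedMapeError(ValueError):
    """Raised when every observed point is zero, leaving MAPE undefined."""


def mape(observed: Sequence[float], estimated: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent.

    Points with a zero observed value are excluded (with a warning) rather
    than producing infinite terms; if all points are zero the MAPE is
    undefined and an :class:`UndefinedMapeError` is raised.
    """
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.shape != est.shape:
        raise ValueError(f"series lengths differ: {obs.shape} vs {est.shape}")
    if obs.size == 0:
        raise UndefinedMapeError("empty series")
    nonzero = obs != 0
    if not np.any(nonzero):
        raise UndefinedMapeError("all observed values are zero; MAPE undefined")
    if not np.all(nonzero):
        warnings.warn(
            f"{int((~nonzero).sum())} zero-observed point(s) excluded from MAPE"
        )
    return float(
        np.mean(np.abs(obs[nonzero] - est[nonzero]) / np.abs(obs[nonzero])) * 100.0
    )


@dataclass
class MapeTable:
    """Per-cell MAPE grid with an equal-weighted overall summary.

    For the 4x4 model there are 88 cells: 16 subgroups x {Alive, Entering,
    Dying, Deregistration} plus 12 Ageing and 12 FrailtyTransition cells
    (keyed by the source state of the transition). Cells whose MAPE is
    undefined are stored as NaN and excluded from the overall mean.
    """

    cells: Dict[CellKey, float]

    def __post_init__(self) -> None:
        for key, value in self.cells.items():
            band, state, variable = key
            if variable not in MAPE_VARIABLES:
                raise ValueError(f"unknown MAPE variable {variable!r} in cell {key}")
            if not math.isnan(value) and value < 0:
                raise ValueError(f"negative MAPE {value} in cell {key}")

    def __len__(self) -> int:
        return len(self.cells)

    def values(self) -> np.ndarray:
        return np.array(list(self.cells.values()), dtype=float)

    def overall(self, weighting: str = "flat") -> float:
        """Equal-weighted summary across cells.

        ``flat`` (default): unweighted mean of every cell. ``by_class``: mean
        of the six per-variable means.
        """
        if weighting == "flat":
            return float(np.nanmean(self.values()))
        if weighting == "by_class":
            means = []
            for variable in MAPE_VARIABLES:
                vals = [v for (b, s, var), v in self.cells.items() if var == variable]
                if vals:
                    means.append(np.nanmean(vals))
            return float(np.mean(means))
        raise ValueError(f"unknown weighting {weighting!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"band": b, "state": s, "variable": var, "mape": v}
            for (b, s, var), v in self.cells.items()
        ]
        return pd.DataFrame(rows, columns=["band", "state", "variable", "mape"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MapeTable":
        required = {"band", "state", "variable", "mape"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"MAPE table missing columns: {sorted(missing)}")
        cells = {
            (str(r["band"]), str(r["state"]), str(r["variable"])): float(r["mape"])
            for _, r in frame.iterrows()
        }
        return cls(cells)


def _expected_cell_keys() -> Iterable[CellKey]:
    for sg in iter_subgroups():
        b, s = sg.band.label, sg.state.label
        for variable in ("Alive", "Entering", "Dying", "Deregistration"):
            yield (b, s, variable)
        if sg.band.value < N_BANDS - 1:
            yield (b, s, "Ageing")
        if sg.state.value < N_STATES - 1:
            yield (b, s, "FrailtyTransition")


#: MAPE variable -> flow record attribute
_FLOW_FOR_VARIABLE = {
    "Entering": "entries",
    "Dying": "deaths",
    "Deregistration": "deregs",
    "Ageing": "ageing_out",
    "FrailtyTransition": "progression_out",
}
_OBS_FOR_VARIABLE = {
    "Entering": "entries",
    "Dying": "deaths",
    "Deregistration": "deregs",
    "Ageing": "ageing_out",
    "FrailtyTransition": "progression_out",
}


def build_mape_table(observations, trajectory: Trajectory) -> MapeTable:
    """Score a simulated trajectory against observed cohort data.

    Stocks are compared at the start of every year in the overlap (including
    year 0, which contributes zero error when the initial conditions were
    copied from the observations); flows are compared on the within-year
    totals. Requires at least a 2-year overlap.
    """
    obs_years = observations.years
    traj_years = trajectory.years()
    flow_years = traj_years[:-1]  # the year each FlowRecord covers
    stock_overlap = [y for y in obs_years if y in traj_years]
    flow_overlap = [y for y in obs_years if y in flow_years]
    if len(stock_overlap) < 2:
        raise ValueError(
            f"observed years {obs_years[0]}..{obs_years[-1]} and simulated years "
            f"{traj_years[0]}..{traj_years[-1]} overlap in fewer than 2 years"
        )

    cells: Dict[CellKey, float] = {}
    for key in _expected_cell_keys():
        band = AgeBand.from_label(key[0]).value
        state = FrailtyState.from_label(key[1]).value
        variable = key[2]
        if variable == "Alive":
            obs_series = [
                observations.series("alive_start", band, state)[obs_years.index(y)]
                for y in stock_overlap
            ]
            est_series = [
                trajectory.states[traj_years.index(y)].alive[band, state]
                for y in stock_overlap
            ]
        else:
            obs_col = _OBS_FOR_VARIABLE[variable]
            flow_attr = _FLOW_FOR_VARIABLE[variable]
            obs_series = [
                observations.series(obs_col, band, state)[obs_years.index(y)]
                for y in flow_overlap
            ]
            est_series = [
                getattr(trajectory.flows[flow_years.index(y)], flow_attr)[band, state]
                for y in flow_overlap
            ]
        try:
            cells[key] = mape(obs_series, est_series)
        except UndefinedMapeError:
            warnings.warn(f"MAPE undefined for cell {key}; recorded as NaN")
            cells[key] = float("nan")
    return MapeTable(cells)


@dataclass(frozen=True)
class ScalingFactors:
    """Multipliers applied to entry and de-registration specs.

    Each factor is either a single global multiplier or a per-subgroup
    mapping keyed by (band index, state index).
    """

    entry_scale: Union[float, Mapping[Tuple[int, int], float]] = 1.0
    dereg_scale: Union[float, Mapping[Tuple[int, int], float]] = 1.0
    prevalence_targets: Optional[Mapping[Tuple[int, int], float]] = None

    def _factor(self, which: str, key: Tuple[int, int]) -> float:
        raw = getattr(self, which)
        value = float(raw) if np.isscalar(raw) else float(raw[key])
        if value < 0:
            raise ValueError(f"{which} factor {value} for {key} must be >= 0")
        return value


def rescale_parameters(params: ModelParameters, factors: ScalingFactors) -> ModelParameters:
    """Multiply entry and de-registration specs through by the given factors.

    Both constant values and polynomial coefficients scale linearly; death,
    ageing and progression specs are untouched. Factors of zero produce the
    closed national-model parameters.
    """
    entry = {
        key: spec.scaled(factors._factor("entry_scale", key))
        for key, spec in params.entry.items()
    }
    dereg = {
        key: spec.scaled(factors._factor("dereg_scale", key))
        for key, spec in params.dereg.items()
    }
    return ModelParameters(
        death=dict(params.death),
        dereg=dereg,
        entry=entry,
        ageing=dict(params.ageing),
        progression=dict(params.progression),
        n_bands=params.n_bands,
        n_states=params.n_states,
    )


def scale_initial_prevalence(
    state: PopulationState,
    targets: Mapping[Tuple[int, int], float],
    mode: str = "band",
) -> PopulationState:
    """Replace the frailty mix of the alive stocks with target shares.

    ``band`` mode (default): within each age band the alive total is
    preserved and redistributed across frailty states by the target shares
    (which must sum to 1 within each band). ``overall`` mode: the grand total
    is preserved and redistributed across all 16 subgroups.
    """
    nb, ns = state.shape
    share = np.zeros((nb, ns))
    for (b, s), v in targets.items():
        if v < 0:
            raise ValueError(f"negative prevalence target {v} for subgroup ({b},{s})")
        share[b, s] = v
    new = state.copy()
    if mode == "band":
        sums = share.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(
                f"per-band target shares must sum to 1; got {sums.tolist()}"
            )
        band_totals = state.alive.sum(axis=1, keepdims=True)
        new.alive = band_totals * share
    elif mode == "overall":
        total_share = share.sum()
        if abs(total_share - 1.0) > 1e-6:
            raise ValueError(f"overall target shares must sum to 1; got {total_share}")
        new.alive = state.alive.sum() * share
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return new
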