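"""File readers and writers: observations, parameters, projections, results.

All tables are long/tidy CSV with a mandatory header and the exact label
strings "50-64", "65-74", "75-84", "85+" and "Fit", "Mild", "Moderate",
"Severe". Parameter files are YAML (or JSON, by extension) with one block
per flow family keyed by "band/state". Every writer/reader pair round-trips
losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple, Union

import pandas as pd
import yaml

from .calibration import CohortObservations, OBS_COLUMNS
from .domain import AgeBand, FrailtyState, N_BANDS, N_STATES, Subgroup, iter_subgroups
from .engine import ConfigurationError, EntrySpec, FlowSpec, ModelParameters, Trajectory
from .projection import PopulationProjection
from .validation import MapeTable

__all__ = [
    "read_observations",
    "write_observations",
    "read_params",
    "write_params",
    "read_projection",
    "write_projection",
    "read_mape_table",
    "write_mape_table",
    "write_trajectory",
]

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: Tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing column(s) {missing}; found {list(frame.columns)}"
        )
    return frame


def read_observations(path: PathLike) -> CohortObservations:
    """Load a cohort observation table, validating schema and completeness."""
    frame = _read_csv(path, OBS_COLUMNS)
    try:
        return CohortObservations.from_frame(frame)
    except ValueError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def write_observations(observations: CohortObservations, path: PathLike) -> None:
    observations.to_frame().to_csv(path, index=False)


# --- parameter files -------------------------------------------------------

_FLOW_FAMILIES = ("death", "dereg", "entry", "ageing", "progression")


def _spec_to_dict(spec) -> dict:
    if spec.kind == "constant":
        value = spec.p if isinstance(spec, FlowSpec) else spec.rate
        key = "p" if isinstance(spec, FlowSpec) else "rate"
        return {"kind": "constant", key: float(value)}
    out = {"kind": "polynomial", "beta": [float(b) for b in spec.beta]}
    if spec.t_max is not None:
        out["t_max"] = float(spec.t_max)
    return out


def _spec_from_dict(raw: dict, family: str, label: str, path) -> object:
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: {family}[{label}] must be a mapping")
    cls = EntrySpec if family == "entry" else FlowSpec
    allowed = {"kind", "beta", "t_max", "rate" if family == "entry" else "p"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: {family}[{label}] has unknown key(s) {sorted(unknown)}"
        )
    try:
        if raw.get("kind") == "polynomial":
            return cls(
                kind="polynomial",
                beta=tuple(raw["beta"]),
                t_max=raw.get("t_max"),
            )
        if family == "entry":
            return EntrySpec(kind="constant", rate=float(raw["rate"]))
        return FlowSpec(kind="constant", p=float(raw["p"]))
    except (KeyError, TypeError, ConfigurationError) as exc:
        raise ConfigurationError(f"{path}: {family}[{label}]: {exc}") from exc


def write_params(params: ModelParameters, path: PathLike) -> None:
    """Serialise a 4x4 parameter set to YAML or JSON (by file extension)."""
    if (params.n_bands, params.n_states) != (N_BANDS, N_STATES):
        raise ConfigurationError("parameter files support the standard 4x4 grid only")
    params.validate()
    flows: Dict[str, dict] = {}
    for family in _FLOW_FAMILIES:
        specs = getattr(params, family)
        flows[family] = {
            Subgroup.from_index(b * N_STATES + s).label: _spec_to_dict(spec)
            for (b, s), spec in sorted(specs.items())
        }
    doc = {"n_bands": N_BANDS, "n_states": N_STATES, "flows": flows}
    path = Path(path)
    with path.open("w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=True)


def read_params(path: PathLike) -> ModelParameters:
    """Load and strictly validate a parameter file (YAML or JSON)."""
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(doc) - {"n_bands", "n_states", "flows"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    if doc.get("n_bands", N_BANDS) != N_BANDS or doc.get("n_states", N_STATES) != N_STATES:
        raise ConfigurationError(f"{path}: parameter files support the 4x4 grid only")
    flows = doc.get("flows")
    if not isinstance(flows, dict):
        raise ConfigurationError(f"{path}: missing 'flows' mapping")
    unknown = set(flows) - set(_FLOW_FAMILIES)
    if unknown:
        raise ConfigurationError(f"{path}: unknown flow family(ies) {sorted(unknown)}")

    parsed: Dict[str, Dict[Tuple[int, int], object]] = {f: {} for f in _FLOW_FAMILIES}
    for family in _FLOW_FAMILIES:
        for label, raw in (flows.get(family) or {}).items():
            try:
                band_label, state_label = str(label).split("/")
                key = (
                    AgeBand.from_label(band_label).value,
                    FrailtyState.from_label(state_label).value,
                )
            except ValueError as exc:
                raise ConfigurationError(
                    f"{path}: bad subgroup label {label!r} in {family}: {exc}"
                ) from exc
            parsed[family][key] = _spec_from_dict(raw, family, label, path)
    params = ModelParameters(
        death=parsed["death"],
        dereg=parsed["dereg"],
        entry=parsed["entry"],
        ageing=parsed["ageing"],
        progression=parsed["progression"],
    )
    try:
        params.validate()
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    return params


# --- projections -----------------------------------------------------------


def read_projection(path: PathLike) -> PopulationProjection:
    """Load a projection table: year, entrants_50 [, band, population]."""
    frame = _read_csv(path, ("year", "entrants_50"))
    entrants = {}
    for _, row in frame.iterrows():
        if pd.isna(row["year"]):
            continue
        entrants[int(row["year"])] = float(row["entrants_50"])
    band_population = None
    if "band" in frame.columns and "population" in frame.columns:
        pop_rows = frame.dropna(subset=["band", "population"])
        if len(pop_rows):
            band_population = {
                str(r["band"]): float(r["population"]) for _, r in pop_rows.iterrows()
            }
            for label in band_population:
                AgeBand.from_label(label)  # validates
    return PopulationProjection(entrants_50=entrants, band_population=band_population)


def write_projection(projection: PopulationProjection, path: PathLike) -> None:
    rows = [
        {"year": year, "entrants_50": projection.entrants_50[year]}
        for year in projection.years()
    ]
    columns = ["year", "entrants_50"]
    if projection.band_population:
        columns += ["band", "population"]
        rows += [
            {"band": band, "population": pop}
            for band, pop in projection.band_population.items()
        ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# --- results ---------------------------------------------------------------


def write_mape_table(table: MapeTable, path: PathLike, weighting: str = "flat") -> None:
    """Write the MAPE grid with the overall summary in a footer row."""
    frame = table.to_frame()
    footer = pd.DataFrame(
        [{"band": "overall", "state": "", "variable": "", "mape": table.overall(weighting)}]
    )
    pd.concat([frame, footer], ignore_index=True).to_csv(path, index=False)


def read_mape_table(path: PathLike) -> MapeTable:
    frame = _read_csv(path, ("band", "state", "variable", "mape"))
    frame = frame[frame["band"] != "overall"]
    return MapeTable.from_frame(frame)


def write_trajectory(trajectory: Trajectory, path: PathLike) -> None:
    """Tidy export: one row per (year, band, state, variable)."""
    rows = []
    years = trajectory.years()
    stock_vars = ("alive", "died_cum", "left_cum", "entered_cum")
    flow_vars = ("deaths", "deregs", "entries", "ageing_out", "progression_out")
    for k, state in enumerate(trajectory.states):
        for sg in iter_subgroups():
            b, s = sg.band.value, sg.state.value
            for var in stock_vars:
                rows.append(
                    {
                        "year": years[k],
                        "band": sg.band.label,
                        "state": sg.state.label,
                        "variable": var,
                        "value": float(getattr(state, var)[b, s]),
                    }
                )
            if k < len(trajectory.flows):
                for var in flow_vars:
                    rows.append(
                        {
                            "year": years[k],
                            "band": sg.band.label,
                            "state": sg.state.label,
                            "variable": var,
                            "value": float(getattr(trajectory.flows[k], var)[b, s]),
                        }
                    )
    pd.DataFrame(rows, columns=["year", "band", "state", "variable", "value"]).to_csv(
        path, index=False
    )
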