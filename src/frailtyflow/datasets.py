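"""Loaders for the packaged reference tables (transcribed, 2 dp).

Four small CSVs ship with the package: the initial per-subgroup percentage
shares of the two source cohorts, the 88-cell internal and external MAPE
grids, and the 2017/2027 projection summary counts.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .domain import AgeBand, FrailtyState, N_BANDS, N_STATES

__all__ = [
    "table1_shares",
    "load_initial_shares",
    "load_internal_mape",
    "load_external_mape",
    "load_projection_summary",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("frailtyflow.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_initial_shares() -> pd.DataFrame:
    """Initial subgroup percentage shares for both cohorts (long format)."""
    return _read("initial_shares.csv")


def table1_shares(cohort: str = "RCGP") -> np.ndarray:
    """Initial percentage shares of one cohort as an (n_bands, n_states) array."""
    frame = load_initial_shares()
    sub = frame[frame["cohort"] == cohort]
    if sub.empty:
        known = sorted(frame["cohort"].unique())
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {known}")
    grid = np.zeros((N_BANDS, N_STATES))
    for _, row in sub.iterrows():
        b = AgeBand.from_label(row["band"]).value
        s = FrailtyState.from_label(row["state"]).value
        grid[b, s] = float(row["percent"])
    return grid


def load_internal_mape():
    """The 88-cell internal-validation MAPE grid as a MapeTable."""
    from .validation import MapeTable

    return MapeTable.from_frame(_read("mape_internal.csv"))


def load_external_mape():
    """The 88-cell external-validation MAPE grid as a MapeTable."""
    from .validation import MapeTable

    return MapeTable.from_frame(_read("mape_external.csv"))


def load_projection_summary() -> pd.DataFrame:
    """Published 2017/2027 per-subgroup counts and percentages (long format)."""
    return _read("projection_2017_2027.csv")


def projection_counts(year: int) -> dict:
    """Subgroup counts of one summary year keyed by (band label, state label)."""
    frame = load_projection_summary()
    sub = frame[frame["year"] == year]
    if sub.empty:
        raise ValueError(f"no packaged summary for year {year}")
    return {
        (row["band"], row["state"]): float(row["number"]) for _, row in sub.iterrows()
    }
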