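"""Robustness analysis: systematic perturbation of sensitivity and adaptive
capacity.

Sensitivity and adaptive-capacity scores are varied from -100% to +100% of
their baseline values in 10% increments (21 levels per axis, 441
combinations), with exposure left at its projected values. For each cell
the additive vulnerability is recomputed per nation on the baseline min-max
anchors — no per-cell rescaling, which would cancel any cohort-wide
perturbation — and the cell records the median percent change from the
baseline vulnerability across nations. Nations whose baseline vulnerability
is numerically near zero are excluded from the median (a percent change
from ~0 is unbounded) and counted per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig

log = logging.getLogger(__name__)

#: perturbation levels: -1.0, -0.9, ..., +1.0 (fractions of baseline)
GRID_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(-10, 11) / 10.0, 1))


def build_grid() -> list[tuple[float, float]]:
    """All (delta_S, delta_AC) combinations: 21 x 21 = 441 cells."""
    return [(ds, dac) for ds in GRID_LEVELS for dac in GRID_LEVELS]


def apply_perturbation(
    indices: pd.DataFrame, delta_S: float, delta_AC: float
) -> pd.DataFrame:
    """Scale S and AC by (1 + delta), clamped to [0, 1]; E unchanged.

    Clamping events (a perturbed score exceeding 1) are logged; scores
    cannot fall below 0 since deltas are bounded at -1.
    """
    if not -1.0 <= delta_S <= 1.0 or not -1.0 <= delta_AC <= 1.0:
        raise ValueError("perturbation deltas must lie in [-1, 1]")
    out = indices.copy()
    s_new = indices["S"] * (1.0 + delta_S)
    ac_new = indices["AC"] * (1.0 + delta_AC)
    n_clamped = int((s_new > 1.0).sum() + (ac_new > 1.0).sum())
    if n_clamped:
        log.debug(
            "clamped %d perturbed score(s) to 1.0 at (dS=%+.1f, dAC=%+.1f)",
            n_clamped, delta_S, delta_AC,
        )
    out["S"] = s_new.clip(0.0, 1.0)
    out["AC"] = ac_new.clip(0.0, 1.0)
    return out


@dataclass
class ScenarioGrid:
    """Tidy 441-row grid of median percent change in vulnerability."""

    cells: pd.DataFrame  # delta_S, delta_AC, median_pct_change, n_used, n_excluded
    floor: float

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    def cell(self, delta_S: float, delta_AC: float) -> pd.Series:
        m = self.cells[
            np.isclose(self.cells["delta_S"], delta_S)
            & np.isclose(self.cells["delta_AC"], delta_AC)
        ]
        if m.empty:
            raise KeyError((delta_S, delta_AC))
        return m.iloc[0]


def _raw_v(indices: pd.DataFrame, model: str, config: ModelConfig) -> pd.Series:
    if model == "additive":
        return indices["S"] + indices["E"] - indices["AC"]
    if config.multiplicative_form == "product":
        return indices["S"] * indices["E"] * (1.0 - indices["AC"])
    return indices["S"] * indices["E"] / (indices["AC"] + config.epsilon)


def median_percent_change(
    indices: pd.DataFrame,
    model: str = "additive",
    config: ModelConfig | None = None,
    floor: float = 0.01,
) -> ScenarioGrid:
    """Median percent change in vulnerability over the 441-cell grid.

    ``indices`` holds the baseline rescaled S, E, AC per nation. Baseline
    vulnerability is the rescaled score of the main model; each cell's
    simulated vulnerability is computed from perturbed S and AC on the
    *baseline* anchors. Per nation the percent change is
    100 x (V_sim - V_base) / V_base; nations with V_base below ``floor``
    (e.g. the least vulnerable nation, which rescales to exactly 0) are
    excluded from the cell's median and counted in ``n_excluded``.
    """
    config = config or ModelConfig()
    v_raw_base = _raw_v(indices, model, config)
    lo, hi = float(v_raw_base.min()), float(v_raw_base.max())
    if hi == lo:
        raise ValueError("baseline vulnerability has zero range")
    v_base = (v_raw_base - lo) / (hi - lo)
    included = v_base >= floor
    n_excluded = int((~included).sum())
    if n_excluded:
        log.info(
            "%d nation(s) below baseline floor %.3g excluded from grid medians: %s",
            n_excluded, floor, list(v_base.index[~included]),
        )
    rows = []
    for ds, dac in build_grid():
        pert = apply_perturbation(indices, ds, dac)
        v_sim = (_raw_v(pert, model, config) - lo) / (hi - lo)
        pct = 100.0 * (v_sim[included] - v_base[included]) / v_base[included]
        rows.append({
            "delta_S": ds,
            "delta_AC": dac,
            "median_pct_change": float(pct.median()) if len(pct) else float("nan"),
            "n_used": int(included.sum()),
            "n_excluded": n_excluded,
        })
    return ScenarioGrid(pd.DataFrame(rows), floor)
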