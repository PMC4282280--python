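"""Indicator preparation: scaling, unit conversion and category reduction.

Every indicator is placed on a common 0-1 scale by linear, absolute min-max
scaling over the cohort of nations — the lowest value observed maps to zero
and the highest to one, with no distributional normalisation, so the true
spread of values carries through to the final scores. Redundant indicators
within a category are collapsed by retaining the single member that
correlates (Spearman) most strongly with the others; the three climate
members are instead combined multiplicatively into one climate-impact value
before scaling.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CLIMATE_MEMBERS, CategoryConfig, CategorySpec, Polarity
from .errors import (
    CoefficientMissingError,
    ReductionError,
    UndefinedRatioError,
    ZeroRangeError,
)
from .io import IndicatorTable

log = logging.getLogger(__name__)


def scale_minmax(values, polarity: Polarity = "higher") -> pd.Series:
    """Scale a vector to [0, 1] linearly over its observed range.

    ``polarity="lower"`` reverses the result (1 - scaled) so that more of
    the underlying construct always scores higher. Missing values propagate
    as missing; a constant or all-missing vector raises
    :class:`~herdvuln.errors.ZeroRangeError`.
    """
    s = pd.Series(values, dtype=float)
    observed = s.dropna()
    if len(observed) < 2:
        raise ZeroRangeError(
            f"need >= 2 observed values to scale, got {len(observed)}"
        )
    lo, hi = float(observed.min()), float(observed.max())
    if hi == lo:
        raise ZeroRangeError(f"zero range: all observed values equal {lo}")
    scaled = (s - lo) / (hi - lo)
    if polarity == "lower":
        scaled = 1.0 - scaled
    return scaled


#: nominal livestock-unit coefficients for grazing species (reference cow = 1)
DEFAULT_LIVESTOCK_COEFFICIENTS: dict[str, float] = {
    "cattle": 1.0,
    "buffalo": 1.0,
    "sheep": 0.15,
    "goat": 0.10,
    "camel": 1.10,
    "horse": 0.80,
    "donkey": 0.50,
    "mule": 0.60,
}


def to_livestock_units(
    counts: Mapping[str, float],
    coeffs: Mapping[str, float] | None = None,
) -> float:
    """Convert species head counts to livestock units (LU).

    LU = sum over species of count x coefficient, which makes herds of
    different species comparable (a reference cow counts 1.0, a sheep 0.15).
    """
    if coeffs is None:
        coeffs = DEFAULT_LIVESTOCK_COEFFICIENTS
    total = 0.0
    for species, n in counts.items():
        if species not in coeffs:
            raise CoefficientMissingError(
                f"no livestock-unit coefficient for species {species!r}"
            )
        if n < 0:
            raise ValueError(f"negative head count for {species!r}")
        total += float(n) * float(coeffs[species])
    return total


def read_livestock_coefficients(path) -> dict[str, float]:
    """Read a two-column (species, coefficient) CSV of LU coefficients."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("coefficient file needs two columns: species, coefficient")
    species, coef = df.columns[:2]
    out = dict(zip(df[species].astype(str), df[coef].astype(float)))
    if any(v <= 0 for v in out.values()):
        raise ValueError("livestock-unit coefficients must be positive")
    return out


def self_sufficiency_ratio(production, exports, imports):
    """Home-produced share of consumption: (prod - exp)/(prod - exp + imp).

    Values are clamped to [0, 1]: exports exceeding production (re-export
    artefacts) would otherwise push the ratio negative, which is flagged
    with a warning. A non-positive denominator (no apparent consumption)
    raises :class:`~herdvuln.errors.UndefinedRatioError`; callers should
    treat that nation's value as missing.
    """
    production = np.asarray(production, dtype=float)
    exports = np.asarray(exports, dtype=float)
    imports = np.asarray(imports, dtype=float)
    if (production < 0).any() or (exports < 0).any() or (imports < 0).any():
        raise ValueError("production, exports and imports must be >= 0")
    net = production - exports
    if (net < 0).any():
        warnings.warn(
            "exports exceed production (re-export artefact); clamping "
            "net production to zero",
            stacklevel=2,
        )
        net = np.clip(net, 0.0, None)
    denom = net + imports
    if (denom <= 0).any():
        raise UndefinedRatioError(
            "self-sufficiency denominator (production - exports + imports) <= 0"
        )
    ratio = net / denom
    return ratio if ratio.ndim else float(ratio)


def climate_impact_raw(delta_t, delta_p, w):
    """Raw climate-impact value cc = |dt| * |dp| * w per nation.

    The projected temperature and precipitation changes enter as absolute
    magnitudes — what matters for livestock systems is the degree of change
    in either direction — weighted by the share of the population
    historically affected by droughts, flooding and extreme weather (w, %).
    Missing inputs propagate as missing.
    """
    delta_t = pd.Series(delta_t, dtype=float)
    delta_p = pd.Series(delta_p, dtype=float).set_axis(delta_t.index)
    w = pd.Series(w, dtype=float).set_axis(delta_t.index)
    if (w.dropna() < 0).any():
        raise ValueError("extreme-weather population share w must be >= 0")
    return delta_t.abs() * delta_p.abs() * w


def climate_impact(delta_t, delta_p, w) -> pd.Series:
    """Climate-impact scores: raw cc values min-max scaled over nations."""
    return scale_minmax(climate_impact_raw(delta_t, delta_p, w), polarity="higher")


def reduce_category(
    members: pd.DataFrame,
    order: list[str] | None = None,
    absolute: bool = True,
) -> tuple[str, pd.Series]:
    """Pick the single most representative indicator of a category.

    Each member is scored by its mean (absolute, by default) Spearman rank
    correlation against the other members, computed on pairwise-complete
    observations with midranks for ties; the member with the largest mean is
    retained. A single-member category returns that member. Exact ties are
    broken by the declared order (first listed wins) and logged.

    Returns ``(retained_name, mean_correlations)``.
    """
    if order is None:
        order = list(members.columns)
    members = members[order]
    if members.shape[1] == 1:
        only = members.columns[0]
        return only, pd.Series({only: np.nan})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        rho = members.corr(method="spearman", min_periods=3)
    np.fill_diagonal(rho.values, np.nan)
    if absolute:
        rho = rho.abs()
    mean_rho = rho.mean(axis=0)  # skips NaN pairs
    if mean_rho.isna().all():
        raise ReductionError(
            "no within-category Spearman correlation could be computed "
            f"for members {list(members.columns)}"
        )
    best = float(mean_rho.max())
    tied = [c for c in order if np.isclose(mean_rho[c], best, atol=1e-12)]
    if len(tied) > 1:
        log.info("reduction tie among %s; retaining first listed %r", tied, tied[0])
    return tied[0], mean_rho


def prepare_scores(table: IndicatorTable) -> pd.DataFrame:
    """Collapse a raw indicator table to the eight 0-1 category scores.

    Returns a DataFrame indexed by nation_id with one column per category
    code (ss, fs, nc, cc, pg, he, ec, gv), each min-max scaled over the
    cohort with the declared polarity applied.
    """
    ind = table.indicators
    if len(ind) < 2:
        raise ZeroRangeError("need >= 2 nations to scale indicators")
    out = {}
    for cat in table.config.categories:
        out[cat.code] = _category_score(ind, cat, table.config.absolute_correlation)
    return pd.DataFrame(out, index=ind.index)


def _category_score(
    ind: pd.DataFrame, cat: CategorySpec, absolute: bool
) -> pd.Series:
    present = [m for m in cat.members if m in ind.columns]
    if not present:
        raise ReductionError(f"category {cat.name!r} has no columns in the table")
    if cat.rule == "composite-climate":
        raw = climate_impact_raw(
            ind[CLIMATE_MEMBERS[0]], ind[CLIMATE_MEMBERS[1]], ind[CLIMATE_MEMBERS[2]]
        )
        zero_w = (ind[CLIMATE_MEMBERS[2]] == 0) & raw.eq(0)
        if zero_w.any():
            log.info(
                "climate: %d nation(s) score cc=0 because w=0 despite projected "
                "change: %s", int(zero_w.sum()), list(raw.index[zero_w]),
            )
        return scale_minmax(raw, polarity="higher")
    if cat.rule == "mean":
        scaled = pd.DataFrame({
            m: scale_minmax(ind[m], cat.polarity_of(m)) for m in present
        })
        return scaled.mean(axis=1)
    retained, _ = reduce_category(ind[present], order=present, absolute=absolute)
    return scale_minmax(ind[retained], cat.polarity_of(retained))
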