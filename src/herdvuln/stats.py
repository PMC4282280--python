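"""Ranking extremes, population-weighted group summaries and test statistics.

Group comparisons weight each nation's rescaled score by its population so
that small nations do not contribute disproportionately to a regional mean.
Model agreement uses the Wilcoxon signed-rank test on paired per-nation
scores (the statistic is the sum of positive-difference ranks, the V
reported by R's ``wilcox.test``); indicator influence uses Spearman rank
correlation with midranks for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUPINGS = ("region", "income_group", "developed_status")

#: two-sided significance threshold used throughout
ALPHA = 0.05


def percentile_extremes(
    results: pd.DataFrame, fraction: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The ceiling(fraction x n) most and least vulnerable nations.

    ``results`` is one model/variant's table with a ``rank`` column
    (1 = most vulnerable). Returns (top, bottom), each ordered by rank.
    With fraction < 0.5 the two lists are disjoint.
    """
    if results.empty:
        raise ValueError("empty results collection")
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(results)
    k = math.ceil(fraction * n)
    ordered = results.sort_values(["rank", "nation_id"]).reset_index(drop=True)
    return ordered.head(k), ordered.tail(k).iloc[::-1].reset_index(drop=True)


def weighted_group_mean(
    scores: pd.DataFrame,
    weights: pd.Series,
    groups: pd.Series,
    value_cols: tuple[str, ...] = ("v", "S", "E", "AC"),
    rank_by: str = "v",
) -> pd.DataFrame:
    """Population-weighted mean scores per group, ranked by mean vulnerability.

    For each group g: mean_g = sum(w_i x_i) / sum(w_i) over member nations.
    Groups are ranked 1 = highest weighted mean of ``rank_by``.
    """
    w = pd.Series(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    df = scores[list(value_cols)].copy()
    df["_w"] = w.to_numpy()
    df["_g"] = pd.Series(groups).to_numpy()
    rows = []
    for label, sub in df.groupby("_g", sort=True):
        wsum = sub["_w"].sum()
        if wsum <= 0:
            raise ValueError(f"group {label!r} has no positive weight")
        row = {"group": label, "n_nations": len(sub)}
        for col in value_cols:
            row[col] = float((sub[col] * sub["_w"]).sum() / wsum)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["rank"] = out[rank_by].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


def group_summaries(
    results: pd.DataFrame, meta: pd.DataFrame,
    groupings: tuple[str, ...] = GROUPINGS,
) -> pd.DataFrame:
    """Weighted group means for every grouping variable, stacked tidily.

    ``results`` is one model/variant's table; ``meta`` is indexed by
    nation_id with population and the grouping columns.
    """
    joined = results.set_index("nation_id").join(meta, how="left")
    frames = []
    for grouping in groupings:
        g = weighted_group_mean(
            joined, joined["population"], joined[grouping]
        )
        g.insert(0, "grouping", grouping)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def spearman_influence(
    components: pd.DataFrame, targets: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation of every component against every target.

    Returns a tidy frame with one row per (component, target) pair: rho,
    two-sided p-value, n of paired observations, and whether the
    correlation is significant at alpha = 0.05. A constant vector yields an
    undefined (NaN) rho, reported rather than raised.
    """
    rows = []
    for comp in components.columns:
        for targ in targets.columns:
            x = pd.Series(components[comp], dtype=float)
            y = pd.Series(targets[targ], dtype=float).set_axis(x.index)
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = sps.spearmanr(x[ok], y[ok])
            rows.append({
                "component": comp, "target": targ,
                "rho": float(rho), "p_value": float(p), "n": n,
                "significant": bool(p < ALPHA) if not math.isnan(p) else False,
            })
    return pd.DataFrame(rows)


@dataclass
class ModelAgreement:
    """Wilcoxon signed-rank comparison of two paired score vectors."""

    statistic: float  # sum of positive-difference ranks (R's V)
    p_value: float | None
    n: int  # pairs with a non-zero difference
    n_zero_dropped: int
    method: str  # "exact", "approx" or "degenerate"

    @property
    def note(self) -> str:
        if self.method == "degenerate":
            return "all paired differences are zero; no test performed"
        return (
            f"{self.n_zero_dropped} zero difference(s) dropped before ranking; "
            f"p-value by {self.method} method"
        )


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum of ranks of positive differences, midranks on tied magnitudes."""
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_two_sided_p(d: np.ndarray) -> float:
    """Two-sided p by enumerating all 2^n sign assignments (midrank-safe)."""
    w_obs, ranks = _signed_rank_statistic(d)
    n = len(d)
    total = ranks.sum()
    # P(W >= w_obs) and P(W <= w_obs) under random independent signs
    ge = le = 0
    for mask in range(1 << n):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if w >= w_obs - 1e-12:
            ge += 1
        if w <= w_obs + 1e-12:
            le += 1
    count = min(ge, le)
    return min(1.0, 2.0 * count / (1 << n))


def wilcoxon_model_compare(
    a, b, exact_max_n: int = 15
) -> ModelAgreement:
    """Compare two models' paired per-nation scores by signed ranks.

    Zero differences are dropped before ranking (so n can fall below the
    cohort size, as when two models agree exactly on some nations). The
    two-sided p-value is computed by exact enumeration of sign assignments
    for n <= ``exact_max_n`` and otherwise by the normal approximation with
    the tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        return ModelAgreement(0.0, None, 0, n_dropped, "degenerate")
    w_plus, ranks = _signed_rank_statistic(d)
    if n <= exact_max_n:
        return ModelAgreement(w_plus, _exact_two_sided_p(d), n, n_dropped, "exact")
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ModelAgreement(w_plus, min(1.0, p), n, n_dropped, "approx")
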