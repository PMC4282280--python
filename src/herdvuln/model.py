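"""Index composition and vulnerability models.

Sensitivity, exposure and adaptive capacity are equal-weight averages of
their category scores:

    S  = (ss + fs + nc) / 3
    E  = (cc + pg) / 2
    AC = (he + ec + gv) / 3

each rescaled to [0, 1] over the cohort. Vulnerability combines them either
additively,

    V_raw = S + E - AC,

where the three indices contribute equally (an extreme value in one can be
offset by the others), or multiplicatively,

    V_raw = S * E * (1 - AC)     (default form)

where extremes dominate the result. Raw vulnerability is min-max rescaled to
[0, 1] per cohort: 0 marks the least and 1 the most vulnerable nation. Since
rescaling is affine-invariant, any positive-affine variant of the additive
combination (e.g. (S + E + (1 - AC)) / 3) yields the identical final score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import INDEX_OF_CODE, ModelConfig
from .prep import scale_minmax

log = logging.getLogger(__name__)

SCORE_CODES = list(INDEX_OF_CODE)  # ss fs nc cc pg he ec gv
INDEX_COMPONENTS = {
    "S": ["ss", "fs", "nc"],
    "E": ["cc", "pg"],
    "AC": ["he", "ec", "gv"],
}

MODELS = ("additive", "multiplicative")
VARIANTS = ("combined", "climate-only", "population-only")


def compose_sensitivity(ss, fs, nc):
    """S before rescaling: mean of the three sensitivity scores."""
    return (np.asarray(ss, float) + np.asarray(fs, float) + np.asarray(nc, float)) / 3.0


def compose_exposure(cc, pg):
    """E before rescaling: mean of the climate and population-growth scores."""
    return (np.asarray(cc, float) + np.asarray(pg, float)) / 2.0


def compose_adaptive_capacity(he, ec, gv):
    """AC before rescaling: mean of health, economy and governance scores."""
    return (np.asarray(he, float) + np.asarray(ec, float) + np.asarray(gv, float)) / 3.0


def rescale_index(values) -> pd.Series:
    """Min-max rescale an index over the cohort (order-preserving)."""
    return scale_minmax(values, polarity="higher")


def compose_indices(scores: pd.DataFrame) -> pd.DataFrame:
    """Compose and rescale S, E, AC from the eight category scores.

    ``scores`` is indexed by nation_id with columns ss..gv. Nations with a
    missing component get a missing index. Returns the input columns plus
    S, E, AC (rescaled over the cohort).
    """
    missing = [c for c in SCORE_CODES if c not in scores.columns]
    if missing:
        raise KeyError(f"missing category score column(s): {missing}")
    out = scores.copy()
    out["S"] = compose_sensitivity(scores["ss"], scores["fs"], scores["nc"])
    out["E"] = compose_exposure(scores["cc"], scores["pg"])
    out["AC"] = compose_adaptive_capacity(scores["he"], scores["ec"], scores["gv"])
    for col in ("S", "E", "AC"):
        out[col] = rescale_index(out[col])
    return out


def _rank_desc(v: pd.Series) -> pd.Series:
    """Rank 1 = most vulnerable; ties share the smaller rank (min method)."""
    ranks = v.rank(ascending=False, method="min").astype(int)
    if ranks.duplicated().any():
        log.info("tied vulnerability ranks at %s",
                 sorted(ranks[ranks.duplicated(keep=False)].unique()))
    return ranks


def _package(indices: pd.DataFrame, v_raw: pd.Series, model: str,
             variant: str) -> pd.DataFrame:
    v = rescale_index(v_raw)
    return pd.DataFrame({
        "nation_id": indices.index,
        "model": model,
        "variant": variant,
        "S": indices["S"].to_numpy(),
        "E": indices["E"].to_numpy(),
        "AC": indices["AC"].to_numpy(),
        "v_raw": v_raw.to_numpy(),
        "v": v.to_numpy(),
        "rank": _rank_desc(v).to_numpy(),
    }).reset_index(drop=True)


def vulnerability_additive(indices: pd.DataFrame,
                           variant: str = "combined") -> pd.DataFrame:
    """Additive vulnerability V = rescale(S + E - AC), ranked descending."""
    v_raw = indices["S"] + indices["E"] - indices["AC"]
    return _package(indices, v_raw, "additive", variant)


def vulnerability_multiplicative(
    indices: pd.DataFrame,
    config: ModelConfig | None = None,
    variant: str = "combined",
) -> pd.DataFrame:
    """Multiplicative vulnerability, default form V_raw = S*E*(1-AC)."""
    config = config or ModelConfig()
    S, E, AC = indices["S"], indices["E"], indices["AC"]
    if config.multiplicative_form == "product":
        v_raw = S * E * (1.0 - AC)
    else:
        v_raw = S * E / (AC + config.epsilon)
    return _package(indices, v_raw, "multiplicative", variant)


def scenario_variant(
    scores: pd.DataFrame,
    vary: str,
    model: str = "additive",
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Vulnerability with one exposure driver varying and the other frozen.

    ``vary="climate-only"`` lets the climate score cc vary while the
    population-growth score pg is held constant (and vice versa for
    ``"population-only"``). Held constant means replaced by its cohort mean
    (default policy), so it contributes no between-nation variance while E
    stays on a comparable scale; the ``drop-term`` policy removes the frozen
    component from E entirely.
    """
    config = config or ModelConfig()
    if vary not in ("climate-only", "population-only"):
        raise ValueError(f"vary must be climate-only or population-only, got {vary!r}")
    frozen = "pg" if vary == "climate-only" else "cc"
    varying = "cc" if frozen == "pg" else "pg"
    mod = scores.copy()
    if config.hold_constant_policy == "cohort-mean":
        mod[frozen] = scores[frozen].mean()
        mod["E"] = compose_exposure(mod["cc"], mod["pg"])
    else:  # drop-term: exposure from the varying driver alone
        mod["E"] = np.asarray(mod[varying], float)
    out = mod.copy()
    out["S"] = rescale_index(
        compose_sensitivity(mod["ss"], mod["fs"], mod["nc"])
    ).to_numpy()
    out["E"] = rescale_index(out["E"]).to_numpy()
    out["AC"] = rescale_index(
        compose_adaptive_capacity(mod["he"], mod["ec"], mod["gv"])
    ).to_numpy()
    if model == "additive":
        return vulnerability_additive(out, variant=vary)
    return vulnerability_multiplicative(out, config, variant=vary)


def run_models(
    scores: pd.DataFrame,
    models: tuple[str, ...] = MODELS,
    variants: tuple[str, ...] = VARIANTS,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Run every requested model x variant and stack the tidy results.

    ``scores`` must hold the eight category scores; the combined variant
    composes indices directly, scenario variants freeze one exposure driver.
    """
    config = config or ModelConfig()
    indices = compose_indices(scores)
    frames = []
    for model in models:
        for variant in variants:
            if variant == "combined":
                if model == "additive":
                    frames.append(vulnerability_additive(indices))
                else:
                    frames.append(vulnerability_multiplicative(indices, config))
            else:
                frames.append(scenario_variant(scores, variant, model, config))
    return pd.concat(frames, ignore_index=True)
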