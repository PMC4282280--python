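"""Synthetic nation-table generator with known latent structure.

The generator emulates the statistical shape the vulnerability pipeline
assumes — eight indicator categories whose members rank-correlate within a
category, a three-part climate exposure (projected temperature and
precipitation change plus an extreme-weather population share), projected
population growth spanning negative values, heavy-tailed GDP and national
populations, and group labels — while recording the latent sensitivity,
exposure and adaptive-capacity values each nation's indicators were drawn
from, so recovery of the true vulnerability ordering can be tested.

Generative model (Gaussian copula):

* latent standard-normal scores z_S, z_E, z_AC per nation, with z_S and
  z_AC negatively correlated (default -0.4: highly sensitive nations tend
  to have low adaptive capacity) and z_E independent;
* each category c of index I observes z_c = z_I + noise_sd * eta_c;
* each redundant member j of a reducible category observes
  u_cj = z_c + tau * eps_cj, where tau is set from the target
  intra-category Spearman rho via the bivariate-normal identity
  rho_s = (6/pi) * arcsin(r/2), r = 1/(1+tau^2), then mapped through a
  strictly monotone, unit-bearing marginal transform;
* the three climate members are distinct physical quantities, each
  observing z_c with noise_sd-scale noise only (the intra-category rho
  knob does not apply to them).

With ``noise_sd=0`` and one indicator per category the emitted table is a
deterministic monotone image of the latents, and the pipeline recovers the
latent composites exactly. All nations, names and codes are synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from string import ascii_uppercase

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.stats import norm

from .config import INDEX_OF_CODE, default_category_config
from .errors import ConfigError
from .io import DEVELOPED_STATUS, INCOME_GROUPS, REGIONS, IndicatorTable
from .model import (
    compose_adaptive_capacity,
    compose_exposure,
    compose_sensitivity,
    rescale_index,
)
from .prep import climate_impact_raw, scale_minmax


class GroupProbabilities(BaseModel):
    """Categorical label distributions for the synthetic metadata."""

    # proportions roughly matching a 148-nation global cohort
    region: dict[str, float] = Field(default_factory=lambda: dict(zip(
        REGIONS, [0.115, 0.318, 0.162, 0.088, 0.014, 0.034, 0.269]
    )))
    income_group: dict[str, float] = Field(default_factory=lambda: dict(zip(
        INCOME_GROUPS, [0.19, 0.26, 0.28, 0.27]
    )))
    developed_status: dict[str, float] = Field(default_factory=lambda: dict(zip(
        DEVELOPED_STATUS, [0.24, 0.52, 0.24]
    )))
    #: base food-deficit rate; the realised probability rises with latent S
    food_deficit_base: float = Field(default=0.15, ge=0.0, le=1.0)


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic nation generator."""

    n_nations: int = Field(default=148, ge=2)
    seed: int = 0
    intra_category_rho: float = Field(default=0.8, ge=0.0, le=1.0)
    indicators_per_category: int = Field(default=3, ge=1)
    noise_sd: float = Field(default=0.05, ge=0.0)
    s_ac_correlation: float = Field(default=-0.4, gt=-1.0, lt=1.0)
    population_lognormal_mu: float = 16.0
    population_lognormal_sigma: float = Field(default=1.3, ge=0.0)
    group_probabilities: GroupProbabilities = Field(
        default_factory=GroupProbabilities
    )


@dataclass
class LatentTruth:
    """Ground truth stored alongside a generated table.

    ``data`` is indexed by nation_id with the latent S/E/AC values (on the
    [0, 1] probability scale), the noiseless-pipeline composites ``true_S``,
    ``true_E``, ``true_AC``, the implied additive raw vulnerability and the
    true descending rank (1 = most vulnerable).
    """

    data: pd.DataFrame

    @property
    def true_rank(self) -> pd.Series:
        return self.data["true_rank"]

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path)
        return path


def _nation_ids(n: int) -> list[str]:
    """Deterministic synthetic ISO3-style codes: AAA, AAB, AAC, ..."""
    if n > 26**3:
        raise ConfigError("at most 17576 synthetic nations supported")
    ids = []
    for i in range(n):
        a, rest = divmod(i, 26 * 26)
        b, c = divmod(rest, 26)
        ids.append(ascii_uppercase[a] + ascii_uppercase[b] + ascii_uppercase[c])
    return ids


def _tau(rho_s: float) -> float:
    """Indicator noise scale achieving a target pairwise Spearman rho.

    For two indicators z + tau*eps_i their Pearson correlation is
    r = 1/(1+tau^2); for a bivariate normal the Spearman correlation is
    (6/pi) asin(r/2). Inverting: r = 2 sin(pi rho_s / 6).
    """
    if rho_s >= 1.0:
        return 0.0
    if rho_s <= 0.0:
        return math.inf
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    return math.sqrt(1.0 / r - 1.0)


# strictly monotone marginal transforms, one per (category code, member slot);
# slot 1 of fs and he measures the construct in the opposite direction and is
# declared polarity="lower" in the default category config
def _marginal(code: str, j: int, u: np.ndarray) -> np.ndarray:
    p = norm.cdf(u)
    if code == "ss":      # self-sufficiency ratio of animal-product supply
        return 0.02 + 0.96 * p
    if code == "fs":      # food-insecurity measures
        if j == 1:        # dietary energy adequacy (%): high = secure
            return 130.0 - 60.0 * p
        return 70.0 * p   # prevalence of food inadequacy (%)
    if code == "nc":      # grazing products' share of dietary energy (%)
        return 2.0 + 38.0 * p
    if code == "pg":      # projected population change 2010-2050 (%)
        return -15.0 + 175.0 * p
    if code == "he":      # health
        if j == 1:        # under-5 mortality (per 1000): high = poor health
            return 150.0 * (1.0 - p)
        return 45.0 + 40.0 * p  # life expectancy (years)
    if code == "ec":      # total GDP (USD), heavy-tailed
        return np.exp(22.0 + 2.5 * u)
    if code == "gv":      # governance estimate (WGI-like, -2.5..2.5)
        return -2.5 + 5.0 * p
    raise ConfigError(f"no marginal transform for category code {code!r}")


def _climate_members(u_t, u_p, u_w, sign):
    delta_t = 0.8 + 2.8 * norm.cdf(u_t)            # degC, all-warming cohort
    delta_p = sign * (10.0 + 240.0 * norm.cdf(u_p))  # mm, mixed signs
    w = 60.0 * norm.cdf(u_w)                       # % population affected
    return delta_t, delta_p, w


def generate_nations(
    config: SyntheticConfig | None = None,
) -> tuple[IndicatorTable, LatentTruth]:
    """Generate a synthetic nation table and its latent ground truth.

    Returns ``(table, truth)`` where the table carries the matching
    eight-category config. Identical config (including seed) yields an
    identical table.
    """
    config = config or SyntheticConfig()
    n = config.n_nations
    rng = np.random.default_rng(config.seed)

    r = config.s_ac_correlation
    z_s, z_helper = rng.standard_normal((2, n))
    z_ac = r * z_s + math.sqrt(1.0 - r * r) * z_helper
    z_e = rng.standard_normal(n)
    z_index = {"sensitivity": z_s, "exposure": z_e, "adaptive_capacity": z_ac}

    cat_config = default_category_config(config.indicators_per_category)
    tau = _tau(config.intra_category_rho)
    if math.isinf(tau) and config.indicators_per_category > 1:
        raise ConfigError("intra_category_rho=0 is not representable; use > 0")

    columns: dict[str, np.ndarray] = {}
    noiseless: dict[str, np.ndarray] = {}
    p_sign = rng.choice([-1.0, 1.0], size=n)  # precipitation sign pattern
    for cat in cat_config.categories:
        z_parent = z_index[INDEX_OF_CODE[cat.code]]
        z_c = z_parent + config.noise_sd * rng.standard_normal(n)
        if cat.rule == "composite-climate":
            eps = config.noise_sd * rng.standard_normal((3, n))
            dt, dp, w = _climate_members(
                z_c + eps[0], z_c + eps[1], z_c + eps[2], p_sign
            )
            columns["delta_t"], columns["delta_p"], columns["extreme_weather_w"] = (
                dt, dp, w
            )
            dt0, dp0, w0 = _climate_members(z_parent, z_parent, z_parent, p_sign)
            noiseless[cat.code] = np.asarray(
                climate_impact_raw(dt0, dp0, w0), dtype=float
            )
        else:
            for j, member in enumerate(cat.members):
                u = z_c if config.indicators_per_category == 1 else (
                    z_c + tau * rng.standard_normal(n)
                )
                columns[member] = _marginal(cat.code, j, u)
            noiseless[cat.code] = _marginal(cat.code, 0, z_parent)

    ids = _nation_ids(n)
    gp = config.group_probabilities
    latent = {k: norm.cdf(v) for k, v in z_index.items()}
    meta = pd.DataFrame({
        "nation_id": ids,
        "name": [f"Synthetic Nation {i + 1}" for i in range(n)],
        "region": rng.choice(
            list(gp.region), size=n, p=_normed(gp.region)
        ),
        "income_group": rng.choice(
            list(gp.income_group), size=n, p=_normed(gp.income_group)
        ),
        "developed_status": rng.choice(
            list(gp.developed_status), size=n, p=_normed(gp.developed_status)
        ),
        "food_deficit": rng.uniform(size=n)
        < np.clip(gp.food_deficit_base + 0.5 * latent["sensitivity"], 0, 1),
        "population": rng.lognormal(
            config.population_lognormal_mu, config.population_lognormal_sigma, n
        ).astype(np.int64),
    })
    table = IndicatorTable(
        pd.concat([meta, pd.DataFrame(columns, index=meta.index)], axis=1),
        cat_config,
    )

    idx = pd.Index(ids, name="nation_id")
    scores0 = pd.DataFrame(
        {code: scale_minmax(pd.Series(vals, index=idx)) for code, vals in
         noiseless.items()},
    )
    truth = pd.DataFrame(index=idx)
    truth["latent_S"] = latent["sensitivity"]
    truth["latent_E"] = latent["exposure"]
    truth["latent_AC"] = latent["adaptive_capacity"]
    truth["true_S"] = rescale_index(
        compose_sensitivity(scores0["ss"], scores0["fs"], scores0["nc"])
    ).to_numpy()
    truth["true_E"] = rescale_index(
        compose_exposure(scores0["cc"], scores0["pg"])
    ).to_numpy()
    truth["true_AC"] = rescale_index(
        compose_adaptive_capacity(scores0["he"], scores0["ec"], scores0["gv"])
    ).to_numpy()
    truth["true_v_raw"] = truth["true_S"] + truth["true_E"] - truth["true_AC"]
    truth["true_rank"] = (
        truth["true_v_raw"].rank(ascending=False, method="min").astype(int)
    )
    return table, LatentTruth(truth)


def _normed(d: dict[str, float]) -> list[float]:
    total = sum(d.values())
    return [v / total for v in d.values()]
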