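"""Declarative configuration: indicator categories and model options.

A :class:`CategoryConfig` declares, for every indicator column of an input
table, which of the eight categories it belongs to, its welfare polarity
(whether larger raw values mean *more* of the index construct), and how the
category is collapsed to a single 0-1 score:

* ``spearman-max`` — retain the member with the highest mean absolute
  Spearman correlation against the other members, then min-max scale it;
* ``mean`` — min-max scale every member and average the scores;
* ``composite-climate`` — combine ``delta_t``, ``delta_p`` and
  ``extreme_weather_w`` multiplicatively into a single climate-impact value
  before scaling.

Each category feeds exactly one of the three indices: sensitivity (S),
exposure (E) or adaptive capacity (AC).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError

Polarity = Literal["higher", "lower"]
ReductionRule = Literal["spearman-max", "mean", "composite-climate"]
IndexName = Literal["sensitivity", "exposure", "adaptive_capacity"]

#: members the climate composite requires, in fixed order
CLIMATE_MEMBERS = ("delta_t", "delta_p", "extreme_weather_w")

#: categories feeding each index, keyed by the short score code
INDEX_OF_CODE: dict[str, IndexName] = {
    "ss": "sensitivity",
    "fs": "sensitivity",
    "nc": "sensitivity",
    "cc": "exposure",
    "pg": "exposure",
    "he": "adaptive_capacity",
    "ec": "adaptive_capacity",
    "gv": "adaptive_capacity",
}


class CategorySpec(BaseModel):
    """One indicator category: its members and how it collapses to a score."""

    name: str
    code: str  # short score code: ss, fs, nc, cc, pg, he, ec, gv
    members: list[str] = Field(min_length=1)
    rule: ReductionRule = "spearman-max"
    polarity: dict[str, Polarity] = Field(default_factory=dict)

    @field_validator("members")
    @classmethod
    def _unique_members(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("duplicate member indicator in category")
        return v

    @model_validator(mode="after")
    def _check_climate(self) -> "CategorySpec":
        if self.rule == "composite-climate" and tuple(self.members) != CLIMATE_MEMBERS:
            raise ValueError(
                "composite-climate category members must be exactly "
                f"{list(CLIMATE_MEMBERS)}, got {self.members}"
            )
        return self

    def polarity_of(self, member: str) -> Polarity:
        return self.polarity.get(member, "higher")


class CategoryConfig(BaseModel):
    """Ordered list of categories covering every indicator column."""

    categories: list[CategorySpec]
    #: use absolute Spearman rho in the reduction step (signed if False)
    absolute_correlation: bool = True
    #: missing-data policy for nations with incomplete minimal indicators
    missing_policy: Literal["exclude", "impute-median"] = "exclude"

    @model_validator(mode="after")
    def _check_disjoint(self) -> "CategoryConfig":
        seen: dict[str, str] = {}
        codes: set[str] = set()
        for cat in self.categories:
            if cat.code in codes:
                raise ValueError(f"duplicate category code {cat.code!r}")
            codes.add(cat.code)
            if cat.code not in INDEX_OF_CODE:
                raise ValueError(
                    f"unknown category code {cat.code!r}; expected one of "
                    f"{sorted(INDEX_OF_CODE)}"
                )
            for m in cat.members:
                if m in seen:
                    raise ValueError(
                        f"indicator {m!r} appears in categories "
                        f"{seen[m]!r} and {cat.name!r}"
                    )
                seen[m] = cat.name
        return self

    @property
    def indicator_names(self) -> list[str]:
        return [m for cat in self.categories for m in cat.members]

    def category_of(self, indicator: str) -> CategorySpec:
        for cat in self.categories:
            if indicator in cat.members:
                return cat
        raise ConfigError(f"indicator {indicator!r} not declared in any category")

    def by_code(self, code: str) -> CategorySpec:
        for cat in self.categories:
            if cat.code == code:
                return cat
        raise ConfigError(f"no category with code {code!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"category config not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # pydantic ValidationError or ValueError
            raise ConfigError(f"invalid category config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
        return path


class ModelConfig(BaseModel):
    """Options for the vulnerability combination step."""

    #: multiplicative form: S*E*(1-AC) ("product") or S*E/(AC+eps) ("ratio")
    multiplicative_form: Literal["product", "ratio"] = "product"
    epsilon: float = Field(default=0.01, gt=0.0)
    #: how the frozen exposure component is held constant in scenario variants
    hold_constant_policy: Literal["cohort-mean", "drop-term"] = "cohort-mean"


def default_category_config(indicators_per_category: int = 1) -> CategoryConfig:
    """The eight-category minimal structure with generic member names.

    With ``indicators_per_category == 1`` each reducible category holds a
    single generically named indicator (``ss_0``, ``fs_0``, ...); larger
    values add ``_1``, ``_2``, ... members for the Spearman reduction step.
    The climate category always holds its three fixed members.
    """
    if indicators_per_category < 1:
        raise ConfigError("indicators_per_category must be >= 1")

    def members(code: str) -> list[str]:
        return [f"{code}_{j}" for j in range(indicators_per_category)]

    # reversed-polarity members: constructs where the natural measurement
    # direction opposes the index (e.g. dietary adequacy vs food insecurity)
    def polarity(code: str) -> dict[str, Polarity]:
        if code in ("fs", "he") and indicators_per_category >= 2:
            return {f"{code}_1": "lower"}
        return {}

    cats = [
        CategorySpec(name="self_sufficiency", code="ss", members=members("ss"),
                     polarity=polarity("ss")),
        CategorySpec(name="food_insecurity", code="fs", members=members("fs"),
                     polarity=polarity("fs")),
        CategorySpec(name="nutritional_contribution", code="nc",
                     members=members("nc"), polarity=polarity("nc")),
        CategorySpec(name="climate", code="cc", members=list(CLIMATE_MEMBERS),
                     rule="composite-climate"),
        CategorySpec(name="population_growth", code="pg", members=members("pg"),
                     polarity=polarity("pg")),
        CategorySpec(name="health", code="he", members=members("he"),
                     polarity=polarity("he")),
        CategorySpec(name="economy", code="ec", members=members("ec"),
                     polarity=polarity("ec")),
        CategorySpec(name="governance", code="gv", members=members("gv"),
                     polarity=polarity("gv")),
    ]
    return CategoryConfig(categories=cats)


def config_hash(obj: BaseModel) -> str:
    """Stable short hash of a pydantic config, for run manifests."""
    payload = json.dumps(obj.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
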