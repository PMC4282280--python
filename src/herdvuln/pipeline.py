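"""End-to-end run orchestration: one config in, a directory of outputs out.

Stage order mirrors the analysis: read (or synthesise) the nation table,
screen completeness, collapse indicators to the eight category scores,
compose and rescale the S/E/AC indices, compute vulnerability under every
requested model and scenario variant, summarise (extremes, weighted group
means, influence correlations, model agreement), and run the perturbation
grid. A manifest records the seed, a config hash and every file written, so
a run is reproducible and auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import grid as grid_mod
from . import io as io_mod
from . import model as model_mod
from . import stats as stats_mod
from .config import CategoryConfig, ModelConfig, config_hash, default_category_config
from .errors import ConfigError
from .synth import SyntheticConfig, generate_nations

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Everything one reproducible pipeline run needs."""

    input_csv: Optional[str] = None
    category_config: Optional[str] = None  # YAML path; default structure if None
    from_index_scores: bool = False  # input already holds S, E, AC columns
    synth: Optional[SyntheticConfig] = None
    model: ModelConfig = Field(default_factory=ModelConfig)
    models: tuple[str, ...] = model_mod.MODELS
    variants: tuple[str, ...] = model_mod.VARIANTS
    grid_floor: float = Field(default=0.01, ge=0.0)
    run_grid: bool = True
    extreme_fraction: float = Field(default=0.1, gt=0.0, lt=0.5)
    outdir: str = "herdvuln_out"
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.input_csv is None) == (self.synth is None):
            raise ValueError(
                "exactly one of input_csv or synth parameters must be given"
            )
        if self.from_index_scores and self.input_csv is None:
            raise ValueError("from_index_scores requires input_csv")
        return self


def _load_category_config(cfg: RunConfig) -> CategoryConfig:
    if cfg.category_config is not None:
        return CategoryConfig.from_yaml(cfg.category_config)
    if cfg.synth is not None:
        return default_category_config(cfg.synth.indicators_per_category)
    return default_category_config()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every requested stage; return the output manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(df, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, **kw)
        written.append(name)

    meta = None
    if cfg.from_index_scores:
        raw = pd.read_csv(cfg.input_csv, dtype={"nation_id": str})
        missing = [c for c in ("nation_id", "S", "E", "AC") if c not in raw.columns]
        if missing:
            raise ConfigError(
                f"--from-index-scores input lacks column(s): {missing}"
            )
        indices = raw.set_index("nation_id")[["S", "E", "AC"]].astype(float)
        scores = None
        if "population" in raw.columns:
            meta = raw.set_index("nation_id").drop(columns=["S", "E", "AC"])
    else:
        cat_config = _load_category_config(cfg)
        if cfg.synth is not None:
            synth_cfg = cfg.synth.model_copy(update={"seed": cfg.seed})
            table, truth = generate_nations(synth_cfg)
            emit(table.data, "table.csv", index=False)
            emit(truth.data, "truth.csv")
        else:
            table = io_mod.read_indicator_csv(cfg.input_csv, cat_config)
        report = io_mod.validate_table(table)
        if not report.is_clean:
            log.info(
                "validation: %d missing cell(s), %d sparse, %d zero-range "
                "indicator(s)", len(report.missing_cells),
                len(report.sparse_indicators), len(report.zero_range_indicators),
            )
        table = io_mod.apply_missing_policy(table)
        meta = table.meta
        from .prep import prepare_scores

        scores = prepare_scores(table)
        emit(scores, "scores.csv")
        indices = model_mod.compose_indices(scores)

    emit(indices[["S", "E", "AC"]], "indices.csv")

    if scores is not None:
        results = model_mod.run_models(
            scores, cfg.models, cfg.variants, cfg.model
        )
    else:
        frames = []
        for m in cfg.models:
            if m == "additive":
                frames.append(model_mod.vulnerability_additive(indices))
            else:
                frames.append(
                    model_mod.vulnerability_multiplicative(indices, cfg.model)
                )
        results = pd.concat(frames, ignore_index=True)
    io_mod.write_results(results, outdir / "results.csv")
    written.append("results.csv")
    io_mod.write_long_export(results, outdir / "results_long.csv")
    written.append("results_long.csv")

    main = results[
        (results["model"] == "additive") & (results["variant"] == "combined")
    ].reset_index(drop=True)
    top, bottom = stats_mod.percentile_extremes(main, cfg.extreme_fraction)
    emit(pd.concat([top.assign(extreme="most"), bottom.assign(extreme="least")]),
         "extremes.csv", index=False)

    if meta is not None and "population" in meta.columns:
        groupings = tuple(g for g in stats_mod.GROUPINGS if g in meta.columns)
        if groupings:
            emit(stats_mod.group_summaries(main, meta, groupings),
                 "group_summaries.csv", index=False)

    reports: dict = {}
    main_v = main.set_index("nation_id")["v"]
    infl_targets = pd.DataFrame({"v": main_v})
    comp_cols = indices[["S", "E", "AC"]].loc[main_v.index]
    components = comp_cols if scores is None else pd.concat(
        [scores.loc[main_v.index], comp_cols], axis=1
    )
    reports["influence"] = stats_mod.spearman_influence(
        components, infl_targets
    ).to_dict(orient="records")
    if "multiplicative" in cfg.models and "additive" in cfg.models:
        mult = results[
            (results["model"] == "multiplicative")
            & (results["variant"] == "combined")
        ].set_index("nation_id")["v"]
        agr = stats_mod.wilcoxon_model_compare(
            main_v.to_numpy(), mult.loc[main_v.index].to_numpy()
        )
        reports["model_agreement"] = {
            "statistic": agr.statistic, "p_value": agr.p_value,
            "n": agr.n, "n_zero_dropped": agr.n_zero_dropped,
            "method": agr.method,
        }
    with open(outdir / "reports.json", "w", encoding="utf-8") as fh:
        json.dump(reports, fh, indent=2)
    written.append("reports.json")

    if cfg.run_grid:
        scen = grid_mod.median_percent_change(
            indices, model="additive", config=cfg.model, floor=cfg.grid_floor
        )
        scen.to_csv(outdir / "grid.csv")
        written.append("grid.csv")

    manifest = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "n_nations": int(len(indices)),
        "outputs": sorted(written),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
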