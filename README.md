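# herdvuln

Composite vulnerability modelling of national livestock-based food security
under projected climate change and population growth.

Grazing livestock (cattle, sheep, goats, buffalo, camelids, equids) are a
critical food resource in low-income regions and on land unsuited to crops.
`herdvuln` implements the standard sensitivity–exposure–adaptive-capacity
(S/E/AC) vulnerability framework for this system at the national scale: it
turns a per-nation table of raw indicators into 0–1 index scores, combines
them into a vulnerability ranking, and quantifies how robust that ranking is
to future shifts in sensitivity and adaptive capacity. It is aimed at
analysts building or auditing composite country-level indices.

## The model

Each raw indicator is placed on a linear, absolute 0–1 scale over the cohort
(min → 0, max → 1, no distributional normalisation). Redundant indicators
within a category are reduced to the single member with the highest mean
|Spearman ρ| against the others. Climate exposure is a multiplicative
composite before scaling:

    cc = |Δt| · |Δp| · w

where Δt and Δp are the projected changes in annual mean temperature and
precipitation (2045–2065) and w is the share of the population historically
affected by droughts, flooding and extreme weather. The three indices are
equal-weight averages of their category scores, each min-max rescaled:

    S  = (ss + fs + nc) / 3      sensitivity
    E  = (cc + pg) / 2           exposure
    AC = (he + ec + gv) / 3      adaptive capacity

Vulnerability is computed additively, `V_raw = S + E − AC` (rescaled to
[0, 1]; affine-invariant, so any equal-weight variant gives the same V), or
multiplicatively, `V_raw = S·E·(1−AC)`, where extremes dominate. Scenario
variants hold either the climate or the population-growth exposure driver
at its cohort mean. Group comparisons use population-weighted means; model
agreement uses Wilcoxon signed-rank tests and indicator influence Spearman
correlations. A 441-cell grid (S and AC each varied −100%…+100% in 10%
steps) maps the median percent change in vulnerability per scenario.

Because the real data-bank extracts are not redistributable, the package
includes a synthetic nation generator with known latent S/E/AC structure
(for validating that the pipeline recovers a known vulnerability ordering)
and the published index scores of the 30 extreme nations as a fixture.

## Worked example

```python
from herdvuln import (extreme_nations_indices, extreme_nations_fixture,
                      vulnerability_additive)

idx = extreme_nations_indices()          # published S, E, AC of 30 nations
res = vulnerability_additive(idx).set_index("nation_id")
print(res.loc[["KEN", "BDI", "DEU", "JPN"], ["v", "rank"]])
```

prints

```
                  v  rank
nation_id
KEN        1.000000     1
BDI        0.938202     2
DEU        0.061798    26
JPN        0.000000    30
```

Kenya, the cohort maximum, rescales to exactly 1.0 and Japan, the minimum,
to exactly 0.0; Burundi's 0.938 and Germany's 0.062 recompute the published
0.93 and 0.06 to within the rounding of the two-decimal published inputs.
Runnable narrative scripts live in `examples/`:

* `published_extremes.py` — recompute the published vulnerability scores;
* `synthetic_pipeline.py` — full pipeline on a synthetic cohort with
  latent-truth recovery and weighted regional means;
* `model_comparison.py` — additive vs multiplicative agreement and index
  influence;
* `perturbation_grid.py` — the 441-cell robustness grid.

A thin CLI wraps the same stages: `herdvuln synth | prepare | model |
report | grid | run` (see `herdvuln --help`).

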