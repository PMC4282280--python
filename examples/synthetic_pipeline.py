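"""Full pipeline on a synthetic 148-nation cohort with known ground truth.

Generates a nation table whose indicators are noisy monotone images of
latent sensitivity/exposure/adaptive-capacity values, runs indicator
scaling and Spearman category reduction, composes the indices, computes
additive vulnerability, and checks how well the latent vulnerability
ordering is recovered. Also prints the population-weighted regional means.
"""

from scipy.stats import spearmanr

from herdvuln import (
    SyntheticConfig,
    compose_indices,
    generate_nations,
    group_summaries,
    prepare_scores,
    vulnerability_additive,
)

cfg = SyntheticConfig(n_nations=148, seed=2024, noise_sd=0.05,
                      intra_category_rho=0.8, indicators_per_category=3)
table, truth = generate_nations(cfg)

scores = prepare_scores(table)          # 8 category scores in [0, 1]
indices = compose_indices(scores)       # rescaled S, E, AC
res = vulnerability_additive(indices).set_index("nation_id")

rho = spearmanr(res["v"], truth.data["true_v_raw"]).statistic
print(f"cohort: {table.n_nations} synthetic nations, "
      f"{len(table.indicator_names)} indicator columns")
print(f"latent-ordering recovery (Spearman rho): {rho:.3f}")
print("(1.0 would mean the noisy indicators perfectly preserve the latent")
print(" vulnerability ranking; ~0.95 reflects the configured noise level)\n")

groups = group_summaries(res.reset_index().assign(model="additive",
                                                  variant="combined"),
                         table.meta, groupings=("region",))
print("population-weighted regional means (rank 1 = most vulnerable):")
print(groups[["group", "n_nations", "v", "S", "E", "AC", "rank"]]
      .round(3).to_string(index=False))
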