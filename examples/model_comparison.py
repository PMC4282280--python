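"""Compare additive and multiplicative vulnerability on the same cohort.

The additive model (V_raw = S + E - AC) lets an extreme index be offset by
the others; the multiplicative model (V_raw = S * E * (1 - AC)) lets
extremes dominate. Both are rescaled to [0, 1], so only the ordering can
differ. Agreement is tested with a Wilcoxon signed-rank test on the paired
per-nation scores, and indicator influence with Spearman correlations.
"""

from herdvuln import (
    SyntheticConfig,
    compose_indices,
    generate_nations,
    prepare_scores,
    spearman_influence,
    vulnerability_additive,
    vulnerability_multiplicative,
    wilcoxon_model_compare,
)

table, _ = generate_nations(SyntheticConfig(n_nations=148, seed=5))
scores = prepare_scores(table)
indices = compose_indices(scores)

add = vulnerability_additive(indices).set_index("nation_id")
mult = vulnerability_multiplicative(indices).set_index("nation_id")

scores_cmp = wilcoxon_model_compare(add["v"].to_numpy(), mult["v"].to_numpy())
print(f"Wilcoxon on paired scores:   V = {scores_cmp.statistic:.1f}, "
      f"P = {scores_cmp.p_value:.3g}, N = {scores_cmp.n}")
ranks_cmp = wilcoxon_model_compare(
    add["rank"].to_numpy(float), mult["rank"].to_numpy(float)
)
print(f"Wilcoxon on paired rankings: V = {ranks_cmp.statistic:.1f}, "
      f"P = {ranks_cmp.p_value:.3g}, N = {ranks_cmp.n}")
print("(V is the sum of positive-difference ranks. The multiplicative model")
print(" compresses mid-range scores, so the paired scores shift")
print(" systematically, while the orderings themselves show no systematic")
print(" difference — a large P on the rankings comparison.)\n")

infl = spearman_influence(
    indices[["S", "E", "AC"]], add[["v"]].rename(columns={"v": "V"})
)
print("influence of each index on additive vulnerability (Spearman):")
for _, row in infl.iterrows():
    flag = "significant" if row["significant"] else "n.s."
    print(f"  {row['component']:>2} vs V: rho = {row['rho']:+.2f} "
          f"(P = {row['p_value']:.3g}, {flag})")
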