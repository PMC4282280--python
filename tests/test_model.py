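import numpy as np
import pandas as pd
import pytest

from herdvuln import (
    ModelConfig,
    compose_adaptive_capacity,
    compose_exposure,
    compose_indices,
    compose_sensitivity,
    prepare_scores,
    rescale_index,
    run_models,
    scenario_variant,
    vulnerability_additive,
    vulnerability_multiplicative,
)


@pytest.mark.parametrize("fn,args,expected", [
    (compose_sensitivity, (0.3, 0.6, 0.9), 0.6),
    (compose_sensitivity, (0, 0, 0), 0.0),
    (compose_sensitivity, (1, 1, 1), 1.0),
    (compose_exposure, (0.4, 0.8), 0.6),
    (compose_exposure, (0, 0), 0.0),
    (compose_exposure, (1, 0), 0.5),
    (compose_adaptive_capacity, (0.9, 0.6, 0.3), 0.6),
    (compose_adaptive_capacity, (1, 1, 1), 1.0),
    (compose_adaptive_capacity, (0, 0, 0), 0.0),
])
def test_index_composition_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected)


def test_rescale_index_examples_and_oracle():
    np.testing.assert_allclose(rescale_index([0.2, 0.5, 0.8]), [0.0, 0.5, 1.0])
    rng = np.random.default_rng(1)
    x = rng.uniform(size=50)
    lo, hi = x.min(), x.max()
    np.testing.assert_allclose(rescale_index(x), [(v - lo) / (hi - lo) for v in x])


def _random_indices(n=40, seed=2):
    rng = np.random.default_rng(seed)
    idx = pd.DataFrame(
        rng.uniform(size=(n, 3)), columns=["S", "E", "AC"],
        index=pd.Index([f"N{i}" for i in range(n)], name="nation_id"),
    )
    return idx


class TestAdditiveModel:
    def test_affine_equivalent_combinations_identical(self):
        idx = _random_indices()
        v_direct = vulnerability_additive(idx)["v"]
        # (S + E + (1 - AC)) / 3 is a positive-affine image of S + E - AC
        alt_raw = (idx["S"] + idx["E"] + (1 - idx["AC"])) / 3
        v_alt = rescale_index(alt_raw).to_numpy()
        np.testing.assert_allclose(v_direct, v_alt, atol=1e-12)
        # and any a > 0, b shift
        v_shifted = rescale_index(2.7 * (idx["S"] + idx["E"] - idx["AC"]) - 1.3)
        np.testing.assert_allclose(v_direct, v_shifted.to_numpy(), atol=1e-12)

    def test_monotone_in_each_index(self):
        idx = _random_indices()
        base = vulnerability_additive(idx).set_index("nation_id")
        bumped = idx.copy()
        bumped.loc["N5", "S"] = min(1.0, idx.loc["N5", "S"] + 0.05)
        bumped.loc["N5", "AC"] = max(0.0, idx.loc["N5", "AC"] - 0.05)
        res = vulnerability_additive(bumped).set_index("nation_id")
        assert res.loc["N5", "v_raw"] >= base.loc["N5", "v_raw"]

    def test_rank_agrees_between_raw_and_rescaled(self):
        idx = _random_indices(seed=8)
        res = vulnerability_additive(idx)
        rank_raw = res["v_raw"].rank(ascending=False, method="min")
        assert (res["rank"] == rank_raw.astype(int)).all()

    def test_extremes_pin_to_bounds(self):
        res = vulnerability_additive(_random_indices())
        assert res["v"].min() == 0.0 and res["v"].max() == 1.0


class TestPublishedScores:
    def test_all_thirty_scores_within_rounding(self, table2, table2_indices):
        res = vulnerability_additive(table2_indices).set_index("nation_id")
        err = (res["v"] - table2["v"]).abs()
        assert err.max() <= 0.02

    def test_cohort_maximum_is_exactly_one(self, table2_indices):
        res = vulnerability_additive(table2_indices).set_index("nation_id")
        assert res.loc["KEN", "v"] == 1.0
        assert res.loc["JPN", "v"] == 0.0  # cohort minimum

    def test_most_vulnerable_group_recovered(self, table2, table2_indices):
        res = vulnerability_additive(table2_indices).set_index("nation_id")
        top15 = set(res.sort_values("rank").head(15).index)
        assert top15 == set(table2.index[table2["group"] == "most"])


class TestMultiplicativeModel:
    def test_zero_sensitivity_annihilates(self):
        idx = _random_indices()
        idx.loc["N0", "S"] = 0.0
        res = vulnerability_multiplicative(idx).set_index("nation_id")
        assert res.loc["N0", "v_raw"] == 0.0

    def test_full_adaptive_capacity_annihilates(self):
        idx = _random_indices()
        idx.loc["N1", "AC"] = 1.0
        res = vulnerability_multiplicative(idx).set_index("nation_id")
        assert res.loc["N1", "v_raw"] == 0.0

    def test_ratio_form_guarded_by_epsilon(self):
        idx = _random_indices()
        idx.loc["N2", "AC"] = 0.0
        cfg = ModelConfig(multiplicative_form="ratio", epsilon=0.01)
        res = vulnerability_multiplicative(idx, cfg).set_index("nation_id")
        assert np.isfinite(res["v_raw"]).all()


def _random_scores(n=60, seed=4):
    rng = np.random.default_rng(seed)
    codes = ["ss", "fs", "nc", "cc", "pg", "he", "ec", "gv"]
    df = pd.DataFrame(
        rng.uniform(size=(n, len(codes))), columns=codes,
        index=pd.Index([f"N{i}" for i in range(n)], name="nation_id"),
    )
    return df


class TestScenarioVariants:
    def test_constant_pg_makes_climate_only_equal_combined(self):
        scores = _random_scores()
        scores["pg"] = 0.4
        combined = vulnerability_additive(compose_indices(scores))
        climate_only = scenario_variant(scores, "climate-only")
        assert (combined["rank"].to_numpy()
                == climate_only["rank"].to_numpy()).all()

    def test_population_only_ignores_climate(self):
        scores = _random_scores(seed=9)
        base = scenario_variant(scores, "population-only").set_index("nation_id")
        permuted = scores.copy()
        rng = np.random.default_rng(0)
        permuted["cc"] = rng.permutation(permuted["cc"].to_numpy())
        res = scenario_variant(permuted, "population-only").set_index("nation_id")
        assert (base["rank"] == res["rank"]).all()
        np.testing.assert_allclose(base["v"], res["v"])

    def test_drop_term_policy_uses_single_driver(self):
        scores = _random_scores(seed=10)
        cfg = ModelConfig(hold_constant_policy="drop-term")
        res = scenario_variant(scores, "climate-only", config=cfg)
        expected_e = rescale_index(scores["cc"]).to_numpy()
        np.testing.assert_allclose(
            res.set_index("nation_id")["E"].to_numpy(), expected_e
        )


def test_run_models_stacks_every_combination():
    scores = _random_scores(n=30)
    out = run_models(scores)
    assert len(out) == 30 * 2 * 3
    assert set(out["model"]) == {"additive", "multiplicative"}
    assert set(out["variant"]) == {"combined", "climate-only", "population-only"}
    for (_, _), sub in out.groupby(["model", "variant"]):
        # min-method ranks: 1 = most vulnerable; ties (e.g. multiplicative
        # zeros at the S and E minima) share the smaller rank
        expected = sub["v"].rank(ascending=False, method="min").astype(int)
        assert (sub["rank"] == expected).all()
        assert sub["rank"].min() == 1


def test_prepared_synthetic_scores_feed_models(synth_cohort):
    table, _ = synth_cohort
    scores = prepare_scores(table)
    assert scores.shape == (148, 8)
    assert ((scores >= 0) & (scores <= 1)).all().all()
    res = vulnerability_additive(compose_indices(scores))
    assert sorted(res["rank"]) == list(range(1, 149))
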