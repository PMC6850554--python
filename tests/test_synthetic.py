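"""Generator contracts: determinism, bookkeeping, effect recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from middencache import ScenarioConfig, generate_dataset, records_to_frame
from middencache.synthetic import generate_baseline_and_visits, retained_frame


def _as_csv(dataset) -> str:
    return records_to_frame(dataset.middens).to_csv(index=False)


class TestScenarioConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_middens": 3},
            {"attrition_rate": 1.0},
            {"attrition_rate": -0.1},
            {"sex_probs": (0.5, 0.5, 0.5)},
            {"noise_sd": -1.0},
            {"sex_effect": 0.0},
            {"covariate_correlation": 1.0},
            {"aspect_distribution": "clustered"},
            {"aspect_distribution": [10.0] * 39},  # one bearing short
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs).validate()

    def test_defaults_valid(self):
        ScenarioConfig().validate()


class TestGenerateDataset:
    def test_same_seed_is_byte_identical(self):
        cfg = ScenarioConfig(seed=7)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert _as_csv(a) == _as_csv(b)
        va = pd.DataFrame([dataclasses.asdict(v) for v in a.visits])
        vb = pd.DataFrame([dataclasses.asdict(v) for v in b.visits])
        assert va.to_csv(index=False) == vb.to_csv(index=False)

    def test_different_seeds_differ(self):
        assert _as_csv(generate_dataset(ScenarioConfig(seed=1))) != _as_csv(
            generate_dataset(ScenarioConfig(seed=2))
        )

    def test_attrition_bookkeeping(self):
        ds = generate_dataset(ScenarioConfig(n_middens=40, attrition_rate=0.3, seed=3))
        excluded = sum(m.excluded for m in ds.middens)
        retained = sum(not m.excluded for m in ds.middens)
        assert (excluded, retained) == (12, 28)
        assert excluded + retained == 40

    @pytest.mark.parametrize("n,rate", [(10, 0.25), (37, 0.3), (28, 0.0)])
    def test_attrition_floor_rule(self, n, rate):
        ds = generate_dataset(ScenarioConfig(n_middens=n, attrition_rate=rate, seed=5))
        assert sum(m.excluded for m in ds.middens) == int(np.floor(rate * n))

    def test_retained_sex_pattern_matches_study_design(self):
        ds = generate_dataset(ScenarioConfig(seed=11))
        df = retained_frame(ds)
        counts = df["sex"].value_counts()
        assert (counts["male"], counts["female"], counts["unknown"]) == (15, 11, 2)

    def test_null_effects_give_constant_pit_count(self):
        cfg = ScenarioConfig(
            beta_aspect=0.0, beta_trees=0.0, sex_effect=1.0, noise_sd=0.0, seed=4
        )
        ds = generate_dataset(cfg)
        assert len({m.n_pits for m in ds.middens}) == 1

    def test_nonfinite_predictor_names_midden(self):
        cfg = ScenarioConfig(intercept=np.inf, seed=0)
        with pytest.raises(ValueError, match="M0"):
            generate_dataset(cfg)

    def test_truth_has_one_predictor_entry_per_midden(self):
        ds = generate_dataset(ScenarioConfig(seed=9))
        assert set(ds.truth.linear_predictor) == {m.midden_id for m in ds.middens}

    def test_every_visit_references_a_midden(self):
        ds = generate_dataset(ScenarioConfig(seed=9))
        ids = {m.midden_id for m in ds.middens}
        assert all(v.midden_id in ids for v in ds.visits)

    def test_fixed_aspect_list_used_verbatim(self):
        bearings = list(np.linspace(0, 350, 8))
        ds = generate_dataset(
            ScenarioConfig(n_middens=8, aspect_distribution=bearings, seed=1)
        )
        assert [m.aspect_deg for m in ds.middens] == pytest.approx(bearings)

    def test_block_correlation_structure(self):
        """Within-group covariates share the configured latent correlation."""
        cfg = ScenarioConfig(n_middens=4000, attrition_rate=0.0,
                             covariate_correlation=0.6, seed=21)
        df = records_to_frame(generate_dataset(cfg).middens)
        within = df[["altitude_m", "declivity_deg", "humidity_pct"]].corr()
        off = within.to_numpy()[np.triu_indices(3, 1)]
        assert off == pytest.approx(0.6, abs=0.05)
        cross = df[["altitude_m", "mushroom_g"]].corr().iloc[0, 1]
        assert abs(cross) < 0.05


class TestEffectRecovery:
    def test_ols_recovers_generator_slopes(self):
        """At n=200 and noise 0.2 OLS on log counts lands within 3 SE of the
        generating aspect and tree slopes in >=95% of replicates."""
        import statsmodels.api as sm

        from middencache import add_derived_columns

        hits = 0
        reps = 100
        for s in range(reps):
            cfg = ScenarioConfig(
                n_middens=200, attrition_rate=0.0, noise_sd=0.2, seed=30_000 + s
            )
            df = add_derived_columns(records_to_frame(generate_dataset(cfg).middens))
            X = sm.add_constant(df[["aspect_lin", "tree_density"]])
            is_male = (df["sex"] == "male").astype(float)
            res = sm.OLS(df["log_pits"], X.assign(is_male=is_male)).fit()
            ok = (
                abs(res.params["aspect_lin"] - cfg.beta_aspect) < 3 * res.bse["aspect_lin"]
                and abs(res.params["tree_density"] - cfg.beta_trees) < 3 * res.bse["tree_density"]
            )
            hits += ok
        assert hits / reps >= 0.95


class TestBaselineAndVisits:
    def test_zero_offsets_zero_noise_reproduce_baseline(self):
        from middencache import baseline_correct

        cfg = ScenarioConfig(n_middens=5, seed=2)
        baselines, visits = generate_baseline_and_visits(
            cfg, {f"M{i}": 0.0 for i in range(5)}, noise_sd=0.0
        )
        means = baseline_correct(visits, baselines)
        corrected = means.drop(columns=["midden_id", "n_visits"]).to_numpy()
        assert corrected == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_recovered_exactly_without_noise(self):
        from middencache import baseline_correct

        cfg = ScenarioConfig(n_middens=3, seed=2)
        baselines, visits = generate_baseline_and_visits(
            cfg, {"A": 2.0, "B": -1.5, "C": 0.25}, noise_sd=0.0
        )
        means = baseline_correct(visits, baselines).set_index("midden_id")
        assert means.loc["A", "air_temp_c"] == pytest.approx(2.0)
        assert means.loc["B", "pit_temp_c"] == pytest.approx(-1.5)
        assert means.loc["C", "soil_temp_c"] == pytest.approx(0.25)

    def test_noisy_offsets_recovered_within_standard_error_bound(self, rng):
        """With visit noise 0.1 over 6 visits, recovered means stay within
        3*(0.1/sqrt(6)) of the generating offsets."""
        from middencache import baseline_correct

        cfg = ScenarioConfig(n_middens=30, n_visits=6, seed=8)
        offsets = {f"M{i}": float(rng.normal(0, 1)) for i in range(30)}
        baselines, visits = generate_baseline_and_visits(
            cfg, offsets, noise_sd=0.1, rng=np.random.default_rng(99)
        )
        means = baseline_correct(visits, baselines).set_index("midden_id")
        bound = 3 * 0.1 / np.sqrt(6)
        within = [
            abs(means.loc[m, "air_temp_c"] - off) < bound for m, off in offsets.items()
        ]
        assert np.mean(within) >= 0.95
        assert (means["n_visits"] == 6).all()
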