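"""Welch comparisons, per-sex regressions and spatial homogeneity."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from middencache import (
    morans_i,
    per_sex_aspect_regression,
    sex_pit_difference,
    sex_report,
    welch_t,
)
from middencache.sex_inference import inverse_distance_weights


class TestWelch:
    def test_identical_groups_give_zero_t(self, rng):
        a = rng.normal(0, 1, 10)
        res = welch_t(a, a.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_antisymmetric_in_group_order(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.5, 9)
        ab, ba = welch_t(a, b), welch_t(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p == pytest.approx(ba.p)
        assert ab.df == pytest.approx(ba.df)

    def test_satterthwaite_df_below_pooled_df(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0, 3, 11)
        res = welch_t(a, b)
        assert res.df <= 15 + 11 - 2
        assert res.df >= min(15, 11) - 1

    def test_agrees_with_permutation_oracle(self, rng):
        """Welch two-sided p is within 0.02 of a 10000-draw permutation
        p-value on a small two-sample problem."""
        a, b = rng.normal(0.0, 1, 8), rng.normal(1.0, 1, 8)
        res = welch_t(a, b)
        pooled = np.concatenate([a, b])
        perm_rng = np.random.default_rng(123)
        reps = 10000
        perms = pooled[np.argsort(perm_rng.random((reps, 16)), axis=1)]
        ga, gb = perms[:, :8], perms[:, 8:]
        num = ga.mean(1) - gb.mean(1)
        den = np.sqrt(ga.var(1, ddof=1) / 8 + gb.var(1, ddof=1) / 8)
        t_perm = num / den
        assert res.p == pytest.approx(np.mean(np.abs(t_perm) >= abs(res.t)), abs=0.02)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestSexDifference:
    def _frame(self, male_counts, female_counts):
        rows = [{"sex": "male", "n_pits": c, "aspect_lin": 50.0 + i}
                for i, c in enumerate(male_counts)]
        rows += [{"sex": "female", "n_pits": c, "aspect_lin": 60.0 + i}
                 for i, c in enumerate(female_counts)]
        rows += [{"sex": "unknown", "n_pits": 999, "aspect_lin": 100.0}]
        return pd.DataFrame(rows)

    def test_equal_means_zero_percent(self):
        assert sex_pit_difference(self._frame([20, 30], [30, 20])) == 0.0

    def test_percent_difference_arithmetic(self):
        assert sex_pit_difference(self._frame([30, 30], [20, 20])) == pytest.approx(50.0)

    def test_unknown_sex_excluded(self):
        df = self._frame([10, 10], [10, 10])
        assert sex_pit_difference(df) == 0.0  # the 999-pit unknown is ignored

    def test_missing_sex_class_rejected(self):
        df = pd.DataFrame({"sex": ["male"] * 4, "n_pits": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            sex_pit_difference(df)


class TestPerSexRegression:
    def test_zero_effect_slope_covered(self):
        """With no generating aspect effect the slope CI covers zero in
        ~95% of replicates."""
        hits = 0
        reps = 100
        for s in range(reps):
            r = np.random.default_rng(700 + s)
            n = 14
            df = pd.DataFrame(
                {"sex": ["female"] * n,
                 "aspect_lin": r.uniform(45, 225, n),
                 "n_pits": r.poisson(40, n).astype(float)}
            )
            res = per_sex_aspect_regression(df, "female")
            se = abs(res.beta / res.t) if res.t != 0 else np.inf
            hits += abs(res.beta) < 2 * se
        assert hits / reps >= 0.90

    def test_constructed_slope_recovered(self):
        r = np.random.default_rng(5)
        x = np.linspace(45, 225, 12)
        df = pd.DataFrame({"sex": ["male"] * 12, "aspect_lin": x,
                           "n_pits": 80 - 0.3 * x + r.normal(0, 1, 12)})
        res = per_sex_aspect_regression(df, "male")
        assert res.beta == pytest.approx(-0.3, abs=0.02)
        assert res.p < 1e-6
        assert res.n == 12

    def test_identical_aspects_rejected(self):
        df = pd.DataFrame({"sex": ["male"] * 5, "aspect_lin": [90.0] * 5,
                           "n_pits": [1.0, 2, 3, 4, 5]})
        with pytest.raises(ValueError):
            per_sex_aspect_regression(df, "male")

    def test_pooled_data_with_common_slope_gives_overlapping_cis(self):
        r = np.random.default_rng(6)
        n = 40
        df = pd.DataFrame(
            {"sex": np.repeat(["male", "female"], n),
             "aspect_lin": r.uniform(45, 225, 2 * n)}
        )
        df["n_pits"] = 100 - 0.25 * df["aspect_lin"] + r.normal(0, 4, 2 * n)
        m = per_sex_aspect_regression(df, "male")
        f = per_sex_aspect_regression(df, "female")
        se_m, se_f = abs(m.beta / m.t), abs(f.beta / f.t)
        assert abs(m.beta - f.beta) < 2 * (se_m + se_f)


class TestMoransI:
    def test_null_expectation_closed_form(self, rng):
        coords = rng.uniform(0, 10, (33, 2))
        res = morans_i(rng.normal(0, 1, 33), coords, permutations=99, seed=0)
        assert res.expected_I == pytest.approx(-1 / 32)

    def test_values_on_a_gradient_strongly_positive(self):
        x = np.arange(20.0)
        coords = np.column_stack([x, np.zeros_like(x)])
        res = morans_i(x, coords, permutations=999, seed=1)
        assert res.I > 0.3
        assert res.p <= 0.01

    def test_affine_invariance(self, rng):
        coords = rng.uniform(0, 5, (15, 2))
        v = rng.normal(0, 1, 15)
        a = morans_i(v, coords, permutations=99, seed=2)
        b = morans_i(5.0 - 3.0 * v, coords, permutations=99, seed=2)
        assert b.I == pytest.approx(a.I, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            morans_i(np.ones(10), rng.uniform(0, 1, (10, 2)))

    def test_matches_r_ape_oracle(self, rng, tmp_path):
        """Observed and expected I agree with ape::Moran.I on the same
        row-standardized inverse-distance weight matrix."""
        coords = rng.uniform(0, 10, (12, 2))
        vals = rng.normal(0, 1, 12) + 0.3 * coords[:, 0]
        W = inverse_distance_weights(coords)
        np.savetxt(tmp_path / "w.csv", W, delimiter=",")
        np.savetxt(tmp_path / "v.csv", vals)
        script = textwrap.dedent(f"""
            suppressMessages(library(ape))
            w <- as.matrix(read.csv("{tmp_path}/w.csv", header=FALSE))
            v <- scan("{tmp_path}/v.csv", quiet=TRUE)
            m <- Moran.I(v, w, scaled=FALSE)
            cat(sprintf("%.12f %.12f", m$observed, m$expected))
        """)
        try:
            proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                  text=True, timeout=120)
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        assert proc.returncode == 0, proc.stderr
        obs, exp = map(float, proc.stdout.split())
        res = morans_i(vals, coords, permutations=99, seed=0)
        assert res.I == pytest.approx(obs, abs=1e-9)
        assert res.expected_I == pytest.approx(exp, abs=1e-12)


class TestSexReport:
    def test_report_rows_and_consistency(self, study_frame):
        report = sex_report(study_frame).set_index("analysis")
        assert set(report.index) == {
            "pits_by_sex_welch", "percent_male_excess", "aspect_by_sex_welch",
            "male_aspect_slope", "female_aspect_slope",
        }
        assert report.loc["percent_male_excess", "estimate"] == pytest.approx(
            sex_pit_difference(study_frame)
        )
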