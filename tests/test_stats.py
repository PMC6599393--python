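import numpy as np
import pandas as pd
import pytest

from statedyn.errors import DesignError, StateDynError, ValidationError
from statedyn.io_cohort import GROUP_KEYS
from statedyn.stats import (
    cohens_d,
    holm_correction,
    iti_nt_correlation,
    mixed_anova_fo,
    state_wise_tests,
    subsample_analysis,
    two_way_anova,
)

from oracles import balanced_anova_ss


def balanced_frame(rng, n_per_cell=8, effects=(0.0, 0.0, 0.0), noise=1.0):
    rows = []
    for sex_code, sex in ((1, "girl"), (-1, "boy")):
        for dx_code, dx in ((1, "ADHD"), (-1, "control")):
            mu = effects[0] * sex_code + effects[1] * dx_code + effects[2] * sex_code * dx_code
            for _ in range(n_per_cell):
                rows.append((sex, dx, mu + noise * rng.normal()))
    return pd.DataFrame(rows, columns=["sex", "dx", "value"])


class TestCohensD:
    def test_printed_state1_sex_contrast(self):
        # girls 1.16 (0.46) n=350 vs boys 1.17 (0.52) n=604 -> |d| = 0.02
        d = cohens_d(1.16, 0.46, 350, 1.17, 0.52, 604)
        assert abs(d) == pytest.approx(0.02, abs=0.02)

    def test_printed_state3_variability_contrast(self):
        d = cohens_d(1.45, 0.60, 446, 1.29, 0.54, 508)
        assert abs(d) == pytest.approx(0.28, abs=0.02)

    def test_equal_means(self):
        assert cohens_d(1.0, 0.5, 10, 1.0, 0.5, 10) == 0.0

    def test_sign_convention_second_minus_first(self):
        assert cohens_d(0.0, 1.0, 10, 1.0, 1.0, 10) > 0

    def test_zero_sds_equal_means(self):
        assert cohens_d(2.0, 0.0, 5, 2.0, 0.0, 5) == 0.0

    def test_zero_sds_unequal_means(self):
        with pytest.raises(StateDynError, match="infinite"):
            cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d(1.0, 0.5, 1, 2.0, 0.5, 10)


class TestTwoWayAnova:
    def test_balanced_matches_hand_decomposition(self, rng):
        n = 6
        values = np.empty((2, 2, n))
        df_rows = []
        for i, sex in enumerate(("girl", "boy")):
            for j, dx in enumerate(("ADHD", "control")):
                cell = 0.4 * i - 0.3 * j + 0.2 * i * j + 0.05 * rng.normal(size=n)
                values[i, j] = cell
                df_rows += [(sex, dx, v) for v in cell]
        df = pd.DataFrame(df_rows, columns=["sex", "dx", "value"])
        table = two_way_anova(df["value"].to_numpy(), df["sex"].to_numpy(), df["dx"].to_numpy())
        ss_a, ss_b, ss_ab, ss_err = balanced_anova_ss(values)
        assert table.row("sex")["ss"] == pytest.approx(ss_a, abs=1e-8)
        assert table.row("dx")["ss"] == pytest.approx(ss_b, abs=1e-8)
        assert table.row("sex:dx")["ss"] == pytest.approx(ss_ab, abs=1e-8)
        assert table.ss_error == pytest.approx(ss_err, abs=1e-8)
        assert table.df_error == 4 * n - 4

    def test_identical_values_zero_ss(self, rng):
        df = balanced_frame(rng, effects=(0, 0, 0), noise=0.0)
        df["value"] = 5.0
        table = two_way_anova(df["value"].to_numpy(), df["sex"].to_numpy(), df["dx"].to_numpy())
        for effect in ("sex", "dx", "sex:dx"):
            assert table.row(effect)["ss"] == pytest.approx(0.0, abs=1e-20)
            assert table.row(effect)["partial_eta_sq"] == 0.0

    def test_empty_cell_design_error(self, rng):
        df = balanced_frame(rng)
        df = df[~((df.sex == "girl") & (df.dx == "ADHD"))]
        with pytest.raises(DesignError, match="girl"):
            two_way_anova(df["value"].to_numpy(), df["sex"].to_numpy(), df["dx"].to_numpy())

    def test_type_iii_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        for trial in range(20):
            local = np.random.default_rng(trial)
            # unbalanced cells
            rows = []
            for sex in ("girl", "boy"):
                for dx in ("ADHD", "control"):
                    n = int(local.integers(3, 12))
                    for _ in range(n):
                        rows.append((sex, dx, local.normal() + (sex == "girl") * 0.5))
            df = pd.DataFrame(rows, columns=["sex", "dx", "value"])
            table = two_way_anova(
                df["value"].to_numpy(), df["sex"].to_numpy(), df["dx"].to_numpy(), "III"
            )
            model = smf.ols(
                "value ~ C(sex, Sum) * C(dx, Sum)", data=df
            ).fit()
            ref = sm.stats.anova_lm(model, typ=3)
            for effect, label in (
                ("sex", "C(sex, Sum)"),
                ("dx", "C(dx, Sum)"),
                ("sex:dx", "C(sex, Sum):C(dx, Sum)"),
            ):
                assert table.row(effect)["F"] == pytest.approx(
                    ref.loc[label, "F"], rel=1e-6
                )

    def test_type_ii_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rows = []
        for sex in ("girl", "boy"):
            for dx in ("ADHD", "control"):
                n = 5 if sex == "girl" else 9
                for _ in range(n):
                    rows.append((sex, dx, rng.normal()))
        df = pd.DataFrame(rows, columns=["sex", "dx", "value"])
        table = two_way_anova(
            df["value"].to_numpy(), df["sex"].to_numpy(), df["dx"].to_numpy(), "II"
        )
        model = smf.ols("value ~ C(sex) * C(dx)", data=df).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        assert table.row("sex")["F"] == pytest.approx(ref.loc["C(sex)", "F"], rel=1e-6)
        assert table.row("dx")["F"] == pytest.approx(ref.loc["C(dx)", "F"], rel=1e-6)

    def test_partial_eta_sq_affine_invariant(self, rng):
        df = balanced_frame(rng, effects=(0.5, 0.2, 0.1))
        v = df["value"].to_numpy()
        t1 = two_way_anova(v, df["sex"].to_numpy(), df["dx"].to_numpy())
        t2 = two_way_anova(3.0 * v + 17.0, df["sex"].to_numpy(), df["dx"].to_numpy())
        for effect in ("sex", "dx", "sex:dx"):
            assert t1.row(effect)["partial_eta_sq"] == pytest.approx(
                t2.row(effect)["partial_eta_sq"], abs=1e-10
            )


class TestMixedAnovaFo:
    def _groups(self, n):
        reps = [GROUP_KEYS[i % 4] for i in range(n)]
        sex = np.array([g[0] for g in reps])
        dx = np.array([g[1] for g in reps])
        return sex, dx

    def test_identical_fo_zero_state_ss(self):
        n, k = 20, 5
        fo = np.full((n, k), 1.0 / k)
        sex, dx = self._groups(n)
        table = mixed_anova_fo(fo, sex, dx)
        for effect in ("state", "state:sex", "state:dx", "state:sex:dx"):
            assert table.row(effect)["ss"] == pytest.approx(0.0, abs=1e-18)

    def test_simplex_collinearity_handled(self, rng):
        n, k = 24, 4
        fo = rng.dirichlet(np.ones(k), size=n)  # rows sum to 1 by construction
        sex, dx = self._groups(n)
        table = mixed_anova_fo(fo, sex, dx)  # must not raise
        assert table.row("state:sex:dx")["df"] == k - 1
        assert table.df_error == (k - 1) * (n - 4)

    def test_three_way_interaction_power(self):
        """Group-specific FO profiles drive the three-way interaction."""
        detected = 0
        k = 5
        for rep in range(20):
            local = np.random.default_rng(rep)
            rows_fo, sex, dx = [], [], []
            for gi, (s, d) in enumerate(GROUP_KEYS):
                alpha = np.ones(k)
                alpha[gi % k] = 4.0  # each group favors a different state
                for _ in range(30):
                    rows_fo.append(local.dirichlet(alpha * 8))
                    sex.append(s)
                    dx.append(d)
            table = mixed_anova_fo(np.array(rows_fo), np.array(sex), np.array(dx))
            if table.row("state:sex:dx")["p"] < 0.05:
                detected += 1
        assert detected >= 18

    def test_k_too_small(self):
        with pytest.raises(DesignError):
            mixed_anova_fo(np.ones((10, 1)), *self._groups(10))


class TestStateWiseTests:
    def test_identical_groups(self):
        df = pd.DataFrame(
            {
                "state": [1] * 8,
                "value": [1.0, 2.0, 3.0, 4.0] * 2,
                "sex": ["girl"] * 4 + ["boy"] * 4,
            }
        )
        rows = state_wise_tests(df, "sex")
        assert rows[0].cohens_d == pytest.approx(0.0)
        assert rows[0].p == pytest.approx(1.0)

    def test_untestable_small_group(self):
        df = pd.DataFrame(
            {
                "state": [1, 1, 1],
                "value": [1.0, 2.0, 3.0],
                "dx": ["ADHD", "control", "control"],
            }
        )
        rows = state_wise_tests(df, "dx")
        assert not rows[0].testable

    def test_estimator_consistency(self):
        """Estimated d is unbiased for the true standardized shift."""
        true_d = 0.3
        estimates = []
        for rep in range(200):
            local = np.random.default_rng(rep)
            g1 = local.normal(0.0, 1.0, size=350)
            g2 = local.normal(true_d, 1.0, size=604)
            df = pd.DataFrame(
                {
                    "state": 1,
                    "value": np.concatenate([g1, g2]),
                    "sex": ["girl"] * 350 + ["boy"] * 604,
                }
            )
            estimates.append(state_wise_tests(df, "sex")[0].cohens_d)
        assert np.mean(estimates) == pytest.approx(true_d, abs=0.05)

    def test_type_i_error_calibration(self):
        rejections = 0
        n_reps = 400
        for rep in range(n_reps):
            local = np.random.default_rng(10_000 + rep)
            df = pd.DataFrame(
                {
                    "state": 1,
                    "value": local.normal(size=60),
                    "dx": ["ADHD"] * 30 + ["control"] * 30,
                }
            )
            if state_wise_tests(df, "dx")[0].p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.08


class TestCorrelation:
    def test_perfect_negative(self):
        df = pd.DataFrame({"iti_mean": [3.0, 2.0, 1.0], "nt": [0.1, 0.2, 0.3]})
        r, _ = iti_nt_correlation(df)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_small_r(self):
        small = 0
        for rep in range(40):
            local = np.random.default_rng(rep)
            df = pd.DataFrame(
                {"iti_mean": local.normal(size=500), "nt": local.normal(size=500)}
            )
            r, _ = iti_nt_correlation(df)
            if abs(r) < 0.2:
                small += 1
        assert small >= 38

    def test_zero_variance_error(self):
        df = pd.DataFrame({"iti_mean": [1.0, 1.0, 1.0], "nt": [0.1, 0.2, 0.3]})
        with pytest.raises(DesignError):
            iti_nt_correlation(df)


class TestSubsample:
    def _metrics_frame(self, rng, counts=(99, 347, 251, 257)):
        rows = []
        for (sex, dx), n in zip(GROUP_KEYS, counts):
            for i in range(n):
                rows.append(
                    {
                        "run_id": f"{sex}_{dx}_{i}",
                        "sex": sex,
                        "dx": dx,
                        "iti_mean": rng.normal(1.1, 0.3),
                        "iti_sd": rng.normal(1.4, 0.5),
                        "nt": rng.normal(0.47, 0.07),
                    }
                )
        return pd.DataFrame(rows)

    def test_table_shaped_cohort_matches_smallest(self, rng):
        df = self._metrics_frame(rng)
        result = subsample_analysis(df, seed=0)
        assert result.n_per_group == 99
        sub = df[df["run_id"].isin(result.selected_run_ids)]
        for g in GROUP_KEYS:
            assert ((sub["sex"] == g[0]) & (sub["dx"] == g[1])).sum() == 99

    def test_equal_sizes_identity(self, rng):
        df = self._metrics_frame(rng, counts=(40, 40, 40, 40))
        result = subsample_analysis(df, seed=1)
        assert sorted(result.selected_run_ids) == sorted(df["run_id"])
        full = two_way_anova(df["iti_mean"].to_numpy(), df["sex"].to_numpy(), df["dx"].to_numpy())
        sub = result.tables["iti_mean"]
        assert sub.row("sex")["F"] == pytest.approx(full.row("sex")["F"], rel=1e-12)

    def test_seed_reproducibility(self, rng):
        df = self._metrics_frame(rng)
        r1 = subsample_analysis(df, seed=5)
        r2 = subsample_analysis(df, seed=5)
        assert r1.selected_run_ids == r2.selected_run_ids

    def test_underpowered_warning(self, rng):
        df = self._metrics_frame(rng, counts=(5, 40, 40, 40))
        with pytest.warns(UserWarning, match="underpowered"):
            subsample_analysis(df, seed=0)


class TestHolm:
    def test_monotone_and_bounded(self):
        adj = holm_correction([0.01, 0.04, 0.03, 0.5])
        assert all(0 <= a <= 1 for a in adj)
        assert adj[0] == pytest.approx(0.04)
        assert adj[3] == pytest.approx(0.5)
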