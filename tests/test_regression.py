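"""Tests of design construction and the OLS / restricted-LS / Tobit fits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import icetariff as it
from icetariff.regression import EstimationError, level_column
from icetariff.synthetic import calibrated_truth


def _single_row(levels, spec=it.ICECAP_O):
    df = pd.DataFrame(
        {
            "id": [1],
            **{f"dim{i + 1}": [levels[i]] for i in range(5)},
            "cantril": [7],
            "swls": [25],
            "sex": [1],
            "age": [75],
            "tertiary": [1],
            "married": [1],
            "finance_cat": ["easy"],
            "wealth_or_income": [50_000.0],
        }
    )
    return df


class TestBuildDesign:
    def test_reference_state_has_zero_dummies(self):
        d = it.build_design(_single_row([1, 1, 1, 1, 1]), it.ICECAP_O, include_ses=False)
        dummy_cols = [level_column(dim, l) for dim, l in d.level_keys()]
        assert d.X[dummy_cols].to_numpy().sum() == 0

    def test_worst_state_sets_five_level4_dummies(self):
        d = it.build_design(_single_row([4, 4, 4, 4, 4]), it.ICECAP_O, include_ses=False)
        on = [c for c in d.X.columns if c != "const" and d.X[c].iloc[0] == 1]
        assert sorted(on) == sorted(
            level_column(dim, 4) for dim in it.ICECAP_O.dimensions
        )

    def test_worst_anywhere_dummy(self):
        d = it.build_design(
            _single_row([4, 1, 1, 1, 1]), it.ICECAP_O,
            include_ses=False, include_worst_dummy=True,
        )
        assert d.X["worst_level_any"].iloc[0] == 1.0
        d2 = it.build_design(
            _single_row([3, 3, 3, 3, 3]), it.ICECAP_O,
            include_ses=False, include_worst_dummy=True,
        )
        assert d2.X["worst_level_any"].iloc[0] == 0.0

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="dim3"):
            it.build_design(_single_row([1, 1, 5, 1, 1]), it.ICECAP_O)

    def test_ses_columns_and_scaling(self, o_sample):
        d = it.build_design(o_sample, it.ICECAP_O, include_ses=True)
        assert "wealth_millions" in d.X.columns
        np.testing.assert_allclose(
            d.X["wealth_millions"].to_numpy() * 1e6,
            o_sample["wealth_or_income"].to_numpy(),
        )
        np.testing.assert_allclose(
            d.X["age_sq"].to_numpy(), d.X["age"].to_numpy() ** 2
        )

    def test_at_most_one_dummy_per_dimension(self, o_design):
        for dim in it.ICECAP_O.dimensions:
            cols = [level_column(dim, l) for l in (2, 3, 4)]
            assert o_design.X[cols].sum(axis=1).max() <= 1

    def test_incomplete_rows_dropped(self, o_sample):
        df = o_sample.copy()
        df.loc[df.index[:7], "swls"] = np.nan
        d = it.build_design(df, it.ICECAP_O)
        assert d.n_dropped == 7
        assert d.n == len(df) - 7


class TestOls:
    def test_matches_normal_equations_oracle(self, o_design):
        fit = it.fit_ols(o_design)
        X = o_design.X.to_numpy()
        y = o_design.y.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        est = np.array(
            [fit.intercept]
            + [fit.level_disutilities[k] for k in o_design.level_keys()]
        )
        oracle = pd.Series(beta, index=o_design.X.columns)
        ref = np.array(
            [oracle["const"]]
            + [oracle[level_column(*k)] for k in o_design.level_keys()]
        )
        np.testing.assert_allclose(est, ref, rtol=1e-8, atol=1e-12)

    def test_noiseless_data_recovered_exactly(self, exact_design):
        design, beta = exact_design
        fit = it.fit_ols(design)
        est = pd.Series(
            {c: fit.intercept if c == "const" else None for c in design.X.columns}
        )
        for dim, l in design.level_keys():
            est[level_column(dim, l)] = fit.level_disutilities[(dim, l)]
        np.testing.assert_allclose(est.to_numpy(dtype=float), beta, atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_simulation_recovery_within_three_ses(self):
        truth = calibrated_truth("ICECAP-O")
        cfg = it.default_config("ICECAP-O", n=5000, seed=314, noise_sd=0.07)
        d = it.build_design(it.generate_dataset(cfg), it.ICECAP_O)
        fit = it.fit_ols(d)
        for k, v in truth.level_disutilities.items():
            assert abs(fit.level_disutilities[k] - v) <= 3 * fit.standard_errors[k]

    def test_rank_deficiency_names_columns(self, o_sample):
        df = o_sample.copy()
        df["dim3"] = 1  # constant dimension -> its dummies are all-zero
        d = it.build_design(df, it.ICECAP_O, include_ses=False)
        with pytest.raises(EstimationError, match="role"):
            it.fit_ols(d)


class TestConstrainedOls:
    def test_zero_constraint_equals_column_deletion(self, o_design):
        con = [("role", 2, 0.0)]
        fit = it.fit_constrained_ols(o_design, con)
        dropped = o_design.X.drop(columns=[level_column("role", 2)])
        oracle = sm.OLS(o_design.y.to_numpy(), dropped).fit()
        for col in dropped.columns:
            if col == "const":
                assert fit.intercept == pytest.approx(oracle.params[col], rel=1e-9)
                continue
            key = next(
                (k for k in o_design.level_keys() if level_column(*k) == col), col
            )
            est = (
                fit.level_disutilities[key]
                if isinstance(key, tuple)
                else fit.ses_effects[col]
            )
            assert est == pytest.approx(oracle.params[col], rel=1e-8, abs=1e-12)
            assert fit.standard_errors[key] == pytest.approx(
                oracle.bse[col], rel=1e-6
            )
        assert fit.level_disutilities[("role", 2)] == 0.0
        assert fit.standard_errors[("role", 2)] == 0.0

    def test_empty_constraints_reproduce_ols(self, o_design):
        a = it.fit_ols(o_design)
        b = it.fit_constrained_ols(o_design, [])
        assert a.level_disutilities == b.level_disutilities

    def test_constraining_to_ols_value_is_identity(self, o_design):
        a = it.fit_ols(o_design)
        v = a.level_disutilities[("security", 3)]
        b = it.fit_constrained_ols(o_design, [("security", 3, v)])
        for k in a.level_disutilities:
            assert b.level_disutilities[k] == pytest.approx(
                a.level_disutilities[k], abs=1e-10
            )

    def test_near_zero_constraint_changes_little(self):
        """Zeroing a coefficient that OLS already puts near zero moves the
        remaining coefficients only marginally."""
        truth = calibrated_truth("ICECAP-O")  # role 2 truth is +0.004
        cfg = it.default_config("ICECAP-O", n=4000, seed=21,
                                true_coefficients=truth)
        d = it.build_design(it.generate_dataset(cfg), it.ICECAP_O)
        free = it.fit_ols(d)
        assert abs(free.level_disutilities[("role", 2)]) < 0.02
        tied = it.fit_constrained_ols(d, [("role", 2, 0.0)])
        for k in free.level_disutilities:
            if k == ("role", 2):
                continue
            assert abs(
                tied.level_disutilities[k] - free.level_disutilities[k]
            ) < 0.01

    def test_bad_constraints_rejected(self, o_design):
        with pytest.raises(ValueError):
            it.fit_constrained_ols(o_design, [("role", 2, 0.0), ("role", 2, 0.1)])
        with pytest.raises(ValueError):
            it.fit_constrained_ols(o_design, [("joy", 2, 0.0)])


class TestTobit:
    def test_uncensored_limit_equals_ols(self, o_design):
        d = dataclasses.replace(o_design, y=0.1 + 0.8 * o_design.y)
        ols = it.fit_ols(d)
        tob = it.fit_tobit(d)
        assert tob.n_censored == 0
        assert abs(tob.intercept - ols.intercept) < 1e-3
        for k in ols.level_disutilities:
            assert abs(
                tob.level_disutilities[k] - ols.level_disutilities[k]
            ) < 1e-3

    def test_heavy_censoring_tobit_beats_ols(self):
        """With ~40% of latent SWB clamped at 1, the Tobit slope estimates
        stay near the truth while OLS attenuates toward zero."""
        truth = calibrated_truth("ICECAP-O")
        shifted = dataclasses.replace(truth, intercept=truth.intercept + 0.25)
        cfg = it.default_config(
            "ICECAP-O", n=3000, seed=6, noise_sd=0.1, censor=True,
            measurement_sd=0.0, true_coefficients=shifted,
        )
        d = it.build_design(it.generate_dataset(cfg), it.ICECAP_O)
        ols = it.fit_ols(d)
        tob = it.fit_tobit(d)
        assert tob.n_censored > 0.2 * d.n
        keys = [(dim, 4) for dim in it.ICECAP_O.dimensions]
        err_ols = np.mean(
            [abs(ols.level_disutilities[k] - truth.level_disutilities[k]) for k in keys]
        )
        err_tob = np.mean(
            [abs(tob.level_disutilities[k] - truth.level_disutilities[k]) for k in keys]
        )
        assert err_tob < err_ols

    def test_fully_censored_response_rejected(self, o_design):
        d = dataclasses.replace(
            o_design, y=pd.Series(np.ones(o_design.n), name="swb")
        )
        with pytest.raises(EstimationError):
            it.fit_tobit(d)


class TestMonotonicity:
    def test_published_full_model_has_single_positive_violation(self):
        coefs = it.published_coefficients("ICECAP-O", "full")
        v = it.check_monotonicity(coefs)
        assert len(v) == 1
        assert (v[0].dimension, v[0].level, v[0].kind) == ("role", 2, "positive")

    def test_strictly_decreasing_coefficients_pass(self):
        coefs = it.published_coefficients("ICECAP-O", "constrained")
        assert it.check_monotonicity(coefs) == []

    def test_magnitude_reversal_flagged(self):
        coefs = it.published_coefficients("ICECAP-O", "constrained")
        bad = dataclasses.replace(
            coefs,
            level_disutilities={
                **coefs.level_disutilities,
                ("security", 2): -0.05,
                ("security", 3): -0.03,
                ("security", 4): -0.10,
            },
        )
        v = it.check_monotonicity(bad)
        assert [(x.dimension, x.level) for x in v] == [("security", 3)]

    def test_violations_translate_to_zero_constraints(self):
        coefs = it.published_coefficients("ICECAP-O", "full")
        v = it.check_monotonicity(coefs)
        assert it.constraints_for_violations(coefs, v, policy="zero") == [
            ("role", 2, 0.0)
        ]
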