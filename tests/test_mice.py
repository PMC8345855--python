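"""Chained-equations imputation: contracts, recovery against the truth
sidecar, and the post-imputation combination / deletion steps."""

import numpy as np
import pandas as pd
import pytest

from gcsimpute.cohort import simulate_cohort
from gcsimpute.config import GOSE_COLS, CohortConfig
from gcsimpute.errors import ConfigError, DataError
from gcsimpute.mice import (
    ImputationConfig,
    VariableSpec,
    add_timepoint_aggregates,
    combine_presenting_ed,
    default_covariate_specs,
    default_fill,
    drop_no_outcome,
    impute_timepoint_assessments,
    mice,
)


class TestDefaultFill:
    def test_all_missing_hypoxia_set_absent(self):
        df = pd.DataFrame({"age": [40.0, 50.0], "hypoxia": [np.nan, np.nan],
                           "hypotension": [1.0, np.nan]})
        out = default_fill(df)
        assert (out["hypoxia"] == 0).all()
        assert out["hypotension"].tolist() == [1.0, 0.0]

    def test_no_missing_identity(self):
        df = pd.DataFrame({"age": [40.0], "hypoxia": [1.0], "hypotension": [0.0]})
        pd.testing.assert_frame_equal(default_fill(df), df)

    def test_missing_age_errors(self):
        df = pd.DataFrame({"age": [np.nan], "hypoxia": [0.0], "hypotension": [0.0]})
        with pytest.raises(DataError):
            default_fill(df)


class TestSpecValidation:
    def test_self_prediction_rejected(self):
        s = VariableSpec("x", "impute", "gaussian_linear", ("x", "y"))
        with pytest.raises(ConfigError):
            s.validate()

    def test_impute_needs_family(self):
        with pytest.raises(ConfigError):
            VariableSpec("x", "impute", None, ("y",)).validate()

    def test_config_bounds(self):
        with pytest.raises(ConfigError):
            ImputationConfig(m=1).validate()
        with pytest.raises(ConfigError):
            ImputationConfig(iterations=0).validate()


def _simple_gaussian_problem(n=2000, miss=0.3, seed=0, true_mean=10.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = true_mean + 1.5 * x + 2.0 * rng.standard_normal(n)
    df = pd.DataFrame({"x": x, "y": y})
    mask = rng.random(n) < miss
    df.loc[mask, "y"] = np.nan
    spec = VariableSpec("y", "impute", "gaussian_linear", ("x",))
    return df, y, mask, spec


class TestMiceCore:
    def test_no_missing_cells_identity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [0.0, 1.0, 0.5, 2.0]})
        spec = VariableSpec("y", "impute", "gaussian_linear", ("x",))
        out = mice(df, [spec], ImputationConfig(m=3, iterations=2, seed=0))
        for ds in out.datasets:
            pd.testing.assert_frame_equal(ds, df)

    def test_observed_cells_never_altered(self):
        df, y, mask, spec = _simple_gaussian_problem()
        out = mice(df, [spec], ImputationConfig(m=4, iterations=3, seed=1))
        for ds in out.datasets:
            np.testing.assert_array_equal(ds.loc[~mask, "y"], df.loc[~mask, "y"])
            assert ds["y"].notna().all()

    def test_determinism_given_seed(self):
        df, *_ , spec = _simple_gaussian_problem(n=300)
        a = mice(df, [spec], ImputationConfig(m=3, iterations=2, seed=5))
        b = mice(df, [spec], ImputationConfig(m=3, iterations=2, seed=5))
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)
        c = mice(df, [spec], ImputationConfig(m=3, iterations=2, seed=6))
        assert not c.datasets[0].equals(a.datasets[0])

    def test_gaussian_mcar_mean_recovery(self):
        """30% MCAR on a gaussian variable: the grand mean of imputed
        cells stays within 3 Monte-Carlo SEs of the generating mean."""
        df, y_true, mask, spec = _simple_gaussian_problem(n=2000, miss=0.3, true_mean=10.0)
        out = mice(df, [spec], ImputationConfig(m=20, iterations=5, seed=2))
        imputed = np.concatenate([ds.loc[mask, "y"].to_numpy() for ds in out.datasets])
        # marginal SD of y is sqrt(1.5^2 + 2^2); the m draws per cell are
        # dependent, so use the per-dataset (conservative) SE
        se = np.sqrt(1.5**2 + 2.0**2) / np.sqrt(mask.sum())
        assert abs(imputed.mean() - 10.0) < 3 * se

    def test_binary_mar_coefficient_recovery(self):
        """MAR missingness in a binary variable driven by an observed
        covariate: pooled logistic slope recovers the generating value."""
        from gcsimpute.fitters import fit_logistic_mle
        from gcsimpute.models import rubin_pool
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.standard_normal(n)
        true_b = 1.0
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + true_b * x)))).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        p_miss = 1 / (1 + np.exp(-(np.log(0.25 / 0.75) + 0.8 * x)))  # MAR given x
        mask = rng.random(n) < p_miss
        df.loc[mask, "y"] = np.nan
        spec = VariableSpec("y", "impute", "binary_logistic", ("x",))
        out = mice(df, [spec], ImputationConfig(m=20, iterations=5, seed=4))
        fits = [fit_logistic_mle(ds[["x"]].to_numpy(), ds["y"].to_numpy())
                for ds in out.datasets]
        pooled = rubin_pool(fits)
        est, se = pooled.loc["x0", "estimate"], pooled.loc["x0", "se"]
        assert abs(est - true_b) < 3 * se

    def test_between_imputation_variance_positive(self):
        df, _, mask, spec = _simple_gaussian_problem(n=500)
        out = mice(df, [spec], ImputationConfig(m=20, iterations=3, seed=7))
        stack = np.stack([ds.loc[mask, "y"].to_numpy() for ds in out.datasets])
        var = stack.var(axis=0)
        assert (var > 0).mean() >= 0.99

    def test_congeniality_mcar_smoke(self):
        """Under MCAR, complete-case and post-imputation pooled slope
        estimates agree within Monte-Carlo error."""
        from gcsimpute.fitters import fit_logistic_mle
        from gcsimpute.models import rubin_pool
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        mask = rng.random(n) < 0.25
        df.loc[mask, "y"] = np.nan
        cc = fit_logistic_mle(df.loc[~mask, ["x"]].to_numpy(), df.loc[~mask, "y"].to_numpy())
        out = mice(df, [VariableSpec("y", "impute", "binary_logistic", ("x",))],
                   ImputationConfig(m=20, iterations=5, seed=9))
        pooled = rubin_pool([fit_logistic_mle(ds[["x"]].to_numpy(), ds["y"].to_numpy())
                             for ds in out.datasets])
        assert abs(pooled.loc["x0", "estimate"] - cc.params[1]) < 3 * pooled.loc["x0", "se"]

    def test_zero_observed_cases_errors(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        spec = VariableSpec("y", "impute", "gaussian_linear", ("x",))
        with pytest.raises(DataError):
            mice(df, [spec], ImputationConfig(m=2, iterations=1, seed=0))

    def test_incomplete_predictor_without_spec_errors(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "y": [np.nan, 2.0]})
        spec = VariableSpec("y", "impute", "gaussian_linear", ("x",))
        with pytest.raises(DataError):
            mice(df, [spec], ImputationConfig(m=2, iterations=1, seed=0))


@pytest.fixture(scope="module")
def imputed(default_cohort):
    cohort, _ = default_cohort
    out = mice(default_fill(cohort), default_covariate_specs(),
               ImputationConfig(m=5, iterations=3, seed=0))
    return cohort, out


@pytest.fixture(scope="module")
def full_imputed(default_cohort):
    cohort, _ = default_cohort
    out = impute_timepoint_assessments(
        cohort, ImputationConfig(m=3, iterations=3, seed=1))
    return cohort, out


class TestCohortImputation:
    def test_no_missing_covariates_remain(self, imputed):
        _, out = imputed
        for ds in out.datasets:
            for col in ("glucose", "hb", "marshall", "tsah", "edh",
                        "gose_3mo", "gose_6mo", "gose_12mo"):
                assert ds[col].notna().all(), col

    def test_ordinal_support_respected(self, imputed):
        _, out = imputed
        for ds in out.datasets:
            assert ds["marshall"].isin(range(1, 7)).all()
            assert ds["gose_6mo"].between(1, 8).all()

    def test_drop_no_outcome(self, imputed):
        cohort, out = imputed
        all_missing = cohort[list(GOSE_COLS)].isna().all(axis=1)
        dropped = drop_no_outcome(out)
        for ds in dropped.datasets:
            assert len(ds) == len(cohort) - all_missing.sum()
        # a patient with an observed 3-month GOSE only is retained
        partial = cohort[cohort["gose_3mo"].notna() & cohort["gose_6mo"].isna()
                         & cohort["gose_12mo"].isna()]
        if len(partial):
            assert partial.index[0] in dropped.datasets[0].index


class TestTimepointImputation:
    def test_gcs_sum_support(self, full_imputed):
        _, out = full_imputed
        for ds in out.datasets:
            for tp in ("preh", "study_arr", "ed_disch"):
                assert ds[f"gcs_sum_{tp}"].between(3, 15).all()
                assert ds[f"gcs_motor_{tp}"].between(1, 6).all()
                assert ds[f"pupils_agg_{tp}"].isin([0, 1, 2]).all()

    def test_referring_imputed_only_for_transfers(self, full_imputed):
        _, out = full_imputed
        for ds in out.datasets:
            transfers = ds["transfer"] == 1
            assert ds.loc[transfers, "gcs_sum_ref_arr"].notna().all()
            assert ds.loc[~transfers, "gcs_sum_ref_arr"].isna().all()

    def test_imputation_beats_marginal_draw(self, default_cohort):
        """Masked-then-imputed discharge GCS is closer to the pre-mask
        value than drawing blindly from the observed marginal."""
        cfg = CohortConfig(n_patients=2000, seed=13)
        cohort, truth = simulate_cohort(cfg)
        prepped = add_timepoint_aggregates(cohort)
        truth_agg = add_timepoint_aggregates(
            truth.assign(transfer=cohort["transfer"]))
        col = "gcs_sum_ed_disch"
        mask = prepped[col].isna() & truth_agg[col].notna()
        out = impute_timepoint_assessments(cohort, ImputationConfig(m=5, iterations=3, seed=2))
        true_vals = truth_agg.loc[mask, col].to_numpy()
        errs = [np.abs(ds.loc[mask, col].to_numpy() - true_vals).mean()
                for ds in out.datasets]
        rng = np.random.default_rng(0)
        obs = prepped.loc[prepped[col].notna(), col].to_numpy()
        marginal_err = np.abs(rng.choice(obs, size=(20, mask.sum())) - true_vals).mean()
        assert np.mean(errs) < marginal_err

    def test_combine_presenting_ed(self):
        df = pd.DataFrame({
            "transfer": [1.0, 0.0],
            "gcs_sum_ref_arr": [9.0, np.nan],
            "gcs_sum_study_arr": [11.0, 12.0],
            "gcs_motor_ref_arr": [4.0, np.nan],
            "gcs_motor_study_arr": [5.0, 6.0],
            "pupils_agg_ref_arr": [1.0, np.nan],
            "pupils_agg_study_arr": [0.0, 0.0],
        })
        out = combine_presenting_ed(df)
        assert out["gcs_sum_presenting"].tolist() == [9.0, 12.0]
        assert out["pupils_agg_presenting"].tolist() == [1.0, 0.0]
        # Series input round-trips through the same rule
        rec = combine_presenting_ed(df.iloc[0])
        assert rec["gcs_sum_presenting"] == 9.0
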