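"""Multiple imputation by chained equations (MICE).

Per-variable conditional models, matched to each variable's type:

* ``gaussian_linear`` — Bayesian linear regression (conjugate draw of
  the residual variance and coefficients) for approximately normal
  covariates (glucose, haemoglobin);
* ``binary_logistic`` — logistic regression with a normal
  approximation to the parameter posterior at the MLE (EDH, tSAH);
* ``ordinal_proportional_odds`` — proportional-odds regression, same
  posterior approximation, draws respecting the observed category
  support (Marshall class, GOSE, per-time-point GCS sum / motor /
  pupil scores).

Each of the M completed datasets starts from an independent random
fill drawn from the observed marginals and runs a fixed number of
sweeps over the variables in a fixed, documented visit order:
covariates first (glucose, haemoglobin, EDH, tSAH, Marshall), then
time-point assessments, then the GOSE outcomes.  3- and 12-month GOSE
act as auxiliaries for the 6-month outcome and are themselves
imputable (mutual auxiliaries).  Observed cells are never altered.

Conditional fits that fail or separate are retried through a ridge
schedule (see :mod:`gcsimpute.fitters`) before an error is raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .baseline import gcs_motor_at_timepoint, gcs_sum_at_timepoint
from .config import COVARIATES, GOSE_COLS, TIMEPOINTS
from .errors import ConfigError, DataError
from .fitters import (
    fit_logistic_mle,
    fit_proportional_odds_mle,
    fit_with_retries,
    po_category_probs,
)

FAMILIES = ("gaussian_linear", "binary_logistic", "ordinal_proportional_odds")


@dataclass(frozen=True)
class VariableSpec:
    """Conditional-model specification for one variable."""

    name: str
    role: str  # complete | impute | default_fill | outcome
    family: str | None = None
    predictors: tuple[str, ...] = ()
    #: optional boolean column restricting which rows can carry a value
    #: (e.g. referring-ED assessments exist only for transfers)
    eligible_col: str | None = None

    def validate(self) -> None:
        if self.role == "impute":
            if self.family not in FAMILIES:
                raise ConfigError(f"specs.{self.name}.family", f"unknown family {self.family!r}")
            if not self.predictors:
                raise ConfigError(f"specs.{self.name}.predictors", "must be non-empty")
            if self.name in self.predictors:
                raise ConfigError(f"specs.{self.name}.predictors", "variable may not predict itself")


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 200
    iterations: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigError("m", "need at least 2 completed datasets")
        if self.iterations < 1:
            raise ConfigError("iterations", "need at least 1 sweep")


@dataclass
class CompletedDatasetSet:
    """M completed copies of a cohort plus provenance."""

    datasets: list[pd.DataFrame]
    specs: tuple[VariableSpec, ...]
    config: ImputationConfig
    seeds: list[list[int]]
    orig_missing: pd.DataFrame  # boolean mask over the spec-involved columns

    @property
    def m(self) -> int:
        return len(self.datasets)


# ----------------------------------------------------------------------

def default_fill(cohort: pd.DataFrame) -> pd.DataFrame:
    """Default-fill rules applied before chained imputation.

    Missing hypoxia / hypotension are assumed absent (0).  Age must be
    complete.
    """
    if cohort["age"].isna().any():
        raise DataError("age must be complete")
    out = cohort.copy()
    for col in ("hypoxia", "hypotension"):
        out[col] = out[col].fillna(0.0)
    return out


def default_covariate_specs() -> tuple[VariableSpec, ...]:
    """Specs for the covariate-and-outcome-only imputation run.

    Visit order: glucose, haemoglobin, EDH, tSAH, Marshall, then the
    three GOSE outcomes (3/12-month GOSE as mutual auxiliaries of the
    6-month outcome).
    """
    base = ("age", "hypoxia", "hypotension")
    ct = ("marshall", "tsah", "edh")
    return (
        VariableSpec("glucose", "impute", "gaussian_linear",
                     base + ("hb",) + ct + ("gose_6mo",)),
        VariableSpec("hb", "impute", "gaussian_linear",
                     base + ("glucose",) + ct + ("gose_6mo",)),
        VariableSpec("edh", "impute", "binary_logistic",
                     base + ("glucose", "hb", "marshall", "tsah", "gose_6mo")),
        VariableSpec("tsah", "impute", "binary_logistic",
                     base + ("glucose", "hb", "marshall", "edh", "gose_6mo")),
        VariableSpec("marshall", "impute", "ordinal_proportional_odds",
                     base + ("glucose", "hb", "tsah", "edh") + GOSE_COLS[:1] + GOSE_COLS[1:]),
        VariableSpec("gose_3mo", "impute", "ordinal_proportional_odds",
                     base + ("glucose", "hb") + ct + ("gose_6mo", "gose_12mo")),
        VariableSpec("gose_6mo", "impute", "ordinal_proportional_odds",
                     base + ("glucose", "hb") + ct + ("gose_3mo", "gose_12mo")),
        VariableSpec("gose_12mo", "impute", "ordinal_proportional_odds",
                     base + ("glucose", "hb") + ct + ("gose_3mo", "gose_6mo")),
    )


def _fix_marshall_predictors(specs):
    # marshall's own spec must not list marshall as predictor
    fixed = []
    for s in specs:
        preds = tuple(p for p in s.predictors if p != s.name)
        fixed.append(VariableSpec(s.name, s.role, s.family, preds, s.eligible_col))
    return tuple(fixed)


AGGREGATE_VARS = ("gcs_sum", "gcs_motor", "pupils_agg")


def assessment_specs() -> tuple[VariableSpec, ...]:
    """Specs for the per-time-point assessment variables.

    Each GCS sum / motor / pupil score at each time point is imputed as
    ordinal, predicted by the other time points' assessments (the
    structurally absent referring-ED columns are never predictors),
    the covariates and the GOSE auxiliaries.  Referring-ED targets are
    restricted to secondarily transferred patients.
    """
    cov = ("age", "glucose", "hb", "marshall", "tsah", "edh", "hypoxia", "hypotension")
    agg_cols = [f"{v}_{tp}" for tp in TIMEPOINTS for v in AGGREGATE_VARS]
    non_ref = [c for c in agg_cols if not c.endswith("_ref_arr")]
    specs = []
    for tp in TIMEPOINTS:
        for v in AGGREGATE_VARS:
            name = f"{v}_{tp}"
            preds = tuple(c for c in non_ref if c != name) + cov + GOSE_COLS
            specs.append(VariableSpec(
                name, "impute", "ordinal_proportional_odds", preds,
                eligible_col="transfer" if tp == "ref_arr" else None))
    return tuple(specs)


def full_specs() -> tuple[VariableSpec, ...]:
    """Visit order for the full (time-point) imputation run: covariates,
    then assessments, then GOSE outcomes."""
    cov_specs = list(default_covariate_specs())
    gose = [s for s in cov_specs if s.name in GOSE_COLS]
    cov = [s for s in cov_specs if s.name not in GOSE_COLS]
    return tuple(cov) + assessment_specs() + tuple(gose)


# ----------------------------------------------------------------------
# Conditional draw machinery

def _chol_psd(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((cov + cov.T) / 2)
        w = np.clip(w, 1e-12, None)
        return v * np.sqrt(w)


def _draw_gaussian(rng, X_obs, y_obs, X_mis):
    n, p1 = X_obs.shape[0], X_obs.shape[1] + 1
    X1 = np.hstack([np.ones((n, 1)), X_obs])
    beta_hat, *_ = np.linalg.lstsq(X1, y_obs, rcond=None)
    resid = y_obs - X1 @ beta_hat
    df = max(n - p1, 1)
    sse = float(resid @ resid)
    sigma2 = sse / max(rng.chisquare(df), 1e-12)
    xtx = X1.T @ X1
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    beta = beta_hat + _chol_psd(sigma2 * xtx_inv) @ rng.standard_normal(p1)
    X1m = np.hstack([np.ones((len(X_mis), 1)), X_mis])
    return X1m @ beta + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def _draw_binary_values(rng, X_obs, y01, X_mis):
    fit = fit_with_retries(fit_logistic_mle, X_obs, y01)
    beta = fit.params + _chol_psd(fit.cov) @ rng.standard_normal(len(fit.params))
    p = expit(np.hstack([np.ones((len(X_mis), 1)), X_mis]) @ beta)
    return (rng.random(len(X_mis)) < p).astype(float)


def _draw_ordinal(rng, X_obs, y_obs, X_mis):
    cats = np.unique(y_obs)
    if cats.size == 1:
        return np.full(len(X_mis), cats[0])
    if cats.size == 2:
        y01 = (y_obs == cats[1]).astype(float)
        d = _draw_binary_values(rng, X_obs, y01, X_mis)
        return np.where(d == 1.0, cats[1], cats[0])
    codes = np.searchsorted(cats, y_obs)
    fit = fit_with_retries(fit_proportional_odds_mle, X_obs, codes, cats.size)
    k1 = fit.n_cutpoints
    L = _chol_psd(fit.cov)
    params = None
    for _ in range(8):  # redraw until cutpoints stay monotone
        cand = fit.params + L @ rng.standard_normal(len(fit.params))
        if np.all(np.diff(cand[:k1]) > 0):
            params = cand
            break
    if params is None:  # isotonise the last draw
        cand[:k1] = np.maximum.accumulate(cand[:k1])
        cand[:k1] += 1e-6 * np.arange(k1)
        params = cand
    probs = po_category_probs(params[:k1], params[k1:], X_mis)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(X_mis))
    idx = (u[:, None] > cum).sum(axis=1)
    return cats[np.minimum(idx, cats.size - 1)]


# ----------------------------------------------------------------------

def mice(cohort: pd.DataFrame, specs: Sequence[VariableSpec], config: ImputationConfig) -> CompletedDatasetSet:
    """Chained-equations multiple imputation.

    Produces ``config.m`` completed copies of the cohort.  Only the
    columns named in ``specs`` (and their predictors) participate;
    other columns pass through untouched.  Every predictor must either
    be complete or itself carry an impute spec.
    """
    config.validate()
    specs = _fix_marshall_predictors(specs)
    for s in specs:
        s.validate()
    impute_specs = [s for s in specs if s.role == "impute"]
    spec_names = {s.name for s in impute_specs}
    involved: list[str] = []
    for s in impute_specs:
        for c in (s.name, *s.predictors):
            if c not in involved:
                involved.append(c)
    for c in involved:
        if c not in cohort.columns:
            raise DataError(f"column {c!r} not in cohort")

    elig: dict[str, np.ndarray] = {}
    n = len(cohort)
    for s in impute_specs:
        if s.eligible_col is not None:
            elig[s.name] = cohort[s.eligible_col].to_numpy(float) == 1.0
        else:
            elig[s.name] = np.ones(n, dtype=bool)
        if s.eligible_col is not None:
            for other in impute_specs:
                if s.name in other.predictors:
                    raise ConfigError(
                        f"specs.{other.name}.predictors",
                        f"{s.name} has restricted eligibility and cannot be a predictor")

    base = {c: cohort[c].to_numpy(float) for c in involved}
    miss = {c: np.isnan(base[c]) for c in involved}
    for c in involved:
        if c not in spec_names:
            if miss[c].any():
                raise DataError(f"predictor {c!r} has missing cells but no impute spec")
    for s in impute_specs:
        obs = ~miss[s.name] & elig[s.name]
        if not obs.any():
            raise DataError(f"variable {s.name!r} has zero observed cases")

    ss = np.random.SeedSequence([int(config.seed), 0x6D696365])
    children = ss.spawn(config.m)
    datasets: list[pd.DataFrame] = []
    seed_trace: list[list[int]] = []

    for j in range(config.m):
        rng = np.random.default_rng(children[j])
        seed_trace.append([int(config.seed), j])
        work = {c: base[c].copy() for c in involved}
        # initial fill: random draw from the observed marginal
        for s in impute_specs:
            obs_vals = base[s.name][~miss[s.name] & elig[s.name]]
            target = miss[s.name] & elig[s.name]
            work[s.name][target] = rng.choice(obs_vals, size=int(target.sum()), replace=True)
        for _it in range(config.iterations):
            for s in impute_specs:
                target = miss[s.name] & elig[s.name]
                if not target.any():
                    continue
                obs = ~miss[s.name] & elig[s.name]
                X_all = np.column_stack([work[p] for p in s.predictors])
                X_obs, y_obs, X_mis = X_all[obs], base[s.name][obs], X_all[target]
                if s.family == "gaussian_linear":
                    drawn = _draw_gaussian(rng, X_obs, y_obs, X_mis)
                elif s.family == "binary_logistic":
                    vals = np.unique(y_obs)
                    if vals.size == 1:
                        drawn = np.full(len(X_mis), vals[0])
                    else:
                        y01 = (y_obs == vals[-1]).astype(float)
                        d = _draw_binary_values(rng, X_obs, y01, X_mis)
                        drawn = np.where(d == 1.0, vals[-1], vals[0])
                else:
                    drawn = _draw_ordinal(rng, X_obs, y_obs, X_mis)
                work[s.name][target] = drawn
        ds = cohort.copy()
        for c in spec_names:
            ds[c] = work[c]
        datasets.append(ds)

    mask_df = pd.DataFrame({c: miss[c] for c in involved}, index=cohort.index)
    return CompletedDatasetSet(datasets, tuple(specs), config, seed_trace, mask_df)


# ----------------------------------------------------------------------

def add_timepoint_aggregates(
    cohort: pd.DataFrame, sum_policy: str = "nc_if_either", motor_policy: str = "nc_if_m",
) -> pd.DataFrame:
    """Add per-time-point GCS sum / motor / pupil aggregate columns
    (``gcs_sum_<tp>``, ``gcs_motor_<tp>``, ``pupils_agg_<tp>``) computed
    from the components under the given sub-score policies."""
    out = cohort.copy()
    for tp in TIMEPOINTS:
        out[f"gcs_sum_{tp}"] = gcs_sum_at_timepoint(
            cohort[f"eye_{tp}"], cohort[f"verbal_{tp}"], cohort[f"motor_{tp}"], sum_policy)
        out[f"gcs_motor_{tp}"] = gcs_motor_at_timepoint(cohort[f"motor_{tp}"], motor_policy)
        out[f"pupils_agg_{tp}"] = cohort[f"pupils_{tp}"].to_numpy(float)
    return out


def impute_timepoint_assessments(
    cohort: pd.DataFrame,
    config: ImputationConfig,
    sum_policy: str = "nc_if_either",
    motor_policy: str = "nc_if_m",
) -> CompletedDatasetSet:
    """Full imputation run: covariates, per-time-point assessment
    scores (ordinal over their category support) and GOSE outcomes."""
    prepped = add_timepoint_aggregates(default_fill(cohort), sum_policy, motor_policy)
    return mice(prepped, full_specs(), config)


def combine_presenting_ed(data):
    """Combine referring-ED and study-ED arrival assessments into a
    single *presenting ED arrival* time point: the referring value for
    secondary transfers, otherwise the study-hospital value (the first
    ED to which the patient presented).

    Accepts a completed dataset (DataFrame) or a single record
    (Series); returns the same type with ``*_presenting`` fields added.
    """
    if isinstance(data, pd.Series):
        return combine_presenting_ed(data.to_frame().T).iloc[0]
    out = data.copy()
    is_transfer = out["transfer"].to_numpy(float) == 1.0
    for v in AGGREGATE_VARS:
        ref = out[f"{v}_ref_arr"].to_numpy(float)
        study = out[f"{v}_study_arr"].to_numpy(float)
        out[f"{v}_presenting"] = np.where(is_transfer, ref, study)
    return out


def drop_no_outcome(dataset_set: CompletedDatasetSet) -> CompletedDatasetSet:
    """Remove patients whose GOSE was originally missing at all of 3, 6
    and 12 months from every completed dataset (deleted after
    imputation for statistical efficiency; the row set is identical
    across datasets)."""
    mask = dataset_set.orig_missing
    for c in GOSE_COLS:
        if c not in mask.columns:
            raise DataError("GOSE columns were not part of the imputation; cannot apply deletion")
    drop = mask[list(GOSE_COLS)].all(axis=1)
    keep_idx = mask.index[~drop]
    datasets = [ds.loc[keep_idx].copy() for ds in dataset_set.datasets]
    return CompletedDatasetSet(
        datasets, dataset_set.specs, dataset_set.config, dataset_set.seeds,
        mask.loc[keep_idx].copy())
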