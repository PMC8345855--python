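"""Outcome models and McFadden pseudo-R² comparison.

Two model families, both on the IMPACT covariate set (age, glucose,
haemoglobin, Marshall CT class, tSAH, EDH) plus one candidate GCS-type
variable and one candidate pupil variable:

* logistic regression for dichotomous 6-month survival (GOSE 1 = dead,
  GOSE >= 2 = alive — vegetative state counts as survival);
* proportional-odds regression for the full ordinal 6-month GOSE.

Model quality is compared by McFadden's pseudo-R²,
``1 - logL(model) / logL(null)``, where the null model is
intercept-only (logistic) or cutpoints-only (proportional odds).  Per
completed imputation a separate fit is produced and the distribution
of R² values across the M completed datasets is reported; Rubin's
rules are applied to coefficients only, when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FitError
from .fitters import (
    FitResult,
    fit_logistic_mle,
    fit_proportional_odds_mle,
    fit_with_retries,
)

#: IMPACT fixed covariates entering every outcome model.  GCS / GCSm
#: and Marshall enter as linear numeric terms.
FIXED_COVARIATES = ("age", "glucose", "hb", "marshall", "tsah", "edh")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid."""

    family: str  # "logistic" (6-month survival) or "propodds" (GOSE)
    gcs_col: str
    pupil_col: str
    stratum: str = "all"  # "all" or "icu"
    fixed_covariates: tuple[str, ...] = FIXED_COVARIATES
    include_hypoxia_hypotension: bool = False
    outcome_col: str = "gose_6mo"

    def covariate_columns(self) -> list[str]:
        cols = [self.gcs_col, self.pupil_col, *self.fixed_covariates]
        if self.include_hypoxia_hypotension:
            cols += ["hypoxia", "hypotension"]
        return cols

    def validate(self) -> None:
        if self.family not in ("logistic", "propodds"):
            raise DataError(f"unknown model family {self.family!r}")
        if self.stratum not in ("all", "icu"):
            raise DataError(f"unknown stratum filter {self.stratum!r}")


def dichotomise_survival(gose) -> np.ndarray:
    """Map 6-month GOSE (1-8) to survival: 1 = alive (GOSE >= 2),
    0 = dead (GOSE = 1)."""
    g = np.asarray(gose, dtype=float)
    valid = g[~np.isnan(g)]
    if valid.size and ((valid < 1) | (valid > 8)).any():
        raise DataError("GOSE outside [1, 8]")
    out = np.where(np.isnan(g), np.nan, (g >= 2).astype(float))
    return out


def build_design(dataset: pd.DataFrame, spec: ModelSpec):
    """Stratum filter + complete-case restriction on the model columns.

    Returns ``(X, gose, names, index)``; residual missingness in the
    candidate columns is handled here by per-model complete-case
    deletion.
    """
    spec.validate()
    df = dataset
    if spec.stratum == "icu":
        df = df[df["stratum"] == "icu"]
    cols = spec.covariate_columns()
    use = df[cols + [spec.outcome_col]].dropna()
    if len(use) == 0:
        raise DataError("no complete rows for model fit")
    X = use[cols].to_numpy(dtype=float)
    return X, use[spec.outcome_col].to_numpy(dtype=float), list(cols), use.index


def fit_logistic(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Logistic survival model on one (completed) dataset."""
    X, gose, names, _ = build_design(dataset, spec)
    y = dichotomise_survival(gose)
    if np.unique(y).size < 2:
        raise DataError("survival outcome has a single class")
    return fit_with_retries(fit_logistic_mle, X, y, param_names=names)


def fit_proportional_odds(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Proportional-odds GOSE model on one (completed) dataset.

    Empty GOSE categories are collapsed before fitting (the category
    mapping is positional: observed values in ascending order).
    """
    X, gose, names, _ = build_design(dataset, spec)
    if np.unique(gose).size < 2:
        raise DataError("ordinal outcome has a single category")
    cats, codes = np.unique(gose, return_inverse=True)
    return fit_with_retries(fit_proportional_odds_mle, X, codes, len(cats), param_names=names)


def fit_model(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    if spec.family == "logistic":
        return fit_logistic(dataset, spec)
    return fit_proportional_odds(dataset, spec)


def mcfadden_r2(fit: FitResult) -> float:
    """McFadden pseudo-R²: ``1 - logL(model) / logL(null)``.

    Zero iff the model adds no likelihood over the null; requires a
    non-degenerate outcome (null log-likelihood < 0).
    """
    if fit.loglike_null >= 0.0:
        raise DataError("degenerate outcome: null log-likelihood is zero")
    r2 = 1.0 - fit.loglike / fit.loglike_null
    if -1e-10 < r2 < 0.0:  # numerically-null model
        r2 = 0.0
    return float(r2)


@dataclass
class R2Distribution:
    """Per-imputation pseudo-R² values for one model-grid cell."""

    values: np.ndarray
    n_nonconverged: int = 0

    def summary(self) -> dict[str, float]:
        v = self.values
        return {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "q25": float(np.quantile(v, 0.25)),
            "q75": float(np.quantile(v, 0.75)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n": int(v.size),
            "n_nonconverged": int(self.n_nonconverged),
        }


def per_imputation_r2(datasets: Iterable[pd.DataFrame], spec: ModelSpec) -> R2Distribution:
    """Fit the model on every completed dataset, one R² per dataset.

    Non-converged fits are excluded (with a count) rather than pooled;
    no Rubin combination of R² is attempted — the distribution itself
    is the reported quantity.
    """
    values: list[float] = []
    bad = 0
    for ds in datasets:
        try:
            fit = fit_model(ds, spec)
        except FitError:
            bad += 1
            continue
        if not fit.converged:
            bad += 1
            continue
        values.append(mcfadden_r2(fit))
    if not values:
        raise FitError("no converged fits in any completed dataset")
    return R2Distribution(np.asarray(values), bad)


def rubin_pool(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rubin's rules for the slope coefficients of M per-dataset fits.

    Returns estimate, total SE, and the between/within variance split,
    indexed by parameter name.  Applies to coefficients only (never to
    pseudo-R²).
    """
    if len(fits) < 2:
        raise DataError("Rubin pooling needs >= 2 fits")
    names = fits[0].param_names
    est = np.stack([f.params for f in fits])
    var = np.stack([np.diag(f.cov) for f in fits])
    m = len(fits)
    qbar = est.mean(axis=0)
    ubar = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    total = ubar + (1 + 1 / m) * b
    return pd.DataFrame(
        {"estimate": qbar, "se": np.sqrt(total), "within_var": ubar, "between_var": b},
        index=names)
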