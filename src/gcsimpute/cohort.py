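"""Synthetic TBI cohort generation.

A single latent injury-severity score per patient (standard-normal,
higher = worse) drives everything the downstream analysis assumes to be
correlated: GCS components and pupil reactivity observed at up to four
time points, care stratum, baseline covariates, untestability of verbal
and motor components, and the ordinal GOSE outcome.  Ordinal scores are
produced by thresholding continuous latent values (a latent-threshold
construction), which guarantees a monotone severity -> GCS relationship.

Pipeline stages (each deterministic given the config seed):

    generate_cohort  -> fully observed cohort + latent truth
    apply_untestability -> intubation/sedation flags; verbal/motor masked
    apply_missingness   -> MAR not-recorded masking of cells
    write_cohort / read_cohort -> CSV round-trip ("" = missing, "UT" =
    untestable)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .config import (
    COVARIATES,
    GOSE_COLS,
    TIMEPOINTS,
    CohortConfig,
    all_assessment_columns,
)
from .errors import DataError

# Threshold cutpoints (on the latent neuro scale, higher = better
# neurology) mapping the continuous latent into ordinal components.
_EYE_CUTS = np.array([-1.2, -0.4, 0.4])
_VERBAL_CUTS = np.array([-1.5, -0.75, 0.0, 0.75])
_MOTOR_CUTS = np.array([-1.8, -1.1, -0.5, 0.1, 0.8])
#: severity thresholds for 1 and 2 unreactive pupils
_PUPIL_CUTS = np.array([1.2, 1.8])
#: component-specific jitter so E/V/M are correlated but not collinear
_COMPONENT_JITTER_SD = 0.3
#: pupil-assessment noise scales with the same per-time-point
#: reliability as the GCS assessment
_PUPIL_NOISE_SCALE = 0.5
#: latent decline between consecutive time points that counts as
#: neuroworsening
_NEUROWORSENING_DROP = 1.0

FLAG_COLUMNS = [f"intubated_{tp}" for tp in TIMEPOINTS] + [f"sedated_{tp}" for tp in TIMEPOINTS]


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _threshold(x: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """1-based ordinal category from a continuous latent value."""
    return 1 + np.searchsorted(cuts, x, side="left").astype(float)


def generate_cohort(config: CohortConfig, return_truth: bool = False):
    """Generate a fully observed cohort (nothing masked yet).

    Returns the cohort table, and with ``return_truth=True`` also the
    truth sidecar (latent severity, per-time-point latent neuro values,
    neuroworsening flag and pre-mask copies of every maskable column).
    The cohort carries a private ``_severity`` column consumed by the
    untestability stage and dropped on write.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_patients
    cp = config.covariate_params

    severity = rng.standard_normal(n)

    # Care stratum: severity plus noise, thresholded at the mixture
    # quantiles of the latent's marginal distribution.
    strat_lat = severity + config.stratum_noise_sd * rng.standard_normal(n)
    s_scale = float(np.sqrt(1.0 + config.stratum_noise_sd**2))
    t_ed = norm.ppf(min(config.p_ed, 1.0 - 1e-12)) * s_scale if config.p_ed > 0 else -np.inf
    t_hosp = (
        norm.ppf(min(config.p_ed + config.p_hosp, 1.0 - 1e-12)) * s_scale
        if config.p_ed + config.p_hosp > 0
        else -np.inf
    )
    stratum = np.where(strat_lat < t_ed, "ed", np.where(strat_lat < t_hosp, "hosp", "icu"))

    transfer = (rng.random(n) < config.p_transfer).astype(float)

    # Covariates.
    age = np.clip(cp.age_mean + cp.age_loading * severity + cp.age_sd * rng.standard_normal(n),
                  cp.age_min, cp.age_max)
    glucose = cp.glucose_mean + cp.glucose_loading * severity + cp.glucose_sd * rng.standard_normal(n)
    hb = cp.hb_mean + cp.hb_loading * severity + cp.hb_sd * rng.standard_normal(n)
    marshall = _threshold(severity + cp.marshall_noise_sd * rng.standard_normal(n),
                          np.asarray(cp.marshall_cuts))
    tsah = (rng.random(n) < expit(cp.tsah_link.intercept + cp.tsah_link.slope * severity)).astype(float)
    edh = (rng.random(n) < expit(cp.edh_link.intercept + cp.edh_link.slope * severity)).astype(float)
    hypoxia = (rng.random(n) < expit(cp.hypoxia_link.intercept + cp.hypoxia_link.slope * severity)).astype(float)
    hypotension = (rng.random(n) < expit(cp.hypotension_link.intercept + cp.hypotension_link.slope * severity)).astype(float)

    data: dict[str, np.ndarray] = {
        "patient_id": np.arange(n, dtype=float),
        "stratum": stratum,
        "transfer": transfer,
        "age": age,
        "glucose": glucose,
        "hb": hb,
        "marshall": marshall,
        "tsah": tsah,
        "edh": edh,
        "hypoxia": hypoxia,
        "hypotension": hypotension,
    }

    # Per-time-point latent neuro state (higher = better) and ordinal
    # components.  Resuscitation drift improves the latent state at each
    # successive time point; per-time-point noise encodes assessment
    # reliability.  Component-specific offsets are drawn once per
    # patient (a patient-specific E/V/M profile), so with zero noise
    # and zero drift every time point reproduces the same components.
    eye_off = _COMPONENT_JITTER_SD * rng.standard_normal(n)
    verbal_off = _COMPONENT_JITTER_SD * rng.standard_normal(n)
    motor_off = _COMPONENT_JITTER_SD * rng.standard_normal(n)
    true_neuro = np.empty((n, 4))
    for t, tp in enumerate(TIMEPOINTS):
        noise = config.noise_sd_by_timepoint[t] * rng.standard_normal(n)
        x = -severity + config.resuscitation_drift * t + noise
        true_neuro[:, t] = x
        eye = _threshold(x + eye_off, _EYE_CUTS)
        verbal = _threshold(x + verbal_off, _VERBAL_CUTS)
        motor = _threshold(x + motor_off, _MOTOR_CUTS)
        pup_sd = _PUPIL_NOISE_SCALE * config.noise_sd_by_timepoint[t]
        pup_lat = severity - config.resuscitation_drift * t + pup_sd * rng.standard_normal(n)
        pupils = np.searchsorted(_PUPIL_CUTS, pup_lat, side="left").astype(float)
        if tp == "ref_arr":
            # The referring-hospital assessment exists only for
            # secondary transfers.
            absent = transfer == 0
            for arr in (eye, verbal, motor, pupils):
                arr[absent] = np.nan
        data[f"eye_{tp}"] = eye
        data[f"verbal_{tp}"] = verbal
        data[f"motor_{tp}"] = motor
        data[f"pupils_{tp}"] = pupils

    neuroworsening = (np.diff(true_neuro, axis=1) < -_NEUROWORSENING_DROP).any(axis=1)

    # GOSE via a proportional-odds (latent logistic) model on severity
    # and covariates.  3- and 12-month scores are noisy ordinal copies
    # of the same linear predictor, shifted by the recovery drift.
    oc = config.outcome_coefficients
    lp_bad = (
        oc.get("severity", 0.0) * severity
        + oc.get("age", 0.0) * (age - cp.age_mean) / cp.age_sd
        + oc.get("glucose", 0.0) * (glucose - cp.glucose_mean) / cp.glucose_sd
        + oc.get("hb", 0.0) * (hb - cp.hb_mean) / cp.hb_sd
        + oc.get("marshall", 0.0) * (marshall - 2.0)
        + oc.get("tsah", 0.0) * tsah
        + oc.get("edh", 0.0) * edh
        + oc.get("hypoxia", 0.0) * hypoxia
        + oc.get("hypotension", 0.0) * hypotension
    )
    cut = np.asarray(config.gose_cutpoints)

    def _draw_gose(shift: float, extra_sd: float) -> np.ndarray:
        u = -lp_bad + shift + rng.logistic(size=n)
        if extra_sd > 0:
            u = u + extra_sd * rng.standard_normal(n)
        return 1 + np.searchsorted(cut, u, side="left").astype(float)

    data["gose_3mo"] = _draw_gose(-config.recovery_drift, config.gose_aux_noise_sd)
    data["gose_6mo"] = _draw_gose(0.0, 0.0)
    data["gose_12mo"] = _draw_gose(config.recovery_drift, config.gose_aux_noise_sd)
    data["_severity"] = severity

    cohort = pd.DataFrame(data)

    if not return_truth:
        return cohort
    truth = pd.DataFrame({
        "patient_id": np.arange(n, dtype=float),
        "severity": severity,
        "neuroworsening": neuroworsening.astype(float),
    })
    for t, tp in enumerate(TIMEPOINTS):
        truth[f"true_neuro_{tp}"] = true_neuro[:, t]
    for col in all_assessment_columns() + list(COVARIATES) + list(GOSE_COLS):
        truth[col] = cohort[col].to_numpy()
    return cohort, truth


def apply_untestability(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Draw intubation/sedation flags and mask the affected components.

    Intubation masks the verbal component; deep sedation/paralysis
    masks the motor component.  Both probabilities are non-decreasing in
    latent severity and drawn independently at each time point.  Masked
    cells stay distinguishable from not-recorded cells through the flag
    columns (flag set and value absent = untestable).
    """
    config.validate()
    out = cohort.copy()
    rng = _rng(config, 2)
    if "_severity" not in out.columns:
        raise DataError("cohort lacks the _severity column produced by generate_cohort")
    sev = out["_severity"].to_numpy(float)
    n = len(out)
    p_int = expit(config.p_intubated.intercept + config.p_intubated.slope * sev)
    p_sed = expit(config.p_sedated.intercept + config.p_sedated.slope * sev)
    for tp in TIMEPOINTS:
        recorded = out[f"eye_{tp}"].notna().to_numpy() | out[f"verbal_{tp}"].notna().to_numpy() \
            | out[f"motor_{tp}"].notna().to_numpy() | out[f"pupils_{tp}"].notna().to_numpy()
        intubated = (rng.random(n) < p_int).astype(float)
        sedated = (rng.random(n) < p_sed).astype(float)
        intubated[~recorded] = np.nan
        sedated[~recorded] = np.nan
        out[f"intubated_{tp}"] = intubated
        out[f"sedated_{tp}"] = sedated
        out.loc[intubated == 1, f"verbal_{tp}"] = np.nan
        out.loc[sedated == 1, f"motor_{tp}"] = np.nan
    return out


def apply_missingness(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """MAR masking of assessment cells and covariates.

    An assessment is documented or not as a whole: one draw per patient
    and time point masks all four cells together (the marginal per-cell
    missingness still equals ``missing_prob_by_timepoint``), which is
    how registry capture behaves.  The probability depends only on the
    time point (and the MNAR sensitivity shift when enabled);
    covariates use their configured per-variable probabilities.  The
    stratum, transfer flag, untestability flags and age are never
    masked.
    """
    config.validate()
    out = cohort.copy()
    rng = _rng(config, 3)
    n = len(out)
    sev = out["_severity"].to_numpy(float) if "_severity" in out.columns else np.zeros(n)
    for t, tp in enumerate(TIMEPOINTS):
        p = config.missing_prob_by_timepoint[t]
        if config.mnar_severity_shift != 0.0 and 0.0 < p < 1.0:
            p_vec = expit(logit(p) + config.mnar_severity_shift * sev)
        else:
            p_vec = np.full(n, p)
        mask = rng.random(n) < p_vec
        for comp in ("eye", "verbal", "motor", "pupils"):
            out.loc[mask, f"{comp}_{tp}"] = np.nan
    for col, p in config.covariate_missing_probs.items():
        mask = rng.random(n) < p
        out.loc[mask, col] = np.nan
    return out


def simulate_cohort(config: CohortConfig):
    """Full generation pipeline; returns ``(cohort, truth)``.

    The returned cohort no longer carries the private latent column.
    """
    full, truth = generate_cohort(config, return_truth=True)
    masked = apply_missingness(apply_untestability(full, config), config)
    return masked.drop(columns=["_severity"]), truth


# ----------------------------------------------------------------------
# CSV round-trip.  Missing cells are written empty; untestable verbal /
# motor cells are written as the sentinel "UT".

def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.drop(columns=["_severity"], errors="ignore").copy()
    for tp in TIMEPOINTS:
        icol, scol = f"intubated_{tp}", f"sedated_{tp}"
        if icol in out.columns:
            ut_v = (out[icol] == 1) & out[f"verbal_{tp}"].isna()
            out[f"verbal_{tp}"] = out[f"verbal_{tp}"].astype(object)
            out.loc[ut_v, f"verbal_{tp}"] = "UT"
        if scol in out.columns:
            ut_m = (out[scol] == 1) & out[f"motor_{tp}"].isna()
            out[f"motor_{tp}"] = out[f"motor_{tp}"].astype(object)
            out.loc[ut_m, f"motor_{tp}"] = "UT"
    out.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stratum": str})
    for col in df.columns:
        if col in ("stratum",):
            continue
        if df[col].dtype == object:
            df[col] = df[col].replace("UT", np.nan)
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, float_format="%.6g")
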