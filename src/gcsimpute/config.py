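"""Configuration for the synthetic TBI cohort generator.

The generator emulates the structure of a multi-centre TBI registry in
which Glasgow Coma Scale (GCS) components and pupil reactivity are
recorded at up to four time points between injury and emergency-
department (ED) discharge, with untestable components (intubation,
sedation/paralysis), secondary transfers, an ED / hospital-admission /
ICU-admission stratification, IMPACT-style baseline covariates and an
ordinal 8-category GOSE outcome at 3, 6 and 12 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .errors import ConfigError

#: Canonical time-point keys, in chronological order.
TIMEPOINTS = ("preh", "ref_arr", "study_arr", "ed_disch")

#: Human-readable names used in reports.
TIMEPOINT_LABELS = {
    "preh": "pre-hospital",
    "ref_arr": "referring ED arrival",
    "study_arr": "study ED arrival",
    "ed_disch": "ED discharge",
}

STRATA = ("ed", "hosp", "icu")

#: Baseline covariates that may carry missing values.
COVARIATES = ("age", "glucose", "hb", "marshall", "tsah", "edh", "hypoxia", "hypotension")

GOSE_COLS = ("gose_3mo", "gose_6mo", "gose_12mo")


@dataclass(frozen=True)
class MonotoneLink:
    """Logistic link p(severity) = expit(intercept + slope * severity).

    ``slope >= 0`` guarantees the probability is non-decreasing in
    severity, which is the clinical expectation for intubation and
    sedation after more severe injury.
    """

    intercept: float
    slope: float

    def validate(self, name: str) -> None:
        if self.slope < 0:
            raise ConfigError(name, f"slope must be >= 0, got {self.slope}")


@dataclass(frozen=True)
class CovariateParams:
    """Marginals and severity-loadings for the baseline covariates.

    Continuous covariates are ``mean + loading * severity + N(0, sd)``;
    binary covariates are Bernoulli with a logistic link in severity;
    the Marshall CT class is a 6-category threshold of
    ``severity + N(0, marshall_noise_sd)``.
    """

    age_mean: float = 45.0
    age_sd: float = 20.0
    age_loading: float = 0.0
    age_min: float = 16.0
    age_max: float = 95.0
    glucose_mean: float = 7.5       # mmol/L
    glucose_sd: float = 2.5
    glucose_loading: float = 0.8
    hb_mean: float = 13.5           # g/dL
    hb_sd: float = 1.8
    hb_loading: float = -0.5
    marshall_noise_sd: float = 0.8
    marshall_cuts: tuple[float, ...] = (-0.8, 0.0, 0.6, 1.2, 1.8)
    tsah_link: MonotoneLink = MonotoneLink(-0.8, 0.9)
    edh_link: MonotoneLink = MonotoneLink(-2.2, 0.3)
    hypoxia_link: MonotoneLink = MonotoneLink(-2.0, 0.8)
    hypotension_link: MonotoneLink = MonotoneLink(-2.3, 0.9)

    def validate(self) -> None:
        for nm in ("age_sd", "glucose_sd", "hb_sd", "marshall_noise_sd"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"covariate_params.{nm}", "SD must be >= 0")
        if list(self.marshall_cuts) != sorted(self.marshall_cuts):
            raise ConfigError("covariate_params.marshall_cuts", "cuts must be increasing")
        for nm in ("tsah_link", "edh_link", "hypoxia_link", "hypotension_link"):
            getattr(self, nm).validate(f"covariate_params.{nm}")


def _default_outcome_coefficients() -> dict[str, float]:
    # Log-odds weights on the "bad outcome" linear predictor of the
    # GOSE-generating proportional-odds model.  Signs follow prognostic
    # convention: severity, age, glucose, Marshall, tSAH, hypoxia and
    # hypotension worsen outcome; haemoglobin and (operable) EDH are
    # protective.  Continuous covariates enter standardised.
    return {
        "severity": 1.6,
        "age": 0.5,
        "glucose": 0.15,
        "hb": -0.15,
        "marshall": 0.2,
        "tsah": 0.3,
        "edh": -0.2,
        "hypoxia": 0.3,
        "hypotension": 0.4,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of one synthetic cohort.

    Identical config + seed produces a bit-identical cohort at every
    generation stage.
    """

    n_patients: int = 2000
    seed: int = 0
    p_transfer: float = 0.30
    # Stratum mixture (must sum to 1): ED-only, hospital admission, ICU.
    p_ed: float = 0.25
    p_hosp: float = 0.275
    p_icu: float = 0.475
    #: Assessment noise SD on the latent neuro scale, one per time point.
    #: Pre-hospital assessments are the least reliable.
    noise_sd_by_timepoint: tuple[float, float, float, float] = (1.0, 0.6, 0.5, 0.4)
    #: Mean improvement in the latent neuro state per successive time
    #: point (resuscitation effect).
    resuscitation_drift: float = 0.15
    #: Probability an assessment cell is not recorded, per time point.
    #: Documentation quality improves along the care pathway, so the
    #: probabilities decrease from pre-hospital to ED discharge.
    missing_prob_by_timepoint: tuple[float, float, float, float] = (0.35, 0.12, 0.08, 0.05)
    #: Per-covariate / per-outcome not-recorded probabilities (age never
    #: missing by contract).
    covariate_missing_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "glucose": 0.15,
            "hb": 0.12,
            "marshall": 0.08,
            "tsah": 0.08,
            "edh": 0.08,
            "hypoxia": 0.30,
            "hypotension": 0.30,
            "gose_3mo": 0.30,
            "gose_6mo": 0.15,
            "gose_12mo": 0.35,
        }
    )
    p_intubated: MonotoneLink = MonotoneLink(-2.2, 1.5)
    p_sedated: MonotoneLink = MonotoneLink(-2.5, 1.4)
    outcome_coefficients: Mapping[str, float] = field(default_factory=_default_outcome_coefficients)
    #: Cutpoints of the GOSE proportional-odds model (7 thresholds for 8
    #: categories, on the latent logistic scale).
    gose_cutpoints: tuple[float, ...] = (-3.2, -2.4, -1.6, -0.6, 0.4, 1.4, 2.6)
    #: Shift of the 3-month (earlier, worse) and 12-month (later,
    #: recovered) GOSE linear predictors relative to 6 months.
    recovery_drift: float = 0.3
    #: Extra latent noise SD for the 3/12-month GOSE copies.
    gose_aux_noise_sd: float = 0.5
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    #: Stratum noise when assigning ED/hosp/ICU from severity; larger
    #: values decouple stratum from severity.
    stratum_noise_sd: float = 0.8
    #: MNAR sensitivity switch: when non-zero, assessment missingness
    #: logit additionally shifts by ``mnar_severity_shift * severity``
    #: (defaults off so the mechanism is MAR by construction).
    mnar_severity_shift: float = 0.0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients", "must be a positive count")
        mix = self.p_ed + self.p_hosp + self.p_icu
        if abs(mix - 1.0) > 1e-12:
            raise ConfigError("p_ed/p_hosp/p_icu", f"stratum mixture sums to {mix!r}, not 1")
        for nm in ("p_transfer", "p_ed", "p_hosp", "p_icu"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(nm, f"probability {v} outside [0, 1]")
        if len(self.noise_sd_by_timepoint) != 4:
            raise ConfigError("noise_sd_by_timepoint", "needs exactly four values")
        if any(s < 0 for s in self.noise_sd_by_timepoint):
            raise ConfigError("noise_sd_by_timepoint", "SDs must be >= 0")
        if len(self.missing_prob_by_timepoint) != 4:
            raise ConfigError("missing_prob_by_timepoint", "needs exactly four values")
        if any(not 0.0 <= p <= 1.0 for p in self.missing_prob_by_timepoint):
            raise ConfigError("missing_prob_by_timepoint", "probabilities must be in [0, 1]")
        for k, p in self.covariate_missing_probs.items():
            if k == "age":
                raise ConfigError("covariate_missing_probs.age", "age is complete by contract")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_missing_probs.{k}", f"probability {p} outside [0, 1]")
        self.p_intubated.validate("p_intubated")
        self.p_sedated.validate("p_sedated")
        if list(self.gose_cutpoints) != sorted(self.gose_cutpoints) or len(self.gose_cutpoints) != 7:
            raise ConfigError("gose_cutpoints", "need 7 increasing thresholds")
        if self.gose_aux_noise_sd < 0:
            raise ConfigError("gose_aux_noise_sd", "SD must be >= 0")
        if self.stratum_noise_sd < 0:
            raise ConfigError("stratum_noise_sd", "SD must be >= 0")
        self.covariate_params.validate()

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "covariate_params" in d and isinstance(d["covariate_params"], Mapping):
            cp = dict(d["covariate_params"])
            for nm in ("tsah_link", "edh_link", "hypoxia_link", "hypotension_link"):
                if nm in cp and isinstance(cp[nm], Mapping):
                    cp[nm] = MonotoneLink(**cp[nm])
            if "marshall_cuts" in cp:
                cp["marshall_cuts"] = tuple(cp["marshall_cuts"])
            d["covariate_params"] = CovariateParams(**cp)
        for nm in ("p_intubated", "p_sedated"):
            if nm in d and isinstance(d[nm], Mapping):
                d[nm] = MonotoneLink(**d[nm])
        for nm in ("noise_sd_by_timepoint", "missing_prob_by_timepoint", "gose_cutpoints"):
            if nm in d:
                d[nm] = tuple(d[nm])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def assessment_columns(tp: str) -> list[str]:
    """Column names holding one time point's recorded assessment."""
    return [f"eye_{tp}", f"verbal_{tp}", f"motor_{tp}", f"pupils_{tp}"]


def all_assessment_columns() -> list[str]:
    cols: list[str] = []
    for tp in TIMEPOINTS:
        cols.extend(assessment_columns(tp))
    return cols
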