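"""Derived baseline GCS / GCS-motor / pupil scores by substitution.

A TBI patient may have neurological assessments at up to four time
points (pre-hospital, referring-ED arrival for secondary transfers,
study-ED arrival, ED discharge).  A *substitution strategy* picks one
of them as the patient's baseline:

IMPACT   ED discharge, then backwards in time
         (ed_disch -> study_arr -> ref_arr -> preh)
TARN     first ED contact, then forwards
         (ref_arr -> study_arr -> preh)
ERASMUS  study-hospital arrival, then backwards
         (study_arr -> ref_arr -> preh)
BEST     best neurology over all time points (highest GCS / GCSm,
         fewest unreactive pupils)
WORST    worst neurology over all time points

A *sub-score policy* decides what to do when the verbal (intubated) or
motor (sedated / paralysed) component is unavailable: either the sum is
not calculable (NC) or the missing component is substituted with 1.
Untestable and simply not-recorded components are pooled for policy
purposes.  The policy is applied per time point before the strategy's
fallback runs, so a not-calculable time point is skipped rather than
terminating the search.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import TIMEPOINTS
from .errors import ConfigError, DataError

# Sub-score policies for the GCS sum
SUM_POLICIES = ("nc_if_either", "nc_if_m_v1", "nc_if_v_m1", "both_1")
# Sub-score policies for the motor score
MOTOR_POLICIES = ("nc_if_m", "m_1")

STRATEGIES = ("best", "worst", "impact", "tarn", "erasmus")

#: Fallback orders for the sequential strategies (missing / NC time
#: points are skipped).  BEST / WORST take an extremum instead.
FALLBACK_ORDERS = {
    "impact": ("ed_disch", "study_arr", "ref_arr", "preh"),
    "tarn": ("ref_arr", "study_arr", "preh"),
    "erasmus": ("study_arr", "ref_arr", "preh"),
}

_COMPONENT_RANGES = {"eye": (1, 4), "verbal": (1, 5), "motor": (1, 6), "pupils": (0, 2)}


def _check_range(values: np.ndarray, name: str) -> None:
    lo, hi = _COMPONENT_RANGES[name]
    v = values[~np.isnan(values)]
    if v.size and ((v < lo) | (v > hi)).any():
        raise DataError(f"{name} component outside [{lo}, {hi}]")


def gcs_sum_at_timepoint(eye, verbal, motor, policy: str):
    """GCS sum (3-15) for one assessment under a sub-score policy.

    Absent and untestable verbal/motor are treated alike.  An absent
    eye component always renders the sum not calculable (NaN).
    Substituted components contribute exactly 1.
    """
    if policy not in SUM_POLICIES:
        raise ConfigError("policy", f"unknown sum policy {policy!r}")
    e = np.asarray(eye, dtype=float)
    v = np.asarray(verbal, dtype=float)
    m = np.asarray(motor, dtype=float)
    _check_range(e, "eye")
    _check_range(v, "verbal")
    _check_range(m, "motor")
    v_miss, m_miss = np.isnan(v), np.isnan(m)
    if policy == "nc_if_either":
        nc = v_miss | m_miss
    elif policy == "nc_if_m_v1":
        nc = m_miss
    elif policy == "nc_if_v_m1":
        nc = v_miss
    else:  # both_1
        nc = np.zeros_like(v_miss)
    total = e + np.where(v_miss, 1.0, v) + np.where(m_miss, 1.0, m)
    total = np.where(nc | np.isnan(e), np.nan, total)
    if total.ndim == 0:
        return float(total)
    return total


def gcs_motor_at_timepoint(motor, policy: str):
    """GCS motor score (1-6) under a motor sub-score policy."""
    if policy not in MOTOR_POLICIES:
        raise ConfigError("policy", f"unknown motor policy {policy!r}")
    m = np.asarray(motor, dtype=float)
    _check_range(m, "motor")
    if policy == "m_1":
        m = np.where(np.isnan(m), 1.0, m)
    if m.ndim == 0:
        return float(m)
    return m


def timepoint_values(cohort: pd.DataFrame, variable: str, policy: str | None) -> pd.DataFrame:
    """Per-time-point derived values for one variable.

    ``variable`` is one of ``gcs`` (sum), ``gcsm`` (motor), ``pupils``.
    Returns a frame with one column per time point, NaN where the value
    is missing or not calculable under the policy.
    """
    out = {}
    for tp in TIMEPOINTS:
        if variable == "gcs":
            out[tp] = gcs_sum_at_timepoint(
                cohort[f"eye_{tp}"], cohort[f"verbal_{tp}"], cohort[f"motor_{tp}"],
                policy or "nc_if_either")
        elif variable == "gcsm":
            out[tp] = gcs_motor_at_timepoint(cohort[f"motor_{tp}"], policy or "nc_if_m")
        elif variable == "pupils":
            p = cohort[f"pupils_{tp}"].to_numpy(dtype=float)
            _check_range(p, "pupils")
            out[tp] = p
        else:
            raise ConfigError("variable", f"unknown variable {variable!r}")
    return pd.DataFrame(out, index=cohort.index)


def derive_baseline(
    cohort: pd.DataFrame,
    variable: str,
    strategy: str,
    policy: str | None = None,
) -> pd.DataFrame:
    """Derive one baseline variable for every patient.

    Returns a frame with columns ``value`` and ``source`` (the time
    point actually used, ``None`` iff the value is missing).  For BEST
    and WORST, ties are broken toward the later time point.
    """
    strategy = strategy.lower()
    if strategy not in STRATEGIES:
        raise ConfigError("strategy", f"unknown strategy {strategy!r}")
    tv = timepoint_values(cohort, variable, policy)
    vals = tv.to_numpy(dtype=float)  # (n, 4) in chronological order

    n = vals.shape[0]
    value = np.full(n, np.nan)
    src_idx = np.full(n, -1)

    if strategy in FALLBACK_ORDERS:
        order = [TIMEPOINTS.index(tp) for tp in FALLBACK_ORDERS[strategy]]
        for j in order:
            take = (src_idx == -1) & ~np.isnan(vals[:, j])
            value[take] = vals[take, j]
            src_idx[take] = j
    else:
        best = strategy == "best"
        # pupils are coded as the number of *unreactive* pupils, so the
        # best neurology is the minimum
        take_max = best if variable in ("gcs", "gcsm") else not best
        fill = -np.inf if take_max else np.inf
        filled = np.where(np.isnan(vals), fill, vals)
        any_obs = ~np.isnan(vals).all(axis=1)
        ext = filled.max(axis=1) if take_max else filled.min(axis=1)
        # latest time point achieving the extremum
        hit = filled == ext[:, None]
        src = 3 - np.argmax(hit[:, ::-1], axis=1)
        value[any_obs] = ext[any_obs]
        src_idx[any_obs] = src[any_obs]

    source = pd.Series(
        [TIMEPOINTS[i] if i >= 0 else None for i in src_idx],
        index=cohort.index, dtype=object)
    return pd.DataFrame({"value": value, "source": source}, index=cohort.index)


def derive(record: pd.Series, strategy: str, policy: str | None, variable: str):
    """Single-patient convenience wrapper; returns ``(value, source)``."""
    res = derive_baseline(record.to_frame().T, variable, strategy, policy)
    v = res["value"].iloc[0]
    return (float(v) if not np.isnan(v) else np.nan), res["source"].iloc[0]


def add_derived_columns(
    cohort: pd.DataFrame,
    strategies: Sequence[str] = STRATEGIES,
    sum_policy: str = "nc_if_either",
    motor_policy: str = "nc_if_m",
) -> pd.DataFrame:
    """Append derived baseline columns (``gcs_<strategy>`` etc.) plus
    ``*_src`` source-time-point columns."""
    out = cohort.copy()
    for strat in strategies:
        for var, pol in (("gcs", sum_policy), ("gcsm", motor_policy), ("pupils", None)):
            d = derive_baseline(cohort, var, strat, pol)
            out[f"{var}_{strat}"] = d["value"]
            out[f"{var}_{strat}_src"] = d["source"]
    return out


def missingness_table(
    cohort: pd.DataFrame,
    strategies: Sequence[str] = ("best", "worst", "impact", "tarn", "erasmus"),
    sum_policies: Sequence[str] = SUM_POLICIES,
    motor_policies: Sequence[str] = MOTOR_POLICIES,
) -> pd.DataFrame:
    """Percent of patients with a missing derived value, per strategy x
    sub-score policy x variable (layout of a strategy-comparison table:
    rows = (variable, policy), columns = strategies, values = percent
    missing to two decimals)."""
    if len(cohort) == 0:
        raise DataError("empty cohort")
    n = len(cohort)
    rows = []
    index = []
    specs = [("gcs", p) for p in sum_policies] + [("gcsm", p) for p in motor_policies] \
        + [("pupils", "missing_pupils")]
    for var, pol in specs:
        row = {}
        for strat in strategies:
            d = derive_baseline(cohort, var, strat, None if var == "pupils" else pol)
            row[strat] = round(100.0 * float(d["value"].isna().sum()) / n, 2)
        rows.append(row)
        index.append((var, pol))
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["variable", "policy"]))


def strategy_correlations(
    cohort: pd.DataFrame,
    strategies: Sequence[str] = STRATEGIES,
    sum_policy: str = "nc_if_either",
    motor_policy: str = "nc_if_m",
    min_joint: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations among all derived
    baseline variants (GCS sum, motor and pupils under every strategy).

    Cells with fewer than ``min_joint`` jointly observed rows are NaN
    (flagged unavailable); the diagonal is exactly 1.
    """
    cols = {}
    for strat in strategies:
        cols[f"gcs_{strat}"] = derive_baseline(cohort, "gcs", strat, sum_policy)["value"]
        cols[f"gcsm_{strat}"] = derive_baseline(cohort, "gcsm", strat, motor_policy)["value"]
        cols[f"pupils_{strat}"] = derive_baseline(cohort, "pupils", strat, None)["value"]
    df = pd.DataFrame(cols)
    corr = df.corr(method="spearman", min_periods=min_joint)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def source_distribution(
    cohort: pd.DataFrame, strategy: str, policy: str | None = "nc_if_either",
    variable: str = "gcs",
) -> pd.Series:
    """Fraction of non-missing derived values drawn from each time
    point (sums to 1 over patients with a derived value)."""
    d = derive_baseline(cohort, variable, strategy, policy)
    src = d["source"].dropna()
    counts = src.value_counts()
    total = float(counts.sum())
    return pd.Series(
        [counts.get(tp, 0) / total if total else np.nan for tp in TIMEPOINTS],
        index=list(TIMEPOINTS), name=f"{variable}_{strategy}")


def severity_bands(gcs_values: Iterable[float]) -> pd.Series:
    """Counts of derived GCS sums in the conventional mild (13-15),
    moderate (9-12) and severe (3-8) bands; NaNs are excluded."""
    v = np.asarray(list(gcs_values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size and ((v < 3) | (v > 15)).any():
        raise DataError("GCS sum outside [3, 15]")
    return pd.Series({
        "mild": int(((v >= 13) & (v <= 15)).sum()),
        "moderate": int(((v >= 9) & (v <= 12)).sum()),
        "severe": int(((v >= 3) & (v <= 8)).sum()),
    })
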