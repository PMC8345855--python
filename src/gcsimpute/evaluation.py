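"""Orchestration of the two strategy-comparison experiments.

*Substitution experiment* — impute covariates and outcomes once by
chained equations, delete patients with no GOSE at any follow-up, then
derive baseline GCS / GCSm / pupils under every requested substitution
strategy and sub-score policy and compare outcome-model pseudo-R²
across the M completed datasets.  Residual missingness in a derived
candidate is handled by per-model complete-case deletion; the single
set of completed covariate datasets is shared across all strategy
cells so cells stay comparable.

*Time-point experiment* — additionally impute the per-time-point GCS
sum / motor / pupil scores themselves, collapse the two arrival
assessments into a single presenting-ED time point, and compare model
performance across pre-hospital, presenting-ED-arrival and
ED-discharge assessments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import baseline
from .errors import DataError
from .mice import (
    CompletedDatasetSet,
    ImputationConfig,
    combine_presenting_ed,
    default_covariate_specs,
    default_fill,
    drop_no_outcome,
    impute_timepoint_assessments,
    mice,
)
from .models import ModelSpec, R2Distribution, per_imputation_r2

#: time points compared in the fully imputed experiment (the two
#: arrival assessments are combined into "presenting")
EVAL_TIMEPOINTS = ("preh", "presenting", "ed_disch")

_SUMMARY_KEYS = ("mean", "median", "q25", "q75", "min", "max", "n", "n_nonconverged")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one evaluation run."""

    m: int = 20
    iterations: int = 5
    seed: int = 0
    families: tuple[str, ...] = ("logistic", "propodds")
    strata: tuple[str, ...] = ("all", "icu")
    # substitution experiment axes
    gcs_variables: tuple[str, ...] = ("gcs",)
    gcs_strategies: tuple[str, ...] = baseline.STRATEGIES
    sum_policies: tuple[str, ...] = ("both_1",)
    motor_policies: tuple[str, ...] = ("m_1",)
    pupil_strategies: tuple[str, ...] = baseline.STRATEGIES
    # policies used when forming the observed per-time-point scores in
    # the fully imputed experiment
    timepoint_sum_policy: str = "nc_if_either"
    timepoint_motor_policy: str = "nc_if_m"
    timepoints: tuple[str, ...] = EVAL_TIMEPOINTS

    def imputation_config(self) -> ImputationConfig:
        return ImputationConfig(m=self.m, iterations=self.iterations, seed=self.seed)


@dataclass
class R2Grid:
    """Distribution of per-imputation pseudo-R² indexed by grid axes."""

    frame: pd.DataFrame  # one row per cell; axis columns + summary + values
    axes: tuple[str, ...]
    experiment: str

    def cell_values(self, **axis_values) -> np.ndarray:
        sel = self.frame
        for k, v in axis_values.items():
            sel = sel[sel[k] == v]
        if len(sel) != 1:
            raise KeyError(f"{axis_values} selects {len(sel)} cells")
        return np.asarray(sel.iloc[0]["r2_values"])

    def mean_by(self, *group_axes: str) -> pd.Series:
        return self.frame.groupby(list(group_axes))["mean"].mean()

    def to_csv_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["r2_values"] = out["r2_values"].map(
            lambda v: ";".join(f"{x:.10g}" for x in v))
        return out


def _grid_rows(cells: list[dict], axes: Sequence[str], experiment: str) -> R2Grid:
    if not cells:
        raise DataError(f"experiment {experiment!r} produced an empty grid")
    return R2Grid(pd.DataFrame(cells), tuple(axes), experiment)


def _cell(dist: R2Distribution, **axis_values) -> dict:
    row = dict(axis_values)
    row.update(dist.summary())
    row["r2_values"] = dist.values
    return row


# ----------------------------------------------------------------------

def run_substitution_experiment(cohort: pd.DataFrame, config: RunConfig) -> R2Grid:
    """R² grid over substitution strategies and sub-score policies."""
    filled = default_fill(cohort)
    dsset = mice(filled, default_covariate_specs(), config.imputation_config())
    dsset = drop_no_outcome(dsset)
    kept = dsset.datasets[0].index

    # derived candidates, computed once on the original (pre-imputation)
    # assessment columns
    derived: dict[str, pd.Series] = {}
    axes_list: list[tuple[str, str, str]] = []  # (variable, strategy, policy)
    for var in config.gcs_variables:
        pols = config.sum_policies if var == "gcs" else config.motor_policies
        for strat in config.gcs_strategies:
            for pol in pols:
                col = f"{var}_{strat}_{pol}"
                derived[col] = baseline.derive_baseline(cohort, var, strat, pol)["value"]
                axes_list.append((var, strat, pol))
    for pstrat in config.pupil_strategies:
        derived[f"pupils_{pstrat}"] = baseline.derive_baseline(cohort, "pupils", pstrat, None)["value"]

    derived_df = pd.DataFrame(derived).loc[kept]
    datasets = [pd.concat([ds, derived_df], axis=1) for ds in dsset.datasets]

    cells = []
    for var, strat, pol in axes_list:
        gcs_col = f"{var}_{strat}_{pol}"
        for pstrat in config.pupil_strategies:
            for family in config.families:
                for stratum in config.strata:
                    spec = ModelSpec(family=family, gcs_col=gcs_col,
                                     pupil_col=f"pupils_{pstrat}", stratum=stratum)
                    dist = per_imputation_r2(datasets, spec)
                    cells.append(_cell(
                        dist, gcs_variable=var, gcs_strategy=strat, policy=pol,
                        pupil_strategy=pstrat, family=family, stratum=stratum))
    axes = ("gcs_variable", "gcs_strategy", "policy", "pupil_strategy", "family", "stratum")
    return _grid_rows(cells, axes, "substitution")


def run_timepoint_experiment(cohort: pd.DataFrame, config: RunConfig) -> R2Grid:
    """R² grid over fully imputed assessment time points."""
    dsset = impute_timepoint_assessments(
        cohort, config.imputation_config(),
        sum_policy=config.timepoint_sum_policy,
        motor_policy=config.timepoint_motor_policy)
    dsset = drop_no_outcome(dsset)
    datasets = [combine_presenting_ed(ds) for ds in dsset.datasets]

    cells = []
    for tp in config.timepoints:
        for var, col in (("gcs", f"gcs_sum_{tp}"), ("gcsm", f"gcs_motor_{tp}")):
            for family in config.families:
                for stratum in config.strata:
                    spec = ModelSpec(family=family, gcs_col=col,
                                     pupil_col=f"pupils_agg_{tp}", stratum=stratum)
                    dist = per_imputation_r2(datasets, spec)
                    cells.append(_cell(
                        dist, timepoint=tp, gcs_variable=var, family=family,
                        stratum=stratum))
    return _grid_rows(cells, ("timepoint", "gcs_variable", "family", "stratum"), "timepoint")


# ----------------------------------------------------------------------
# Report bundle

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _boxplot(grid: R2Grid, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = grid.frame
    combos = frame[["family", "stratum"]].drop_duplicates().itertuples(index=False)
    combos = list(combos)
    fig, axs = plt.subplots(len(combos), 1, figsize=(10, 3.2 * len(combos)), squeeze=False)
    label_axes = [a for a in grid.axes if a not in ("family", "stratum")]
    for ax, (family, stratum) in zip(axs.ravel(), combos):
        sub = frame[(frame["family"] == family) & (frame["stratum"] == stratum)]
        data = list(sub["r2_values"])
        labels = ["/".join(str(r[a]) for a in label_axes) for _, r in sub.iterrows()]
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("McFadden pseudo-$R^2$")
        ax.set_title(f"{grid.experiment}: {family}, {stratum} strata")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(
    grids: Mapping[str, R2Grid],
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    make_figures: bool = True,
) -> dict:
    """Write the report bundle: CSV tables, one box-whisker figure per
    R² grid, and a JSON index listing every emitted file with its
    SHA-256.  Every figure is regenerable from the CSVs alone."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, grid in grids.items():
        if len(grid.frame) == 0:
            raise DataError(f"experiment {name!r} produced an empty grid")
        p = out / f"{name}_r2.csv"
        grid.to_csv_frame().to_csv(p, index=False, float_format="%.10g")
        written.append(p)
        if make_figures:
            _boxplot(grid, out / f"{name}_r2.png")
    for name, table in tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, float_format="%.10g")
        written.append(p)
    index = {
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True) + "\n")
    return index


def standard_tables(cohort: pd.DataFrame, config: RunConfig) -> dict[str, pd.DataFrame]:
    """The descriptive tables accompanying an evaluation run: percent
    missing per strategy x policy, pairwise Spearman correlations of
    the derived variants, and source-time-point distributions."""
    tables = {
        "missingness": baseline.missingness_table(cohort),
        "spearman": baseline.strategy_correlations(cohort),
    }
    src = {}
    for strat in config.gcs_strategies:
        src[strat] = baseline.source_distribution(cohort, strat, "nc_if_either", "gcs")
    tables["source_distribution"] = pd.DataFrame(src).T
    return tables
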