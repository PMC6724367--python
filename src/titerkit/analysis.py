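"""Condition-level titer analyses.

Operates on per-ovariole record tables (CSV schema: ``ovariole,
acquisition_order, condition, gsc_single, gsc_cluster_total,
gsc_cluster_cells, stage4, stage10``; blank = missing) and produces
per-stage condition summaries (medians, percent-of-control, decision-tree
tests), per-cell titers within GSC clusters, cross-stage regressions, and
acquisition-order drift checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import stats as _stats
from .errors import SchemaError

STAGE_COLUMNS = ("gsc_single", "stage4", "stage10")
STAGE_PAIRS = (
    ("gsc_single", "stage4"),
    ("stage4", "stage10"),
    ("gsc_single", "stage10"),
)


@dataclass
class StageSummary:
    stage: str
    n: int
    median: float
    percent_of_control: float | None = None
    test_vs_control: _stats.TestResult | None = None


@dataclass
class ConditionSummary:
    """Per-stage summaries for one condition, relative to a control."""

    condition: str
    is_control: bool
    stages: dict[str, StageSummary] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _stage_values(df: pd.DataFrame, condition: str, stage: str) -> np.ndarray:
    vals = df.loc[df["condition"] == condition, stage].dropna().to_numpy(float)
    return vals


def summarize_condition(
    records: pd.DataFrame,
    control: str | None = "un-enriched",
    stages=STAGE_COLUMNS,
    diag_alpha: float = 0.05,
    seed: int | None = None,
) -> dict[str, ConditionSummary]:
    """Medians, percent-of-control and tests per condition and stage.

    Percent-of-control is 100 * median(treatment) / median(control), using
    medians (titer distributions are skewed).  When the control label is
    absent, summaries are still produced but flagged and carry no percent or
    test.
    """
    if "condition" not in records.columns:
        raise SchemaError("records need a 'condition' column")
    conditions = list(dict.fromkeys(records["condition"]))
    have_control = control is not None and control in conditions
    out: dict[str, ConditionSummary] = {}
    for cond in conditions:
        summary = ConditionSummary(cond, is_control=(cond == control))
        if not have_control:
            summary.flags.append("no-control")
        for stage in stages:
            if stage not in records.columns:
                continue
            vals = _stage_values(records, cond, stage)
            if vals.size == 0:
                continue
            st = StageSummary(stage=stage, n=int(vals.size),
                              median=float(np.median(vals)))
            if have_control and cond != control:
                ctrl = _stage_values(records, control, stage)
                if ctrl.size:
                    st.percent_of_control = 100.0 * st.median / float(np.median(ctrl))
                    if vals.size >= 3 and ctrl.size >= 3:
                        st.test_vs_control = _stats.compare_two_groups(
                            vals, ctrl, diag_alpha=diag_alpha, seed=seed
                        )
            summary.stages[stage] = st
        out[cond] = summary
    return out


def per_cell_cluster_titer(cluster_total, n_cells):
    """Average titer per cell within a GSC cluster (total / cell count)."""
    total = np.asarray(cluster_total, dtype=float)
    cells = np.asarray(n_cells, dtype=float)
    if np.any(cells == 0):
        raise ValueError("n_cells must be >= 1")
    out = total / cells
    return float(out) if out.ndim == 0 else out


def cluster_per_cell_median(records: pd.DataFrame) -> float:
    """Median of per-ovariole cluster per-cell titers."""
    sub = records.dropna(subset=["gsc_cluster_total", "gsc_cluster_cells"])
    per_cell = per_cell_cluster_titer(
        sub["gsc_cluster_total"].to_numpy(float),
        sub["gsc_cluster_cells"].to_numpy(float),
    )
    return float(np.median(per_cell))


@dataclass
class StagePairRegression:
    predictor: str
    response: str
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    n: int = 0
    error: str | None = None


def cross_stage_regression(records: pd.DataFrame) -> dict[tuple[str, str], StagePairRegression]:
    """OLS of later-stage titer on earlier-stage titer, per stage pair.

    Low R-squared across pairs indicates each egg chamber is an independent
    colonization event rather than an ovariole-wide titer trend.  A
    zero-variance predictor yields a per-pair error; other pairs still fit.
    """
    out = {}
    for earlier, later in STAGE_PAIRS:
        reg = StagePairRegression(predictor=earlier, response=later)
        sub = records.dropna(subset=[earlier, later])
        x = sub[earlier].to_numpy(float)
        y = sub[later].to_numpy(float)
        reg.n = int(x.size)
        if x.size < 3:
            reg.error = f"only {x.size} complete records (need >= 3)"
        elif np.ptp(x) == 0:
            reg.error = "zero variance in predictor"
        else:
            fit = linregress(x, y)
            reg.slope = float(fit.slope)
            reg.intercept = float(fit.intercept)
            reg.r_squared = float(fit.rvalue**2)
        out[(earlier, later)] = reg
    return out


@dataclass
class DriftResult:
    """Comparison of first-k vs last-k acquired records within a condition."""

    condition: str
    stage: str
    k: int
    median_first: float
    median_last: float
    test: _stats.TestResult
    drift_alpha: float
    flagged: bool


def acquisition_drift(
    records: pd.DataFrame,
    condition: str,
    stage: str,
    k: int,
    diag_alpha: float = 0.05,
    drift_alpha: float = 0.01,
    seed: int | None = None,
) -> DriftResult:
    """Test for time-correlated titer drift across an imaging session.

    Compares the first k vs the last k records by acquisition order via the
    decision tree; a p below ``drift_alpha`` flags the session as drifting
    (some "non-demonic intrusion" in the words of the field).
    """
    sub = records[records["condition"] == condition].dropna(subset=[stage])
    if "acquisition_order" not in sub.columns or sub["acquisition_order"].isna().any():
        raise SchemaError("records must carry acquisition_order for drift checks")
    if sub["acquisition_order"].duplicated().any():
        raise SchemaError("acquisition_order must be unique within a session")
    sub = sub.sort_values("acquisition_order")
    n = len(sub)
    if k > n // 2:
        raise ValueError(f"k={k} exceeds half of {n} records")
    first = sub[stage].to_numpy(float)[:k]
    last = sub[stage].to_numpy(float)[-k:]
    test = _stats.compare_two_groups(first, last, diag_alpha=diag_alpha, seed=seed)
    return DriftResult(
        condition=condition,
        stage=stage,
        k=k,
        median_first=float(np.median(first)),
        median_last=float(np.median(last)),
        test=test,
        drift_alpha=drift_alpha,
        flagged=bool(test.p_two_tailed < drift_alpha),
    )
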