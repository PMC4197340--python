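"""Paired barefoot-vs-shod statistics, summary-table arithmetic, ICC and
paired-design sample size.

The study design is a paired comparison: each subject lands both barefoot
and shod (3 trials per condition, averaged within subject before testing),
compared with a two-tailed paired t-test at alpha = 0.05.  Reported table
values are rounded to one decimal, half away from zero, and the printed
"mean difference" is barefoot − shod computed on the rounded summary means.
Measurement reliability is quantified with ICC(3,1) (two-way mixed effects,
consistency, single measurement).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractViolationError

__all__ = [
    "PairedComparison", "ReliabilityReport",
    "paired_t", "mean_difference_from_summary", "round_half_away",
    "icc_consistency", "paired_sample_size", "build_summary_tables",
    "trial_variables", "TABLE1_VARIABLES", "TABLE2_VARIABLES",
]


@dataclass(frozen=True)
class PairedComparison:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float      # mean(a) − mean(b), unrounded
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class ReliabilityReport:
    model: str                  # e.g. "ICC(3,1) two-way mixed, consistency"
    icc: Dict[str, float]       # per-variable/axis ICC


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def paired_t(a, b, variable: str = "") -> PairedComparison:
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n−1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractViolationError("paired samples must be equal-length 1-D")
    n = len(a)
    if n < 2:
        raise ContractViolationError("paired t-test needs at least 2 pairs")
    d = a - b
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise ContractViolationError(
            "differences have zero variance; paired t-test is degenerate")
    t = d.mean() / (sd_d / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return PairedComparison(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        mean_difference=float(d.mean()), t=float(t), p=float(p), n=n)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the tables' presentation rounding)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def mean_difference_from_summary(mean_a: float, mean_b: float,
                                 decimals: int = 1) -> float:
    """Mean-difference cell from two printed summary means."""
    if not (np.isfinite(mean_a) and np.isfinite(mean_b)):
        raise ContractViolationError("summary means must be finite")
    return round_half_away(mean_a - mean_b, decimals)


def icc_consistency(repeats) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single measurement.

    ``repeats`` is an (items × raters) matrix.  With MSR the between-item
    and MSE the residual mean square of the two-way ANOVA without
    interaction, ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE).
    """
    X = np.asarray(repeats, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ContractViolationError("need ≥2 items and ≥2 raters")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        raise ContractViolationError("zero variance; ICC undefined")
    return float((msr - mse) / denom)


def paired_sample_size(effect_size_d: float, alpha: float = 0.05,
                       power: float = 0.9, two_tailed: bool = True,
                       n_max: int = 10_000) -> int:
    """Smallest n with noncentral-t power ≥ target for a paired design.

    ``effect_size_d`` is the standardized mean difference mean(d)/sd(d).
    """
    if effect_size_d <= 0:
        raise ContractViolationError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ContractViolationError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = n - 1
        nc = effect_size_d * math.sqrt(n)
        if two_tailed:
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            achieved = (sps.nct.sf(tcrit, df, nc)
                        + sps.nct.cdf(-tcrit, df, nc))
        else:
            tcrit = sps.t.ppf(1 - alpha, df)
            achieved = sps.nct.sf(tcrit, df, nc)
        if achieved >= power:
            return n
    raise ContractViolationError("target power unreachable within n_max")


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

TABLE1_VARIABLES = [
    ("talocrural", "dorsiflexion"), ("talocrural", "eversion"),
    ("talocrural", "external_rotation"),
    ("subtalar", "dorsiflexion"), ("subtalar", "eversion"),
    ("subtalar", "external_rotation"),
]

TABLE2_PERIODS = ["toe_contact_to_heel_contact", "heel_contact_to_150ms"]
TABLE2_VARIABLES = [(p, j, ax) for p in TABLE2_PERIODS
                    for (j, ax) in TABLE1_VARIABLES]


def trial_variables(trial) -> Dict[str, float]:
    """The scalar outcome variables of one trial.

    Toe-contact joint angles (6), per-period angular changes (12) and the
    peak vertical GRF per body weight, keyed as ``tc|<joint>|<axis>``,
    ``<period>|<joint>|<axis>`` and ``peak_vgrf_bw``.
    """
    from .kinematics import angular_change
    out: Dict[str, float] = {}
    ev = trial.events
    ev.validate_ordering()
    for joint, series in trial.angles.items():
        for ax in ("dorsiflexion", "eversion", "external_rotation"):
            out[f"tc|{joint}|{ax}"] = float(
                np.interp(ev.toe_contact, series.time_ms, series.axis(ax)))
        d1 = angular_change(series, ev.toe_contact, ev.heel_contact)
        d2 = angular_change(series, ev.heel_contact, ev.late_mark)
        for ax in ("dorsiflexion", "eversion", "external_rotation"):
            out[f"toe_contact_to_heel_contact|{joint}|{ax}"] = getattr(d1, ax)
            out[f"heel_contact_to_150ms|{joint}|{ax}"] = getattr(d2, ax)
    from .events import peak_vgrf_bw
    out["peak_vgrf_bw"] = peak_vgrf_bw(trial.grf,
                                       window_ms=(ev.window_start, ev.window_end))
    return out


def build_summary_tables(trials: Sequence, decimals: int = 1,
                         average_trials: bool = True):
    """Condition summary tables in the layout of the study's Tables 1 and 2.

    Trials are averaged within subject and condition first; subjects missing
    a condition are excluded with a warning.  Returns ``(table1, table2,
    comparisons)`` where the tables are DataFrames and ``comparisons`` maps
    variable keys to :class:`PairedComparison`.  With a single complete
    subject, between-subject statistics are refused (t and p are NaN) but
    the per-subject summary is still produced.
    """
    rows: List[dict] = []
    for tr in trials:
        rows.append({"subject": tr.subject, "condition": tr.condition,
                     **trial_variables(tr)})
    df = pd.DataFrame(rows)
    variables = [c for c in df.columns if c not in ("subject", "condition")]
    agg = (df.groupby(["subject", "condition"])[variables].mean().reset_index()
           if average_trials else df)

    wide = agg.pivot_table(index="subject", columns="condition",
                           values=variables, aggfunc="mean")
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        warnings.warn(f"subjects missing a condition excluded: {sorted(dropped)}")

    comparisons: Dict[str, PairedComparison] = {}
    n = len(complete)
    for var in variables:
        a = complete[(var, "barefoot")].to_numpy()
        b = complete[(var, "shod")].to_numpy()
        if n >= 2:
            try:
                comparisons[var] = paired_t(a, b, variable=var)
            except ContractViolationError:
                # zero-variance differences: report the summary, no test
                comparisons[var] = PairedComparison(
                    var, float(a.mean()), float(a.std(ddof=1)),
                    float(b.mean()), float(b.std(ddof=1)),
                    float(a.mean() - b.mean()),
                    float("nan"), float("nan"), n)
        else:
            comparisons[var] = PairedComparison(
                var, float(a.mean()), float("nan"), float(b.mean()),
                float("nan"), float(a.mean() - b.mean()),
                float("nan"), float("nan"), n)

    def _row(var, joint, axis, period=None):
        c = comparisons[var]
        mb = round_half_away(c.mean_a, decimals)
        ms = round_half_away(c.mean_b, decimals)
        row = {
            "joint": joint, "variable": axis,
            "barefoot_mean": mb,
            "barefoot_sd": round_half_away(c.sd_a, decimals) if n >= 2 else float("nan"),
            "shod_mean": ms,
            "shod_sd": round_half_away(c.sd_b, decimals) if n >= 2 else float("nan"),
            "mean_difference": mean_difference_from_summary(mb, ms, decimals),
            "p_value": c.p,
        }
        if period is not None:
            row = {"period": period, **row}
        return row

    table1 = pd.DataFrame([_row(f"tc|{j}|{ax}", j, ax)
                           for j, ax in TABLE1_VARIABLES])
    t2_rows = [_row(f"{p}|{j}|{ax}", j, ax, period=p)
               for p, j, ax in TABLE2_VARIABLES]
    c = comparisons["peak_vgrf_bw"]
    mb = round_half_away(c.mean_a, 2)
    ms = round_half_away(c.mean_b, 2)
    t2_rows.append({"period": "window", "joint": "", "variable": "peak_vgrf_bw",
                    "barefoot_mean": mb,
                    "barefoot_sd": round_half_away(c.sd_a, 2) if n >= 2 else float("nan"),
                    "shod_mean": ms,
                    "shod_sd": round_half_away(c.sd_b, 2) if n >= 2 else float("nan"),
                    "mean_difference": mean_difference_from_summary(mb, ms, 1),
                    "p_value": c.p})
    table2 = pd.DataFrame(t2_rows)
    return table1, table2, comparisons
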