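"""Kaplan-Meier analysis with median-split and scan-mode cutoff selection.

A cohort is a table of (expression, follow-up time, event flag). The
expression value splits patients into low/high groups either at the median
or by "scan" mode: every admissible split between distinct expression
values (both groups at least ``min_group`` patients) is tested with the
two-sample log-rank statistic and the split with the smallest nominal
p-value is reported, together with a Bonferroni adjustment over the number
of cutoffs actually tested. The nominal scan-mode p is anti-conservative by
construction; the Bonferroni-adjusted value is conservative.

The log-rank statistic is computed in its standard counting-process form
(observed minus expected events with hypergeometric variance at each
distinct event time, chi-square with 1 df); it is implemented directly so
the scan loop stays cheap and the zero-variance degenerate case follows a
fixed convention (chi2 = 0, p = 1, with a warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["expression", "time", "event"]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (cohort["time"] <= 0).any():
        raise ValueError("follow-up times must be > 0")
    if not np.isfinite(cohort["expression"]).all():
        raise ValueError("expression values must be finite")
    if not cohort["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return cohort


def _logrank_arrays(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> tuple[float, float]:
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b]).astype(float)
    in_a = np.concatenate([np.ones(len(time_a)), np.zeros(len(time_b))])

    order = np.argsort(times, kind="mergesort")
    times, events, in_a = times[order], events[order], in_a[order]

    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return 0.0, 1.0

    n = len(times)
    # at-risk counts just before each distinct event time
    idx = np.searchsorted(times, event_times, side="left")
    n_risk = n - idx
    n_risk_a = len(time_a) - np.searchsorted(np.sort(time_a), event_times, side="left")
    # events at each distinct event time
    d_total = np.zeros(event_times.size)
    d_a = np.zeros(event_times.size)
    pos = np.searchsorted(event_times, times[events == 1])
    np.add.at(d_total, pos, 1.0)
    np.add.at(d_a, pos, in_a[events == 1])

    expected_a = d_total * n_risk_a / n_risk
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_total
            * (n_risk_a / n_risk)
            * (1 - n_risk_a / n_risk)
            * (n_risk - d_total)
            / np.where(n_risk > 1, n_risk - 1, 1.0)
        )
    var[n_risk <= 1] = 0.0
    v_total = float(var.sum())
    if v_total == 0.0:
        warnings.warn("log-rank: zero total variance; no comparable event times (p = 1)")
        return 0.0, 1.0
    chi_square = float((d_a.sum() - expected_a.sum()) ** 2 / v_total)
    return chi_square, float(stats.chi2.sf(chi_square, df=1))


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi_square, p).

    Both groups must be non-empty with at least one event overall. Groups
    are cohort subsets with ``time`` and ``event`` columns.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if (group_a["event"].sum() + group_b["event"].sum()) == 0:
        raise ValueError("log-rank requires at least one event overall")
    return _logrank_arrays(
        group_a["time"].to_numpy(float),
        group_a["event"].to_numpy(float),
        group_b["time"].to_numpy(float),
        group_b["event"].to_numpy(float),
    )


def km_curve(cohort: pd.DataFrame) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a step function as a DataFrame (time, survival) starting at
    (0, 1); survival is non-increasing and drops only at event times.
    """
    if len(cohort) == 0:
        raise ValueError("cohort subset is empty")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(cohort["time"], cohort["event"])
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    ).reset_index(drop=True)


@dataclass
class ScanResult:
    """Outcome of a cutoff analysis (median or scan mode)."""

    mode: str
    cutoff: float
    n_low: int
    n_high: int
    chi_square: float
    p_nominal: float
    p_adjusted: float | None
    n_cutoffs_tested: int

    def to_dict(self) -> dict:
        return asdict(self)


def scan_cutoff(
    cohort: pd.DataFrame,
    min_group: int = 8,
    mode: Literal["scan", "median"] = "scan",
) -> ScanResult:
    """Split the cohort on expression and pick the cutoff by log-rank.

    Patients with expression exactly equal to the cutoff go to the low
    group. ``median`` mode tests the single median split. ``scan`` mode
    tests every split between distinct expression values that leaves both
    groups with at least ``min_group`` patients and reports the one with
    the smallest nominal p (ties resolve to the smaller cutoff);
    ``p_adjusted`` is the Bonferroni bound ``min(1, p * n_cutoffs_tested)``.
    """
    validate_cohort(cohort)
    if mode not in ("scan", "median"):
        raise ValueError(f"unknown cutoff mode {mode!r}")
    n = len(cohort)
    if n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} patients, got {n}")

    expr = cohort["expression"].to_numpy(float)
    order = np.argsort(expr, kind="mergesort")
    time = cohort["time"].to_numpy(float)[order]
    event = cohort["event"].to_numpy(float)[order]
    expr_sorted = expr[order]

    def split_at(n_low: int) -> tuple[float, float]:
        return _logrank_arrays(
            time[:n_low], event[:n_low], time[n_low:], event[n_low:]
        )

    if mode == "median":
        cutoff = float(np.median(expr))
        n_low = int((expr_sorted <= cutoff).sum())
        if n_low == 0 or n_low == n:
            raise ValueError("median split leaves one group empty (constant expression?)")
        chi, p = split_at(n_low)
        return ScanResult("median", cutoff, n_low, n - n_low, chi, p, None, 1)

    # distinct-value boundaries: low group = everyone <= the boundary value
    distinct_end = np.nonzero(np.diff(expr_sorted))[0] + 1  # sizes of "<= value" groups
    candidates = [c for c in distinct_end if min_group <= c <= n - min_group]
    if not candidates:
        raise ValueError(
            f"no admissible split: cannot form two groups of >= {min_group} "
            "with the given expression ties"
        )
    best = None
    for n_low in candidates:
        chi, p = split_at(int(n_low))
        if best is None or p < best[1]:
            best = (chi, p, int(n_low))
    chi, p, n_low = best
    cutoff = float(expr_sorted[n_low - 1])
    return ScanResult(
        "scan", cutoff, n_low, n - n_low, chi, p,
        min(1.0, p * len(candidates)), len(candidates),
    )
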