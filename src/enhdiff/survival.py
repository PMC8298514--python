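"""Kaplan-Meier estimation, fixed-timepoint rates, log-rank comparison, and
expression-based patient stratification.

The product-limit estimator and the two-group log-rank test come from
lifelines; this module wraps them behind a small step-function curve type so
that fixed-timepoint evaluation (e.g. the 2-year rate, t = 24 months) uses an
explicit right-continuous convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io_formats import ConfigError

logger = logging.getLogger(__name__)

TWO_YEARS_MONTHS = 24.0


@dataclass
class KMCurve:
    """A right-continuous Kaplan-Meier step function.

    ``times`` are the distinct event times in increasing order and
    ``survival`` the post-event S(t) values; S(t) = 1 before the first event.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier curve for one group of (time_months, event) records."""
    if records.empty:
        raise ConfigError("km_estimate needs >= 1 record")
    times = records["time_months"].to_numpy(dtype=float)
    if (times < 0).any():
        raise ConfigError("negative survival time")
    events = records["event"].to_numpy(dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function evaluation of S(t)."""
    if t < 0:
        raise ConfigError("t must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank(records: pd.DataFrame, group_a: str, group_b: str) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    a = records[records["group"] == group_a]
    b = records[records["group"] == group_b]
    if a.empty or b.empty:
        raise ConfigError("both groups must be non-empty")
    if not (a["event"].any() or b["event"].any()):
        logger.warning("logrank: no events in either group, p = 1")
        return 0.0, 1.0
    res = logrank_test(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def median_split(
    expression: pd.DataFrame, gene_id: str, samples: list[str] | None = None
) -> pd.Series:
    """Split samples into "high"/"low" at the median expression of one gene.

    Samples strictly above the median are high, strictly below are low;
    samples exactly at the median alternate low/high in sorted sample_id
    order, starting with low, to balance the group sizes.
    """
    if gene_id not in expression.index:
        raise ConfigError(f"gene {gene_id!r} not in expression matrix")
    values = expression.loc[gene_id]
    if samples is not None:
        values = values[samples]
    if len(values) < 2:
        raise ConfigError("median_split needs >= 2 samples")
    if values.nunique() == 1:
        raise ConfigError("no split possible: all-equal expression")
    med = float(values.median())
    labels = pd.Series(index=values.index, dtype=object, name="group")
    labels[values > med] = "high"
    labels[values < med] = "low"
    tied = sorted(values.index[values == med])
    for i, sample in enumerate(tied):
        labels[sample] = "low" if i % 2 == 0 else "high"
    return labels


def stratified_km(
    expression: pd.DataFrame,
    survival_records: pd.DataFrame,
    gene_id: str,
    timepoint: float = TWO_YEARS_MONTHS,
) -> dict:
    """Expression-stratified survival: median split, per-group KM, log-rank.

    ``survival_records`` must be indexed by (or carry a subject_id column
    matching) the expression sample ids.  Returns the group labels, the two
    curves, the fixed-timepoint rates, and the log-rank statistic/p.
    """
    records = survival_records.copy()
    if "subject_id" in records.columns:
        records = records.set_index("subject_id")
    shared = [s for s in records.index if s in expression.columns]
    labels = median_split(expression, gene_id, shared)
    records = records.loc[labels.index]
    records["group"] = labels
    curves = {
        g: km_estimate(records[records["group"] == g]) for g in ("low", "high")
    }
    rates = {g: survival_at(curves[g], timepoint) for g in curves}
    stat, p = logrank(records.reset_index(), "low", "high")
    return {"labels": labels, "curves": curves, "rates": rates,
            "logrank_stat": stat, "logrank_p": p}


def km_curve_frame(curve: KMCurve) -> pd.DataFrame:
    """Tabular form of a KM curve for TSV output."""
    return pd.DataFrame(
        {
            "time_months": curve.times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "events": curve.events,
        }
    )
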