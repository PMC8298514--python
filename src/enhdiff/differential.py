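"""Paired differential element calling and the six-group classification.

An element is *gained* in a comparison when, in at least ``recurrence_min``
patient pairs, the case/reference signal fold change is >= ``fc_min`` AND the
absolute signal difference is >= ``diff_min`` (defaults 2.0 and 0.5 RPKM);
*lost* symmetrically (fc <= 1/fc_min, diff <= -diff_min).  Calls are validated
with a two-sided paired t-test, BH-corrected across called elements.  The two
tumor-vs-normal call sets combine into six groups: G1 (EC-specific gain),
G2 (LNC-specific gain), G3 (common gain), G4 (EC-specific loss), G5
(LNC-specific loss), G6 (common loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io_formats import ConfigError

GAINED = "gained"
LOST = "lost"
UNALTERED = "unaltered"

GROUPS = ("G1", "G2", "G3", "G4", "G5", "G6")

#: pseudocount on RPKM for fold-change computation; small relative to the
#: 0.5 RPKM absolute-difference guard.
DEFAULT_EPSILON = 0.1


@dataclass
class PairwiseChangeTable:
    """Per-element, per-patient-pair fold changes and signed differences."""

    fc: pd.DataFrame  # elements x patients
    diff: pd.DataFrame  # elements x patients
    comparison: str
    epsilon: float


def pairwise_change(
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    comparison: str = "EC_vs_Nor",
    epsilon: float = DEFAULT_EPSILON,
) -> PairwiseChangeTable:
    """Per-pair fold change (case+eps)/(ref+eps) and difference case - ref."""
    if not pairs:
        raise ConfigError("pairs must be non-empty")
    missing = [s for _, c, r in pairs for s in (c, r) if s not in matrix.columns]
    if missing:
        raise ConfigError(f"pair references missing samples: {sorted(set(missing))}")
    patients = [p for p, _, _ in pairs]
    case = matrix[[c for _, c, _ in pairs]].to_numpy(dtype=float)
    ref = matrix[[r for _, _, r in pairs]].to_numpy(dtype=float)
    fc = (case + epsilon) / (ref + epsilon)
    diff = case - ref
    return PairwiseChangeTable(
        fc=pd.DataFrame(fc, index=matrix.index, columns=patients),
        diff=pd.DataFrame(diff, index=matrix.index, columns=patients),
        comparison=comparison,
        epsilon=epsilon,
    )


def call_differential(
    table: PairwiseChangeTable,
    fc_min: float = 2.0,
    diff_min: float = 0.5,
    recurrence_min: int = 6,
) -> pd.DataFrame:
    """Call gained / lost / unaltered elements from recurrent per-pair votes.

    Returns a frame indexed by element with columns status, gain_votes,
    loss_votes, recurrence_count, mean_fc, conflict.
    """
    if fc_min <= 1 or diff_min <= 0:
        raise ConfigError("fc_min must exceed 1 and diff_min must be positive")
    n_pairs = table.fc.shape[1]
    if not (1 <= recurrence_min <= n_pairs):
        raise ConfigError(f"recurrence_min must be in [1, {n_pairs}]")
    fc = table.fc.to_numpy()
    diff = table.diff.to_numpy()
    gain_votes = ((fc >= fc_min) & (diff >= diff_min)).sum(axis=1)
    loss_votes = ((fc <= 1.0 / fc_min) & (diff <= -diff_min)).sum(axis=1)
    gained = gain_votes >= recurrence_min
    lost = loss_votes >= recurrence_min
    conflict = gained & lost
    status = np.where(
        conflict, UNALTERED, np.where(gained, GAINED, np.where(lost, LOST, UNALTERED))
    )
    recurrence = np.where(
        status == GAINED, gain_votes, np.where(status == LOST, loss_votes, 0)
    )
    return pd.DataFrame(
        {
            "status": status,
            "gain_votes": gain_votes,
            "loss_votes": loss_votes,
            "recurrence_count": recurrence,
            "mean_fc": fc.mean(axis=1),
            "conflict": conflict,
        },
        index=table.fc.index,
    )


def paired_significance(
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    calls: pd.DataFrame,
    q_max: float = 0.1,
) -> tuple[pd.Series, float]:
    """Two-sided paired t-test on per-pair differences for called elements.

    BH adjustment runs across all gained/lost elements of the comparison.
    Zero-variance differences get p=0 when the mean difference is nonzero and
    p=1 otherwise.  Returns (q-values for called elements, fraction with
    q < ``q_max``); the fraction is nan when nothing was called.
    """
    if len(pairs) < 2:
        raise ConfigError("paired significance needs >= 2 pairs")
    called = calls.index[calls["status"] != UNALTERED]
    if called.empty:
        return pd.Series(dtype=float), float("nan")
    case = matrix.loc[called, [c for _, c, _ in pairs]].to_numpy(dtype=float)
    ref = matrix.loc[called, [r for _, _, r in pairs]].to_numpy(dtype=float)
    d = case - ref
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate rows handled below
        tres = stats.ttest_rel(case, ref, axis=1)
        p = np.asarray(tres.pvalue, dtype=float)
    zero_var = d.std(axis=1, ddof=1) == 0
    p[zero_var & (d.mean(axis=1) != 0)] = 0.0
    p[zero_var & (d.mean(axis=1) == 0)] = 1.0
    q = pd.Series(bh_adjust(p), index=called, name="q_value")
    return q, float((q < q_max).mean())


def assign_groups(calls_ec: pd.DataFrame, calls_lnc: pd.DataFrame) -> pd.Series:
    """Six-group classification from EC-vs-Nor and LNC-vs-Nor call sets.

    G1/G2: EC-/LNC-specific gain; G3 common gain; G4/G5: EC-/LNC-specific
    loss; G6 common loss; gained in one and lost in the other -> "discordant";
    otherwise "none".
    """
    if not calls_ec.index.equals(calls_lnc.index):
        if set(calls_ec.index) != set(calls_lnc.index):
            raise ConfigError("call sets cover different element catalogs")
        calls_lnc = calls_lnc.reindex(calls_ec.index)
    ec = calls_ec["status"].to_numpy()
    lnc = calls_lnc["status"].to_numpy()
    rules = {
        (GAINED, UNALTERED): "G1",
        (UNALTERED, GAINED): "G2",
        (GAINED, GAINED): "G3",
        (LOST, UNALTERED): "G4",
        (UNALTERED, LOST): "G5",
        (LOST, LOST): "G6",
        (GAINED, LOST): "discordant",
        (LOST, GAINED): "discordant",
        (UNALTERED, UNALTERED): "none",
    }
    labels = [rules[(a, b)] for a, b in zip(ec, lnc)]
    return pd.Series(labels, index=calls_ec.index, name="group")
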