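"""Super-enhancer stitching, rank-order cutoff, and dual-strategy calls.

Enhancers within ``stitch_distance`` bp (default 12.5 kb, the ROSE
convention) are stitched transitively into candidate regions; candidates are
ranked by total signal and the classic hockey-stick cutoff is applied: with
both axes scaled to [0, 1], the tangency point of the slope-1 line — the rank
minimizing y_scaled - x_scaled — separates super-enhancers (above) from
typical stitched enhancers.

Differential SEs are called by two complementary strategies and combined:
the *mean* strategy thresholds the group-mean signal difference (> 2 gain,
< -2 loss), the *paired* strategy counts per-patient-pair fold-change votes
(fc >= 2 gain, fc <= 0.7 loss, recurrent in >= 5 pairs).  High-confidence
calls are those on which both strategies agree and that pass both the FC and
absolute-difference thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import DEFAULT_EPSILON, GAINED, LOST, UNALTERED
from .elements import Element
from .io_formats import ConfigError, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_STITCH_DISTANCE = 12_500


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched run of enhancers: the candidate unit of SE calling."""

    region_id: str
    interval: GenomicInterval
    constituents: tuple[str, ...]  # element_ids, in coordinate order


def stitch_enhancers(
    enhancers: list[Element], stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[StitchedRegion]:
    """Transitively merge enhancers whose gap is <= ``stitch_distance`` bp.

    With distance 0, overlapping and book-ended enhancers still merge.
    """
    if stitch_distance < 0:
        raise ConfigError("stitch_distance must be >= 0")
    ordered = sorted(enhancers, key=lambda e: e.interval.sort_key())
    regions: list[StitchedRegion] = []
    cur: list[Element] = []

    def flush() -> None:
        if cur:
            iv = GenomicInterval(
                cur[0].interval.chrom, cur[0].interval.start, max(e.interval.end for e in cur)
            )
            rid = f"se{len(regions):04d}"
            regions.append(StitchedRegion(rid, iv, tuple(e.element_id for e in cur)))

    run_end = None
    for el in ordered:
        if (
            not cur
            or el.interval.chrom != cur[0].interval.chrom
            or el.interval.start - run_end > stitch_distance
        ):
            flush()
            cur = [el]
            run_end = el.interval.end
        else:
            cur.append(el)
            run_end = max(run_end, el.interval.end)
    flush()
    return regions


def se_signal(
    regions: list[StitchedRegion], signal: pd.DataFrame, lengths: pd.Series
) -> pd.DataFrame:
    """Total signal per stitched region per sample.

    Length-weighted sum over constituents: RPKM x element length / 1000,
    approximating the region-total signal ROSE ranks by.
    """
    rows = []
    for region in regions:
        weights = lengths.loc[list(region.constituents)] / 1000.0
        rows.append(signal.loc[list(region.constituents)].mul(weights, axis=0).sum(axis=0))
    return pd.DataFrame(rows, index=[r.region_id for r in regions])


def rank_superenhancers(total_signal: pd.Series) -> pd.DataFrame:
    """Rank stitched regions and apply the slope-1 tangency cutoff.

    Returns a frame indexed like the input with columns rank (1 = lowest
    signal), signal, is_se.  Degenerate inputs (fewer than 3 regions, or all
    signals equal) yield zero SEs.
    """
    s = total_signal.astype(float)
    if not np.isfinite(s).all() or (s < 0).any():
        raise ConfigError("total signals must be finite and non-negative")
    n = len(s)
    order = np.argsort(s.to_numpy(), kind="mergesort")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    out = pd.DataFrame({"rank": rank, "signal": s, "is_se": False})
    if n < 3:
        logger.warning("rank_superenhancers: fewer than 3 regions, no SEs called")
        return out
    sorted_sig = s.to_numpy()[order]
    span = sorted_sig[-1] - sorted_sig[0]
    if span == 0:
        return out  # flat curve lies on the diagonal: no point above tangency
    x = np.arange(n) / (n - 1)
    y = (sorted_sig - sorted_sig[0]) / span
    # tangency of the slope-1 line: last index minimizing y - x
    d = y - x
    cut_idx = n - 1 - int(np.argmin(d[::-1]))
    cutoff_signal = sorted_sig[cut_idx]
    out["is_se"] = s.to_numpy() > cutoff_signal
    out.attrs["cutoff_signal"] = float(cutoff_signal)
    return out


def differential_se_mean(
    se_matrix: pd.DataFrame,
    case_samples: list[str],
    ref_samples: list[str],
    gain_diff: float = 2.0,
    loss_diff: float = -2.0,
) -> pd.DataFrame:
    """Mean-strategy differential SE calls, ranked by signal difference."""
    if not case_samples or not ref_samples:
        raise ConfigError("both groups must be non-empty")
    diff = se_matrix[case_samples].mean(axis=1) - se_matrix[ref_samples].mean(axis=1)
    status = np.where(diff > gain_diff, GAINED, np.where(diff < loss_diff, LOST, UNALTERED))
    out = pd.DataFrame({"status": status, "abs_diff": diff}, index=se_matrix.index)
    return out.sort_values("abs_diff", ascending=False, kind="mergesort")


def differential_se_paired(
    se_matrix: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    recurrence_min: int = 5,
    fc_gain: float = 2.0,
    fc_loss: float = 0.7,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Paired-strategy differential SE calls, ranked by group fold change."""
    if not pairs:
        raise ConfigError("pairs must be non-empty")
    missing = [s for _, c, r in pairs for s in (c, r) if s not in se_matrix.columns]
    if missing:
        raise ConfigError(f"pair references missing samples: {sorted(set(missing))}")
    if not (1 <= recurrence_min <= len(pairs)):
        raise ConfigError(f"recurrence_min must be in [1, {len(pairs)}]")
    case = se_matrix[[c for _, c, _ in pairs]].to_numpy(dtype=float)
    ref = se_matrix[[r for _, _, r in pairs]].to_numpy(dtype=float)
    fc = (case + epsilon) / (ref + epsilon)
    gain_votes = (fc >= fc_gain).sum(axis=1)
    loss_votes = (fc <= fc_loss).sum(axis=1)
    gained = gain_votes >= recurrence_min
    lost = loss_votes >= recurrence_min
    conflict = gained & lost
    status = np.where(
        conflict, UNALTERED, np.where(gained, GAINED, np.where(lost, LOST, UNALTERED))
    )
    group_fc = (case.mean(axis=1) + epsilon) / (ref.mean(axis=1) + epsilon)
    out = pd.DataFrame(
        {
            "status": status,
            "fc": group_fc,
            "recurrence_count": np.where(gained, gain_votes, np.where(lost, loss_votes, 0)),
            "conflict": conflict,
        },
        index=se_matrix.index,
    )
    return out.sort_values("fc", ascending=False, kind="mergesort")


def combine_se_calls(
    mean_calls: pd.DataFrame,
    paired_calls: pd.DataFrame,
    fc_gain: float = 2.0,
    fc_loss: float = 0.7,
    gain_diff: float = 2.0,
    loss_diff: float = -2.0,
) -> pd.DataFrame:
    """Union of the two strategies, with a high-confidence overlap flag.

    combined = gained if either strategy says gained (symmetrically lost);
    conflicting strategies yield unaltered with a conflict flag.
    high_confidence requires both strategies to agree on a non-unaltered
    status AND the SE to pass both the FC and absolute-difference thresholds.
    """
    if set(mean_calls.index) != set(paired_calls.index):
        raise ConfigError("strategy call sets cover different SE catalogs")
    paired = paired_calls.reindex(mean_calls.index)
    m = mean_calls["status"].to_numpy()
    p = paired["status"].to_numpy()
    conflict = ((m == GAINED) & (p == LOST)) | ((m == LOST) & (p == GAINED))
    combined = np.where(
        conflict,
        UNALTERED,
        np.where(
            (m == GAINED) | (p == GAINED),
            GAINED,
            np.where((m == LOST) | (p == LOST), LOST, UNALTERED),
        ),
    )
    fc = paired["fc"].to_numpy()
    diff = mean_calls["abs_diff"].to_numpy()
    agree = (m == p) & (m != UNALTERED)
    hc_gain = agree & (m == GAINED) & (fc > fc_gain) & (diff > gain_diff)
    hc_loss = agree & (m == LOST) & (fc < fc_loss) & (diff < loss_diff)
    out = pd.DataFrame(
        {
            "mean_status": m,
            "paired_status": p,
            "combined_status": combined,
            "high_confidence": hc_gain | hc_loss,
            "fc": fc,
            "abs_diff": diff,
            "recurrence_count": paired["recurrence_count"].to_numpy(),
            "conflict": conflict,
        },
        index=mean_calls.index,
    )
    return out.sort_values("fc", ascending=False, kind="mergesort")
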