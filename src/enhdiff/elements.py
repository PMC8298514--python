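"""Consensus element catalog, promoter/enhancer classification, and signal.

The element catalog is built by merging H3K27ac peaks from all samples into
maximal nonoverlapping intervals.  Elements are classified against TSSs with a
+/- ``window`` bp rule (default 2 kb): a *promoter element* lies completely
within the window of some TSS, an *enhancer* has every base more than
``window`` bp from every TSS, and anything straddling the window edge is
*ambiguous* (excluded from both downstream sets by default).  Signal is
input-subtracted RPKM, floored at zero, optionally quantile-normalized across
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ConfigError, GenomicInterval, TssRecord

logger = logging.getLogger(__name__)

PROMOTER = "promoter_element"
ENHANCER = "enhancer"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ConsensusRegion:
    """A merged consensus interval with the number of contributing samples."""

    interval: GenomicInterval
    n_samples: int = 1


@dataclass(frozen=True)
class Element:
    """A classified consensus element."""

    interval: GenomicInterval
    element_id: str
    element_class: str
    nearest_tss_distance: int


def merge_peaks(
    peak_sets: Mapping[str, Sequence[GenomicInterval]] | Sequence[Sequence[GenomicInterval]],
) -> list[ConsensusRegion]:
    """Merge per-sample peak sets into maximal nonoverlapping intervals.

    Intervals merge when they share at least one base (book-ended half-open
    intervals do not merge).  Each consensus region records how many input
    samples contributed at least one overlapping peak.
    """
    if isinstance(peak_sets, Mapping):
        sets = list(peak_sets.values())
    else:
        sets = list(peak_sets)
    tagged: list[tuple[str, int, int, int]] = []
    for si, peaks in enumerate(sets):
        for iv in peaks:
            tagged.append((iv.chrom, iv.start, iv.end, si))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    out: list[ConsensusRegion] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_samples: set[int] = set()

    def flush() -> None:
        if cur_chrom is not None:
            out.append(
                ConsensusRegion(
                    GenomicInterval(cur_chrom, cur_start, cur_end), len(cur_samples)
                )
            )

    for chrom, start, end, si in tagged:
        if chrom != cur_chrom or start >= cur_end:  # >= : book-ended stays separate
            flush()
            cur_chrom, cur_start, cur_end, cur_samples = chrom, start, end, {si}
        else:
            cur_end = max(cur_end, end)
            cur_samples.add(si)
    flush()
    return out


def classify_elements(
    consensus: Sequence[ConsensusRegion | GenomicInterval],
    tss: Sequence[TssRecord],
    window: int = 2000,
    id_prefix: str = "el",
) -> list[Element]:
    """Classify consensus intervals as promoter elements / enhancers / ambiguous.

    Full-span semantics: promoter iff the whole interval lies within
    [tss - window, tss + window] of some TSS; enhancer iff every base is more
    than ``window`` bp from every TSS.  ``nearest_tss_distance`` is the
    distance from the interval to the nearest TSS position (0 if a TSS falls
    inside the interval).
    """
    if window <= 0:
        raise ConfigError("window must be positive")
    if not tss:
        raise ConfigError("TSS set must be non-empty")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, recs in pd.DataFrame(
        [(t.chrom, t.tss) for t in tss], columns=["chrom", "tss"]
    ).groupby("chrom"):
        by_chrom[chrom] = np.sort(recs["tss"].to_numpy())

    width = len(str(len(consensus)))
    out: list[Element] = []
    for i, region in enumerate(consensus):
        iv = region.interval if isinstance(region, ConsensusRegion) else region
        positions = by_chrom.get(iv.chrom)
        last = iv.end - 1  # last covered base
        if positions is None or positions.size == 0:
            cls, dist = ENHANCER, np.iinfo(np.int64).max
        else:
            # promoter: exists tss in [last - window, start + window]
            lo = np.searchsorted(positions, last - window, side="left")
            promoter = lo < positions.size and positions[lo] <= iv.start + window
            # near: exists tss in [start - window, last + window]
            lo2 = np.searchsorted(positions, iv.start - window, side="left")
            near = lo2 < positions.size and positions[lo2] <= last + window
            cls = PROMOTER if promoter else (AMBIGUOUS if near else ENHANCER)
            j = np.searchsorted(positions, iv.start)
            cand = positions[max(0, j - 1) : j + 2]
            dist = int(
                min(
                    0 if (iv.start <= t <= last) else min(abs(t - iv.start), abs(t - last))
                    for t in cand
                )
            )
        out.append(Element(iv, f"{id_prefix}{i:0{width}d}", cls, dist))
    return out


def rpkm_signal(
    region_counts: pd.DataFrame,
    region_lengths: pd.Series,
    library_sizes: pd.Series,
    input_counts: pd.DataFrame | None = None,
    input_library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Input-subtracted RPKM per region per sample, floored at zero.

    RPKM = reads * 1e9 / (length_bp * library_size).  When an input (control)
    matrix is supplied, returns max(0, RPKM_chip - RPKM_input).
    """
    if (region_counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    lengths = region_lengths.reindex(region_counts.index)
    if (lengths <= 0).any():
        raise ValueError("region lengths must be positive")
    libs = library_sizes.reindex(region_counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = region_counts.mul(1e9).div(lengths, axis=0).div(libs, axis=1)
    if input_counts is not None:
        if input_library_sizes is None:
            raise ValueError("input_library_sizes required with input_counts")
        if (input_counts.to_numpy() < 0).any():
            raise ValueError("negative input read counts")
        ilibs = input_library_sizes.reindex(input_counts.columns)
        irpkm = input_counts.mul(1e9).div(lengths, axis=0).div(ilibs, axis=1)
        rpkm = rpkm - irpkm
    return rpkm.clip(lower=0.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns.

    The reference distribution is the row-wise mean of each column's sorted
    values; each column's values are replaced by the reference values at their
    within-column ranks, with ties receiving the mean reference value over the
    tied rank span (preprocessCore-style).  After normalization every column
    carries an identical multiset of values.
    """
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile_normalize: missing values not allowed")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # average the reference over tied spans
        ranks = rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=assigned)
        counts = np.bincount(ranks)
        out[:, j] = sums[ranks] / counts[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (sample sd, ddof=1); constant rows map to all zeros."""
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[np.broadcast_to(sd == 0, Z.shape)] = 0.0
    Z = np.nan_to_num(Z, nan=0.0)
    return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)


def saturation_curve(
    sample_sets: Mapping[str, set],
    n_permutations: int = 100,
    seed: int = 0,
    stability_threshold: float = 0.01,
) -> tuple[pd.DataFrame, int]:
    """Cumulative unique-element discovery curve over random sample orderings.

    Returns a frame with columns (k, mean, sd) — the mean +/- sd cumulative
    count of distinct elements after k samples — and the saturation point: the
    smallest k where the mean increment from k to k+1 falls below
    ``stability_threshold`` of the running total (n if never reached).
    """
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    names = sorted(sample_sets)
    sets = [frozenset(sample_sets[name]) for name in names]
    n = len(sets)
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen: set = set()
        for k, idx in enumerate(order):
            seen |= sets[idx]
            counts[p, k] = len(seen)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n)
    saturation = n
    for k in range(n - 1):
        increment = mean[k + 1] - mean[k]
        if mean[k] > 0 and increment < stability_threshold * mean[k]:
            saturation = k + 1
            break
    frame = pd.DataFrame({"k": np.arange(1, n + 1), "mean": mean, "sd": sd})
    return frame, saturation
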