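"""Enhancer-gene integration and expression-side utilities.

Links every element to the gene with the nearest TSS (midpoint distance),
quantifies enhancer-expression coupling (direction, dose, Spearman
correlation), selects biomarker panels per differential-enhancer subgroup
(g1/g2/g3/g6), classifies samples by the tissue sign signatures, flags
primed (pre-activated / pre-silenced) genes, and provides CPM filtering, a
Welch-t stand-in differential expression test (externally produced DE tables
are importable), hypergeometric gene-set enrichment, PCA, and hierarchical
clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from ._stats import bh_adjust
from .elements import Element
from .io_formats import ConfigError, TssRecord

logger = logging.getLogger(__name__)

#: expression-side sign patterns of the three tissues over the biomarker
#: subgroups (g1: EC-specific gain, g2: LNC-specific gain, g3: common gain,
#: g6: common loss); "+" = above the cohort median subgroup score.
TISSUE_SIGNATURES = {
    "Nor": {"g1": -1, "g2": -1, "g3": -1, "g6": +1},
    "EC": {"g1": +1, "g2": -1, "g3": +1, "g6": -1},
    "LNC": {"g1": -1, "g2": +1, "g3": +1, "g6": -1},
}

#: enhancer group -> biomarker subgroup, with the expected FC direction
SUBGROUP_OF_GROUP = {"G1": "g1", "G2": "g2", "G3": "g3", "G6": "g6"}
SUBGROUP_DIRECTION = {"g1": +1, "g2": +1, "g3": +1, "g6": -1}


def assign_nearest_gene(
    elements: Sequence[Element], tss: Sequence[TssRecord]
) -> pd.DataFrame:
    """Link each element to the TSS nearest its midpoint.

    Distance ties break on the lexicographically smallest gene_id.  Returns a
    frame indexed by element_id with columns gene_id, distance.
    """
    if not tss:
        raise ConfigError("TSS set must be non-empty")
    frame = pd.DataFrame(
        [(t.chrom, t.tss, t.gene_id) for t in tss], columns=["chrom", "tss", "gene_id"]
    )
    by_chrom = {
        chrom: grp.sort_values(["tss", "gene_id"], kind="mergesort")
        for chrom, grp in frame.groupby("chrom")
    }
    rows = []
    for el in elements:
        mid = el.interval.midpoint
        grp = by_chrom.get(el.interval.chrom)
        if grp is None:
            # no TSS on this chromosome: fall back to the global nearest
            grp = frame.sort_values(["tss", "gene_id"], kind="mergesort")
        pos = grp["tss"].to_numpy()
        j = np.searchsorted(pos, mid)
        best = None
        for k in range(max(0, j - 2), min(len(pos), j + 2)):
            d = abs(pos[k] - mid)
            gid = grp["gene_id"].iat[k]
            if best is None or d < best[0] or (d == best[0] and gid < best[1]):
                best = (d, gid)
        rows.append((el.element_id, best[1], best[0]))
    out = pd.DataFrame(rows, columns=["element_id", "gene_id", "distance"])
    return out.set_index("element_id")


def cpm_filter(
    counts: pd.DataFrame, cpm_min: float = 1.0, min_samples: int = 18
) -> pd.Index:
    """Genes with CPM > ``cpm_min`` in at least ``min_samples`` samples."""
    if min_samples > counts.shape[1]:
        raise ConfigError("min_samples exceeds the number of samples")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ConfigError("column sums must be positive")
    cpm = counts.mul(1e6).div(totals, axis=1)
    keep = (cpm > cpm_min).sum(axis=1) >= min_samples
    return counts.index[keep]


def de_test(
    log_expr: pd.DataFrame,
    case_samples: list[str],
    ref_samples: list[str],
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sided t-test per gene on log2(TPM+1) values ("welch_bh").

    DE iff linear fold change > ``fc_min`` (in either direction) and BH q <
    ``fdr_max``; direction follows the sign of the log2 fold change.  This is
    a simple label-free stand-in for count-model DE; external DE tables with
    columns (gene_id, log2FC, pvalue, padj) can be used interchangeably.
    """
    if len(case_samples) < 2 or len(ref_samples) < 2:
        raise ConfigError("de_test needs >= 2 samples per group")
    case = log_expr[case_samples].to_numpy(dtype=float)
    ref = log_expr[ref_samples].to_numpy(dtype=float)
    log2fc = case.mean(axis=1) - ref.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate rows handled below
        p = stats.ttest_ind(case, ref, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = (case.std(axis=1) == 0) & (ref.std(axis=1) == 0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    q = bh_adjust(p)
    significant = (np.abs(log2fc) > np.log2(fc_min)) & (q < fdr_max)
    direction = np.where(
        ~significant, "ns", np.where(log2fc > 0, "up", "down")
    )
    return pd.DataFrame(
        {"log2FC": log2fc, "pvalue": p, "padj": q, "direction": direction,
         "method": "welch_bh"},
        index=log_expr.index,
    )


def expression_fc(
    tpm: pd.DataFrame, case_samples: list[str], ref_samples: list[str], pseudo: float = 1.0
) -> pd.Series:
    """Linear fold change of group-mean TPM with a pseudocount."""
    return (tpm[case_samples].mean(axis=1) + pseudo) / (
        tpm[ref_samples].mean(axis=1) + pseudo
    )


def enhancer_dose_response(
    links: pd.DataFrame,
    groups: pd.Series,
    gene_fc: pd.Series,
    direction: str = "gained",
    buckets: tuple = (1, 2, 3),
) -> pd.DataFrame:
    """Per-dose expression-FC distributions and adjacent rank-sum tests.

    Genes are bucketed by the number of linked gained (G1/G3 for EC, plus G2
    for LNC callers' output — here simply the groups labeled gained) or lost
    enhancers; the last bucket is open (>= buckets[-1]).  Reports each
    bucket's size and median FC and the two-sided Wilcoxon rank-sum p-value
    against the previous bucket (dose-0 genes form the baseline bucket).
    """
    wanted = {"G1", "G2", "G3"} if direction == "gained" else {"G4", "G5", "G6"}
    counts = (
        links.loc[links.index.intersection(groups.index[groups.isin(wanted)]), "gene_id"]
        .value_counts()
        .reindex(gene_fc.index)
        .fillna(0)
        .astype(int)
    )
    rows = []
    prev_values = gene_fc[counts == 0]
    for i, b in enumerate(buckets):
        if i == len(buckets) - 1:
            mask = counts >= b
            label = f">={b}"
        else:
            mask = counts == b
            label = str(b)
        values = gene_fc[mask]
        if values.empty:
            logger.warning("dose bucket %s empty, skipped", label)
            continue
        if prev_values.empty:
            p = float("nan")
        else:
            p = float(stats.mannwhitneyu(values, prev_values, alternative="two-sided").pvalue)
        rows.append((label, len(values), float(values.median()), p))
        prev_values = values
    return pd.DataFrame(rows, columns=["dose", "n_genes", "median_fc", "p_vs_previous"])


def correlate_signal_expression(
    links: pd.DataFrame,
    signal: pd.DataFrame,
    expression: pd.DataFrame,
    shared_samples: list[str],
) -> pd.Series:
    """Per-link Spearman correlation of element signal vs linked-gene expression.

    Requires >= 3 shared samples; constant vectors yield a missing value.
    """
    if len(shared_samples) < 3:
        raise ConfigError("need >= 3 shared samples for correlation")
    out = {}
    sig = signal[shared_samples]
    expr = expression[shared_samples]
    for element_id, gene_id in links["gene_id"].items():
        if element_id not in sig.index or gene_id not in expr.index:
            out[element_id] = np.nan
            continue
        x = sig.loc[element_id].to_numpy(dtype=float)
        y = expr.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[element_id] = np.nan
            continue
        out[element_id] = float(stats.spearmanr(x, y).statistic)
    return pd.Series(out, name="spearman_r")


@dataclass
class BiomarkerPanel:
    """Ordered biomarker genes for one subgroup (g1/g2/g3/g6)."""

    subgroup: str
    genes: list[str]
    table: pd.DataFrame  # gene_id-indexed: r, fc


def select_biomarkers(
    correlations: pd.Series,  # gene-level r for the subgroup's genes
    fold_changes: pd.Series,  # expression FC (linear) for the same genes
    subgroup: str,
    top_corr: int = 100,
    top_n: int = 10,
) -> BiomarkerPanel:
    """Top positively correlated genes re-ranked by expression fold change.

    Keeps r > 0, takes the ``top_corr`` genes by r, then ranks by FC in the
    subgroup's direction (descending for gain subgroups, ascending for the
    loss subgroup g6) and emits the top ``top_n``.  Ties break on gene_id.
    """
    if subgroup not in SUBGROUP_DIRECTION:
        raise ConfigError(f"unknown subgroup {subgroup!r}")
    frame = pd.DataFrame({"r": correlations, "fc": fold_changes}).dropna()
    frame.index.name = "gene_id"
    frame = frame[frame["r"] > 0]
    if frame.empty:
        logger.warning("select_biomarkers(%s): no positively correlated genes", subgroup)
        return BiomarkerPanel(subgroup, [], frame)
    frame = (
        frame.reset_index()
        .sort_values(["r", "gene_id"], ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
        .head(top_corr)
    )
    ascending = SUBGROUP_DIRECTION[subgroup] < 0
    frame = (
        frame.reset_index()
        .sort_values(["fc", "gene_id"], ascending=[ascending, True], kind="mergesort")
        .set_index("gene_id")
    )
    if len(frame) < top_n:
        logger.warning(
            "select_biomarkers(%s): only %d qualifying genes (< %d)",
            subgroup, len(frame), top_n,
        )
    panel = frame.head(top_n)
    return BiomarkerPanel(subgroup, list(panel.index), panel)


def classify_sample_signature(
    panels: Mapping[str, BiomarkerPanel], expression: pd.DataFrame
) -> pd.Series:
    """Assign each sample a tissue by its g1/g2/g3/g6 sign signature.

    Per sample: each subgroup's score is the mean z-scored (across samples)
    expression of its panel genes; the sign is "+" when the score exceeds the
    cohort mean of the subgroup score (the natural zero line of z-scored
    expression; a cohort *median* would force half the cohort positive per
    subgroup even when the truly-high tissue holds fewer than half the
    samples).  The sample gets the tissue whose signature pattern is at
    minimum Hamming distance; ties give "unclassified".
    """
    used = [sg for sg in ("g1", "g2", "g3", "g6") if sg in panels and panels[sg].genes]
    if not used:
        raise ConfigError("no non-empty panels supplied")
    zed = expression.sub(expression.mean(axis=1), axis=0)
    sd = expression.std(axis=1, ddof=1).replace(0, np.nan)
    zed = zed.div(sd, axis=0).fillna(0.0)
    scores = pd.DataFrame(
        {sg: zed.loc[zed.index.intersection(panels[sg].genes)].mean(axis=0) for sg in used}
    )
    signs = scores.gt(scores.mean(axis=0), axis=1)
    labels = {}
    for sample, row in signs.iterrows():
        dists = {
            tissue: sum(
                (1 if row[sg] else -1) != pattern[sg] for sg in used
            )
            for tissue, pattern in TISSUE_SIGNATURES.items()
        }
        best = min(dists.values())
        winners = [t for t, d in dists.items() if d == best]
        labels[sample] = winners[0] if len(winners) == 1 else "unclassified"
    return pd.Series(labels, name="tissue")


def classify_priming(
    groups: pd.Series,
    de_ec: pd.DataFrame,
    de_lnc: pd.DataFrame,
    links: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Primed genes: enhancer altered in EC, expression change only in LNC.

    pre_activated: genes linked to a common-gain (G3) enhancer, not
    upregulated in EC vs Nor, upregulated in LNC vs Nor.  pre_silenced:
    symmetric with common-loss (G6) and downregulation.
    """
    def linked_genes(group: str) -> set[str]:
        eids = groups.index[groups == group]
        return set(links.loc[links.index.intersection(eids), "gene_id"])

    def is_dir(table: pd.DataFrame, gene: str, direction: str) -> bool:
        return gene in table.index and table.at[gene, "direction"] == direction

    pre_activated = sorted(
        g
        for g in linked_genes("G3")
        if not is_dir(de_ec, g, "up") and is_dir(de_lnc, g, "up")
    )
    pre_silenced = sorted(
        g
        for g in linked_genes("G6")
        if not is_dir(de_ec, g, "down") and is_dir(de_lnc, g, "down")
    )
    return pre_activated, pre_silenced


def hypergeometric_enrichment(
    query: set[str], annotation_sets: Mapping[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set, BH-corrected."""
    if not universe:
        raise ConfigError("universe must be non-empty")
    if not set(query) <= set(universe):
        raise ConfigError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in annotation_sets.items():
        genes = set(genes) & set(universe)
        k = len(set(query) & genes)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N))
        rows.append((name, len(genes), k, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"]).set_index("set")
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def pca(matrix: pd.DataFrame, n_components: int = 2) -> dict:
    """PCA of samples (columns) over row-centered features via SVD.

    Sign convention: each component's largest-magnitude loading is positive,
    so repeated runs are identical.  Returns scores (samples x components),
    loadings (features x components), and variance proportions.
    """
    if matrix.shape[1] < 2:
        raise ConfigError("pca needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x features
    rank = int(np.linalg.matrix_rank(Xc))
    if n_components > rank:
        logger.warning("pca: n_components %d > rank %d, truncated", n_components, rank)
        n_components = rank
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :n_components] * S[:n_components]
    var = S**2 / (Xc.shape[0] - 1)
    proportions = var[:n_components] / var.sum()
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return {
        "scores": pd.DataFrame(scores, index=matrix.columns, columns=cols),
        "loadings": pd.DataFrame(Vt[:n_components].T, index=matrix.index, columns=cols),
        "variance_ratio": pd.Series(proportions, index=cols),
    }


def hierarchical_clustering(
    matrix: pd.DataFrame, k: int | None = None, metric: str = "correlation"
) -> dict:
    """Average-linkage clustering of sample columns.

    Distance is 1 - Pearson correlation (or Euclidean with
    ``metric="euclidean"``).  Returns the scipy linkage matrix, the sample
    order, and flat cluster labels when ``k`` is given.
    """
    if matrix.shape[1] < 2:
        raise ConfigError("clustering needs >= 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    if metric == "correlation":
        constant = X.std(axis=1) == 0
        if constant.any():
            bad = matrix.columns[constant][0]
            raise ConfigError(f"constant sample column {bad!r} under correlation distance")
    Z = linkage(X, method="average", metric=metric)
    out = {"linkage": Z, "samples": list(matrix.columns)}
    if k is not None:
        out["labels"] = pd.Series(
            fcluster(Z, t=k, criterion="maxclust"), index=matrix.columns, name="cluster"
        )
    return out
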