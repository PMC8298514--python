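"""Config-driven orchestration of the full analysis.

Stages run in dependency order — simulate -> elements -> diff -> se ->
integrate -> survive — each reading its inputs from and writing its outputs
to the run directory, so the CLI subcommands can also replay a single stage.
A manifest records every output file with a content digest; reruns with the
same config and seed reproduce the digests bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff_mod
from . import elements as el_mod
from . import integration as integ_mod
from . import superenhancer as se_mod
from . import survival as surv_mod
from .io_formats import (
    COMPARISONS,
    ConfigError,
    FormatError,
    read_matrix,
    read_peaks,
    read_sample_sheet,
    read_tss,
    write_bed,
    write_matrix,
)
from .synthetic import Cohort, CohortConfig, simulate_cohort, simulate_survival, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "elements", "diff", "se", "integrate", "survive")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults follow the published values."""

    # elements
    tss_window: int = 2000
    quantile_normalize: bool = True
    # differential calling
    epsilon: float = 0.1
    fc_min: float = 2.0
    diff_min: float = 0.5
    recurrence_min: dict = field(
        default_factory=lambda: {"EC_vs_Nor": 6, "LNC_vs_Nor": 6, "LNC_vs_EC": 6}
    )
    q_max: float = 0.1
    # super-enhancers
    stitch_distance: int = 12_500
    se_recurrence_min: int = 5
    se_fc_gain: float = 2.0
    se_fc_loss: float = 0.7
    se_gain_diff: float = 2.0
    se_loss_diff: float = -2.0
    # expression
    cpm_min: float = 1.0
    cpm_min_samples: int = 18
    de_fc_min: float = 1.5
    de_fdr_max: float = 0.05
    # biomarkers
    top_corr: int = 100
    top_n: int = 10
    # survival
    survival_timepoint: float = 24.0
    survival_n_per_group: int = 9
    survival_hazard_ratio: float = 2.0
    survival_follow_up: float = 24.0
    # run
    seed: int = 0
    #: CohortConfig overrides ({} = simulate with defaults); None (YAML
    #: ``simulate: null``) switches to file inputs via the ``inputs`` block.
    simulate: dict | None = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # paths, non-simulate mode

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.recurrence_min, int):
            cfg.recurrence_min = {c: cfg.recurrence_min for c in COMPARISONS}
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        return CohortConfig(**overrides)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _elements_from_bed(path: Path, tss_path: Path, window: int) -> list[el_mod.Element]:
    peaks = read_peaks(path, format="bed6")
    tss = read_tss(tss_path)
    classified = el_mod.classify_elements(peaks, tss, window=window)
    # keep the BED names as element ids when present
    out = []
    for el, peak in zip(classified, peaks):
        eid = peak.name or el.element_id
        out.append(el_mod.Element(el.interval, eid, el.element_class, el.nearest_tss_distance))
    return out


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> Cohort:
    cohort = simulate_cohort(cfg.cohort_config())
    write_cohort(cohort, outdir)
    surv = simulate_survival(
        cfg.survival_n_per_group,
        cfg.survival_hazard_ratio,
        cfg.survival_follow_up,
        seed=cfg.seed + 1,
    )
    surv.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    return cohort


def stage_elements(cfg: PipelineConfig, outdir: Path) -> None:
    bed = outdir / "elements.bed"
    tss_path = outdir / "tss.tsv"
    signal_path = outdir / "signal_rpkm.tsv"
    for path, what in ((bed, "element BED"), (tss_path, "TSS table"), (signal_path, "signal matrix")):
        if not path.exists():
            raise StageError("elements", f"missing {what}: {path}")
    elements = _elements_from_bed(bed, tss_path, cfg.tss_window)
    frame = pd.DataFrame(
        [
            (e.element_id, e.interval.chrom, e.interval.start, e.interval.end,
             e.element_class, e.nearest_tss_distance)
            for e in elements
        ],
        columns=["element_id", "chrom", "start", "end", "element_class", "nearest_tss_distance"],
    ).set_index("element_id")
    frame.to_csv(outdir / "elements_classified.tsv", sep="\t")
    write_bed([e for e in elements if e.element_class == el_mod.ENHANCER], outdir / "enhancers.bed")
    write_bed(
        [e for e in elements if e.element_class == el_mod.PROMOTER], outdir / "promoters.bed"
    )
    signal = read_matrix(signal_path)
    norm = el_mod.quantile_normalize(signal) if cfg.quantile_normalize else signal
    write_matrix(norm, outdir / "signal_normalized.tsv")


def _load_diff_inputs(outdir: Path):
    sheet = read_sample_sheet(outdir / "samples.tsv")
    signal = read_matrix(outdir / "signal_normalized.tsv")
    catalog = pd.read_csv(outdir / "elements_classified.tsv", sep="\t", index_col=0)
    enh_ids = catalog.index[catalog["element_class"] == el_mod.ENHANCER]
    return sheet, signal, catalog, enh_ids


def stage_diff(cfg: PipelineConfig, outdir: Path) -> None:
    sheet, signal, _, enh_ids = _load_diff_inputs(outdir)
    enh_signal = signal.loc[signal.index.intersection(enh_ids)]
    calls = {}
    for comparison in COMPARISONS:
        pairs = sheet.pairs(comparison)
        if not pairs:
            logger.warning("no complete pairs for %s, skipped", comparison)
            continue
        table = diff_mod.pairwise_change(enh_signal, pairs, comparison, epsilon=cfg.epsilon)
        rec_min = min(cfg.recurrence_min[comparison], len(pairs))
        call = diff_mod.call_differential(
            table, fc_min=cfg.fc_min, diff_min=cfg.diff_min, recurrence_min=rec_min
        )
        q, frac = diff_mod.paired_significance(enh_signal, pairs, call, q_max=cfg.q_max)
        call = call.join(q)
        call.attrs["fraction_q_passing"] = frac
        call.index.name = "element_id"
        call.to_csv(outdir / f"diff_{comparison}.tsv", sep="\t")
        calls[comparison] = call
    groups = diff_mod.assign_groups(calls["EC_vs_Nor"], calls["LNC_vs_Nor"])
    groups.index.name = "element_id"
    groups.to_frame().to_csv(outdir / "groups.tsv", sep="\t")


def stage_se(cfg: PipelineConfig, outdir: Path) -> None:
    sheet, signal, catalog, enh_ids = _load_diff_inputs(outdir)
    enh_rows = catalog.loc[enh_ids]
    elements = [
        el_mod.Element(
            el_mod.GenomicInterval(r.chrom, r.start, r.end), eid, el_mod.ENHANCER,
            int(r.nearest_tss_distance),
        )
        for eid, r in enh_rows.iterrows()
    ]
    regions = se_mod.stitch_enhancers(elements, stitch_distance=cfg.stitch_distance)
    lengths = pd.Series(
        {e.element_id: e.interval.length for e in elements}, name="length"
    )
    sem = se_mod.se_signal(regions, signal.loc[[e.element_id for e in elements]], lengths)
    cat_rows = []
    for region in regions:
        cat_rows.append(
            (region.region_id, region.interval.chrom, region.interval.start,
             region.interval.end, ",".join(region.constituents))
        )
    catalog_frame = pd.DataFrame(
        cat_rows, columns=["se_id", "chrom", "start", "end", "constituents"]
    ).set_index("se_id")
    for tissue in ("Nor", "EC", "LNC"):
        samples = sheet.samples_for(tissue)
        if not samples:
            continue
        ranked = se_mod.rank_superenhancers(sem[samples].mean(axis=1))
        catalog_frame[f"rank_{tissue}"] = ranked["rank"]
        catalog_frame[f"signal_{tissue}"] = ranked["signal"]
        catalog_frame[f"is_se_{tissue}"] = ranked["is_se"]
    catalog_frame.to_csv(outdir / "se_catalog.tsv", sep="\t", float_format="%.6g")
    write_matrix(sem, outdir / "se_signal.tsv")
    for comparison in ("EC_vs_Nor", "LNC_vs_Nor"):
        pairs = sheet.pairs(comparison)
        if not pairs:
            continue
        case_t, ref_t = COMPARISONS[comparison]
        mean_calls = se_mod.differential_se_mean(
            sem, sheet.samples_for(case_t), sheet.samples_for(ref_t),
            gain_diff=cfg.se_gain_diff, loss_diff=cfg.se_loss_diff,
        )
        paired_calls = se_mod.differential_se_paired(
            sem, pairs, recurrence_min=min(cfg.se_recurrence_min, len(pairs)),
            fc_gain=cfg.se_fc_gain, fc_loss=cfg.se_fc_loss, epsilon=cfg.epsilon,
        )
        combined = se_mod.combine_se_calls(
            mean_calls, paired_calls, fc_gain=cfg.se_fc_gain, fc_loss=cfg.se_fc_loss,
            gain_diff=cfg.se_gain_diff, loss_diff=cfg.se_loss_diff,
        )
        combined.index.name = "se_id"
        combined.to_csv(outdir / f"se_calls_{comparison}.tsv", sep="\t", float_format="%.6g")


def stage_integrate(cfg: PipelineConfig, outdir: Path) -> None:
    sheet = read_sample_sheet(outdir / "samples.tsv")
    signal = read_matrix(outdir / "signal_normalized.tsv")
    tpm = read_matrix(outdir / "expression_tpm.tsv")
    counts = read_matrix(outdir / "expression_counts.tsv")
    catalog = pd.read_csv(outdir / "elements_classified.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(outdir / "groups.tsv", sep="\t", index_col=0)["group"]
    tss = read_tss(outdir / "tss.tsv")
    elements = [
        el_mod.Element(
            el_mod.GenomicInterval(r.chrom, r.start, r.end), eid, r.element_class,
            int(r.nearest_tss_distance),
        )
        for eid, r in catalog.iterrows()
    ]
    links = integ_mod.assign_nearest_gene(elements, tss)
    links.to_csv(outdir / "links.tsv", sep="\t")

    kept = integ_mod.cpm_filter(
        counts, cpm_min=cfg.cpm_min, min_samples=min(cfg.cpm_min_samples, counts.shape[1])
    )
    log_expr = np.log2(tpm.loc[kept] + 1.0)
    shared = [s for s in sheet.samples if s in tpm.columns]

    de_tables = {}
    fcs = {}
    for comparison in ("EC_vs_Nor", "LNC_vs_Nor"):
        case_t, ref_t = COMPARISONS[comparison]
        case = [s for s in sheet.samples_for(case_t) if s in tpm.columns]
        ref = [s for s in sheet.samples_for(ref_t) if s in tpm.columns]
        de = integ_mod.de_test(
            log_expr, case, ref, fc_min=cfg.de_fc_min, fdr_max=cfg.de_fdr_max
        )
        de.index.name = "gene_id"
        de.to_csv(outdir / f"de_{comparison}.tsv", sep="\t", float_format="%.6g")
        de_tables[comparison] = de
        fcs[comparison] = integ_mod.expression_fc(tpm, case, ref)

    for direction in ("gained", "lost"):
        dose = integ_mod.enhancer_dose_response(
            links, groups, fcs["EC_vs_Nor"], direction=direction
        )
        dose.to_csv(outdir / f"dose_{direction}.tsv", sep="\t", index=False, float_format="%.6g")

    corr = integ_mod.correlate_signal_expression(links, signal, tpm, shared)
    panels = {}
    panel_rows = []
    for group, subgroup in integ_mod.SUBGROUP_OF_GROUP.items():
        eids = groups.index[groups == group]
        sub_links = links.loc[links.index.intersection(eids)]
        gene_r = (
            pd.DataFrame({"gene_id": sub_links["gene_id"], "r": corr.loc[sub_links.index]})
            .groupby("gene_id")["r"].max()
        )
        comparison = "LNC_vs_Nor" if subgroup == "g2" else "EC_vs_Nor"
        panel = integ_mod.select_biomarkers(
            gene_r, fcs[comparison].reindex(gene_r.index), subgroup,
            top_corr=cfg.top_corr, top_n=cfg.top_n,
        )
        panels[subgroup] = panel
        for rank, gene in enumerate(panel.genes, start=1):
            panel_rows.append(
                (subgroup, rank, gene, panel.table.at[gene, "r"], panel.table.at[gene, "fc"])
            )
    pd.DataFrame(
        panel_rows, columns=["subgroup", "rank", "gene_id", "r", "fc"]
    ).to_csv(outdir / "biomarker_panels.tsv", sep="\t", index=False, float_format="%.6g")

    labels = integ_mod.classify_sample_signature(panels, np.log2(tpm + 1.0))
    truth_tissue = sheet.frame.set_index("sample_id")["tissue"]
    out = labels.to_frame("assigned")
    out["tissue"] = truth_tissue.reindex(out.index)
    out.index.name = "sample_id"
    out.to_csv(outdir / "signature_assignments.tsv", sep="\t")

    pre_act, pre_sil = integ_mod.classify_priming(
        groups, de_tables["EC_vs_Nor"], de_tables["LNC_vs_Nor"], links
    )
    pd.DataFrame(
        [("pre_activated", g) for g in pre_act] + [("pre_silenced", g) for g in pre_sil],
        columns=["priming", "gene_id"],
    ).to_csv(outdir / "priming.tsv", sep="\t", index=False)


def stage_survive(cfg: PipelineConfig, outdir: Path) -> None:
    path = outdir / "survival.tsv"
    if not path.exists():
        raise StageError("survive", f"missing survival records: {path}")
    records = pd.read_csv(path, sep="\t")
    summary = {}
    for group in sorted(records["group"].unique()):
        curve = surv_mod.km_estimate(records[records["group"] == group])
        surv_mod.km_curve_frame(curve).to_csv(
            outdir / f"km_{group}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        summary[f"rate_{group}"] = surv_mod.survival_at(curve, cfg.survival_timepoint)
    groups = sorted(records["group"].unique())
    if len(groups) == 2:
        stat, p = surv_mod.logrank(records, groups[0], groups[1])
        summary["logrank_stat"], summary["logrank_p"] = stat, p
    (outdir / "survival_summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n"
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "elements": stage_elements,
    "diff": stage_diff,
    "se": stage_se,
    "integrate": stage_integrate,
    "survive": stage_survive,
}


def _stage_inputs(cfg: PipelineConfig, outdir: Path) -> None:
    """Non-simulate mode: copy/validate the configured input files into place."""
    required = {
        "elements_bed": "elements.bed",
        "tss": "tss.tsv",
        "signal": "signal_rpkm.tsv",
        "sample_sheet": "samples.tsv",
    }
    optional = {
        "expression_tpm": "expression_tpm.tsv",
        "expression_counts": "expression_counts.tsv",
        "survival": "survival.tsv",
    }
    for key, dest in {**required, **optional}.items():
        src = cfg.inputs.get(key)
        if src is None:
            if key in required:
                raise StageError("elements", f"missing input {key!r} in non-simulate mode")
            continue
        src = Path(src)
        if not src.exists():
            raise StageError("elements", f"input file not found: {src}")
        (outdir / dest).write_bytes(src.read_bytes())


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the requested stages and write an output manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ConfigError(f"unknown stage {stage!r}")
    for stage in stages:
        if stage == "simulate":
            if cfg.simulate is None:
                _stage_inputs(cfg, outdir)
                continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except (StageError, ConfigError, FormatError):
            raise
        except Exception as exc:  # pragma: no cover - defensive wrap
            raise StageError(stage, str(exc)) from exc
    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "parameters": asdict(cfg),
        "seed": cfg.seed,
        "stages": list(stages),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
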