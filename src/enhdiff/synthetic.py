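"""Synthetic paired Nor/EC/LNC cohorts with planted, labeled effects.

The generator emulates the structure of a paired H3K27ac tumor cohort: ~10
patients contribute a normal (Nor) and primary tumor (EC) profile each, a
subset additionally a lymph-node metastasis (LNC) profile, over thousands of
consensus elements.  A configurable number of enhancers carry planted
recurrent gains or losses in one or both tumor tissues (the six classes
G1..G6), applied multiplicatively on RPKM in a fixed-size subset of patient
pairs; genes linked to planted enhancers shift additively on log2 expression,
sign-matched and proportional to the number of altered enhancers (dose).

Conventions (see docs/methods.md): baseline element RPKM is lognormal
(meanlog 1.0, sdlog 0.8) floored at 0.5 RPKM; measurement noise multiplies
the signal by 2**eps with eps ~ Normal(0, noise_sd), i.e. ``noise_sd`` is in
log2 units; the number of carrier pairs per planted element is
ceil(recurrence_fraction * n_pairs).  All randomness derives from a single
seed split into named substreams, so adding one component never perturbs
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import ENHANCER, PROMOTER, Element
from .io_formats import (
    ConfigError,
    GenomicInterval,
    SampleSheet,
    TssRecord,
    write_bed,
    write_matrix,
    write_sample_sheet,
    write_tss,
)

GAIN_CLASSES = {"G1": ("EC",), "G2": ("LNC",), "G3": ("EC", "LNC")}
LOSS_CLASSES = {"G4": ("EC",), "G5": ("LNC",), "G6": ("EC", "LNC")}
PLANT_ORDER = ("G1", "G2", "G3", "G4", "G5", "G6")

_LOCUS_SIZE = 200_000
_GENES_PER_CHROM = 500
_TSS_OFFSET = 100_000


@dataclass
class CohortConfig:
    """Study conditions for a simulated paired cohort."""

    n_patients: int = 10
    n_lnc_patients: int = 8
    n_elements: int = 5000
    promoter_fraction: float = 0.3
    n_gained_ec: int = 50  # G1
    n_gained_lnc: int = 50  # G2
    n_common_gained: int = 100  # G3
    n_lost_ec: int = 50  # G4
    n_lost_lnc: int = 50  # G5
    n_common_lost: int = 100  # G6
    effect_fc: float = 4.0
    recurrence_fraction: float = 0.8
    noise_sd: float = 0.3  # log2 units
    expr_coupling: float = 1.0  # log2 shift per linked altered enhancer
    expr_noise_sd: float = 0.5  # log2 units
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 0.8
    baseline_floor: float = 0.5
    #: planted-loss elements draw baseline from the active tail: an enhancer
    #: can only be lost where it was active in the reference tissue.
    loss_baseline_floor: float = 2.0
    expr_baseline_mean: float = 5.0  # log2 TPM-scale
    expr_baseline_sd: float = 1.5
    dose_pattern: tuple[int, ...] = (1, 2, 3)
    background_per_gene: int = 2
    seed: int = 0

    @property
    def planted_counts(self) -> dict[str, int]:
        return {
            "G1": self.n_gained_ec,
            "G2": self.n_gained_lnc,
            "G3": self.n_common_gained,
            "G4": self.n_lost_ec,
            "G5": self.n_lost_lnc,
            "G6": self.n_common_lost,
        }

    def validate(self) -> None:
        if not (1 <= self.n_lnc_patients <= self.n_patients):
            raise ConfigError("need 1 <= n_lnc_patients <= n_patients")
        if not (0 <= self.promoter_fraction < 1):
            raise ConfigError("promoter_fraction must be in [0, 1)")
        n_enh = self.n_elements - int(round(self.promoter_fraction * self.n_elements))
        if sum(self.planted_counts.values()) > n_enh:
            raise ConfigError("planted counts exceed the number of enhancer elements")
        if not (0 < self.recurrence_fraction <= 1):
            raise ConfigError("recurrence_fraction must be in (0, 1]")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        if self.effect_fc <= 1:
            raise ConfigError("effect_fc must exceed 1")


@dataclass
class CohortTruth:
    """Ground truth for every element and gene of a simulated cohort."""

    element_class: pd.Series  # element_id -> G1..G6 or "unaltered"
    linked_gene: pd.Series  # element_id -> gene_id
    carriers: dict[str, pd.DataFrame]  # tissue -> bool (element x patient)
    expression_shift: pd.DataFrame  # gene x {EC, LNC} log2 shift

    def planted(self, classes: tuple[str, ...] | None = None) -> pd.Index:
        mask = self.element_class != "unaltered"
        if classes is not None:
            mask &= self.element_class.isin(classes)
        return self.element_class.index[mask]


@dataclass
class Cohort:
    """A simulated cohort: elements, annotation, matrices, sheet, and truth."""

    config: CohortConfig
    elements: list[Element]
    tss: list[TssRecord]
    signal: pd.DataFrame  # raw input-subtracted RPKM, elements x samples
    expression_counts: pd.DataFrame  # genes x samples, integer counts
    expression_tpm: pd.DataFrame  # genes x samples
    sample_sheet: SampleSheet
    truth: CohortTruth

    @property
    def enhancers(self) -> list[Element]:
        return [e for e in self.elements if e.element_class == ENHANCER]


def _gene_coords(gene_index: int) -> tuple[str, int]:
    chrom = f"chr{gene_index // _GENES_PER_CHROM + 1}"
    tss = (gene_index % _GENES_PER_CHROM) * _LOCUS_SIZE + _TSS_OFFSET
    return chrom, tss


def _enhancer_interval(chrom: str, tss: int, slot: int) -> GenomicInterval:
    start = tss + 4000 + 7000 * slot
    return GenomicInterval(chrom, start, start + 1000)


_PROMOTER_SLOTS = ((-500, 500), (-1900, -900), (900, 1900))


def _promoter_interval(chrom: str, tss: int, slot: int) -> GenomicInterval:
    lo, hi = _PROMOTER_SLOTS[slot % len(_PROMOTER_SLOTS)]
    return GenomicInterval(chrom, tss + lo, tss + hi)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a paired Nor/EC/LNC cohort with planted differential enhancers."""
    config.validate()
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("carriers", "signal", "expression"),
            np.random.SeedSequence(config.seed).spawn(3),
        )
    }

    n_prom = int(round(config.promoter_fraction * config.n_elements))
    n_enh = config.n_elements - n_prom

    # --- deterministic layout: genes hold planted enhancers per dose cycle,
    # then background enhancers, then promoter elements round-robin.
    elements: list[Element] = []
    linked_gene: list[str] = []
    classes: list[str] = []
    gene_slots: dict[int, int] = {}  # gene index -> next free enhancer slot

    def new_gene() -> int:
        g = len(gene_slots)
        gene_slots[g] = 0
        return g

    width = len(str(config.n_elements))

    def add_enhancer(gene: int, cls: str) -> None:
        chrom, tss = _gene_coords(gene)
        slot = gene_slots[gene]
        gene_slots[gene] = slot + 1
        eid = f"el{len(elements):0{width}d}"
        iv = _enhancer_interval(chrom, tss, slot)
        elements.append(Element(iv, eid, ENHANCER, iv.start - tss))
        linked_gene.append(f"gene{gene:05d}")
        classes.append(cls)

    remaining = dict(config.planted_counts)
    for cls in PLANT_ORDER:
        di = 0
        while remaining[cls] > 0:
            dose = min(config.dose_pattern[di % len(config.dose_pattern)], remaining[cls])
            gene = new_gene()
            for _ in range(dose):
                add_enhancer(gene, cls)
            remaining[cls] -= dose
            di += 1
    n_planted = len(elements)
    while len(elements) < n_enh:
        gene = new_gene()
        for _ in range(min(config.background_per_gene, n_enh - len(elements))):
            add_enhancer(gene, "unaltered")
    n_genes = len(gene_slots)
    for k in range(n_prom):
        gene = k % n_genes
        chrom, tss = _gene_coords(gene)
        eid = f"el{len(elements):0{width}d}"
        iv = _promoter_interval(chrom, tss, k // n_genes)
        elements.append(Element(iv, eid, PROMOTER, min(abs(tss - iv.start), abs(tss - (iv.end - 1)))))
        linked_gene.append(f"gene{gene:05d}")
        classes.append("unaltered")

    element_ids = [e.element_id for e in elements]
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    tss_records = []
    for g in range(n_genes):
        chrom, tss = _gene_coords(g)
        tss_records.append(TssRecord(gene_ids[g], chrom, tss, "+"))

    # --- sample sheet
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    rows = []
    for i, patient in enumerate(patients):
        tissues = ["Nor", "EC"] + (["LNC"] if i < config.n_lnc_patients else [])
        for tissue in tissues:
            rows.append((f"{patient}_{tissue}", patient, tissue))
    sheet = SampleSheet(pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue"]))
    samples = sheet.samples

    # --- carrier pairs per planted element (per affected tissue)
    class_arr = pd.Series(classes, index=element_ids, name="true_class")
    carrier_frames: dict[str, pd.DataFrame] = {}
    rng_c = streams["carriers"]
    for tissue, n_avail in (("EC", config.n_patients), ("LNC", config.n_lnc_patients)):
        carriers = pd.DataFrame(
            False, index=element_ids, columns=patients[:n_avail]
        )
        n_carry = math.ceil(config.recurrence_fraction * n_avail)
        for eid, cls in class_arr.items():
            if cls == "unaltered":
                continue
            affected = GAIN_CLASSES.get(cls) or LOSS_CLASSES.get(cls)
            if tissue in affected:
                chosen = rng_c.choice(n_avail, size=n_carry, replace=False)
                carriers.iloc[carriers.index.get_loc(eid), chosen] = True
        carrier_frames[tissue] = carriers

    # --- signal matrix
    rng_s = streams["signal"]
    baseline = np.exp(
        rng_s.normal(config.baseline_meanlog, config.baseline_sdlog, size=len(elements))
    )
    baseline = np.maximum(baseline, config.baseline_floor)
    is_loss = class_arr.isin(list(LOSS_CLASSES)).to_numpy()
    baseline[is_loss] = np.maximum(baseline[is_loss], config.loss_baseline_floor)
    signal = pd.DataFrame(0.0, index=element_ids, columns=samples)
    mult = {t: pd.DataFrame(1.0, index=element_ids, columns=patients) for t in ("EC", "LNC")}
    for cls, tissues in GAIN_CLASSES.items():
        for t in tissues:
            sel = class_arr == cls
            mult[t].loc[sel] = np.where(
                carrier_frames[t].loc[sel].reindex(columns=patients, fill_value=False),
                config.effect_fc,
                1.0,
            )
    for cls, tissues in LOSS_CLASSES.items():
        for t in tissues:
            sel = class_arr == cls
            mult[t].loc[sel] = np.where(
                carrier_frames[t].loc[sel].reindex(columns=patients, fill_value=False),
                1.0 / config.effect_fc,
                1.0,
            )
    for sample_id, patient, tissue in sheet.frame.itertuples(index=False):
        m = mult[tissue][patient].to_numpy() if tissue in mult else 1.0
        noise = (
            np.exp2(rng_s.normal(0.0, config.noise_sd, size=len(elements)))
            if config.noise_sd > 0
            else 1.0
        )
        signal[sample_id] = baseline * m * noise

    # --- expression, coupled to planted enhancers (dose-additive on log2)
    rng_e = streams["expression"]
    gene_of = pd.Series(linked_gene, index=element_ids)
    shift = pd.DataFrame(0.0, index=gene_ids, columns=["EC", "LNC"])
    for cls, tissues in GAIN_CLASSES.items():
        for t in tissues:
            counts = gene_of[class_arr == cls].value_counts()
            shift.loc[counts.index, t] += config.expr_coupling * counts
    for cls, tissues in LOSS_CLASSES.items():
        for t in tissues:
            counts = gene_of[class_arr == cls].value_counts()
            shift.loc[counts.index, t] -= config.expr_coupling * counts
    expr_base = rng_e.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=n_genes)
    log2_expr = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    for sample_id, patient, tissue in sheet.frame.itertuples(index=False):
        s = shift[tissue].to_numpy() if tissue in ("EC", "LNC") else 0.0
        eps = (
            rng_e.normal(0.0, config.expr_noise_sd, size=n_genes)
            if config.expr_noise_sd > 0
            else 0.0
        )
        log2_expr[sample_id] = expr_base + s + eps
    linear = np.exp2(log2_expr)
    tpm = linear / linear.sum(axis=0) * 1e6
    counts_mat = pd.DataFrame(
        rng_e.poisson(linear.to_numpy()), index=gene_ids, columns=samples
    )

    truth = CohortTruth(
        element_class=class_arr,
        linked_gene=gene_of,
        carriers=carrier_frames,
        expression_shift=shift,
    )
    return Cohort(
        config=config,
        elements=elements,
        tss=tss_records,
        signal=signal,
        expression_counts=counts_mat,
        expression_tpm=tpm,
        sample_sheet=sheet,
        truth=truth,
    )


def simulate_survival(
    n_per_group: int,
    hazard_ratio: float,
    follow_up: float,
    seed: int = 0,
    baseline_hazard: float = 0.03,
) -> pd.DataFrame:
    """Exponential survival with administrative censoring at ``follow_up``.

    The "high" group's hazard is ``hazard_ratio`` times the "low" group's
    baseline (per-month) hazard.  Returns a frame with columns
    (subject_id, time_months, event, group).
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    if hazard_ratio <= 0:
        raise ConfigError("hazard_ratio must be positive")
    if follow_up < 0:
        raise ConfigError("follow_up must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for group, hazard in (("low", baseline_hazard), ("high", baseline_hazard * hazard_ratio)):
        times = rng.exponential(1.0 / hazard, size=n_per_group)
        for i, t in enumerate(times):
            event = bool(t <= follow_up)
            rows.append((f"{group}{i + 1:03d}", min(t, follow_up), event, group))
    return pd.DataFrame(rows, columns=["subject_id", "time_months", "event", "group"])


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk in the pipeline's external formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "elements_bed": outdir / "elements.bed",
        "tss": outdir / "tss.tsv",
        "signal": outdir / "signal_rpkm.tsv",
        "expression_counts": outdir / "expression_counts.tsv",
        "expression_tpm": outdir / "expression_tpm.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_bed(cohort.elements, paths["elements_bed"])
    write_tss(cohort.tss, paths["tss"])
    write_matrix(cohort.signal, paths["signal"])
    write_matrix(cohort.expression_counts, paths["expression_counts"])
    write_matrix(cohort.expression_tpm, paths["expression_tpm"])
    write_sample_sheet(cohort.sample_sheet, paths["sample_sheet"])
    truth_frame = pd.DataFrame(
        {"true_class": cohort.truth.element_class, "linked_gene": cohort.truth.linked_gene}
    )
    truth_frame.index.name = "element_id"
    truth_frame.to_csv(paths["truth"], sep="\t")
    return paths
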