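"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally.  The only
1-based dialect accepted is a minimal GTF-derived gene-span TSV, whose reader
converts on ingest.  Missing values in numeric matrices are errors, never
imputed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("Nor", "EC", "LNC")

#: comparison name -> (case tissue, reference tissue)
COMPARISONS = {
    "EC_vs_Nor": ("EC", "Nor"),
    "LNC_vs_Nor": ("LNC", "Nor"),
    "LNC_vs_EC": ("LNC", "EC"),
}

#: tab-separated matrix float format, shared by every writer so that
#: read_matrix(write_matrix(M)) round-trips byte-identically.
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A malformed input file (bad column, coordinate, or cell)."""


class ConfigError(ValueError):
    """An invalid parameter or configuration value."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    summit: int | None = None  # absolute coordinate, narrowPeak only

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: a single strand-aware base position."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise FormatError(f"TSS for {self.gene_id} is negative")
        if not self.gene_id:
            raise FormatError("gene_id must be non-empty")


@dataclass
class SampleSheet:
    """Cohort sample sheet: sample_id, patient_id, tissue in {Nor, EC, LNC}."""

    frame: pd.DataFrame  # columns: sample_id, patient_id, tissue

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "tissue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample_id: {sorted(set(dups))}")
        bad = set(self.frame["tissue"]) - set(TISSUES)
        if bad:
            raise FormatError(f"unknown tissue values: {sorted(bad)} (expect {TISSUES})")
        if self.frame.duplicated(subset=["patient_id", "tissue"]).any():
            raise FormatError("a (patient_id, tissue) combination occurs more than once")
        # canonical row order: by patient then tissue, independent of input order
        self.frame = (
            self.frame.assign(_t=self.frame["tissue"].map({t: i for i, t in enumerate(TISSUES)}))
            .sort_values(["patient_id", "_t"], kind="mergesort")
            .drop(columns="_t")
            .reset_index(drop=True)
        )

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_for(self, tissue: str) -> list[str]:
        return list(self.frame.loc[self.frame["tissue"] == tissue, "sample_id"])

    def pairs(self, comparison: str) -> list[tuple[str, str, str]]:
        """Complete patient pairs as (patient_id, case_sample, ref_sample)."""
        if comparison not in COMPARISONS:
            raise ConfigError(f"unknown comparison {comparison!r}")
        case_t, ref_t = COMPARISONS[comparison]
        by_patient: dict[str, dict[str, str]] = {}
        for row in self.frame.itertuples(index=False):
            by_patient.setdefault(row.patient_id, {})[row.tissue] = row.sample_id
        out = []
        for patient in sorted(by_patient):
            have = by_patient[patient]
            if case_t in have and ref_t in have:
                out.append((patient, have[case_t], have[ref_t]))
            else:
                logger.warning(
                    "patient %s incomplete for %s (has %s)", patient, comparison, sorted(have)
                )
        return out


_FORMAT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_peaks(path: str | Path, format: str = "bed3") -> list[GenomicInterval]:
    """Read peak calls from BED3/BED6 or ENCODE narrowPeak.

    narrowPeak summit offsets (column 10) are retained as absolute coordinates
    on the interval; an offset of -1 (not available) maps to ``summit=None``.
    Input order is preserved.
    """
    if format not in _FORMAT_COLUMNS:
        raise ConfigError(f"unknown peak format {format!r} (expect {sorted(_FORMAT_COLUMNS)})")
    ncol = _FORMAT_COLUMNS[format]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise FormatError(
                    f"{path}: expected >= {ncol} columns for {format} at line {lineno}, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            name = fields[3] if ncol >= 6 and fields[3] != "." else None
            strand = fields[5] if ncol >= 6 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}: invalid strand {strand!r} at line {lineno}")
            summit = None
            if format == "narrowPeak":
                offset = int(fields[9])
                summit = start + offset if offset >= 0 else None
            out.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name, summit=summit)
            )
    return out


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a sample sheet TSV (sample_id, patient_id, tissue)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric TSV matrix (row ids in the first column).

    Missing or non-numeric cells and duplicate row ids are errors.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()]
        raise FormatError(f"{path}: duplicate row id {dups[0]!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise FormatError(
            f"{path}: non-numeric cell at row {frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    numeric.index.name = frame.index.name
    return numeric


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as TSV with the package-wide float format."""
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a TSS TSV (gene_id, chrom, tss, strand); 0-based positions."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: TSS table missing columns {sorted(missing)}")
    if frame["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id in TSS table")
    return [
        TssRecord(row.gene_id, row.chrom, int(row.tss), row.strand)
        for row in frame.itertuples(index=False)
    ]


def write_tss(records: Sequence[TssRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.gene_id, r.chrom, r.tss, r.strand) for r in records],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    frame.to_csv(path, sep="\t", index=False)


def tss_from_gene_spans(
    spans: Iterable[tuple[str, str, int, int, str]], one_based: bool = False
) -> list[TssRecord]:
    """Derive TSSs from (gene_id, chrom, start, end, strand) gene spans.

    The TSS of a "-"-strand gene is the span's last base (end - 1 in half-open
    coordinates).  ``one_based=True`` converts GTF-style inclusive coordinates.
    """
    out = []
    for gene_id, chrom, start, end, strand in spans:
        if one_based:
            start, end = start - 1, end  # GTF [start, end] inclusive -> half-open
        tss = start if strand != "-" else end - 1
        out.append(TssRecord(gene_id, chrom, tss, strand))
    return out


def write_bed(
    elements: Sequence, path: str | Path, score_scale: float = 100.0
) -> None:
    """Write scored intervals as BED6, sorted by (chrom, start, end).

    Accepts any objects with ``interval`` + ``element_id`` attributes (and an
    optional ``mean_signal``), or bare :class:`GenomicInterval` objects.  The
    BED score is ``mean_signal * score_scale`` clipped to [0, 1000].
    """
    rows = []
    for el in elements:
        iv = getattr(el, "interval", el)
        name = getattr(el, "element_id", None) or iv.name or "."
        signal = getattr(el, "mean_signal", 0.0) or 0.0
        score = int(min(1000, max(0, round(signal * score_scale))))
        rows.append((iv.chrom, iv.start, iv.end, name, score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    buf = io.StringIO()
    for chrom, start, end, name, score in rows:
        buf.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")
    Path(path).write_text(buf.getvalue())
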