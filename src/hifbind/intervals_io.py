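"""Domain types and readers/writers for the genomic file formats the pipeline consumes.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based inclusive) is converted on ingestion and never stored. Chromosome
names are opaque strings; no genome build is assumed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

Strand = Literal["+", "-", "."]

VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """A file violated the declared dialect; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for different chromosomes or adjacency."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-seq interval; ``height`` is the signal value (pileup units)."""

    interval: GenomicInterval
    name: str
    height: float
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak {self.name}: height must be >= 0")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def anchor(self) -> int:
        """Summit when present, else the floor midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class TssRecord:
    """A gene transcription start site, the anchor for promoter windows."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.biotype not in ("coding", "lncRNA", "other"):
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    """Linear fold change of one gene in one condition over its control."""

    gene_id: str
    condition: str
    fold_change: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(
                f"{self.gene_id}/{self.condition}: fold_change must be > 0"
            )


# ---------------------------------------------------------------------------
# Peaks: BED6 and ENCODE narrowPeak
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, format: str = "narrowpeak") -> list[Peak]:
    """Read a peak file in BED6 or ENCODE narrowPeak dialect.

    narrowPeak column 7 (signalValue) becomes the height and column 10 the
    summit offset (-1 meaning absent); in BED6 the score column is used as a
    height fallback.
    """
    if format not in ("bed6", "narrowpeak"):
        raise ValueError(f"unknown peak format {format!r}")
    min_cols = 6 if format == "bed6" else 10
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(cols)}"
                )
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name = cols[3] if cols[3] != "." else f"peak_{lineno}"
                strand = cols[5] if cols[5] in ("+", "-") else "."
                if format == "narrowpeak":
                    height = float(cols[6])
                    offset = int(cols[9])
                    summit = start + offset if offset >= 0 else None
                else:
                    height = float(cols[4])
                    summit = None
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, strand), name, height, summit)
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, format: str = "narrowpeak") -> None:
    """Write peaks in BED6 or narrowPeak; inverse of :func:`read_peaks`."""
    if format not in ("bed6", "narrowpeak"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if format == "narrowpeak":
                offset = p.summit - iv.start if p.summit is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                    f"\t{p.height:g}\t-1\t-1\t{offset}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.height:g}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# TSS tables: tabular and GTF
# ---------------------------------------------------------------------------

_LNCRNA_SYNONYMS = {"lncrna", "lincrna", "lnc_rna"}

TSS_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tss", "biotype"]


def _map_biotype(raw: str) -> str:
    low = raw.lower()
    if low in _LNCRNA_SYNONYMS:
        return "lncRNA"
    if low == "protein_coding" or low == "coding":
        return "coding"
    return "other"


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    # GTF2.2 attribute field: key "value"; pairs; trailing semicolon optional
    out: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_tss_table(path: str | Path, format: str = "tabular") -> list[TssRecord]:
    """Read TSS records from a TAB-separated table (0-based) or a GTF (1-based).

    For GTF gene records the TSS is the 5' end in transcription orientation,
    converted to 0-based: start-1 on the + strand, end-1 on the - strand.
    Records without a usable strand are dropped with a logged warning count.
    """
    if format == "tabular":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
        missing = set(TSS_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        records = [
            TssRecord(r.gene_id, r.symbol, r.chrom, r.strand, int(r.tss), r.biotype)
            for r in df.itertuples(index=False)
        ]
    elif format == "gtf":
        records = []
        dropped = 0
        seen: set[str] = set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                if not raw.strip() or raw.startswith("#"):
                    continue
                cols = raw.rstrip("\n").split("\t")
                if len(cols) < 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
                chrom, _, feature, start, end, _, strand, _, attrs = cols[:9]
                if feature != "gene":
                    continue
                if strand not in ("+", "-"):
                    dropped += 1
                    continue
                a = _parse_gtf_attributes(attrs)
                gene_id = a.get("gene_id")
                if not gene_id or gene_id in seen:
                    dropped += 1
                    continue
                seen.add(gene_id)
                tss = int(start) - 1 if strand == "+" else int(end) - 1
                biotype = _map_biotype(a.get("gene_biotype", a.get("gene_type", "other")))
                records.append(
                    TssRecord(gene_id, a.get("gene_name", gene_id), chrom, strand, tss, biotype)
                )
        if dropped:
            log.warning("read_tss_table: dropped %d GTF records (no strand/id)", dropped)
    else:
        raise ValueError(f"unknown TSS format {format!r}")
    ids = [r.gene_id for r in records]
    if len(ids) != len(set(ids)):
        raise FormatError(f"{path}: duplicate gene_id in TSS table")
    return records


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSS_COLUMNS)
        for r in records:
            w.writerow([r.gene_id, r.symbol, r.chrom, r.strand, r.tss, r.biotype])


# ---------------------------------------------------------------------------
# Expression tables, GMT collections, FASTA
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read fold changes from long form (gene_id/condition/fold_change) or wide
    form (gene_id plus one column per condition); wide form is auto-detected
    and melted."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    if {"condition", "fold_change"} <= set(df.columns):
        long_df = df[["gene_id", "condition", "fold_change"]]
    else:
        long_df = df.melt(id_vars="gene_id", var_name="condition", value_name="fold_change")
    dup = long_df.duplicated(subset=["gene_id", "condition"])
    if dup.any():
        first = long_df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (gene, condition) pair ({first.gene_id}, {first.condition})"
        )
    if (long_df["fold_change"] <= 0).any():
        bad = long_df[long_df["fold_change"] <= 0].iloc[0]
        raise FormatError(
            f"{path}: fold_change must be > 0 (gene {bad.gene_id}, condition {bad.condition})"
        )
    return [
        ExpressionRecord(str(r.gene_id), str(r.condition), float(r.fold_change))
        for r in long_df.itertuples(index=False)
    ]


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path,
                           wide: bool = True) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.condition, r.fold_change) for r in records],
        columns=["gene_id", "condition", "fold_change"],
    )
    if wide:
        df = df.pivot(index="gene_id", columns="condition", values="fold_change").reset_index()
        df.columns.name = None
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: set_name<TAB>description<TAB>genes...

    Empty sets are retained (with a warning) so downstream code can report them.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: GMT needs name and description")
            name = cols[0]
            genes = {g for g in cols[2:] if g}
            if not genes:
                log.warning("read_gmt: set %r at line %d is empty", name, lineno)
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: sequence}, uppercased; alphabet restricted to ACGTN."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        extra = set(s) - VALID_BASES
        if extra:
            raise FormatError(f"{path}: sequence {rec.id} has invalid bases {sorted(extra)}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
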