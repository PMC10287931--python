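"""On-disk formats used by the pipeline.

All genomic/transcriptomic intervals are 0-based, half-open, BED-style.
Aligned reads travel in a BED6+1 dialect ("bed6c"): the six standard BED
columns plus a seventh column holding the comma-separated 0-based offsets
*from the read start* at which T->C (plus strand) or A->G (minus strand)
mismatches were observed, or "." when the read carries none.

Binding sites are written as BED6 with the score column reused for the
conversion count, plus a sidecar TSV carrying the mode location and the
remaining per-site statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed line in a tabular input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class SchemaError(ValueError):
    """A tabular input whose header/columns do not match the documented schema."""


#: canonical column order of a conversion-read table
READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "conversions"]

#: canonical column order of a BED6 footprint-read table
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

ANNOTATION_COLUMNS = ["transcript_id", "utr5_len", "orf_start", "orf_end", "total_len"]

SITE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "read_count",
    "conversion_count",
    "mode_location",
    "strand",
]


@dataclass(frozen=True)
class ConversionRead:
    """One aligned read with its observed crosslink-induced conversions."""

    chrom: str
    start: int
    end: int
    strand: str
    conversion_offsets: tuple[int, ...] = ()
    name: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty read interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")
        length = self.end - self.start
        for off in self.conversion_offsets:
            if not 0 <= off < length:
                raise ValueError(f"conversion offset {off} outside read of length {length}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def conversion_positions(self) -> tuple[int, ...]:
        """Genomic coordinates of the conversions.

        Plus strand: start + offset.  Minus strand: end - 1 - offset (the
        offset counts from the read's 5' end, which maps to the interval end).
        """
        if self.strand == "+":
            return tuple(self.start + o for o in self.conversion_offsets)
        return tuple(self.end - 1 - o for o in self.conversion_offsets)


def _parse_offsets(field: str, length: int, lineno: int) -> tuple[int, ...]:
    if field == ".":
        return ()
    try:
        offsets = tuple(int(x) for x in field.split(","))
    except ValueError as exc:
        raise FormatError(f"bad conversion-offset field {field!r}", lineno) from exc
    for off in offsets:
        if not 0 <= off < length:
            raise FormatError(f"conversion offset {off} outside read of length {length}", lineno)
    return offsets


def read_bed6c(path: str | Path) -> pd.DataFrame:
    """Read a BED6+1 conversion-read file into a validated DataFrame.

    The returned frame has columns READ_COLUMNS with ``conversions`` a tuple
    of ints per row. Malformed lines raise FormatError with the line number.
    """
    rows = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ")):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"expected 7 tab-separated columns, got {len(fields)}", lineno)
            chrom, start_s, end_s, name, score_s, strand, conv = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"non-integer interval {start_s!r}/{end_s!r}", lineno) from exc
            if end <= start:
                raise FormatError(f"empty interval [{start},{end})", lineno)
            if strand not in "+-":
                raise FormatError(f"unknown strand {strand!r}", lineno)
            offsets = _parse_offsets(conv, end - start, lineno)
            rows.append((chrom, start, end, name, score_s, strand, offsets))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_bed6c(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a conversion-read table; inverse of :func:`read_bed6c`."""
    with open(path, "w") as handle:
        for row in reads.itertuples(index=False):
            conv = ",".join(str(o) for o in row.conversions) if len(row.conversions) else "."
            handle.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t{row.strand}\t{conv}\n"
            )


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a plain BED6 file (footprint reads) into a DataFrame."""
    rows = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"expected >=6 columns, got {len(fields)}", lineno)
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"non-integer interval {start_s!r}/{end_s!r}", lineno) from exc
            if end <= start:
                raise FormatError(f"empty interval [{start},{end})", lineno)
            if strand not in "+-":
                raise FormatError(f"unknown strand {strand!r}", lineno)
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    reads[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the transcript annotation TSV.

    Required columns: transcript_id, utr5_len, orf_start, orf_end, total_len
    (all coordinates 0-based half-open in transcript space). An optional
    ``biotype`` column defaults to "mRNA".
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    if "biotype" not in df.columns:
        df["biotype"] = "mRNA"
    for col in ANNOTATION_COLUMNS[1:]:
        df[col] = df[col].astype(int)
    bad = df[(df.orf_end <= df.orf_start) | (df.orf_start != df.utr5_len) | (df.total_len < df.orf_end)]
    if len(bad):
        tid = bad.iloc[0].transcript_id
        raise SchemaError(f"annotation: inconsistent UTR/ORF bounds for {tid}")
    mrna = df[df.biotype == "mRNA"]
    bad_frame = mrna[(mrna.orf_end - mrna.orf_start) % 3 != 0]
    if len(bad_frame):
        raise SchemaError(
            f"annotation: mRNA ORF length not divisible by 3 for {bad_frame.iloc[0].transcript_id}"
        )
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    cols = ANNOTATION_COLUMNS + [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, value_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a per-transcript count table (TSV, header, transcript_id column)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["transcript_id"], "counts")
    if value_columns is not None:
        _require_columns(df, value_columns, "counts")
    return df


def read_track(path: str | Path) -> pd.DataFrame:
    """Read a per-nucleotide score track: transcript_id, pos, score."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["transcript_id", "pos", "score"], "track")
    df["pos"] = df["pos"].astype(int)
    return df


def read_measurements(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a measurement table (luminometer, qPCR ...) checking its columns."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, "measurements")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    """Write called sites as BED6 (score = conversion_count) + mode sidecar.

    The sidecar lives at ``<path>.modes.tsv`` and holds every non-BED column
    (mode_location, read_count, and any annotation added downstream).
    """
    path = Path(path)
    bed = sites[["chrom", "start", "end", "name", "conversion_count", "strand"]]
    bed.to_csv(path, sep="\t", header=False, index=False)
    extra_cols = [c for c in sites.columns if c not in ("chrom", "start", "end", "strand")]
    sidecar = sites[["name"] + [c for c in extra_cols if c != "name"]]
    sidecar.to_csv(path.with_suffix(path.suffix + ".modes.tsv"), sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_sites`."""
    path = Path(path)
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "conversion_count", "strand"],
    )
    sidecar = pd.read_csv(path.with_suffix(path.suffix + ".modes.tsv"), sep="\t")
    merged = bed.drop(columns=["conversion_count"]).merge(sidecar, on="name", how="left")
    for col in ("start", "end", "mode_location", "read_count", "conversion_count"):
        if col in merged.columns:
            merged[col] = merged[col].astype(int)
    return merged


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def reads_from_records(records: Iterable[ConversionRead]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.start, r.end, r.name, "0", r.strand, tuple(r.conversion_offsets))
        for r in records
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def records_from_reads(reads: pd.DataFrame) -> list[ConversionRead]:
    return [
        ConversionRead(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            conversion_offsets=tuple(int(o) for o in row.conversions),
            name=str(row.name),
        )
        for row in reads.itertuples(index=False)
    ]


def validate_file(path: str | Path, kind: str | None = None) -> str:
    """Best-effort validation used by ``larpmap validate``; returns the kind."""
    path = Path(path)
    if kind is None:
        suffix = path.suffix.lower()
        if suffix in (".fa", ".fasta"):
            kind = "fasta"
        elif suffix == ".bed6c":
            kind = "bed6c"
        elif suffix == ".bed":
            kind = "bed6"
        else:
            kind = "annotation"
    readers = {
        "fasta": read_fasta,
        "bed6c": read_bed6c,
        "bed6": read_bed6,
        "annotation": read_annotation,
        "track": read_track,
    }
    if kind not in readers:
        raise ValueError(f"unknown file kind {kind!r}")
    readers[kind](path)
    return kind
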