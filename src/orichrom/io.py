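"""Readers and writers for the standard formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  The GFF3 (1-based
inclusive) and bedGraph dialect conversions happen here and nowhere else,
so off-by-one drift cannot accumulate across modules.

Formats handled: FASTA (genome), GFF3 (genes), BED6 (stranded read 5'
ends, nucleosome calls, NDRs), bedGraph (tracks) and the package's
tab-delimited origin-table dialect (name, chrom, acs_start, acs_end,
acs_strand, timing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("orichrom.io")

#: IUPAC DNA alphabet accepted on FASTA read (uppercased first).
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

ORIGIN_TABLE_COLUMNS = ["name", "chrom", "acs_start", "acs_end", "acs_strand", "timing"]
TIMING_LABELS = ("early", "late", "unknown")


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by chromosome name."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; start/end are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class OriginRecord:
    """A replication origin anchored at its ACS element.

    ``acs_strand`` is the strand whose forward reading of the ACS is
    T-rich; every origin-anchored window in the pipeline is oriented so
    that this strand reads left to right.  ``timing`` is one of
    ``early``, ``late`` or ``unknown``.
    """

    name: str
    chrom: str
    acs_start: int
    acs_end: int
    acs_strand: str
    timing: str = "unknown"

    def __post_init__(self) -> None:
        if self.acs_end - self.acs_start < 1:
            raise ValueError(f"origin {self.name}: empty ACS interval")
        if self.acs_strand not in ("+", "-"):
            raise ValueError(f"origin {self.name}: acs_strand must be + or -")
        if self.timing not in TIMING_LABELS:
            raise ValueError(f"origin {self.name}: timing must be one of {TIMING_LABELS}")

    @property
    def acs_mid(self) -> int:
        return (self.acs_start + self.acs_end) // 2


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; any character outside the IUPAC DNA
    alphabet raises :class:`FormatError` naming the record.
    """
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise FormatError(f"{path}: duplicate FASTA record {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {record.id!r} is empty")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} contains non-IUPAC DNA characters {sorted(bad)}"
            )
        chroms[record.id] = seq
    if not chroms:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------


def _gff_attr_value(attributes: str, key: str) -> str | None:
    for part in attributes.rstrip(";").split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff_genes(path: str | Path) -> list[GeneAnnotation]:
    """Extract ``gene`` features from a GFF3 file.

    GFF 1-based inclusive coordinates are converted to 0-based half-open;
    non-gene features are ignored.  A gene line with ``.`` strand or with
    start > end raises :class:`FormatError` naming the line.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: start {start1} > end {end1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: gene strand must be + or -, got {strand!r}")
            gene_id = _gff_attr_value(attrs, "ID") or _gff_attr_value(attrs, "Name")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene has no ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneAnnotation(gene_id, chrom, start1 - 1, end1, strand))
    return genes


def write_gff_genes(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\torichrom\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Origin table (package TSV dialect)
# ---------------------------------------------------------------------------


def read_origin_table(
    path: str | Path, genome: GenomeSequence | None = None
) -> list[OriginRecord]:
    """Read the tab-delimited origin table.

    Columns: name, chrom, acs_start, acs_end, acs_strand, timing.
    Timing strings outside {early, late} map to ``unknown`` with a
    warning.  Duplicate names, or (when ``genome`` is given) coordinates
    beyond the chromosome length, raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ORIGIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing origin-table columns {missing}")
    if df["name"].duplicated().any():
        dups = sorted(df.loc[df["name"].duplicated(), "name"].unique())
        raise FormatError(f"{path}: duplicate origin names {dups}")
    records: list[OriginRecord] = []
    for row in df.itertuples(index=False):
        timing = str(row.timing).strip().lower()
        if timing not in ("early", "late"):
            logger.warning("origin %s: timing %r mapped to 'unknown'", row.name, row.timing)
            timing = "unknown"
        rec = OriginRecord(
            name=str(row.name),
            chrom=str(row.chrom),
            acs_start=int(row.acs_start),
            acs_end=int(row.acs_end),
            acs_strand=str(row.acs_strand),
            timing=timing,
        )
        if genome is not None:
            length = genome.chrom_lengths.get(rec.chrom)
            if length is None:
                raise FormatError(f"{path}: origin {rec.name} on unknown chromosome {rec.chrom}")
            if rec.acs_start < 0 or rec.acs_end > length:
                raise FormatError(
                    f"{path}: origin {rec.name} ACS [{rec.acs_start},{rec.acs_end}) exceeds "
                    f"{rec.chrom} length {length}"
                )
        records.append(rec)
    return records


def write_origin_table(origins: Iterable[OriginRecord], path: str | Path) -> None:
    rows = [
        (o.name, o.chrom, o.acs_start, o.acs_end, o.acs_strand, o.timing) for o in origins
    ]
    pd.DataFrame(rows, columns=ORIGIN_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED (stranded read 5' ends and generic intervals)
# ---------------------------------------------------------------------------


def read_bed_starts(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> "StrandedStartTrack":
    """Read aligned single-end reads (BED6) into per-strand 5'-end counts.

    The 5' end of a ``+`` read is its BED start; the 5' end of a ``-``
    read is its last covered base (BED end - 1).
    """
    from .coverage import StrandedStartTrack  # local import to avoid a cycle

    track = StrandedStartTrack.zeros(chrom_lengths)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        comment="#",
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in track.plus:
            raise FormatError(f"{path}: read on unknown chromosome {chrom!r}")
        n = len(track.plus[chrom])
        plus_pos = sub.loc[sub["strand"] == "+", "start"].to_numpy()
        minus_pos = sub.loc[sub["strand"] == "-", "end"].to_numpy() - 1
        for pos, arr in ((plus_pos, track.plus[chrom]), (minus_pos, track.minus[chrom])):
            if len(pos) == 0:
                continue
            if pos.min() < 0 or pos.max() >= n:
                raise FormatError(f"{path}: read position outside chromosome {chrom!r}")
            np.add.at(arr, pos, 1)
    return track


def write_bed_starts(
    track: "StrandedStartTrack", path: str | Path, read_length: int = 40
) -> None:
    """Write the start track back out as BED6 reads of ``read_length`` bp."""
    with open(path, "w") as fh:
        for chrom in track.plus:
            n = len(track.plus[chrom])
            for strand, counts in (("+", track.plus[chrom]), ("-", track.minus[chrom])):
                pos = np.repeat(np.nonzero(counts)[0], counts[np.nonzero(counts)[0]])
                if strand == "+":
                    starts = pos
                    ends = np.minimum(pos + read_length, n)
                else:
                    ends = pos + 1
                    starts = np.maximum(ends - read_length, 0)
                for s, e in zip(starts.tolist(), ends.tolist()):
                    fh.write(f"{chrom}\t{s}\t{e}\t.\t0\t{strand}\n")


def write_bed_intervals(
    rows: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write generic BED6 rows (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(track: "CoverageTrack", path: str | Path) -> None:
    """Write a track as bedGraph, run-length merging adjacent equal values.

    NaN anywhere in the track raises ``ValueError``; intervals are
    0-based half-open.
    """
    with open(path, "w") as fh:
        for chrom, values in track.values.items():
            if not np.all(np.isfinite(values)):
                raise ValueError(f"track for {chrom!r} contains non-finite values")
            # run-length boundaries where the value changes
            change = np.nonzero(np.diff(values))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts.tolist(), ends.tolist()):
                # shortest decimal repr that round-trips the float exactly
                fh.write(f"{chrom}\t{s}\t{e}\t{float(values[s])!r}\n")


def read_bedgraph(path: str | Path, chrom_lengths: Mapping[str, int]) -> "CoverageTrack":
    from .coverage import CoverageTrack

    values = {name: np.zeros(length, dtype=float) for name, length in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields
            if chrom not in values:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            values[chrom][int(start) : int(end)] = float(value)
    return CoverageTrack(values)
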