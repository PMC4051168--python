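"""Domain types and readers/writers for the on-disk formats.

All interval-like coordinates are stored 0-based half-open internally.
The BLAST tabular (m8) dialect is 1-based inclusive on disk and is
converted at the I/O boundary only for derived quantities; the
:class:`AlignmentHit` fields keep the m8 convention so that a
write/read round trip is the identity.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReadPair",
    "GenomeMeta",
    "AlignmentHit",
    "TargetInterval",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_m8",
    "write_tables",
    "read_bed",
    "read_genome_table",
    "write_genome_table",
]

_VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised for malformed input files; carries file and position context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = []
        if path is not None:
            ctx.append(str(path))
        if line is not None:
            ctx.append(f"line {line}")
        prefix = f"[{':'.join(ctx)}] " if ctx else ""
        super().__init__(prefix + message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class SequenceRecord:
    """A single read or reference sequence with optional Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if self.qualities is None:
            raise ValueError(f"record {self.id!r} carries no qualities")
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass(frozen=True)
class ReadPair:
    """Two mates of one sequenced fragment."""

    pair_id: str
    read1: SequenceRecord
    read2: SequenceRecord

    def __post_init__(self):
        if len(self.read1) == 0 or len(self.read2) == 0:
            raise ValueError(f"pair {self.pair_id!r}: both mates must be non-empty")


@dataclass(frozen=True)
class GenomeMeta:
    """Reference-genome size and taxonomy used for length normalization and rollup."""

    genome_id: str
    length_bp: int
    species: str
    genus: str
    phylum: str

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError(f"genome {self.genome_id!r}: length_bp must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One local read-vs-genome alignment in the 12-column m8 dialect.

    Coordinates are 1-based inclusive as in m8; ``s_start > s_end`` encodes a
    reverse-strand hit.  ``query_length`` is not an m8 column — it is attached
    from a sidecar read-length map so that read coverage
    ``(q_end - q_start + 1) / query_length`` is computable.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    query_length: int

    def __post_init__(self):
        if not (1 <= self.q_start <= self.q_end <= self.query_length):
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: query span "
                f"[{self.q_start},{self.q_end}] outside read of length {self.query_length}"
            )
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def read_coverage(self) -> float:
        """Fraction of the read covered by the alignment (gaps in the subject
        do not inflate it)."""
        return (self.q_end - self.q_start + 1) / self.query_length

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject interval as 0-based half-open, strand-normalized."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass(frozen=True)
class TargetInterval:
    """A capture target region, 0-based half-open (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; soft-masked lowercase is treated as plain bases.
    An empty file yields an empty list.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        # Light pre-scan for structural errors so we can name a line number.
        text = fh.read()
    stripped = text.strip()
    if not stripped:
        return records
    if not stripped.startswith(">"):
        first_bad = text.splitlines().index(stripped.splitlines()[0]) + 1
        raise ParseError("expected '>' header", path=path, line=first_bad)
    header_lines = [
        i + 1 for i, ln in enumerate(text.splitlines()) if ln.startswith(">")
    ]
    for idx, rec in enumerate(SeqIO.parse(io.StringIO(text), "fasta")):
        if not rec.id:
            raise ParseError("malformed empty header", path=path, line=header_lines[idx])
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(
                f"record {rec.id!r} has empty sequence", path=path, line=header_lines[idx]
            )
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Read 4-line FASTQ with Phred+33 qualities.

    A sequence/quality length mismatch raises :class:`ParseError` naming the
    offending record's first line.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    # drop trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        return records
    if len(lines) % 4 != 0:
        raise ParseError(
            f"truncated FASTQ: {len(lines)} lines is not a multiple of 4",
            path=path,
            line=len(lines),
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        line_no = i + 1
        if not head.startswith("@") or len(head) < 2:
            raise ParseError("malformed FASTQ header", path=path, line=line_no)
        if not plus.startswith("+"):
            raise ParseError("missing '+' separator", path=path, line=line_no + 2)
        if len(seq) != len(qual):
            raise ParseError(
                f"record {head[1:].split()[0]!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)}",
                path=path,
                line=line_no,
            )
        records.append(
            SequenceRecord(
                id=head[1:].split()[0],
                sequence=seq.upper(),
                qualities=tuple(ord(c) - 33 for c in qual),
            )
        )
    return records


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            quals = rec.qualities
            if quals is None:
                quals = (40,) * len(rec.sequence)
            fh.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in quals)
                + "\n"
            )


_M8_COLS = 12


def read_m8(path, read_lengths: Mapping[str, int]) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular output, attaching query lengths.

    ``read_lengths`` maps query_id -> read length in bp; rows whose query_id
    is absent are rejected (the length is required for coverage thresholds).
    """
    hits: list[AlignmentHit] = []
    unknown: list[str] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _M8_COLS:
                raise ParseError(
                    f"expected {_M8_COLS} tab-separated columns, got {len(parts)}",
                    path=path,
                    line=line_no,
                )
            qid = parts[0]
            if qid not in read_lengths:
                unknown.append(qid)
                continue
            try:
                hits.append(
                    AlignmentHit(
                        query_id=qid,
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        aln_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bit_score=float(parts[11]),
                        query_length=int(read_lengths[qid]),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=line_no) from exc
    if unknown:
        uniq = sorted(set(unknown))
        raise ParseError(
            f"{len(uniq)} query id(s) absent from read_lengths: "
            + ", ".join(uniq[:10])
            + ("..." if len(uniq) > 10 else ""),
            path=path,
        )
    return hits


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_tables(objects: Sequence, path, kind: str) -> None:
    """Write domain objects as deterministic tab-separated tables.

    ``kind`` selects the schema: ``m8`` (AlignmentHit), ``abundance_tsv``
    (taxon/sample/abundance triples or an AbundanceTable-like mapping),
    ``genotype_tsv`` (GenotypeCall), ``profile_tsv`` (SubstitutionProfile
    rows), ``bed`` (TargetInterval, written 0-based half-open).  Rows are
    sorted by primary key for reproducible diffs.
    """
    path = Path(path)
    if kind == "m8":
        rows = sorted(objects, key=lambda h: (h.query_id, h.subject_id, -h.bit_score))
        with _open_text(path, "wt") as fh:
            for h in rows:
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            h.subject_id,
                            f"{h.percent_identity:.2f}",
                            str(h.aln_length),
                            str(h.mismatches),
                            str(h.gap_opens),
                            str(h.q_start),
                            str(h.q_end),
                            str(h.s_start),
                            str(h.s_end),
                            _format_float(h.evalue),
                            _format_float(h.bit_score),
                        ]
                    )
                    + "\n"
                )
    elif kind == "abundance_tsv":
        with _open_text(path, "wt") as fh:
            fh.write("taxon\tsample\tabundance\n")
            for taxon, sample, ab in sorted(objects):
                fh.write(f"{taxon}\t{sample}\t{_format_float(ab)}\n")
    elif kind == "genotype_tsv":
        with _open_text(path, "wt") as fh:
            fh.write("gene\tposition\tref\tgenotype\tdepth\tcounts\tphase_set\n")
            for row in sorted(objects, key=lambda r: (r[0], r[1])):
                fh.write("\t".join(str(x) for x in row) + "\n")
    elif kind == "profile_tsv":
        with _open_text(path, "wt") as fh:
            fh.write("strand\tposition\tfrom\tto\tcount\trate\n")
            for strand, pos, frm, to, count, rate in sorted(objects):
                fh.write(f"{strand}\t{pos}\t{frm}\t{to}\t{count}\t{_format_float(rate)}\n")
    elif kind == "bed":
        rows = sorted(objects, key=lambda t: (t.chrom, t.start, t.end))
        with _open_text(path, "wt") as fh:
            for t in rows:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
    else:
        raise ValueError(f"unknown table kind {kind!r}")


def read_bed(path) -> list[TargetInterval]:
    """Read 3-column BED (0-based half-open)."""
    out: list[TargetInterval] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line needs >= 3 columns", path=path, line=line_no)
            try:
                out.append(TargetInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=line_no) from exc
    return out


def write_genome_table(genomes: Iterable[GenomeMeta], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("genome_id\tlength_bp\tspecies\tgenus\tphylum\n")
        for g in sorted(genomes, key=lambda g: g.genome_id):
            fh.write(f"{g.genome_id}\t{g.length_bp}\t{g.species}\t{g.genus}\t{g.phylum}\n")


def read_genome_table(path) -> list[GenomeMeta]:
    """Read the genome id -> (length, species, genus, phylum) TSV."""
    out: list[GenomeMeta] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("genome_id\t"):
            raise ParseError("missing genome table header", path=path, line=1)
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            gid, length, species, genus, phylum = line.split("\t")
            if gid in seen:
                raise ParseError(f"duplicate genome_id {gid!r}", path=path, line=line_no)
            seen.add(gid)
            out.append(GenomeMeta(gid, int(length), species, genus, phylum))
    return out
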