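"""Read QC and profiling: metagenomic read filters, locus pair filters,
strand-aware substitution-bias profiles, and capture summary metrics.

The metagenomic filter implements the prinseq-style rules (mean Phred
quality below threshold, short reads, ambiguous bases, exact sequence
duplicates); the locus pair filter implements the FASTX-style rule (a pair
is dropped when more than ``max_bad_bases`` bases across both mates have
quality at or below ``q_threshold``).

Duplicates here are *exact sequence* duplicates, a different notion from the
coordinate-based PCR duplicates summarized by :func:`capture_metrics`, which
therefore takes duplicate flags as input rather than re-deriving them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .seqio import ReadPair, SequenceRecord, TargetInterval

__all__ = [
    "QCReport",
    "SubstitutionProfile",
    "CaptureMetrics",
    "MappedRead",
    "ReadSummary",
    "filter_metagenomic_reads",
    "filter_locus_pairs",
    "substitution_profile",
    "capture_metrics",
]

_SUB_TYPES = tuple(
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
)  # the 12 ordered substitution types


@dataclass(frozen=True)
class QCReport:
    """Tallies from the metagenomic read filter.

    Each failing rule is counted for every read that violates it, so the
    per-rule counts can exceed ``n_input - n_passed`` when a read violates
    several rules at once.
    """

    n_input: int
    n_low_mean_quality: int
    n_short: int
    n_ambiguous: int
    n_exact_duplicates: int
    n_passed: int


def filter_metagenomic_reads(
    reads: Sequence[SequenceRecord],
    min_mean_q: float = 25.0,
    min_len: int = 50,
) -> tuple[list[SequenceRecord], QCReport]:
    """Apply the metagenomic QC rules; order of rule evaluation is immaterial.

    A read is removed if its mean quality is strictly below ``min_mean_q``,
    its length strictly below ``min_len``, it contains any non-ACGT base, or
    it is an exact sequence duplicate of an earlier *retained* read (first
    occurrence kept).  Reads must carry qualities.
    """
    passed: list[SequenceRecord] = []
    n_low_q = n_short = n_ambig = n_dup = 0
    seen: set[str] = set()
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"read {read.id!r} carries no qualities")
        bad = False
        if read.mean_quality < min_mean_q:
            n_low_q += 1
            bad = True
        if len(read) < min_len:
            n_short += 1
            bad = True
        if any(b not in "ACGT" for b in read.sequence):
            n_ambig += 1
            bad = True
        if bad:
            continue
        if read.sequence in seen:
            n_dup += 1
            continue
        seen.add(read.sequence)
        passed.append(read)
    report = QCReport(
        n_input=len(reads),
        n_low_mean_quality=n_low_q,
        n_short=n_short,
        n_ambiguous=n_ambig,
        n_exact_duplicates=n_dup,
        n_passed=len(passed),
    )
    return passed, report


def filter_locus_pairs(
    pairs: Sequence[ReadPair],
    max_bad_bases: int = 5,
    q_threshold: int = 3,
) -> tuple[list[ReadPair], dict[str, int]]:
    """Drop pairs with more than ``max_bad_bases`` bases of quality <=
    ``q_threshold`` summed over both mates."""
    passed: list[ReadPair] = []
    n_removed = 0
    for pair in pairs:
        if pair.read1.qualities is None or pair.read2.qualities is None:
            raise ValueError(f"pair {pair.pair_id!r} carries mates without qualities")
        bad = sum(q <= q_threshold for q in pair.read1.qualities) + sum(
            q <= q_threshold for q in pair.read2.qualities
        )
        if bad > max_bad_bases:
            n_removed += 1
        else:
            passed.append(pair)
    return passed, {"n_input": len(pairs), "n_removed": n_removed, "n_passed": len(passed)}


@dataclass(frozen=True)
class MappedRead:
    """One aligned read with the reference bases under it.

    ``strand`` is '+' (forward) or '-' (reverse).  Reverse-strand reads are
    assumed stored reverse-complemented (as in a BAM), so their original 5'
    end appears at the *right* end of the stored sequence; the profile is
    indexed along the stored orientation and deliberately not re-oriented.
    """

    read: SequenceRecord
    strand: str
    reference_segment: str
    cigar: str


@dataclass(frozen=True)
class SubstitutionProfile:
    """Per-strand, per-position rates of the 12 substitution types.

    ``rates[strand][(from, to)]`` is a float array of length ``read_length``;
    entry p is (number of reads with from->to at position p) / (number of
    retained reads on that strand).
    """

    read_length: int
    n_reads: dict[str, int]
    counts: dict[str, dict[tuple[str, str], np.ndarray]]

    def rate(self, strand: str, from_base: str, to_base: str) -> np.ndarray:
        n = self.n_reads[strand]
        c = self.counts[strand][(from_base, to_base)]
        return c / n if n else np.zeros_like(c, dtype=float)

    def total_rate(self, strand: str) -> np.ndarray:
        """Summed substitution rate over all 12 types, per position."""
        total = np.zeros(self.read_length)
        for key in _SUB_TYPES:
            total += self.rate(strand, *key)
        return total

    def rows(self):
        """Flat (strand, position, from, to, count, rate) rows for output."""
        for strand in ("forward", "reverse"):
            n = self.n_reads[strand]
            for frm, to in _SUB_TYPES:
                c = self.counts[strand][(frm, to)]
                for pos in range(self.read_length):
                    yield (strand, pos, frm, to, int(c[pos]), (c[pos] / n) if n else 0.0)


def _is_full_match_cigar(cigar: str, length: int) -> bool:
    return cigar in (f"{length}M", f"{length}=")


def substitution_profile(
    mapped_reads: Iterable[MappedRead],
    read_length: int,
) -> SubstitutionProfile:
    """Tally read-vs-reference mismatches per position, strand-separated.

    Reads whose CIGAR is not a single full-length match (``<L>M``) are
    excluded — indels or clipping would shift the positional register.
    Rates divide by the number of *retained* reads of that strand.
    """
    counts = {
        strand: {key: np.zeros(read_length, dtype=np.int64) for key in _SUB_TYPES}
        for strand in ("forward", "reverse")
    }
    n_reads = {"forward": 0, "reverse": 0}
    for mr in mapped_reads:
        if mr.strand not in ("+", "-"):
            raise ValueError(f"bad strand {mr.strand!r}")
        if not _is_full_match_cigar(mr.cigar, len(mr.read.sequence)):
            continue
        if len(mr.reference_segment) != len(mr.read.sequence):
            raise ValueError(
                f"read {mr.read.id!r}: reference segment length "
                f"{len(mr.reference_segment)} != read length {len(mr.read.sequence)}"
            )
        strand = "forward" if mr.strand == "+" else "reverse"
        n_reads[strand] += 1
        seq = mr.read.sequence
        ref = mr.reference_segment
        for pos in range(min(read_length, len(seq))):
            r, q = ref[pos], seq[pos]
            if r != q and r in "ACGT" and q in "ACGT":
                counts[strand][(r, q)][pos] += 1
    return SubstitutionProfile(read_length=read_length, n_reads=n_reads, counts=counts)


@dataclass(frozen=True)
class ReadSummary:
    """Mapping summary of one read for capture metrics."""

    read_id: str
    mapped: bool
    duplicate: bool = False
    chrom: str | None = None
    start: int | None = None  # 0-based half-open alignment interval
    end: int | None = None


@dataclass(frozen=True)
class CaptureMetrics:
    total_reads: int
    pct_unmapped: float
    pct_duplicates: float
    pct_on_target: float
    median_target_coverage: float


OnTargetRule = Literal["midpoint", "any-overlap", "full-containment"]


def capture_metrics(
    read_summary: Sequence[ReadSummary],
    targets: Sequence[TargetInterval],
    on_target_rule: OnTargetRule = "midpoint",
) -> CaptureMetrics:
    """Summarize a capture experiment against its target intervals.

    ``pct_unmapped`` is over all reads; ``pct_duplicates`` over mapped
    reads; ``pct_on_target`` over non-duplicate mapped reads, a read
    counting as on-target by the configured rule (default: alignment
    midpoint inside a target).  ``median_target_coverage`` is the median
    per-base depth over all target bases from non-duplicate mapped reads.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    trees: dict[str, IntervalTree] = {}
    for t in targets:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
    total = len(read_summary)
    mapped = [r for r in read_summary if r.mapped]
    n_unmapped = total - len(mapped)
    n_dup = sum(r.duplicate for r in mapped)
    usable = [r for r in mapped if not r.duplicate]
    n_on = 0
    for r in usable:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        if on_target_rule == "midpoint":
            mid = (r.start + r.end) // 2
            hit = bool(tree.at(mid))
        elif on_target_rule == "any-overlap":
            hit = bool(tree.overlap(r.start, r.end))
        elif on_target_rule == "full-containment":
            hit = any(iv.begin <= r.start and r.end <= iv.end for iv in tree.overlap(r.start, r.end))
        else:
            raise ValueError(f"unknown on-target rule {on_target_rule!r}")
        n_on += hit
    # per-base depth over target bases
    depths: list[np.ndarray] = []
    by_chrom: dict[str, list[ReadSummary]] = {}
    for r in usable:
        by_chrom.setdefault(r.chrom, []).append(r)
    for t in targets:
        d = np.zeros(t.end - t.start, dtype=np.int64)
        for r in by_chrom.get(t.chrom, ()):
            lo = max(t.start, r.start)
            hi = min(t.end, r.end)
            if lo < hi:
                d[lo - t.start : hi - t.start] += 1
        depths.append(d)
    all_depths = np.concatenate(depths)
    return CaptureMetrics(
        total_reads=total,
        pct_unmapped=100.0 * n_unmapped / total if total else 0.0,
        pct_duplicates=100.0 * n_dup / len(mapped) if mapped else 0.0,
        pct_on_target=100.0 * n_on / len(usable) if usable else 0.0,
        median_target_coverage=float(np.median(all_depths)),
    )
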