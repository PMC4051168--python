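"""Seed-and-extend local alignment emitting m8-compatible hits.

The recruitment stage consumes BLAST-style tabular hits.  To keep the
pipeline testable end-to-end without an external aligner, this module
provides a small blastn-like aligner: exact k-mer seeding against a genome
index, Smith-Waterman extension with affine gaps (Biopython's C pairwise
engine), and Karlin-Altschul e-values.

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``
(the BLAST convention).  Defaults emulate blastn's ``-r 1 -q -3 -G 5 -E 2``
with ungapped-lambda Karlin-Altschul parameters; the study-scale database
size knob mirrors an effective search-space override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .seqio import AlignmentHit, SequenceRecord

__all__ = [
    "ScoringScheme",
    "RawAlignment",
    "smith_waterman",
    "evalue",
    "bit_score",
    "align_reads",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul statistics.

    ``lambda_`` and ``K`` parameterize E = K * m * n * exp(-lambda * S);
    ``effective_db_size`` is n (total searched bases).  Defaults approximate
    blastn with reward 1 / penalty 3.
    """

    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = 1.33
    K: float = 0.621
    effective_db_size: float = 1e6

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = -self.mismatch
        # Biopython charges open for the first gap base; fold one extension in
        # so a length-L gap costs gap_open + L*gap_extend.
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass(frozen=True)
class RawAlignment:
    """An AlignmentHit plus the two gapped alignment rows."""

    hit: AlignmentHit
    query_row: str
    subject_row: str
    score: int

    def __post_init__(self):
        if len(self.query_row) != len(self.subject_row):
            raise ValueError("aligned rows must have equal length")


def _rows_stats(qrow: str, srow: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, columns) from two gapped rows."""
    matches = mismatches = gap_opens = 0
    in_gap = False
    for qc, sc in zip(qrow, srow):
        if qc == "-" or sc == "-":
            if not in_gap:
                gap_opens += 1
                in_gap = True
        else:
            in_gap = False
            if qc == sc:
                matches += 1
            else:
                mismatches += 1
    return matches, mismatches, gap_opens, len(qrow)


def smith_waterman(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: ScoringScheme | None = None,
) -> RawAlignment | None:
    """Optimal local alignment of ``query`` against ``subject`` (forward
    orientation only).

    Returns ``None`` when the best local score is below one match (no
    meaningful alignment).  Percent identity is matches over alignment
    columns, gaps included.  Traceback is deterministic (the engine's first
    optimal path).
    """
    if scoring is None:
        scoring = ScoringScheme()
    if not query.sequence or not subject.sequence:
        raise ValueError("sequences must be non-empty")
    aligner = scoring.aligner()
    alns = aligner.align(subject.sequence, query.sequence)
    if len(alns) == 0 or alns.score < scoring.match:
        return None
    best = alns[0]
    score = int(round(alns.score))
    srow, qrow = str(best[0]), str(best[1])
    matches, mismatches, gap_opens, columns = _rows_stats(qrow, srow)
    (s_lo, s_hi) = best.coordinates[0][0], best.coordinates[0][-1]
    (q_lo, q_hi) = best.coordinates[1][0], best.coordinates[1][-1]
    ev = evalue(score, len(query.sequence), scoring)
    hit = AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        percent_identity=100.0 * matches / columns,
        aln_length=columns,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q_lo + 1,
        q_end=q_hi,
        s_start=s_lo + 1,
        s_end=s_hi,
        evalue=ev,
        bit_score=bit_score(score, scoring),
        query_length=len(query.sequence),
    )
    return RawAlignment(hit=hit, query_row=qrow, subject_row=srow, score=score)


def evalue(score: float, query_len: int, scoring: ScoringScheme) -> float:
    """Karlin-Altschul expected number of chance alignments.

    E = K * m * n * exp(-lambda * S) with m the query length and n the
    effective database size; strictly decreasing in score, linear in both
    lengths.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    return scoring.K * query_len * scoring.effective_db_size * math.exp(
        -scoring.lambda_ * score
    )


def bit_score(score: float, scoring: ScoringScheme) -> float:
    """Scale a raw score into bits: S' = (lambda*S - ln K) / ln 2."""
    return (scoring.lambda_ * score - math.log(scoring.K)) / math.log(2.0)


class _GenomeIndex:
    """Exact k-mer index of one genome (forward strand)."""

    def __init__(self, genome: SequenceRecord, k: int):
        self.genome = genome
        self.k = k
        index: dict[str, list[int]] = {}
        seq = genome.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(i)
        self.index = index


def _seed_windows(
    read_seq: str, gi: _GenomeIndex, pad: int
) -> list[tuple[int, int]]:
    """Candidate subject windows from shared k-mers, merged by diagonal."""
    k = gi.k
    diags: dict[int, list[int]] = {}
    for i in range(len(read_seq) - k + 1):
        positions = gi.index.get(read_seq[i : i + k])
        if positions:
            for p in positions:
                diags.setdefault(p - i, []).append(p)
    if not diags:
        return []
    # Merge nearby diagonals (indels shift the diagonal a little); window is
    # the read span projected on the subject plus padding.
    glen = len(gi.genome.sequence)
    rlen = len(read_seq)
    starts = sorted(max(0, d - pad) for d in diags)
    windows: list[tuple[int, int]] = []
    for s in starts:
        e = min(glen, s + rlen + 2 * pad)
        if windows and s <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], e))
        else:
            windows.append((s, e))
    return windows


def align_reads(
    reads: list[SequenceRecord],
    genomes: list[SequenceRecord],
    scoring: ScoringScheme | None = None,
    k: int = 11,
    min_score: int = 0,
    max_evalue: float = 0.01,
    window_pad: int = 25,
) -> list[AlignmentHit]:
    """Align each read against each genome via k-mer seeding + local extension.

    Both read strands are tried; reverse-strand hits are reported in
    read-forward query coordinates with ``s_start > s_end`` (the m8
    convention).  Only the best-scoring extension per read x genome is
    reported; hits with score < ``min_score`` or e-value > ``max_evalue``
    (the external-aligner-style reporting cutoff) are suppressed.
    """
    if scoring is None:
        total = float(sum(len(g.sequence) for g in genomes)) or 1.0
        scoring = ScoringScheme(effective_db_size=total)
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    for r in reads:
        if k > len(r.sequence):
            raise ValueError(f"seed length {k} exceeds read {r.id!r} length {len(r)}")
    indexes = [_GenomeIndex(g, k) for g in genomes]
    aligner = scoring.aligner()
    hits: list[AlignmentHit] = []
    for read in reads:
        fwd = read.sequence
        rev = revcomp(fwd)
        for gi in indexes:
            best: tuple[int, AlignmentHit] | None = None
            for strand, seq in (("+", fwd), ("-", rev)):
                for w_lo, w_hi in _seed_windows(seq, gi, window_pad):
                    window = gi.genome.sequence[w_lo:w_hi]
                    alns = aligner.align(window, seq)
                    if len(alns) == 0 or alns.score < max(scoring.match, min_score):
                        continue
                    score = int(round(alns.score))
                    ev = evalue(score, len(fwd), scoring)
                    if ev > max_evalue:
                        continue
                    best_aln = alns[0]
                    srow, qrow = str(best_aln[0]), str(best_aln[1])
                    matches, mismatches, gap_opens, columns = _rows_stats(qrow, srow)
                    s_lo = w_lo + int(best_aln.coordinates[0][0])
                    s_hi = w_lo + int(best_aln.coordinates[0][-1])
                    q_lo = int(best_aln.coordinates[1][0])
                    q_hi = int(best_aln.coordinates[1][-1])
                    if strand == "+":
                        qs, qe = q_lo + 1, q_hi
                        ss, se = s_lo + 1, s_hi
                    else:
                        # report in read-forward coordinates; subject coords
                        # reversed to encode the strand
                        rlen = len(fwd)
                        qs, qe = rlen - q_hi + 1, rlen - q_lo
                        ss, se = s_hi, s_lo + 1
                    hit = AlignmentHit(
                        query_id=read.id,
                        subject_id=gi.genome.id,
                        percent_identity=100.0 * matches / columns,
                        aln_length=columns,
                        mismatches=mismatches,
                        gap_opens=gap_opens,
                        q_start=qs,
                        q_end=qe,
                        s_start=ss,
                        s_end=se,
                        evalue=ev,
                        bit_score=bit_score(score, scoring),
                        query_length=len(fwd),
                    )
                    if best is None or score > best[0]:
                        best = (score, hit)
            if best is not None:
                hits.append(best[1])
    return hits
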