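"""Tiered fragment recruitment and genome-length-normalized abundance.

Reads are assigned to reference genomes from their local-alignment hits
under three nested threshold tiers:

* ``lenient``  — distant homology: >= 50% identity, no coverage floor;
* ``stringent`` — recent homology: >= 80% identity and the alignment must
  cover >= 75% of the read;
* ``species``  — species binning: >= 95% identity with the same coverage
  floor.

All tiers additionally require e-value <= 1e-3.  Within a tier a read goes
to the genome with the best alignment (bit) score among passing hits; ties
go to the lexicographically smallest genome id and are flagged ambiguous.
Per-genome read counts are then divided by genome length and renormalized,
so abundance reflects organism (cell) frequency rather than genome size,
and rolled up through the genome taxonomy to species, genus and phylum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import AlignmentHit, GenomeMeta

__all__ = [
    "TierThresholds",
    "DEFAULT_TIERS",
    "ReadAssignment",
    "AbundanceTable",
    "CoverageTrack",
    "classify_read",
    "recruit_all",
    "normalize_abundance",
    "rollup",
    "coverage_track",
]


@dataclass(frozen=True)
class TierThresholds:
    """Identity / read-coverage / e-value thresholds for one tier."""

    name: str
    min_identity: float
    min_read_coverage: float | None
    max_evalue: float = 1e-3

    def passes(self, hit: AlignmentHit) -> bool:
        if hit.percent_identity < self.min_identity:
            return False
        if self.min_read_coverage is not None and hit.read_coverage < self.min_read_coverage:
            return False
        return hit.evalue <= self.max_evalue


DEFAULT_TIERS: tuple[TierThresholds, ...] = (
    TierThresholds("lenient", 50.0, None, 1e-3),
    TierThresholds("stringent", 80.0, 0.75, 1e-3),
    TierThresholds("species", 95.0, 0.75, 1e-3),
)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    tier: str
    genome_id: str | None  # None = unassigned (discarded at this tier)
    best_bit_score: float | None = None
    ambiguous: bool = False

    @property
    def assigned(self) -> bool:
        return self.genome_id is not None


def classify_read(
    hits_for_one_read: list[AlignmentHit], tier: TierThresholds
) -> ReadAssignment:
    """Assign one read at one tier: filter, argmax bit score, deterministic ties.

    All hits must share one query id.  If no hit passes the tier the read is
    unassigned; among passing hits the best bit score wins, with equal
    scores broken toward the lexicographically smallest genome id and
    flagged ``ambiguous``.
    """
    if not hits_for_one_read:
        raise ValueError("need at least one hit (use recruit_all for hitless reads)")
    qids = {h.query_id for h in hits_for_one_read}
    if len(qids) != 1:
        raise ValueError(f"hits span multiple query ids: {sorted(qids)}")
    read_id = hits_for_one_read[0].query_id
    passing = [h for h in hits_for_one_read if tier.passes(h)]
    if not passing:
        return ReadAssignment(read_id, tier.name, None)
    best_score = max(h.bit_score for h in passing)
    top = sorted(
        (h for h in passing if h.bit_score == best_score), key=lambda h: h.subject_id
    )
    return ReadAssignment(
        read_id=read_id,
        tier=tier.name,
        genome_id=top[0].subject_id,
        best_bit_score=best_score,
        ambiguous=len(top) > 1,
    )


def recruit_all(
    hits: list[AlignmentHit],
    tiers: tuple[TierThresholds, ...] = DEFAULT_TIERS,
    genomes: list[GenomeMeta] | None = None,
) -> dict[str, tuple[dict[str, int], list[ReadAssignment]]]:
    """Classify every read at every tier.

    Returns ``{tier name: (per-genome assigned-read counts, assignments)}``;
    unassigned reads appear in the assignment list with ``genome_id=None``
    and are excluded from the counts (they are discarded from diversity
    analysis at that tier).  When ``genomes`` is given, every subject id in
    the hits must be present in it.
    """
    if genomes is not None:
        known = {g.genome_id for g in genomes}
        unknown = sorted({h.subject_id for h in hits} - known)
        if unknown:
            raise ValueError(f"subject id(s) not in genome table: {', '.join(unknown)}")
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.query_id, []).append(h)
    out: dict[str, tuple[dict[str, int], list[ReadAssignment]]] = {}
    for tier in tiers:
        counts: dict[str, int] = {}
        assignments: list[ReadAssignment] = []
        for read_id in sorted(by_read):
            a = classify_read(by_read[read_id], tier)
            assignments.append(a)
            if a.assigned:
                counts[a.genome_id] = counts.get(a.genome_id, 0) + 1
        out[tier.name] = (counts, assignments)
    return out


@dataclass(frozen=True)
class AbundanceTable:
    """Relative abundances at one taxonomic level for one sample/tier."""

    level: str  # genome | species | genus | phylum
    entries: dict[str, float]
    sample_id: str = "sample"
    tier: str = "species"

    def __post_init__(self):
        if self.entries:
            total = sum(self.entries.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances sum to {total}, not 1")
            if any(v < 0 for v in self.entries.values()):
                raise ValueError("negative abundance")


def normalize_abundance(
    counts: dict[str, int],
    genomes: list[GenomeMeta],
    sample_id: str = "sample",
    tier: str = "species",
) -> AbundanceTable:
    """Genome-length-normalized relative abundance.

    abundance(g) = (counts[g] / length[g]) / sum_h (counts[h] / length[h]).
    """
    meta = {g.genome_id: g for g in genomes}
    if not counts:
        return AbundanceTable(level="genome", entries={}, sample_id=sample_id, tier=tier)
    dens: dict[str, float] = {}
    for gid, c in counts.items():
        if gid not in meta:
            raise ValueError(f"genome {gid!r} missing from genome table")
        length = meta[gid].length_bp
        if length <= 0:
            raise ValueError(f"genome {gid!r} has non-positive length")
        dens[gid] = c / length
    total = sum(dens.values())
    entries = {gid: d / total for gid, d in dens.items()}
    return AbundanceTable(level="genome", entries=entries, sample_id=sample_id, tier=tier)


_LEVELS = ("species", "genus", "phylum")


def rollup(
    table: AbundanceTable, genomes: list[GenomeMeta], level: str
) -> AbundanceTable:
    """Sum a genome-level table within species, genus or phylum; the total
    abundance is conserved exactly."""
    if table.level != "genome":
        raise ValueError("rollup starts from a genome-level table")
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    meta = {g.genome_id: g for g in genomes}
    entries: dict[str, float] = {}
    for gid, ab in table.entries.items():
        if gid not in meta:
            raise ValueError(f"genome {gid!r} missing taxonomy")
        taxon = getattr(meta[gid], level)
        entries[taxon] = entries.get(taxon, 0.0) + ab
    return AbundanceTable(level=level, entries=entries, sample_id=table.sample_id, tier=table.tier)


@dataclass(frozen=True)
class CoverageTrack:
    """Depth of recruited reads along one genome.

    ``localized`` flags likely artifacts: >= ``localized_mass`` of recruited
    bases falling within <= ``localized_span`` of the genome (reads piling
    on one short region rather than tiling the genome).
    """

    genome_id: str
    depth_runs: tuple[tuple[int, int, int], ...]  # (start, end, depth) RLE
    fraction_covered: float
    localized: bool

    def depth_array(self, length: int) -> np.ndarray:
        d = np.zeros(length, dtype=np.int64)
        for start, end, depth in self.depth_runs:
            d[start:end] = depth
        return d


def coverage_track(
    assignments: list[ReadAssignment],
    hits: list[AlignmentHit],
    genome: GenomeMeta,
    localized_mass: float = 0.5,
    localized_span: float = 0.01,
) -> CoverageTrack:
    """Accumulate subject-interval depth for reads assigned to one genome.

    Raises the localization flag when >= ``localized_mass`` of recruited
    bases fall in <= ``localized_span`` of the genome length (the
    short-conserved-region artifact heuristic).
    """
    assigned = {a.read_id for a in assignments if a.genome_id == genome.genome_id}
    depth = np.zeros(genome.length_bp + 1, dtype=np.int64)  # diff array
    for h in hits:
        if h.query_id not in assigned or h.subject_id != genome.genome_id:
            continue
        lo, hi = h.subject_interval
        if lo < 0 or hi > genome.length_bp:
            raise ValueError(
                f"hit interval [{lo},{hi}) outside genome of length {genome.length_bp}"
            )
        depth[lo] += 1
        depth[hi] -= 1
    depth = np.cumsum(depth[:-1])
    covered = int(np.count_nonzero(depth))
    frac = covered / genome.length_bp
    # localization: smallest window (in sorted per-base depth terms) holding
    # `localized_mass` of the recruited bases
    total_bases = int(depth.sum())
    localized = False
    if total_bases > 0:
        sorted_depth = np.sort(depth)[::-1]
        cum = np.cumsum(sorted_depth)
        n_needed = int(np.searchsorted(cum, localized_mass * total_bases) + 1)
        localized = n_needed <= localized_span * genome.length_bp
    # run-length encode
    runs: list[tuple[int, int, int]] = []
    if depth.size:
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        for s, e in zip(starts, ends):
            d = int(depth[s])
            if d > 0:
                runs.append((int(s), int(e), d))
    return CoverageTrack(
        genome_id=genome.genome_id,
        depth_runs=tuple(runs),
        fraction_covered=frac,
        localized=localized,
    )
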