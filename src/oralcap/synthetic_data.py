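"""Synthetic inputs with known truth for every pipeline stage.

Three generators cover the study's data types:

* a microbial community read pool (multinomial genome mixture, uniform
  per-base substitution error, optional exact duplicates) for the
  fragment-recruitment stage;
* position-targeted substitution "damage" injection for the
  substitution-bias profiler;
* a diploid multigene locus with divergent paralogues, known genotypes,
  phase and gene presence/absence, for the genotyping stage.

Read origins follow the *cell abundance* convention: the probability a read
comes from a genome is proportional to ``weight x genome length``, so that
equal weights make longer genomes yield proportionally more reads and
genome-length normalization downstream recovers the input weights.

All generators are deterministic functions of their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import revcomp
from .seqio import GenomeMeta, ReadPair, SequenceRecord

__all__ = [
    "CommunitySpec",
    "DamageSpec",
    "DiploidLocusSpec",
    "ReadOrigin",
    "VariantTruth",
    "LocusSimulation",
    "simulate_genomes",
    "simulate_reads",
    "inject_positional_substitutions",
    "simulate_paralogous_locus",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_Q = 40


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _from_str(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


@dataclass(frozen=True)
class CommunitySpec:
    """A weighted mixture of genomes plus read-simulation parameters."""

    members: tuple[tuple[GenomeMeta, float], ...]
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        weights = [w for _, w in self.members]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("weights must be >= 0 and sum to > 0")
        species = [m.species for m, _ in self.members]
        if len(set(species)) != len(species):
            raise ValueError("at most one genome per species in a community")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class DamageSpec:
    """Position-targeted substitutions applied to one strand's reads.

    ``entries`` is a tuple of (position, from_base, to_base, rate).
    """

    entries: tuple[tuple[int, str, str, float], ...]
    strand: str = "forward"

    def __post_init__(self):
        if self.strand not in ("forward", "reverse"):
            raise ValueError("strand must be 'forward' or 'reverse'")
        for pos, frm, to, rate in self.entries:
            if not (0.0 <= rate <= 1.0):
                raise ValueError("damage rates must be in [0, 1]")
            if frm not in "ACGT" or to not in "ACGT" or frm == to:
                raise ValueError(f"bad substitution {frm}->{to}")


@dataclass(frozen=True)
class ReadOrigin:
    """Provenance of one simulated read."""

    genome_id: str
    start: int
    strand: str  # '+' or '-'
    duplicate_of: str | None = None


def simulate_genomes(
    n: int,
    length_range: tuple[int, int],
    gc: float = 0.5,
    seed: int = 0,
    n_genera: int | None = None,
    n_phyla: int | None = None,
) -> tuple[list[SequenceRecord], list[GenomeMeta]]:
    """Generate ``n`` i.i.d. random genomes with a nested taxonomy.

    Each genome is its own species; species are assigned round-robin to
    ``n_genera`` genera (default ceil(n/2)) and genera round-robin to
    ``n_phyla`` phyla (default ceil(n/4)), so species nest in genera nest
    in phyla.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length_range")
    n_genera = n_genera or max(1, (n + 1) // 2)
    n_phyla = n_phyla or max(1, (n + 3) // 4)
    rng = np.random.default_rng(seed)
    # base probabilities: GC split evenly over G/C, AT over A/T
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records: list[SequenceRecord] = []
    metas: list[GenomeMeta] = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = _to_str(rng.choice(_BASES, size=length, p=probs))
        gid = f"genome{i:03d}"
        genus = i % n_genera
        phylum = genus % n_phyla
        records.append(SequenceRecord(id=gid, sequence=seq))
        metas.append(
            GenomeMeta(
                genome_id=gid,
                length_bp=length,
                species=f"species{i:03d}",
                genus=f"genus{genus:03d}",
                phylum=f"phylum{phylum:03d}",
            )
        )
    return records, metas


def _mutate_uniform(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with a uniformly chosen different base at ``rate``."""
    if rate <= 0:
        return arr
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift by 1..3 in base space: always a different base
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr


def simulate_reads(
    spec: CommunitySpec,
    genome_seqs: dict[str, SequenceRecord],
    n_reads: int,
    duplicate_fraction: float = 0.0,
) -> tuple[list[SequenceRecord], dict[str, ReadOrigin]]:
    """Draw single-end reads from a weighted genome mixture.

    Read counts per genome are multinomial with probability proportional to
    ``weight x length``; start positions are uniform and strand random.
    Substitution errors are applied per base at ``spec.error_rate``.  The
    last ``round(duplicate_fraction * n_reads)`` reads are exact copies of
    previously emitted reads (fresh ids, ``duplicate_of`` set in the truth).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not (0.0 <= duplicate_fraction < 1.0):
        raise ValueError("duplicate_fraction must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    metas = [m for m, _ in spec.members]
    for m in metas:
        if m.genome_id not in genome_seqs:
            raise ValueError(f"no sequence provided for {m.genome_id}")
        if spec.read_length > len(genome_seqs[m.genome_id].sequence):
            raise ValueError("read_length exceeds a genome length")
    w = np.array([wt * m.length_bp for m, wt in spec.members], dtype=float)
    p = w / w.sum()
    n_dup = int(round(duplicate_fraction * n_reads))
    n_orig = n_reads - n_dup
    source = rng.choice(len(metas), size=n_orig, p=p)
    reads: list[SequenceRecord] = []
    truth: dict[str, ReadOrigin] = {}
    L = spec.read_length
    quals = (_DEFAULT_Q,) * L
    arrs = {m.genome_id: _from_str(genome_seqs[m.genome_id].sequence) for m in metas}
    for i, gi in enumerate(source):
        meta = metas[gi]
        garr = arrs[meta.genome_id]
        start = int(rng.integers(0, garr.size - L + 1))
        frag = garr[start : start + L].copy()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = _from_str(revcomp(_to_str(frag)))
        frag = _mutate_uniform(frag, spec.error_rate, rng)
        rid = f"read{i:07d}"
        reads.append(SequenceRecord(id=rid, sequence=_to_str(frag), qualities=quals))
        truth[rid] = ReadOrigin(meta.genome_id, start, strand)
    for j in range(n_dup):
        src = reads[int(rng.integers(0, n_orig))]
        rid = f"read{n_orig + j:07d}"
        reads.append(SequenceRecord(id=rid, sequence=src.sequence, qualities=src.qualities))
        o = truth[src.id]
        truth[rid] = ReadOrigin(o.genome_id, o.start, o.strand, duplicate_of=src.id)
    return reads, truth


def inject_positional_substitutions(
    reads: list[SequenceRecord],
    damage: DamageSpec,
    seed: int = 0,
    strands: dict[str, str] | None = None,
) -> list[SequenceRecord]:
    """Flip ``from_base -> to_base`` at fixed read positions with given rates.

    ``strands`` maps read id to '+'/'-' (e.g. the simulation truth); only
    reads on the spec's strand are touched.  With ``strands=None`` every
    read is treated as forward.
    """
    want = "+" if damage.strand == "forward" else "-"
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    for read in reads:
        strand = strands.get(read.id, "+") if strands else "+"
        if strand != want:
            out.append(read)
            continue
        arr = _from_str(read.sequence)
        changed = False
        for pos, frm, to, rate in damage.entries:
            if pos >= arr.size:
                raise ValueError(f"damage position {pos} beyond read length {arr.size}")
            if arr[pos] == ord(frm) and rng.random() < rate:
                arr[pos] = ord(to)
                changed = True
        out.append(
            SequenceRecord(read.id, _to_str(arr), read.qualities) if changed else read
        )
    return out


@dataclass(frozen=True)
class DiploidLocusSpec:
    """A multigene locus with paralogues, two haplotypes and known genotypes."""

    n_target_genes: int = 3
    n_homologues: int = 3
    paralogue_divergence: float = 0.10
    het_sites: int = 5
    hom_alt_sites: int = 2
    depth: float = 40.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    gene_length: int = 1000
    absent_genes: tuple[int, ...] = ()
    homologue_depth: float | None = None  # defaults to `depth`
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.paralogue_divergence <= 0.3):
            raise ValueError("paralogue_divergence must be in (0, 0.3]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.het_sites + self.hom_alt_sites > self.gene_length:
            raise ValueError("more variant sites than gene positions")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must cover two read lengths")
        if self.gene_length < self.insert_mean:
            raise ValueError("gene_length must exceed insert_mean")


@dataclass(frozen=True)
class VariantTruth:
    """One true variant site on a target gene's mapping reference."""

    gene: str
    position: int  # 0-based on the target reference
    ref: str
    alleles: tuple[str, str]  # (haplotype 1 base, haplotype 2 base)

    @property
    def is_het(self) -> bool:
        return self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class LocusSimulation:
    """Everything the genotyping stage needs, with truth attached."""

    target_refs: list[SequenceRecord]
    homologue_refs: list[SequenceRecord]
    pairs: list[ReadPair]
    truth_variants: dict[str, list[VariantTruth]]
    truth_presence: dict[str, bool]
    pair_origins: dict[str, str]  # pair_id -> "gene/hap{1,2}" or homologue id
    homologue_parents: dict[str, str]  # homologue id -> parent target gene
    homologue_variant_positions: dict[str, set[int]]
    # positions (on the parent target's reference) where a homologue differs


def _mutate_at(
    arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = arr.copy()
    base_idx = np.searchsorted(_BASES, out[positions])
    shift = rng.integers(1, 4, size=positions.size)
    out[positions] = _BASES[(base_idx + shift) % 4]
    return out


def simulate_paralogous_locus(spec: DiploidLocusSpec) -> LocusSimulation:
    """Simulate a diploid HLA/KIR-like locus.

    Per target gene: a mapping reference, two haplotypes differing from it at
    ``het_sites`` heterozygous and ``hom_alt_sites`` homozygous-alternate
    positions (the het alternate allele lands on a random haplotype, fixing
    the true phase), and paired-end reads at the stated mean depth.
    Homologues are derived from targets by substitution at the divergence
    rate and contribute their own read pairs — the cross-mapping
    contamination the positive/negative filter chain must remove.  Genes in
    ``absent_genes`` are listed in the panel but emit zero pairs.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.gene_length
    targets: list[SequenceRecord] = []
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth_variants: dict[str, list[VariantTruth]] = {}
    truth_presence: dict[str, bool] = {}
    for g in range(spec.n_target_genes):
        gene = f"gene{g:02d}"
        ref = rng.choice(_BASES, size=L)
        n_var = spec.het_sites + spec.hom_alt_sites
        # Variant sites are planted away from the reference edges: fragments
        # are drawn fully inside the reference, so coverage ramps over the
        # first/last read length and edge sites would be under-covered for
        # reasons unrelated to the filters under test.
        interior = np.arange(spec.read_length, L - spec.read_length)
        if interior.size < n_var:
            raise ValueError("gene_length too small for the requested variant sites")
        positions = np.sort(rng.choice(interior, size=n_var, replace=False))
        het_pos = set(positions[: spec.het_sites].tolist())
        hap1, hap2 = ref.copy(), ref.copy()
        variants: list[VariantTruth] = []
        for pos in positions.tolist():
            ref_base = chr(ref[pos])
            alt = chr(_BASES[(int(np.searchsorted(_BASES, ref[pos])) + int(rng.integers(1, 4))) % 4])
            if pos in het_pos:
                alt_on_hap1 = bool(rng.random() < 0.5)
                if alt_on_hap1:
                    hap1[pos] = ord(alt)
                    alleles = (alt, ref_base)
                else:
                    hap2[pos] = ord(alt)
                    alleles = (ref_base, alt)
            else:
                hap1[pos] = ord(alt)
                hap2[pos] = ord(alt)
                alleles = (alt, alt)
            variants.append(VariantTruth(gene, int(pos), ref_base, alleles))
        targets.append(SequenceRecord(id=gene, sequence=_to_str(ref)))
        haplotypes[gene] = (hap1, hap2)
        truth_variants[gene] = variants
        truth_presence[gene] = g not in spec.absent_genes
    homologues: list[SequenceRecord] = []
    homologue_sources: list[str] = []
    homologue_var_pos: dict[str, set[int]] = {}
    for h in range(spec.n_homologues):
        parent = targets[h % spec.n_target_genes]
        arr = _from_str(parent.sequence)
        n_div = rng.binomial(L, spec.paralogue_divergence)
        n_div = max(1, int(n_div))
        positions = rng.choice(L, size=n_div, replace=False)
        hom = _mutate_at(arr, positions, rng)
        hid = f"pseudo{h:02d}"
        homologues.append(SequenceRecord(id=hid, sequence=_to_str(hom)))
        homologue_sources.append(parent.id)
        homologue_var_pos[hid] = set(int(p) for p in positions)

    pairs: list[ReadPair] = []
    pair_origins: dict[str, str] = {}
    quals = (_DEFAULT_Q,) * spec.read_length
    counter = 0

    def emit_pairs(source_arr: np.ndarray, label: str, depth: float):
        nonlocal counter
        n_pairs = int(round(depth * L / (2.0 * spec.read_length)))
        rl = spec.read_length
        for _ in range(n_pairs):
            insert = int(np.clip(rng.normal(spec.insert_mean, spec.insert_sd), 2 * rl, L))
            start = int(rng.integers(0, L - insert + 1))
            frag = source_arr[start : start + insert]
            r1 = _to_str(frag[:rl])
            r2 = revcomp(_to_str(frag[-rl:]))
            pid = f"pair{counter:06d}"
            counter += 1
            pairs.append(
                ReadPair(
                    pair_id=pid,
                    read1=SequenceRecord(f"{pid}/1", r1, quals),
                    read2=SequenceRecord(f"{pid}/2", r2, quals),
                )
            )
            pair_origins[pid] = label

    hap_depth = spec.depth / 2.0
    for gene, (hap1, hap2) in haplotypes.items():
        if not truth_presence[gene]:
            continue
        emit_pairs(hap1, f"{gene}/hap1", hap_depth)
        emit_pairs(hap2, f"{gene}/hap2", hap_depth)
    hdepth = spec.homologue_depth if spec.homologue_depth is not None else spec.depth
    for hom in homologues:
        emit_pairs(_from_str(hom.sequence), hom.id, hdepth)
    # shuffle pair order so downstream code cannot rely on emission order
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    return LocusSimulation(
        target_refs=targets,
        homologue_refs=homologues,
        pairs=pairs,
        truth_variants=truth_variants,
        truth_presence=truth_presence,
        pair_origins=pair_origins,
        homologue_parents={
            h.id: src for h, src in zip(homologues, homologue_sources)
        },
        homologue_variant_positions=homologue_var_pos,
    )
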