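#!/usr/bin/env python
"""Simulate the study community: five microbial genomes at known cell
abundances, an off-target read pool with 1% sequencing error, 10% exact
duplicates, and position-0 purine damage on forward-strand reads.

Writes FASTA/FASTQ/truth under scratch/community/ (inputs for the later
steps) and the genome/weight manifest under results/.
"""

from pathlib import Path

from oralcap import synthetic_data as sd
from oralcap.seqio import write_fasta, write_fastq, write_genome_table

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "community"
RESULTS = ROOT / "results"

SEED_GENOMES = 211
SEED_READS = 212
SEED_DAMAGE = 213
WEIGHTS = (0.30, 0.25, 0.20, 0.15, 0.10)
N_READS = 20000


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    genomes, metas = sd.simulate_genomes(5, (8000, 15000), seed=SEED_GENOMES)
    spec = sd.CommunitySpec(
        members=tuple(zip(metas, WEIGHTS)),
        read_length=100,
        error_rate=0.01,
        seed=SEED_READS,
    )
    reads, truth = sd.simulate_reads(
        spec, {g.id: g for g in genomes}, N_READS, duplicate_fraction=0.10
    )
    strands = {rid: o.strand for rid, o in truth.items()}
    damage = sd.DamageSpec(entries=((0, "A", "G", 0.10),), strand="forward")
    reads = sd.inject_positional_substitutions(
        reads, damage, seed=SEED_DAMAGE, strands=strands
    )
    write_fasta(genomes, SCRATCH / "genomes.fa")
    write_fastq(reads, SCRATCH / "reads.fq")
    write_genome_table(metas, RESULTS / "community_genomes.tsv")
    with open(SCRATCH / "truth.tsv", "w") as fh:
        fh.write("read_id\tgenome_id\tstart\tstrand\tduplicate_of\n")
        for rid in sorted(truth):
            o = truth[rid]
            fh.write(
                f"{rid}\t{o.genome_id}\t{o.start}\t{o.strand}\t{o.duplicate_of or '.'}\n"
            )
    with open(RESULTS / "community_weights.tsv", "w") as fh:
        fh.write("genome_id\tweight\n")
        for m, w in spec.members:
            fh.write(f"{m.genome_id}\t{w}\n")
    n_dup = sum(1 for o in truth.values() if o.duplicate_of is not None)
    print(f"simulated {len(genomes)} genomes "
          f"({min(m.length_bp for m in metas)}-{max(m.length_bp for m in metas)} bp)")
    print(f"emitted {len(reads)} reads ({n_dup} exact duplicates), "
          f"error rate {spec.error_rate}, planted A->G damage 0.10 at position 0")
    print(f"inputs under {SCRATCH}, manifests under {RESULTS}")


if __name__ == "__main__":
    main()
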