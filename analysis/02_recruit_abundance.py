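#!/usr/bin/env python
"""QC-filter the simulated off-target pool, recruit reads to the reference
genomes at the three threshold tiers, and estimate genome-length-normalized
relative abundances with taxonomic rollup and per-genome coverage.

Reads the inputs written by 01_simulate_community.py; writes per-tier
abundance tables and a recruitment summary under results/.
"""

from pathlib import Path

from oralcap import align, recruitment as rc
from oralcap.readqc import filter_metagenomic_reads
from oralcap.seqio import read_fasta, read_fastq, read_genome_table, write_tables

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "community"
RESULTS = ROOT / "results"


def main():
    if not (SCRATCH / "reads.fq").exists():
        raise SystemExit("run analysis/01_simulate_community.py first")
    genomes = read_fasta(SCRATCH / "genomes.fa")
    metas = read_genome_table(RESULTS / "community_genomes.tsv")
    reads = read_fastq(SCRATCH / "reads.fq")
    passed, report = filter_metagenomic_reads(reads)
    print(f"QC: {report.n_passed}/{report.n_input} reads pass "
          f"({report.n_exact_duplicates} exact duplicates removed)")
    hits = align.align_reads(passed, genomes)
    write_tables(hits, SCRATCH / "hits.m8", kind="m8")
    res = rc.recruit_all(hits, genomes=metas)
    rows = []
    for tier_name, (counts, assigns) in res.items():
        n_assigned = sum(counts.values())
        print(f"{tier_name}: {n_assigned} reads recruited "
              f"({100 * n_assigned / len(passed):.1f}% of QC-passed)")
        table = rc.normalize_abundance(counts, metas, tier=tier_name)
        for level in ("species", "genus", "phylum"):
            rolled = rc.rollup(table, metas, level)
            rows += [
                (taxon, f"{tier_name}:{level}", ab)
                for taxon, ab in rolled.entries.items()
            ]
        rows += [(g, f"{tier_name}:genome", ab) for g, ab in table.entries.items()]
    write_tables(rows, RESULTS / "abundance_by_tier.tsv", kind="abundance_tsv")
    # coverage sanity check on the most abundant genome at species tier
    counts, assigns = res["species"]
    top = max(counts, key=counts.get)
    meta = next(m for m in metas if m.genome_id == top)
    track = rc.coverage_track(assigns, hits, meta)
    print(f"top genome {top}: {counts[top]} reads, "
          f"{100 * track.fraction_covered:.1f}% of genome covered, "
          f"localization flag {'ON' if track.localized else 'off'}")
    print(f"abundance tables -> {RESULTS / 'abundance_by_tier.tsv'}")


if __name__ == "__main__":
    main()
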