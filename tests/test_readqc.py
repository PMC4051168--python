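import math

import numpy as np
import pytest

from conftest import make_read
from helpers_oracles import midpoint_on_target
from oralcap import synthetic_data as sd
from oralcap.readqc import (
    MappedRead,
    ReadSummary,
    capture_metrics,
    filter_locus_pairs,
    filter_metagenomic_reads,
    substitution_profile,
)
from oralcap.seqio import ReadPair, SequenceRecord, TargetInterval


class TestMetagenomicFilter:
    def test_each_rule_counted_with_exact_boundaries(self):
        reads = [
            make_read("ok", "A" * 50, q=40),            # passes: boundary length 50
            make_read("short", "A" * 49, q=40),          # too short
            make_read("lowq", "A" * 60, q=24),           # mean quality < 25
            make_read("exactq", "A" * 60, q=25),         # mean exactly 25: retained
            make_read("ambig", "A" * 59 + "N", q=40),    # ambiguous base
            make_read("dup", "A" * 50, q=40),            # duplicate of "ok"
        ]
        passed, rep = filter_metagenomic_reads(reads)
        assert [r.id for r in passed] == ["ok", "exactq"]
        assert rep.n_input == 6
        assert rep.n_short == 1
        assert rep.n_low_mean_quality == 1
        assert rep.n_ambiguous == 1
        assert rep.n_exact_duplicates == 1
        assert rep.n_passed == 2

    def test_multiply_failing_read_counted_per_rule(self):
        reads = [make_read("bad", "N" * 10, q=5)]  # short + low-q + ambiguous
        _, rep = filter_metagenomic_reads(reads)
        assert (rep.n_short, rep.n_low_mean_quality, rep.n_ambiguous) == (1, 1, 1)
        assert rep.n_passed == 0

    def test_first_duplicate_occurrence_kept(self):
        reads = [make_read("a", "C" * 50), make_read("b", "C" * 50), make_read("c", "C" * 50)]
        passed, rep = filter_metagenomic_reads(reads)
        assert [r.id for r in passed] == ["a"]
        assert rep.n_exact_duplicates == 2

    def test_missing_qualities_is_error(self):
        with pytest.raises(ValueError, match="qualities"):
            filter_metagenomic_reads([SequenceRecord("x", "A" * 50)])

    def test_rule_order_invariance_via_predicate_independence(self):
        # a read failing only the duplicate rule must survive any reordering
        # of the predicate rules: predicates see the read alone
        reads = [make_read("a", "G" * 50), make_read("lowq_dup", "G" * 50, q=10)]
        passed, rep = filter_metagenomic_reads(reads)
        # low-quality duplicate: counted low-quality, not counted duplicate
        # (predicates are applied to every read; dedup only among survivors)
        assert rep.n_low_mean_quality == 1
        assert rep.n_exact_duplicates == 0
        assert [r.id for r in passed] == ["a"]


class TestLocusPairFilter:
    def _pair(self, q1, q2):
        return ReadPair(
            "p",
            SequenceRecord("p/1", "A" * len(q1), tuple(q1)),
            SequenceRecord("p/2", "A" * len(q2), tuple(q2)),
        )

    def test_six_bad_bases_removed(self):
        pair = self._pair([3] * 6 + [40] * 44, [40] * 50)
        passed, counts = filter_locus_pairs([pair])
        assert passed == []
        assert counts["n_removed"] == 1

    def test_five_bad_bases_retained_strict_boundary(self):
        pair = self._pair([3] * 3 + [40] * 47, [2] * 2 + [40] * 48)
        passed, _ = filter_locus_pairs([pair])
        assert len(passed) == 1

    def test_all_high_quality_retained(self):
        pair = self._pair([40] * 50, [40] * 50)
        passed, _ = filter_locus_pairs([pair])
        assert len(passed) == 1

    def test_missing_qualities_error(self):
        pair = ReadPair("p", SequenceRecord("1", "ACGT"), SequenceRecord("2", "ACGT"))
        with pytest.raises(ValueError):
            filter_locus_pairs([pair])


def _mapped(read, ref, strand="+", cigar=None):
    return MappedRead(
        read=read,
        strand=strand,
        reference_segment=ref,
        cigar=cigar or f"{len(read.sequence)}M",
    )


class TestSubstitutionProfile:
    def test_error_free_reads_give_all_zero_profile(self):
        reads = [make_read(f"r{i}", "ACGT" * 10) for i in range(20)]
        prof = substitution_profile(
            [_mapped(r, r.sequence) for r in reads], read_length=40
        )
        assert prof.total_rate("forward").sum() == 0.0
        assert prof.total_rate("reverse").sum() == 0.0

    def test_indel_and_clip_cigars_excluded(self):
        r = make_read("r", "A" * 75)
        entries = [
            _mapped(r, "A" * 75),                      # kept
            _mapped(r, "A" * 75, cigar="30M1I44M"),    # excluded: insertion
            _mapped(r, "A" * 75, cigar="5S70M"),       # excluded: clipping
        ]
        prof = substitution_profile(entries, read_length=75)
        assert prof.n_reads["forward"] == 1

    def test_planted_damage_recovered_and_reverse_untouched(self):
        rng = np.random.default_rng(8)
        genome = "".join(rng.choice(list("ACGT"), size=20000))
        gsr = SequenceRecord("g", genome)
        from oralcap.seqio import GenomeMeta

        m = GenomeMeta("g", 20000, "sp", "ge", "ph")
        spec = sd.CommunitySpec(members=((m, 1.0),), read_length=60, error_rate=0.0, seed=9)
        reads, truth = sd.simulate_reads(spec, {"g": gsr}, 10000)
        strands = {rid: o.strand for rid, o in truth.items()}
        damage = sd.DamageSpec(entries=((0, "A", "G", 0.10),), strand="forward")
        damaged = sd.inject_positional_substitutions(reads, damage, seed=10, strands=strands)
        entries = []
        for read in damaged:
            o = truth[read.id]
            ref = genome[o.start : o.start + 60]
            from oralcap.align import revcomp

            if o.strand == "-":
                ref = revcomp(ref)
            entries.append(_mapped(read, ref, strand=o.strand))
        prof = substitution_profile(entries, read_length=60)
        n_fwd = prof.n_reads["forward"]
        # ~1/4 of forward reads have A at position 0; each flips w.p. 0.1
        p = 0.25 * 0.10
        rate = prof.rate("forward", "A", "G")[0]
        sd_bin = math.sqrt(p * (1 - p) / n_fwd)
        assert abs(rate - p) < 3 * sd_bin
        assert prof.rate("reverse", "A", "G")[0] == 0.0
        # no other substitution type contaminated at position 0
        assert prof.total_rate("forward")[0] == pytest.approx(rate)

    def test_uniform_error_rate_recovered_at_interior_positions(self):
        rng = np.random.default_rng(15)
        genome = "".join(rng.choice(list("ACGT"), size=20000))
        gsr = SequenceRecord("g", genome)
        from oralcap.seqio import GenomeMeta

        m = GenomeMeta("g", 20000, "sp", "ge", "ph")
        e = 0.02
        spec = sd.CommunitySpec(members=((m, 1.0),), read_length=40, error_rate=e, seed=16)
        reads, truth = sd.simulate_reads(spec, {"g": gsr}, 8000)
        from oralcap.align import revcomp

        entries = []
        for read in reads:
            o = truth[read.id]
            ref = genome[o.start : o.start + 40]
            if o.strand == "-":
                ref = revcomp(ref)
            entries.append(_mapped(read, ref, strand=o.strand))
        prof = substitution_profile(entries, read_length=40)
        for strand in ("forward", "reverse"):
            n = prof.n_reads[strand]
            total = prof.total_rate(strand)
            sd_bin = math.sqrt(e * (1 - e) / n)
            for pos in range(5, 35):
                assert abs(total[pos] - e) < 4 * sd_bin

    def test_reference_length_mismatch_error(self):
        r = make_read("r", "ACGT")
        with pytest.raises(ValueError, match="length"):
            substitution_profile([_mapped(r, "ACG")], read_length=4)


class TestCaptureMetrics:
    def test_unmapped_percentage(self):
        targets = [TargetInterval("chr1", 0, 1000)]
        summary = [ReadSummary(f"r{i}", mapped=i >= 10, chrom="chr1", start=0, end=100)
                   for i in range(100)]
        summary = [
            ReadSummary(r.read_id, r.mapped, False, "chr1" if r.mapped else None,
                        0 if r.mapped else None, 100 if r.mapped else None)
            for r in summary
        ]
        m = capture_metrics(summary, targets)
        assert m.pct_unmapped == pytest.approx(10.0)

    def test_uniform_depth_median(self):
        targets = [TargetInterval("chr1", 0, 1000)]
        summary = [
            ReadSummary(f"r{i}", True, False, "chr1", 0, 1000) for i in range(12)
        ]
        m = capture_metrics(summary, targets)
        assert m.median_target_coverage == 12

    def test_duplicates_over_mapped_reads(self):
        targets = [TargetInterval("chr1", 0, 100)]
        summary = [
            ReadSummary("u", False),
            ReadSummary("m1", True, False, "chr1", 0, 50),
            ReadSummary("m2", True, True, "chr1", 0, 50),
        ]
        m = capture_metrics(summary, targets)
        assert m.pct_duplicates == pytest.approx(50.0)

    def test_on_target_matches_brute_force_midpoint_oracle(self, rng):
        targets = [
            TargetInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 5000, 8), rng.integers(50, 400, 8))
        ]
        tuples = [(t.start, t.end) for t in targets]
        summary = []
        expected_on = 0
        n_usable = 0
        for i in range(300):
            start = int(rng.integers(0, 5200))
            end = start + 100
            summary.append(ReadSummary(f"r{i}", True, False, "chr1", start, end))
            n_usable += 1
            expected_on += midpoint_on_target(start, end, tuples)
        m = capture_metrics(summary, targets)
        assert m.pct_on_target == pytest.approx(100.0 * expected_on / n_usable)

    def test_empty_targets_is_error(self):
        with pytest.raises(ValueError):
            capture_metrics([ReadSummary("r", False)], [])

    def test_duplicate_fraction_recovered_from_synthetic_community(self):
        # coordinate-free check: flags carried through from generator truth
        from oralcap.seqio import GenomeMeta, SequenceRecord as SR

        rng = np.random.default_rng(77)
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        m = GenomeMeta("g", 5000, "sp", "ge", "ph")
        spec = sd.CommunitySpec(members=((m, 1.0),), read_length=50, error_rate=0.0, seed=78)
        reads, truth = sd.simulate_reads(spec, {"g": SR("g", genome)}, 4000, duplicate_fraction=0.15)
        targets = [TargetInterval("g", 0, 5000)]
        summary = [
            ReadSummary(r.id, True, truth[r.id].duplicate_of is not None,
                        "g", truth[r.id].start, truth[r.id].start + 50)
            for r in reads
        ]
        met = capture_metrics(summary, targets)
        assert met.pct_duplicates == pytest.approx(15.0, abs=0.01)
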