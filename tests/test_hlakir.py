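import numpy as np
import pytest

from oralcap import hlakir as hk
from oralcap import readqc, synthetic_data as sd
from oralcap.align import revcomp
from oralcap.seqio import ReadPair, SequenceRecord


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _pair(pid, s1, s2, q=40):
    return ReadPair(
        pid,
        SequenceRecord(f"{pid}/1", s1, (q,) * len(s1)),
        SequenceRecord(f"{pid}/2", s2, (q,) * len(s2)),
    )


def _mutate_exact(seq, n_mut, rng):
    """Substitute at exactly n_mut distinct positions."""
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
    return "".join(arr)


@pytest.fixture
def panel(rng):
    target = SequenceRecord("geneA", _rand_seq(rng, 600))
    hom = SequenceRecord("pseudoA", _mutate_exact(target.sequence, 60, rng))
    return hk.LocusPanel(
        target_refs={"geneA": (target,)},
        homologue_refs=(hom,),
        low_stringency=5,
    )


class TestPositiveFilter:
    def test_exact_window_mate_kept(self, panel, rng):
        ref = panel.target_refs["geneA"][0].sequence
        pair = _pair("p1", ref[100:200], revcomp(ref[300:400]))
        assert hk.positive_filter([pair], panel, "geneA") == [pair]

    def test_unrelated_pair_dropped(self, panel, rng):
        pair = _pair("p2", _rand_seq(rng, 100), _rand_seq(rng, 100))
        assert hk.positive_filter([pair], panel, "geneA") == []

    def test_stringency_controls_divergent_mate(self, panel, rng):
        ref = panel.target_refs["geneA"][0].sequence
        window = ref[100:200]
        mate = _mutate_exact(window, 10, rng)  # 10% divergence over the read
        pair = _pair("p3", mate, _rand_seq(rng, 100))
        strict = hk.LocusPanel(panel.target_refs, panel.homologue_refs, low_stringency=3)
        loose = hk.LocusPanel(panel.target_refs, panel.homologue_refs, low_stringency=12)
        assert hk.positive_filter([pair], strict, "geneA") == []
        assert hk.positive_filter([pair], loose, "geneA") == [pair]

    def test_unknown_gene_rejected(self, panel):
        with pytest.raises(ValueError, match="absent"):
            hk.positive_filter([], panel, "nope")


class TestNegativeFilter:
    def test_target_exclusive_pair_retained(self, panel, rng):
        ref = panel.target_refs["geneA"][0].sequence
        hom = panel.homologue_refs[0].sequence
        # find a window where target and homologue differ a lot
        best = max(
            range(0, 500, 10),
            key=lambda s: sum(a != b for a, b in zip(ref[s : s + 100], hom[s : s + 100])),
        )
        pair = _pair("p", ref[best : best + 100], revcomp(ref[best : best + 100]))
        assert hk.negative_filter([pair], panel) == [pair]

    def test_pair_matching_homologue_removed(self, panel):
        hom = panel.homologue_refs[0].sequence
        pair = _pair("p", hom[100:200], revcomp(hom[300:400]))
        assert hk.negative_filter([pair], panel) == []

    def test_empty_homologue_set_warns_and_passes(self, panel, rng):
        empty = hk.LocusPanel(panel.target_refs, (), low_stringency=5)
        pair = _pair("p", _rand_seq(rng, 100), _rand_seq(rng, 100))
        with pytest.warns(UserWarning, match="pass-through"):
            assert hk.negative_filter([pair], empty) == [pair]


class TestCallGenotypes:
    REF = SequenceRecord("g", "A" * 50)

    def _col(self, pos, counts):
        base = {"A": 0, "C": 0, "G": 0, "T": 0}
        base.update(counts)
        return hk.PileupColumn("g", pos, base)

    def test_hom_at_depth_25(self):
        calls = hk.call_genotypes([self._col(0, {"G": 25})], self.REF)
        c = calls[0]
        assert (c.kind, c.alleles) == ("hom", ("G",))

    def test_hom_at_depth_19_is_no_call(self):
        c = hk.call_genotypes([self._col(0, {"G": 19})], self.REF)[0]
        assert (c.kind, c.reason) == ("no_call", "low_depth")

    def test_het_at_depth_12(self):
        c = hk.call_genotypes([self._col(0, {"A": 6, "G": 6})], self.REF)[0]
        assert (c.kind, c.alleles) == ("het", ("A", "G"))

    def test_het_at_depth_9_is_no_call(self):
        c = hk.call_genotypes([self._col(0, {"A": 5, "G": 4})], self.REF)[0]
        assert (c.kind, c.reason) == ("no_call", "low_depth")

    def test_hom_ref_requires_hom_depth(self):
        c20 = hk.call_genotypes([self._col(0, {"A": 20})], self.REF)[0]
        c19 = hk.call_genotypes([self._col(0, {"A": 19})], self.REF)[0]
        assert (c20.kind, c20.alleles) == ("hom", ("A",))
        assert c19.kind == "no_call"

    def test_three_alleles_never_forced_diploid(self):
        c = hk.call_genotypes([self._col(0, {"A": 10, "C": 10, "G": 10})], self.REF)[0]
        assert (c.kind, c.reason) == ("no_call", "multi_allelic")

    def test_allele_fraction_floor_suppresses_error_base(self):
        # one stray base at depth 21 must not create a het
        c = hk.call_genotypes([self._col(0, {"A": 20, "G": 1})], self.REF)[0]
        assert (c.kind, c.alleles) == ("hom", ("A",))

    def test_is_variant_classification(self):
        hom_ref = hk.call_genotypes([self._col(0, {"A": 25})], self.REF)[0]
        hom_alt = hk.call_genotypes([self._col(0, {"G": 25})], self.REF)[0]
        assert not hom_ref.is_variant
        assert hom_alt.is_variant


class TestGenePresence:
    def test_threshold_is_inclusive(self):
        calls = hk.gene_presence({"a": 5.0, "b": 4.99, "c": 0.0}, presence_min_depth=5.0)
        assert [(c.gene, c.present) for c in calls] == [
            ("a", True), ("b", False), ("c", False),
        ]


class TestPhaseLocal:
    def _setup_pairs(self, ref, sites, pairing, n_pairs, rng, span=150):
        """Generate pairs observing `sites` with a fixed allele `pairing`."""
        pairs = []
        for i in range(n_pairs):
            hap = i % 2
            arr = list(ref.sequence)
            for pos, alleles in zip(sites, pairing):
                arr[pos] = alleles[hap]
            s = "".join(arr)
            lo = max(0, min(sites) - 20)
            r1 = s[lo : lo + span // 2]
            r2 = revcomp(s[lo + span // 2 : lo + span])
            pairs.append(_pair(f"ph{i}", r1, r2))
        return pairs

    def test_consistent_pairing_one_phase_set(self, rng):
        ref = SequenceRecord("g", _rand_seq(rng, 400))
        sites = (60, 110)
        pairing = (("A", "G"), ("C", "T"))
        pairs = self._setup_pairs(ref, sites, pairing, 30, rng)
        cols = hk.pileup(pairs, ref, "g")
        calls = hk.call_genotypes(cols, ref)
        phased = hk.phase_local(calls, pairs, ref)
        het = {c.position: c for c in phased if c.is_het}
        assert set(het) >= set(sites)
        assert het[60].phase_set is not None
        assert het[60].phase_set == het[110].phase_set
        # allele pairing preserved: (A with C) and (G with T)
        combo = {het[60].phase_alleles, het[110].phase_alleles}
        assert ({p[0] for p in combo} == {"A", "C"}) or (
            {p[0] for p in combo} == {"G", "T"}
        )

    def test_distant_sites_stay_in_separate_phase_sets(self, rng):
        ref = SequenceRecord("g", _rand_seq(rng, 2000))
        near = self._setup_pairs(ref, (60, 110), (("A", "G"), ("C", "T")), 30, rng)
        far = self._setup_pairs(ref, (1800, 1850), (("A", "G"), ("C", "T")), 30, rng)
        pairs = near + [
            _pair(f"f{i}", p.read1.sequence, p.read2.sequence)
            for i, p in enumerate(far)
        ]
        cols = hk.pileup(pairs, ref, "g")
        calls = hk.call_genotypes(cols, ref)
        phased = hk.phase_local(calls, pairs, ref)
        het = {c.position: c for c in phased if c.is_het}
        assert het[60].phase_set != het[1800].phase_set

    def test_conflicting_evidence_flags_sites_unphased(self, rng):
        ref = SequenceRecord("g", _rand_seq(rng, 400))
        sites = (60, 110)
        cis = self._setup_pairs(ref, sites, (("A", "G"), ("C", "T")), 16, rng)
        trans_pairs = self._setup_pairs(ref, sites, (("A", "G"), ("T", "C")), 16, rng)
        pairs = cis + [
            _pair(f"x{i}", p.read1.sequence, p.read2.sequence)
            for i, p in enumerate(trans_pairs)
        ]
        cols = hk.pileup(pairs, ref, "g")
        calls = hk.call_genotypes(cols, ref)
        phased = hk.phase_local(calls, pairs, ref)
        het = {c.position: c for c in phased if c.is_het}
        assert het[60].phase_conflict and het[110].phase_conflict
        assert het[60].phase_set is None


class TestConcordance:
    def _call(self, gene, pos, ref, kind, alleles, depth=30):
        return hk.GenotypeCall(gene, pos, ref, kind, alleles, depth, {})

    def test_identical_call_sets_rate_one(self):
        calls = [self._call("g", i, "A", "het", ("A", "G")) for i in range(10)]
        truth = {("g", i): ("A", "G") for i in range(10)}
        res = hk.concordance(calls, truth)
        assert res.rate == 1.0

    def test_99_of_100(self):
        calls = [self._call("g", i, "A", "hom", ("G",)) for i in range(100)]
        truth = {("g", i): ("G", "G") for i in range(99)}
        truth[("g", 99)] = ("T", "T")
        res = hk.concordance(calls, truth)
        assert res.rate == pytest.approx(0.99)

    def test_non_ref_only_excludes_hom_ref_truth(self):
        calls = [
            self._call("g", 0, "A", "hom", ("G",)),   # truth hom-ref: excluded
            self._call("g", 1, "A", "het", ("A", "G")),
        ]
        truth = {("g", 0): ("A", "A"), ("g", 1): ("A", "G")}
        res = hk.concordance(calls, truth, non_ref_only=True)
        assert res.n_compared == 1
        assert res.rate == 1.0

    def test_no_calls_counted_separately(self):
        calls = [
            self._call("g", 0, "A", "no_call", ()),
            self._call("g", 1, "A", "hom", ("G",)),
        ]
        truth = {("g", 0): ("G", "G"), ("g", 1): ("G", "G")}
        res = hk.concordance(calls, truth)
        assert (res.n_compared, res.n_no_call, res.rate) == (1, 1, 1.0)

    def test_empty_comparison_rejected(self):
        with pytest.raises(ValueError):
            hk.concordance([], {("g", 0): ("A", "A")})


class TestEndToEnd:
    def test_filter_chain_monotone_and_truth_recovered(self, locus_sim):
        spec, sim = locus_sim
        panel = hk.LocusPanel(
            target_refs={t.id: (t,) for t in sim.target_refs},
            homologue_refs=tuple(sim.homologue_refs),
        )
        passed, _ = readqc.filter_locus_pairs(sim.pairs)
        for gene in panel.target_refs:
            cand = hk.positive_filter(passed, panel, gene)
            retained = hk.negative_filter(cand, panel)
            assert {p.pair_id for p in retained} <= {p.pair_id for p in cand}
            assert {p.pair_id for p in cand} <= {p.pair_id for p in passed}
            # every retained homologue-origin pair has no divergent site in span
            hom_ids = {h.id for h in sim.homologue_refs}
            leaked = [
                p for p in retained if sim.pair_origins[p.pair_id] in hom_ids
            ]
            # homologue pairs may survive only if indistinguishable from the
            # target (no divergence site under either mate)
            for p in leaked:
                origin = sim.pair_origins[p.pair_id]
                parent = sim.homologue_parents[origin]
                hom_seq = next(h for h in sim.homologue_refs if h.id == origin)
                tgt_seq = next(t for t in sim.target_refs if t.id == parent)
                for mate in (p.read1, p.read2):
                    assert (
                        mate.sequence in tgt_seq.sequence
                        or revcomp(mate.sequence) in tgt_seq.sequence
                    )
        res = hk.genotype_locus(passed, panel)
        for gene, variants in sim.truth_variants.items():
            truth = {(v.gene, v.position): tuple(sorted(v.alleles)) for v in variants}
            conc = hk.concordance(res.calls[gene], truth)
            assert conc.rate == 1.0

    def test_phasing_matches_planted_haplotypes(self, locus_sim):
        spec, sim = locus_sim
        panel = hk.LocusPanel(
            target_refs={t.id: (t,) for t in sim.target_refs},
            homologue_refs=tuple(sim.homologue_refs),
        )
        res = hk.genotype_locus(sim.pairs, panel)
        for gene, variants in sim.truth_variants.items():
            truth_het = {v.position: v.alleles for v in variants if v.is_het}
            phased = [
                c for c in res.calls[gene]
                if c.phase_set is not None and c.position in truth_het
            ]
            by_set: dict[int, list] = {}
            for c in phased:
                by_set.setdefault(c.phase_set, []).append(c)
            for members in by_set.values():
                if len(members) < 2:
                    continue
                # within a set, phase_alleles columns must match one of the
                # two true haplotype assignments
                col_a = tuple(c.phase_alleles[0] for c in members)
                hap1 = tuple(truth_het[c.position][0] for c in members)
                hap2 = tuple(truth_het[c.position][1] for c in members)
                assert col_a in (hap1, hap2)

    def test_lower_depth_drives_het_to_no_call_not_wrong_hom(self):
        for seed in range(3):
            spec = sd.DiploidLocusSpec(
                n_target_genes=1, n_homologues=1, depth=8.0,
                gene_length=700, seed=100 + seed,
            )
            sim = sd.simulate_paralogous_locus(spec)
            panel = hk.LocusPanel(
                target_refs={t.id: (t,) for t in sim.target_refs},
                homologue_refs=tuple(sim.homologue_refs),
            )
            res = hk.genotype_locus(sim.pairs, panel)
            for gene, variants in sim.truth_variants.items():
                for v in variants:
                    if not v.is_het:
                        continue
                    call = next(
                        c for c in res.calls[gene] if c.position == v.position
                    )
                    assert call.kind in ("het", "no_call")

    def test_absent_gene_called_absent(self):
        spec = sd.DiploidLocusSpec(
            n_target_genes=2, n_homologues=1, depth=30, gene_length=700,
            seed=55, absent_genes=(1,),
        )
        sim = sd.simulate_paralogous_locus(spec)
        panel = hk.LocusPanel(
            target_refs={t.id: (t,) for t in sim.target_refs},
            homologue_refs=tuple(sim.homologue_refs),
        )
        res = hk.genotype_locus(sim.pairs, panel)
        presence = {p.gene: p.present for p in res.presence}
        assert presence == {"gene00": True, "gene01": False}


class TestSelectReference:
    def test_best_matching_allele_chosen(self, rng):
        ref = SequenceRecord("geneA*01", _rand_seq(rng, 500))
        other = SequenceRecord("geneA*02", _mutate_exact(ref.sequence, 25, rng))
        panel = hk.LocusPanel(
            target_refs={"geneA": (other, ref)}, homologue_refs=(), low_stringency=5
        )
        pairs = [
            _pair(f"p{i}", ref.sequence[s : s + 100], revcomp(ref.sequence[s + 150 : s + 250]))
            for i, s in enumerate(range(0, 250, 50))
        ]
        chosen = hk.select_reference(pairs, panel, "geneA")
        assert chosen.id == "geneA*01"
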