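import random

import pytest
from hypothesis import given, settings, strategies as st

from crispritools.genome_io import Feature, GenomeRecord, revcomp
from crispritools.guide_design import (
    DesignParams,
    GuideCandidate,
    count_binding_sites,
    design_guides,
    enumerate_candidates,
    filter_unique,
    rank_candidates,
    specificity_pattern,
    validate_pairing,
)
from tests.conftest import make_feature, make_genome, random_seq
from tests.oracles import (
    brute_force_candidates,
    brute_force_site_count,
    pairing_run_oracle,
    rc,
)

P = DesignParams()


def test_params_ordering_invariant_enforced():
    with pytest.raises(ValueError):
        DesignParams(seed_len=25)
    with pytest.raises(ValueError):
        DesignParams(min_pairing_run=5)  # < exact_core_len


class TestEnumerate:
    def test_no_cc_means_no_candidates(self):
        seq = ("ATG" * 40).replace("C", "A")  # no C at all
        genome = make_genome("T" * 10 + seq + "T" * 10)
        feat = make_feature(10, 10 + len(seq))
        assert enumerate_candidates(feat, genome, P) == []

    def test_planted_ccn_single_candidate(self):
        # 60-nt CDS with exactly one CC at sense offset 9
        rng = random.Random(3)
        while True:
            sense = random_seq(rng, 60).replace("C", "T")
            sense = sense[:9] + "CCA" + sense[12:60]
            if sense.count("CC") == 1:
                break
        genome = make_genome("A" * 20 + sense + "A" * 20)
        feat = make_feature(20, 80)
        cands = enumerate_candidates(feat, genome, P)
        assert len(cands) == 1
        c = cands[0]
        assert c.dist5 == 9
        assert c.spacer == revcomp(sense[12:32])
        assert c.pam == revcomp(sense[9:12])
        assert c.pam[1:] == "GG"
        # agrees with the independent brute-force scan of both strands
        brute = brute_force_candidates(feat, genome[0])
        assert brute == {(c.spacer, c.dist5, c.proto_start, c.proto_end, c.pam_strand)}

    def test_feature_shorter_than_footprint_is_empty(self):
        genome = make_genome("CC" + "A" * 40)
        feat = make_feature(0, 22, ftype="sRNA")
        assert enumerate_candidates(feat, genome, P) == []

    def test_spacer_and_pam_shapes(self, standard_fixture):
        records, features, _ = standard_fixture
        for feat in features:
            for c in enumerate_candidates(feat, records, P):
                assert len(c.spacer) == 20
                assert len(c.pam) == 3 and c.pam[1:] == "GG"
                assert c.seed == c.spacer[-12:]

    def test_self_consistency_of_coordinates(self, standard_fixture):
        records, features, _ = standard_fixture
        by_id = {r.id: r for r in records}
        for feat in features:
            for c in enumerate_candidates(feat, records, P):
                plus = by_id[c.record_id].seq[c.proto_start : c.proto_end]
                observed = plus if c.pam_strand == "+" else revcomp(plus)
                assert observed == c.spacer
                if c.pam_strand == "+":
                    pam = by_id[c.record_id].seq[c.proto_end : c.proto_end + 3]
                else:
                    pam = revcomp(by_id[c.record_id].seq[c.proto_start - 3 : c.proto_start])
                assert pam == c.pam

    def test_n_containing_candidates_dropped(self):
        sense = "ATG" + "CCA" + "N" + "A" * 19 + "T" * 40
        genome = make_genome(sense)
        feat = make_feature(0, len(sense))
        assert enumerate_candidates(feat, genome, P) == []

    def test_template_rule_scans_sense_strand(self):
        spacer = "ATTATTATTATTATTATTAT"
        sense = "ATG" + spacer + "AGG" + "T" * 34
        genome = make_genome(sense)
        feat = make_feature(0, len(sense))
        both = enumerate_candidates(
            feat, genome, DesignParams(strand_rule="template")
        )
        assert [c.spacer for c in both] == [spacer]
        assert both[0].targets_template and both[0].pam_strand == "+"


class TestSpecificityPattern:
    def _cand(self, seed):
        return GuideCandidate(
            feature_id="g", record_id="chr", spacer="A" * 8 + seed, pam="AGG",
            proto_start=0, proto_end=20, pam_strand="+", seed=seed,
            seed_gc=0.5, dist5=0,
        )

    def test_worked_example(self):
        pat = specificity_pattern(self._cand("ACACACACACAC"), P)
        assert pat == "ACACACACACACNGG"
        assert sum(1 for c in pat if c != "N") == 14

    @pytest.mark.parametrize("seed_len,spacer_len", [(10, 20), (12, 20), (12, 22)])
    def test_informative_length_is_seed_plus_two(self, seed_len, spacer_len):
        params = DesignParams(seed_len=seed_len, spacer_len=spacer_len,
                              min_pairing_run=seed_len, exact_core_len=7)
        seed = "ACGT" * 5
        cand = self._cand(seed[:seed_len])
        pat = specificity_pattern(cand, params)
        assert sum(1 for c in pat if c != "N") == seed_len + 2


class TestCountBindingSites:
    def test_sole_self_site(self):
        proto = "ATTATTATTATTATTATTAT"
        genome = make_genome(proto + "AGG")
        feat = make_feature(0, 23, ftype="sRNA", strand="-")
        (cand,) = enumerate_candidates(feat, genome, P)
        count, hits = count_binding_sites(cand, genome, P)
        assert count == 1 and hits[0].strand == "+"

    def test_planted_three_loci_one_reverse(self):
        seed = "ATTAGTATTGAT"
        site = seed + "TGG"  # seed + PAM instance, 15 nt
        # seed at [10,22), PAM at [22,25); protospacer+PAM footprint [2,25)
        genome = make_genome(
            "A" * 10 + site + "A" * 30 + site + "A" * 30 + rc(site) + "A" * 10
        )
        feat = make_feature(2, 25, ftype="sRNA", strand="-")
        cand = next(c for c in cands_at(feat, genome, 0))
        assert cand.seed == seed
        count, hits = count_binding_sites(cand, genome, P)
        assert count == 3
        assert sorted(h.strand for h in hits) == ["+", "+", "-"]
        assert count == brute_force_site_count(seed + "NGG", genome)

    def test_seed_without_gg_pam_not_counted(self):
        seed = "ATTAGTATTGAT"
        genome = make_genome(
            "A" * 10 + seed + "TGG" + "A" * 20 + seed + "ACG" + "A" * 5
        )
        feat = make_feature(2, 25, ftype="sRNA", strand="-")
        cand = next(c for c in cands_at(feat, genome, 0))
        count, _ = count_binding_sites(cand, genome, P)
        assert count == 1  # the second seed copy lacks GG at PAM 2-3

    def test_circular_wrap_only_when_circular(self):
        seed = "ATTAGTATTGAT"
        site = seed + "TGG"
        # split the site across the origin: last 8 nt at the end, rest at the start
        linear = make_genome(site[8:] + "A" * 60 + site[:8])
        circular = make_genome(site[8:] + "A" * 60 + site[:8], circular=True)
        cand = GuideCandidate(
            feature_id="x", record_id="chr", spacer="A" * 8 + seed, pam="TGG",
            proto_start=0, proto_end=20, pam_strand="+", seed=seed,
            seed_gc=0.0, dist5=0,
        )
        assert count_binding_sites(cand, linear, P)[0] == 0
        assert count_binding_sites(cand, circular, P)[0] == 1
        assert brute_force_site_count(seed + "NGG", circular) == 1

    def test_genomic_n_never_matches(self):
        seed = "ATTAGTATTGAT"
        genome = make_genome("A" * 5 + seed[:-1] + "N" + "TGG" + "A" * 5)
        cand = GuideCandidate(
            feature_id="x", record_id="chr", spacer="A" * 8 + seed, pam="TGG",
            proto_start=0, proto_end=20, pam_strand="+", seed=seed,
            seed_gc=0.0, dist5=0,
        )
        assert count_binding_sites(cand, genome, P)[0] == 0


def cands_at(feat, genome, dist5):
    return [c for c in enumerate_candidates(feat, genome, P) if c.dist5 == dist5]


class TestFilterUnique:
    def test_partition_and_planted_duplicate(self, standard_fixture):
        records, features, truth = standard_fixture
        feat = next(f for f in features if f.id == "gene_00")
        cands = enumerate_candidates(feat, records, P)
        kept, discarded = filter_unique(cands, records, P)
        assert {id(c) for c in kept} | {id(c) for c in discarded} == {id(c) for c in cands}
        assert not ({id(c) for c in kept} & {id(c) for c in discarded})
        dup = next(c for c in discarded)
        assert dup.offtarget_count == truth["offtarget_counts"]["gene_00:0"] == 3

    def test_require_unique_false_keeps_all(self, standard_fixture):
        records, features, _ = standard_fixture
        relaxed = DesignParams(require_unique=False)
        feat = next(f for f in features if f.id == "gene_00")
        cands = enumerate_candidates(feat, records, relaxed)
        kept, discarded = filter_unique(cands, records, relaxed)
        assert discarded == [] and len(kept) == len(cands)
        assert all(c.offtarget_count >= 1 for c in kept)

    def test_removing_record_never_increases_counts(self):
        spec_genome = [
            GenomeRecord(id="rec_a", seq="ATTAGTATTGATTGG" + "A" * 50),
            GenomeRecord(id="rec_b", seq="C" * 20 + "ATTAGTATTGATAGG" + "C" * 20),
        ]
        cand = GuideCandidate(
            feature_id="x", record_id="rec_a", spacer="A" * 8 + "ATTAGTATTGAT",
            pam="TGG", proto_start=0, proto_end=20, pam_strand="+",
            seed="ATTAGTATTGAT", seed_gc=0.0, dist5=0,
        )
        full, _ = count_binding_sites(cand, spec_genome, P)
        reduced, _ = count_binding_sites(cand, spec_genome[:1], P)
        assert reduced <= full


class TestValidatePairing:
    def test_perfect_match_passes(self):
        s = "ACGTACGTACGTACGTACGT"
        rep = validate_pairing(s, s, P)
        assert rep.passed and rep.run == 20 and rep.mismatches == ()

    def test_single_mismatch_sweep(self):
        """Mismatch at PAM-proximal positions 1-12 kills pairing; 13-20 tolerated."""
        spacer = "ACGTACGTACGTACGTACGT"
        for pos in range(1, 21):  # 1 = PAM-proximal = last spacer base
            idx = len(spacer) - pos
            site = spacer[:idx] + ("A" if spacer[idx] != "A" else "C") + spacer[idx + 1 :]
            rep = validate_pairing(spacer, site, P)
            assert rep.run == pairing_run_oracle(spacer, site) == pos - 1
            assert rep.passed == (pos >= 13)
            assert rep.mismatches == (pos,)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            validate_pairing("ACGT", "ACG")


class TestRanking:
    def _cand(self, dist5, seed="G" * 12, start=0):
        return GuideCandidate(
            feature_id="g", record_id="chr", spacer="A" * 8 + seed, pam="AGG",
            proto_start=start, proto_end=start + 20, pam_strand="+", seed=seed,
            seed_gc=(seed.count("G") + seed.count("C")) / 12, dist5=dist5,
        )

    def test_five_prime_proximity_order(self):
        ranked = rank_candidates([self._cand(40), self._cand(5)], P)
        assert [c.dist5 for c in ranked] == [5, 40]
        assert [c.rank for c in ranked] == [1, 2]

    def test_single_candidate_rank_one(self):
        assert rank_candidates([self._cand(7)], P)[0].rank == 1

    def test_low_gc_flag_at_4_of_12(self):
        weak = self._cand(0, seed="GCGC" + "AT" * 4)  # 4 G/C in 12 -> 33.3%
        strong = self._cand(1, seed="GCGCGC" + "AT" * 3)  # 6/12 = 50%
        ranked = rank_candidates([weak, strong], P)
        assert ranked[0].low_gc_flag and abs(ranked[0].seed_gc - 1 / 3) < 1e-9
        assert not ranked[1].low_gc_flag

    def test_deterministic_tie_break(self):
        a, b = self._cand(5, start=100), self._cand(5, start=50)
        assert [c.proto_start for c in rank_candidates([a, b], P)] == [50, 100]


class TestOracleEquivalence:
    """Production scan vs naive brute force on random genomes."""

    N_GENOMES = 100
    GENOME_LEN = 2000

    def test_random_genomes(self):
        rng = random.Random(1234)
        checked_counts = 0
        for g in range(self.N_GENOMES):
            seq = random_seq(rng, self.GENOME_LEN)
            genome = make_genome(seq, circular=(g % 4 == 0))
            strand = "+" if g % 2 == 0 else "-"
            start = rng.randrange(0, self.GENOME_LEN - 400)
            feat = make_feature(start, start + 300, strand=strand)
            cands = enumerate_candidates(feat, genome, P)
            got = {
                (c.spacer, c.dist5, c.proto_start, c.proto_end, c.pam_strand)
                for c in cands
            }
            assert got == brute_force_candidates(feat, genome[0])
            # spot-check binding-site counting against the sliding-window oracle
            for c in cands[:2]:
                count, _ = count_binding_sites(c, genome, P)
                assert count >= 1
                assert count == brute_force_site_count(
                    specificity_pattern(c, P), genome
                )
                checked_counts += 1
        assert checked_counts > 50

    def test_strand_symmetry(self):
        """Designing against the revcomp'd genome with flipped strands gives
        the same spacer multiset."""
        rng = random.Random(77)
        for _ in range(20):
            seq = random_seq(rng, 800)
            L = len(seq)
            genome = make_genome(seq)
            mirror = make_genome(rc(seq))
            start = rng.randrange(0, L - 300)
            for strand, flipped in (("+", "-"), ("-", "+")):
                feat = make_feature(start, start + 240, strand=strand)
                mfeat = make_feature(L - (start + 240), L - start, strand=flipped)
                spacers = sorted(c.spacer for c in enumerate_candidates(feat, genome, P))
                mspacers = sorted(c.spacer for c in enumerate_candidates(mfeat, mirror, P))
                assert spacers == mspacers


def test_design_guides_end_to_end(standard_fixture):
    records, features, truth = standard_fixture
    feat = next(f for f in features if f.id == "gene_00")
    kept, discarded = design_guides(feat, records, P)
    # the planted duplicate (3 genome sites) is discarded; the unique one kept
    assert [c.dist5 for c in kept] == [60]
    assert kept[0].rank == 1 and kept[0].offtarget_count == 1
    assert [c.dist5 for c in discarded] == [9]
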