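"""Affine-gap global alignment against independent oracles, nearest-wild-type
search, matched mutants and restriction-site stripping."""

import itertools

import numpy as np
import pytest
from Bio import Align

import oriforge as of
from oriforge.similarity import MutantSpec, apply_matched_mutations_tracked

from _oracles import (
    brute_force_best_score,
    naive_motif_count,
    plain_gotoh_score,
)


def biopython_score(a, b):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner.score(a.upper(), b.upper())


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = of.global_align("acgtacgt", "acgtacgt")
        assert aln.identity == 1.0
        assert (aln.n_sub, aln.n_ins, aln.n_del) == (0, 0, 0)
        assert aln.score == 5 * 8

    def test_single_substitution(self):
        aln = of.global_align("acgt", "aagt")
        assert aln.n_sub == 1 and aln.n_ins == 0 and aln.n_del == 0
        assert aln.identity == 0.75
        assert aln.score == 3 * 5 - 4

    def test_alignment_strings_ungap_to_inputs(self):
        a, b = "acgtacgttca", "acgttcagg"
        aln = of.global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b
        assert len(aln.aligned_a) == len(aln.aligned_b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            of.global_align("", "acgt")

    def test_score_symmetric_with_ins_del_exchanged(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = "".join(rng.choice(list("acgt"), rng.integers(3, 15)))
            b = "".join(rng.choice(list("acgt"), rng.integers(3, 15)))
            f = of.global_align(a, b)
            r = of.global_align(b, a)
            assert f.score == pytest.approx(r.score)
            assert (f.n_ins, f.n_del) == (r.n_del, r.n_ins)

    def test_matches_enumeration_oracle_all_short_binary_pairs(self):
        """Exhaustive-alignment oracle equivalence over the {a,c} alphabet."""
        seqs = [
            "".join(p)
            for n in range(1, 5)
            for p in itertools.product("ac", repeat=n)
        ]
        for a in seqs:
            for b in seqs:
                assert of.global_align(a, b).score == pytest.approx(
                    brute_force_best_score(a, b)
                ), (a, b)

    def test_matches_enumeration_oracle_random_binary_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = "".join(rng.choice(list("ac"), rng.integers(5, 7)))
            b = "".join(rng.choice(list("ac"), rng.integers(5, 7)))
            assert of.global_align(a, b).score == pytest.approx(
                brute_force_best_score(a, b)
            ), (a, b)

    def test_matches_plain_dp_and_biopython_on_random_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = "".join(rng.choice(list("acgt"), rng.integers(1, 13)))
            b = "".join(rng.choice(list("acgt"), rng.integers(1, 13)))
            got = of.global_align(a, b).score
            assert got == pytest.approx(plain_gotoh_score(a, b)), (a, b)
            assert got == pytest.approx(biopython_score(a, b)), (a, b)


class TestClosestWildtype:
    REFS = None

    @pytest.fixture()
    def refs(self):
        rng = np.random.default_rng(3)
        return {
            f"wt{i}": "".join(rng.choice(list("acgt"), 300)) for i in range(6)
        }

    def test_member_query_returns_itself(self, refs):
        rid, aln = of.closest_wildtype(refs["wt2"], refs)
        assert rid == "wt2" and aln.identity == 1.0

    def test_mutated_query_finds_its_source(self, refs):
        rng = np.random.default_rng(9)
        wt = refs["wt4"]
        pos = rng.choice(300, 5, replace=False)
        q = list(wt)
        for p in pos:
            q[p] = {"a": "c", "c": "g", "g": "t", "t": "a"}[q[p]]
        rid, aln = of.closest_wildtype("".join(q), refs)
        assert rid == "wt4"
        assert aln.n_sub == 5

    def test_k_larger_than_query_uses_fallback(self, refs):
        rid, aln = of.closest_wildtype("acgtacg", refs, k_prefilter=50)
        assert rid in refs and aln.score == of.global_align("acgtacg", refs[rid]).score


class TestMatchedMutants:
    def test_zero_spec_is_identity(self):
        assert of.apply_matched_mutations("acgtacgt", MutantSpec(0, 0, 0, seed=1)) == "acgtacgt"

    def test_length_accounting(self):
        wt = "acgtacgtacgt"
        assert len(of.apply_matched_mutations(wt, MutantSpec(0, 1, 0, seed=2))) == 13
        assert len(of.apply_matched_mutations(wt, MutantSpec(0, 0, 3, seed=2))) == 9
        assert len(of.apply_matched_mutations(wt, MutantSpec(4, 2, 2, seed=2))) == 12

    def test_substitutions_change_exactly_n_positions(self):
        wt = "a" * 50
        mut = of.apply_matched_mutations(wt, MutantSpec(7, 0, 0, seed=3))
        assert sum(1 for x, y in zip(wt, mut) if x != y) == 7

    def test_excessive_deletions_rejected(self):
        with pytest.raises(ValueError):
            of.apply_matched_mutations("acgt", MutantSpec(0, 0, 9, seed=0))

    def test_realigned_mutant_identity_close_to_matched_spectrum(self):
        """Re-aligning a matched mutant to its wild type gives a similarity
        near (but not necessarily equal to) the spectrum it was matched to:
        interacting mutations can shift the optimal alignment slightly."""
        rng = np.random.default_rng(11)
        wt = "".join(rng.choice(list("acgt"), 300))
        spec = MutantSpec(n_sub=20, n_ins=5, n_del=5, seed=4)
        mut = of.apply_matched_mutations(wt, spec)
        aln = of.global_align(mut, wt)
        target_identity = (300 - 20 - 5) / 305  # naive expectation from the edit counts
        assert abs(aln.identity - target_identity) < 0.03

    def test_coordinate_tracking_follows_indels(self):
        wt = "acgtacgtacgt"
        mut, pos_map = apply_matched_mutations_tracked(wt, MutantSpec(0, 2, 2, seed=8))
        for wt_i, mut_i in enumerate(pos_map):
            if mut_i >= 0:
                assert mut[mut_i] == wt[wt_i]
        assert (pos_map == -1).sum() == 2


class TestStripSites:
    FORBIDDEN = None

    def setup_method(self):
        self.forbidden = of.expand_motifs(["GATC"])

    def test_motif_free_input_unchanged(self):
        seq = "aaaaccccttttgggg"
        out, n = of.strip_restriction_sites_minimal(seq, self.forbidden, seed=0)
        assert out == seq and n == 0

    def test_embedded_site_removed_by_substitution(self):
        seq = "aaaagatcaaaa"
        out, n = of.strip_restriction_sites_minimal(seq, self.forbidden, seed=1)
        assert n >= 1
        assert len(out) == len(seq)
        assert naive_motif_count(out, ["GATC"]) == 0
        # the edit lies inside the site
        assert any(out[i] != seq[i] for i in range(4, 8))

    def test_full_restriction_fixture_cleared(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("acgt"), 400))
        forbidden = of.expand_motifs(of.make_motif_fixture())
        out, n = of.strip_restriction_sites_minimal(seq, forbidden, seed=2)
        assert len(out) == 400
        assert naive_motif_count(out, forbidden) == 0


class TestNearDuplicateFilter:
    def test_exact_duplicate_removed_and_dissimilar_retained(self):
        rng = np.random.default_rng(31)
        train = {"t1": "".join(rng.choice(list("acgt"), 200))}
        unrelated = "".join(rng.choice(list("acgt"), 200))
        test = {"dup": train["t1"], "far": unrelated}
        retained = of.filter_near_duplicates(test, train)
        assert retained == ["far"]

    def test_96pct_mutant_removed(self):
        rng = np.random.default_rng(33)
        wt = "".join(rng.choice(list("acgt"), 250))
        mut = of.apply_matched_mutations(wt, MutantSpec(9, 0, 0, seed=5))  # ~96.4%
        assert of.filter_near_duplicates({"m": mut}, {"wt": wt}) == []

    def test_idempotent(self):
        rng = np.random.default_rng(35)
        train = {f"t{i}": "".join(rng.choice(list("acgt"), 150)) for i in range(3)}
        test = {f"q{i}": "".join(rng.choice(list("acgt"), 150)) for i in range(4)}
        test["q_dup"] = train["t0"]
        once = of.filter_near_duplicates(test, train)
        twice = of.filter_near_duplicates({k: test[k] for k in once}, train)
        assert once == twice
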