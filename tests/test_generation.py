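"""Motif expansion, truncated sampling, constrained decoding and infill."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oriforge as of
from oriforge.generation import (
    IUPAC,
    MotifPattern,
    nucleus_filter,
    topk_filter,
)

from _oracles import brute_nucleus_support, naive_motif_count, naive_revcomp


class TestMotifExpansion:
    def test_palindrome_collapses_to_itself(self):
        assert of.expand_motifs(["GATC"]) == frozenset({"GATC"})

    def test_degenerate_pair_is_mutually_reverse_complementary(self):
        assert of.expand_motifs(["CCWGG"]) == frozenset({"CCAGG", "CCTGG"})

    def test_non_palindromic_motif_gains_its_reverse_complement(self):
        assert of.expand_motifs(["GGTCTC"]) == frozenset({"GGTCTC", "GAGACC"})

    def test_invalid_iupac_character_named(self):
        with pytest.raises(ValueError, match="'J'"):
            of.expand_motifs(["GAJC"])

    def test_too_short_and_too_degenerate_rejected(self):
        with pytest.raises(ValueError, match="shorter than three"):
            MotifPattern("GA")
        with pytest.raises(ValueError, match="degenerate"):
            MotifPattern("NNNNNN")

    def test_fixture_list_expansion_properties(self):
        motifs = of.make_motif_fixture()
        assert len(motifs) == 12
        assert all(len(m.pattern) >= 3 and m.n_degenerate <= 5 for m in motifs)
        expanded = of.expand_motifs(motifs)
        assert expanded == frozenset(naive_revcomp(m) for m in expanded)

    def test_fixture_file_matches_builtin_list(self):
        path = of.restriction_motif_fixture_path()
        from_file = [m.pattern for m in of.read_motif_list(path)]
        assert from_file == list(of.RESTRICTION_MOTIFS)

    @settings(max_examples=60, deadline=None)
    @given(
        pattern=st.text(alphabet=sorted(IUPAC), min_size=3, max_size=7).filter(
            lambda p: sum(len(IUPAC[c]) > 1 for c in p) <= 5
        )
    )
    def test_expansion_closed_under_reverse_complement(self, pattern):
        expanded = of.expand_motifs([pattern])
        assert expanded == frozenset(naive_revcomp(m) for m in expanded)


class TestTruncationRules:
    def test_nucleus_keeps_smallest_mass_covering_prefix(self):
        probs = np.array([0.9, 0.06, 0.03, 0.01])
        out = nucleus_filter(probs, 0.95)
        assert set(np.nonzero(out)[0]) == {0, 1}
        assert out.sum() == pytest.approx(1.0)

    def test_topk_one_is_argmax(self):
        probs = np.array([0.2, 0.5, 0.3])
        out = topk_filter(probs, 1)
        assert out.tolist() == [0.0, 1.0, 0.0]

    def test_matches_brute_force_on_random_distributions(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            probs = rng.dirichlet(np.ones(10))
            top_p = float(rng.uniform(0.3, 0.99))
            got = set(np.nonzero(nucleus_filter(probs, top_p))[0])
            assert got == brute_nucleus_support(probs, top_p)
            k = int(rng.integers(1, 10))
            kept = set(np.nonzero(topk_filter(probs, k))[0])
            assert kept == set(np.argsort(-probs)[:k])


class TestGenerate:
    def test_greedy_decoding_reproduces_memorized_sequence(self, memorized):
        ts, rec = memorized["tokens"], memorized["record"]
        cfg = of.GenerationConfig(mode=of.TOPK, top_k=1, prompt=ts.ids[:2],
                                  max_len=64, seed=9)
        (out,) = of.generate(memorized["model"], cfg, n_samples=1)
        assert out.oriv == rec.oriv
        assert out.host_species == rec.host_species

    def test_prompt_preserved_and_seeded_determinism(self, memorized):
        ts = memorized["tokens"]
        prompt = list(ts.ids[:8])
        cfg = of.GenerationConfig(mode=of.NUCLEUS, top_p=0.95, prompt=prompt,
                                  max_len=64, seed=11)
        a = of.generate(memorized["model"], cfg, n_samples=4)
        b = of.generate(memorized["model"], cfg, n_samples=4)
        assert [r.oriv for r in a] == [r.oriv for r in b]
        seed_prefix = memorized["record"].oriv[:6]
        assert all(r.oriv.startswith(seed_prefix) for r in a)

    def test_different_seeds_can_differ(self, memorized):
        outs = []
        for seed in (1, 2, 3, 4):
            cfg = of.GenerationConfig(mode=of.NUCLEUS, top_p=0.999,
                                      temperature=2.0,
                                      prompt=memorized["tokens"].ids[:2],
                                      max_len=64, seed=seed)
            outs.append([r.oriv for r in of.generate(memorized["model"], cfg, 2)])
        assert len({tuple(o) for o in outs}) > 1

    def test_forbidden_set_requires_beam_mode(self, memorized):
        cfg = of.GenerationConfig(mode=of.NUCLEUS,
                                  forbidden=of.expand_motifs(["GATC"]),
                                  prompt=memorized["tokens"].ids[:2])
        with pytest.raises(ValueError, match="generate_constrained"):
            of.generate(memorized["model"], cfg)

    def test_invalid_prompt_rejected(self, memorized):
        vocab = memorized["vocab"]
        cfg = of.GenerationConfig(prompt=[vocab["a"], vocab.bos])
        with pytest.raises(ValueError):
            of.generate(memorized["model"], cfg)


class TestGenerateConstrained:
    def test_empty_forbidden_set_directed_to_generate(self, memorized):
        cfg = of.GenerationConfig(mode=of.BEAM,
                                  prompt=memorized["tokens"].ids[:2])
        with pytest.raises(ValueError, match="generate"):
            of.generate_constrained(memorized["model"], cfg)

    def test_unsatisfiable_prefix_raises_infeasibility(self, memorized):
        # every single-base extension of the seed "...aa" is forbidden
        forbidden = of.expand_motifs(["AAA", "AAC", "AAG", "AAT"])
        vocab = memorized["vocab"]
        prompt = list(memorized["tokens"].ids[:2]) + [vocab["a"], vocab["a"]]
        cfg = of.GenerationConfig(mode=of.BEAM, n_beams=4, prompt=prompt,
                                  forbidden=forbidden, max_len=32)
        with pytest.raises(of.InfeasibleGenerationError):
            of.generate_constrained(memorized["model"], cfg)

    def test_prompt_containing_motif_rejected_with_repair_hint(self, memorized):
        vocab = memorized["vocab"]
        prompt = list(memorized["tokens"].ids[:2]) + [
            vocab[c] for c in "gatc"
        ]
        cfg = of.GenerationConfig(mode=of.BEAM, n_beams=2, prompt=prompt,
                                  forbidden=of.expand_motifs(["GATC"]),
                                  max_len=40)
        with pytest.raises(ValueError, match="infill_repair"):
            of.generate_constrained(memorized["model"], cfg)

    def test_outputs_free_of_motif_and_close_to_memorized(self, memorized):
        forbidden = of.expand_motifs(["GATC"])
        cfg = of.GenerationConfig(mode=of.BEAM, n_beams=5,
                                  prompt=memorized["tokens"].ids[:2],
                                  forbidden=forbidden, max_len=64)
        outs = of.generate_constrained(memorized["model"], cfg)
        assert outs
        for r in outs:
            assert naive_motif_count(r.oriv, forbidden) == 0
        # the memorized oriV contains gatc, so the best beam must deviate
        # from it yet stay nearby
        best = outs[0].oriv
        assert best != memorized["record"].oriv
        assert of.global_align(best, memorized["record"].oriv).identity > 0.8


class TestInfillRepair:
    def test_motif_free_input_unchanged(self, memorized):
        forbidden = of.expand_motifs(["GATC"])
        out, n = of.infill_repair("ggaacc", forbidden, memorized["model"],
                                  species="Escherichia coli")
        assert out == "ggaacc" and n == 0

    def test_embedded_site_repaired_within_window(self, memorized):
        forbidden = of.expand_motifs(["GATC"])
        out, n = of.infill_repair("ggatcc", forbidden, memorized["model"],
                                  species="Escherichia coli")
        assert n >= 1
        assert len(out) == 6
        assert naive_motif_count(out, forbidden) == 0
        assert any(out[i] != "ggatcc"[i] for i in range(1, 5))

    def test_idempotent_fixed_point(self, memorized):
        forbidden = of.expand_motifs(["GATC", "GAATTC"])
        seq = memorized["record"].oriv  # contains gatc
        once, n1 = of.infill_repair(seq, forbidden, memorized["model"],
                                    species="Escherichia coli")
        twice, n2 = of.infill_repair(once, forbidden, memorized["model"],
                                     species="Escherichia coli")
        assert n1 >= 1 and n2 == 0 and once == twice
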