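"""Architecture parameter counting, gradients, training and embeddings."""

import numpy as np
import pytest

import oriforge as of
from oriforge.lm import (
    GPT,
    ModelConfig,
    count_parameters,
    init_parameters,
    train_model,
)
from oriforge.records import encode_replicon

# Frozen once from an independent enumeration of tensor shapes for the
# config (2 layers, 2 heads, d_model 64, d_ff 256, context 128, vocab 31):
# embeddings 31*64 + 128*64, per layer 4*64^2+4*64 + 2*64*256+256+64 + 4*64,
# final norm 2*64.
TINY_CONFIG_PARAM_COUNT = 110_272


class TestCountParameters:
    def test_zero_layer_closed_form(self):
        cfg = ModelConfig(vocab_size=10, n_layers=0, n_heads=1, d_model=8,
                          context_len=16)
        # embeddings + final layer norm only
        assert count_parameters(cfg) == 10 * 8 + 16 * 8 + 2 * 8

    def test_tiny_config_regression_constant(self):
        cfg = ModelConfig(vocab_size=31, n_layers=2, n_heads=2, d_model=64,
                          d_ff=256, context_len=128)
        assert count_parameters(cfg) == TINY_CONFIG_PARAM_COUNT

    def test_matches_instantiated_tensor_sizes(self):
        cfg = ModelConfig(vocab_size=13, n_layers=3, n_heads=2, d_model=16,
                          context_len=32)
        params = init_parameters(cfg)
        assert sum(p.size for p in params.values()) == count_parameters(cfg)

    def test_d_model_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, n_heads=5, d_model=64)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        cfg = ModelConfig(vocab_size=11, n_layers=2, n_heads=2, d_model=16,
                          context_len=24, dropout=0.0, seed=3, dtype="float64")
        net = GPT(cfg)
        rng = np.random.default_rng(0)
        ids = rng.integers(0, 10, size=(2, 9))
        _, grads = net.loss_and_grads(ids, pad_id=10, train=True)
        eps = 1e-6
        for key in ["tok_emb", "pos_emb", "l0.Wqkv", "l0.Wo", "l1.W1",
                    "l1.W2", "l0.ln1_g", "lnf_b", "l1.bqkv"]:
            p = net.params[key]
            for fi in rng.integers(0, p.size, size=3):
                orig = p.flat[fi]
                p.flat[fi] = orig + eps
                lp = net.loss_and_grads(ids, 10, train=False)[0]
                p.flat[fi] = orig - eps
                lm = net.loss_and_grads(ids, 10, train=False)[0]
                p.flat[fi] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].flat[fi]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), key


class TestDistribution:
    def test_probability_vector_valid(self, memorized):
        model = memorized["model"]
        ts = memorized["tokens"]
        for cut in (1, 3, len(ts) - 2):
            d = of.next_token_distribution(model, of.TokenSequence(ts.ids[:cut]))
            assert d.shape == (len(memorized["vocab"]),)
            assert (d >= 0).all()
            assert d.sum() == pytest.approx(1.0, abs=1e-6)

    def test_no_temperature_applied(self, memorized):
        # the raw distribution is deterministic and independent of any
        # sampling configuration
        model = memorized["model"]
        prefix = of.TokenSequence(memorized["tokens"].ids[:5])
        d1 = of.next_token_distribution(model, prefix)
        d2 = of.next_token_distribution(model, prefix)
        np.testing.assert_array_equal(d1, d2)

    def test_prefix_too_long_rejected(self, memorized):
        ids = [memorized["vocab"].bos] * memorized["model"].config.context_len
        with pytest.raises(ValueError):
            of.next_token_distribution(memorized["model"], ids)


class TestTraining:
    def test_memorization_reaches_low_loss_and_greedy_recall(self, memorized):
        model = memorized["model"]
        assert model.training_log[-1][1] < 0.1  # nats/token
        ts = memorized["tokens"]
        for t in range(1, len(ts) - 1):
            d = of.next_token_distribution(model, of.TokenSequence(ts.ids[:t]))
            assert int(d.argmax()) == ts.ids[t]

    def test_random_corpus_validation_loss_near_entropy_floor(self):
        rng = np.random.default_rng(1)
        recs = [
            of.RepliconRecord(f"r{i}", of.UNKNOWN, (),
                              "".join(rng.choice(list("acgt"), 40)))
            for i in range(40)
        ]
        vocab = of.build_vocabulary(recs)
        seqs = [encode_replicon(r, vocab, 64) for r in recs]
        cfg = ModelConfig(vocab_size=len(vocab), n_layers=1, n_heads=2,
                          d_model=16, context_len=64, dropout=0.0,
                          learning_rate=3e-3, batch_size=8, max_epochs=6,
                          patience=6, seed=2)
        model = train_model(seqs[:30], seqs[30:], cfg, vocab)
        # i.i.d. uniform nucleotides: ln 4 = 1.386 nats is the floor on the
        # oriV positions, which dominate the sequence
        assert model.training_log[-1][2] > 1.25

    def test_early_stopping_and_best_checkpoint_contract(self, memorized):
        # overfit regime: train on one sequence, validate on another
        rng = np.random.default_rng(4)
        r1 = of.RepliconRecord("a", of.UNKNOWN, (), "acgt" * 8)
        r2 = of.RepliconRecord("b", of.UNKNOWN, (),
                               "".join(rng.choice(list("acgt"), 32)))
        vocab = of.build_vocabulary([r1, r2])
        s1 = encode_replicon(r1, vocab, 64)
        s2 = encode_replicon(r2, vocab, 64)
        cfg = ModelConfig(vocab_size=len(vocab), n_layers=1, n_heads=2,
                          d_model=16, context_len=64, dropout=0.0,
                          learning_rate=1e-2, batch_size=16, max_epochs=40,
                          patience=2, seed=5)
        model = train_model([s1] * 32, [s2], cfg, vocab)
        val = [v for _, _, v in model.training_log]
        best_epoch = int(np.argmin(val)) + 1
        assert model.stopped_epoch <= best_epoch + cfg.patience
        # the returned parameters reproduce the best validation loss
        net = GPT(model.config, model.params)
        realized = net.loss_and_grads(
            np.asarray([s2.ids]), vocab.pad, train=False
        )[0]
        assert realized == pytest.approx(min(val), abs=1e-6)

    def test_empty_split_rejected(self, memorized):
        cfg = ModelConfig(vocab_size=29, n_layers=1, n_heads=1, d_model=8,
                          context_len=16)
        with pytest.raises(ValueError):
            train_model([], [memorized["tokens"]], cfg, memorized["vocab"])

    def test_save_load_round_trip(self, memorized, tmp_path):
        model = memorized["model"]
        model.save(tmp_path / "ckpt")
        loaded = of.TrainedModel.load(tmp_path / "ckpt")
        assert loaded.config == model.config
        for k, v in model.params.items():
            np.testing.assert_array_equal(loaded.params[k], v)
        assert len(loaded.training_log) == len(model.training_log)
        for (e1, t1, v1), (e2, t2, v2) in zip(loaded.training_log,
                                              model.training_log):
            assert e1 == e2
            assert t1 == pytest.approx(t2, abs=1e-6)
            assert v1 == pytest.approx(v2, abs=1e-6)
        assert loaded.stopped_epoch == model.stopped_epoch


class TestEmbeddings:
    def test_output_length_is_d_model(self, memorized):
        emb = of.sequence_embedding(memorized["model"], memorized["tokens"])
        assert emb.shape == (memorized["model"].config.d_model,)

    def test_single_token_input_embedding_is_that_row(self, memorized):
        model = memorized["model"]
        emb = of.sequence_embedding(model, [3], kind="input")
        np.testing.assert_allclose(emb, model.params["tok_emb"][3])

    def test_empty_input_rejected(self, memorized):
        with pytest.raises(ValueError):
            of.sequence_embedding(memorized["model"], [])

    def test_families_separate_in_embedding_space(self, two_family):
        """Mean cosine distance between families exceeds the within-family
        distance, averaged over >= 20 pairs."""
        model = two_family["model"]
        vocab = two_family["vocab"]
        recs = two_family["held"]
        fams = {0: [], 1: []}
        for r in recs:
            fams[int(r.record_id[1])].append(
                of.sequence_embedding(model, encode_replicon(r, vocab, 512))
            )

        def cos_dist(u, v):
            return 1 - np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))

        within, between = [], []
        for f in (0, 1):
            e = fams[f]
            within += [cos_dist(a, b) for i, a in enumerate(e) for b in e[i + 1:]]
        between += [cos_dist(a, b) for a in fams[0] for b in fams[1]]
        assert len(between) >= 20
        assert np.mean(between) > np.mean(within)
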