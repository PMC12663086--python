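"""Shared fixtures: trained tiny models reused across test modules.

Session scope keeps the CPU-minutes budget low: the memorized single-sequence
model, the two-family synthetic model and the gatc-saturated model are each
trained once per test run.
"""

import numpy as np
import pytest

import oriforge as of
from oriforge.lm import ModelConfig, train_model
from oriforge.records import encode_replicon


MEMORIZED_ORIV = "acgtacggttcaagctcgatcgatacgt"


@pytest.fixture(scope="session")
def memorized():
    """A tiny model trained to memorize one replicon exactly."""
    rec = of.RepliconRecord("m", "Escherichia coli", (), MEMORIZED_ORIV)
    vocab = of.build_vocabulary([rec])
    ts = encode_replicon(rec, vocab)
    cfg = ModelConfig(
        vocab_size=len(vocab), n_layers=2, n_heads=2, d_model=32,
        context_len=64, dropout=0.0, learning_rate=3e-3, batch_size=32,
        max_epochs=15, patience=5, seed=0,
    )
    model = train_model([ts] * 200, [ts], cfg, vocab)
    return {"record": rec, "tokens": ts, "model": model, "vocab": vocab}


@pytest.fixture(scope="session")
def two_family():
    """Two-family synthetic corpus (mutation 0.02) and a tiny model trained
    on it, with the last six records of each family held out."""
    spec = of.SyntheticSpec(
        n_families=2, n_records_per_family=30, mutation_rate=0.02,
        rep_fractions=(1.0, 0.0, 0.0), seed=101,
    )
    corpus = of.make_corpus(spec)
    vocab = of.build_vocabulary(corpus.records)
    held = [r for r in corpus.records if int(r.record_id.split("_r")[1]) >= 24]
    train = [r for r in corpus.records if int(r.record_id.split("_r")[1]) < 24]
    enc = lambda rs: [encode_replicon(r, vocab, 512) for r in rs]
    cfg = ModelConfig(
        vocab_size=len(vocab), n_layers=2, n_heads=2, d_model=64,
        context_len=512, dropout=0.0, learning_rate=3e-3, batch_size=4,
        max_epochs=20, patience=5, seed=7,
    )
    model = train_model(enc(train), enc(held), cfg, vocab)
    return {"corpus": corpus, "model": model, "vocab": vocab,
            "held": held, "train": train, "spec": spec}


def gatc_saturated_corpus(seed=5, n_records=120, length=96):
    """Records whose oriVs carry a gatc every twelve bases."""
    rng = np.random.default_rng(seed)
    template = list("".join(rng.choice(list("acgt"), length)))
    for start in range(4, length - 4, 12):
        template[start : start + 4] = "gatc"
    template = "".join(template)
    records = []
    for i in range(n_records):
        arr = list(template)
        for p in np.nonzero(rng.random(length) < 0.02)[0]:
            arr[p] = [b for b in "acgt" if b != arr[p]][rng.integers(3)]
        records.append(
            of.RepliconRecord(f"g{i:03d}", "Escherichia coli", (), "".join(arr))
        )
    return records


@pytest.fixture(scope="session")
def gatc_model():
    """A tiny model trained on the gatc-saturated corpus."""
    records = gatc_saturated_corpus()
    vocab = of.build_vocabulary(records)
    seqs = [encode_replicon(r, vocab, 128) for r in records]
    cfg = ModelConfig(
        vocab_size=len(vocab), n_layers=2, n_heads=2, d_model=32,
        context_len=128, dropout=0.0, learning_rate=3e-3, batch_size=8,
        max_epochs=10, patience=5, seed=3,
    )
    model = train_model(seqs[:100], seqs[100:], cfg, vocab)
    return {"records": records, "model": model, "vocab": vocab}
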