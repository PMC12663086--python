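"""Train a tiny replicon model and score held-out next-nucleotide accuracy.

A 2-layer model (d_model 64) memorizes the family structure of a synthetic
corpus in about a minute on one CPU; teacher-forced accuracy on held-out
records is reported with a sequence-level bootstrap confidence interval.
Uniform chance is 25%.
"""

import oriforge as of
from oriforge.lm import ModelConfig, train_model
from oriforge.records import encode_replicon

corpus = of.make_corpus(of.SyntheticSpec(
    n_families=2, n_records_per_family=20, mutation_rate=0.02,
    rep_fractions=(1.0, 0.0, 0.0), seed=101,
))
vocab = of.build_vocabulary(corpus.records)
held = [r for r in corpus.records if int(r.record_id.split("_r")[1]) >= 16]
train = [r for r in corpus.records if int(r.record_id.split("_r")[1]) < 16]

cfg = ModelConfig(vocab_size=len(vocab), n_layers=2, n_heads=2, d_model=64,
                  context_len=512, dropout=0.0, learning_rate=3e-3,
                  batch_size=4, max_epochs=15, patience=5, seed=7)
enc = lambda rs: [encode_replicon(r, vocab, 512) for r in rs]
model = train_model(enc(train), enc(held), cfg, vocab)
print(f"trained {model.stopped_epoch} epochs; "
      f"final train/valid loss {model.training_log[-1][1]:.3f}/"
      f"{model.training_log[-1][2]:.3f} nats/token")

report = of.next_nucleotide_accuracy(model, held, n_resamples=500, seed=1)
print(f"held-out oriV accuracy: {report.accuracy:.3f} "
      f"(95% CI [{report.ci_low:.3f}, {report.ci_high:.3f}], "
      f"{report.n_positions} positions in {report.n_sequences} sequences)")
print("an accuracy far above 0.25 means the model predicts each origin")
print("base from its host/family context, not from base composition alone.")
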