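"""Generate origins conditioned on a host species and rank their novelty.

Samples replicons with nucleus sampling (top-p 0.95, temperature 1.0) after
prompting with a species token, then reports each generation's similarity
to its nearest wild type — the percent identity of the affine-gap global
alignment against the best training match.
"""

import oriforge as of
from oriforge.lm import ModelConfig, train_model
from oriforge.records import encode_replicon

corpus = of.make_corpus(of.SyntheticSpec(
    n_families=2, n_records_per_family=20, mutation_rate=0.02,
    rep_fractions=(1.0, 0.0, 0.0), seed=101,
))
vocab = of.build_vocabulary(corpus.records)
cfg = ModelConfig(vocab_size=len(vocab), n_layers=2, n_heads=2, d_model=64,
                  context_len=512, dropout=0.0, learning_rate=3e-3,
                  batch_size=4, max_epochs=15, patience=5, seed=7)
held = [r for r in corpus.records if int(r.record_id.split("_r")[1]) >= 16]
train = [r for r in corpus.records if int(r.record_id.split("_r")[1]) < 16]
enc = lambda rs: [encode_replicon(r, vocab, 512) for r in rs]
model = train_model(enc(train), enc(held), cfg, vocab)

species = corpus.species_of_family(0)
gen_cfg = of.GenerationConfig(mode=of.NUCLEUS, top_p=0.95, temperature=1.0,
                              prompt=[vocab.bos, vocab[species]],
                              max_len=450, seed=4)
generations = of.generate(model, gen_cfg, n_samples=5)

references = {r.record_id: r.oriv for r in corpus.records}
print(f"5 origins conditioned on {species}:")
for g in generations:
    rid, aln = of.closest_wildtype(g.oriv, references)
    print(f"  {g.record_id}: {len(g.oriv)} nt, nearest wild type {rid} at "
          f"{aln.identity_pct:.1f}% identity "
          f"({aln.n_sub} sub / {aln.n_ins} ins / {aln.n_del} del)")
print("identities below 100% show the model explores sequence space")
print("rather than copying a training origin verbatim; generations that")
print("run to the length cap mean stop-token timing is still being learned,")
print("typically the last behavior a briefly trained model acquires.")
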