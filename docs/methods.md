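# Methods

## The problem

A plasmid replicon is the minimal unit of autonomous replication: the
origin of vegetative replication (oriV) plus, for many families, one or
more plasmid-encoded replication-initiation (Rep) proteins, all operating
in a particular bacterial host. oriVs are short (median 357 nt in typical
curated collections), poorly annotated, and carry dispersed functional
signals — tandemly repeated Rep-binding iterons, DnaA boxes bound by the
host initiator, AT-rich unwinding regions, and in Rep-independent families
such as ColE1, structured antisense RNAs. `oriforge` treats replicon
design as conditional sequence modeling: learn the joint distribution of
(host, Rep, oriV) with an autoregressive model, sample new origins under
host/Rep/seed conditioning, optionally forbid user-specified sequence
motifs during decoding, and quantify the results with alignment-based
novelty controls, in-silico plausibility metrics, and pooled-competition
fitness statistics.

## Tokenization and data model

Each replicon becomes one token stream:

    <bos> SPECIES [rep amino acids, <sep> between multiple Reps] oriv... <eos>

Host species names are single tokens; Rep proteins use the 20 uppercase
amino-acid letters; oriV uses lowercase `a c g t`, so the two residue
alphabets are disjoint and the stream parses unambiguously. Five special
tokens exist: `<bos>`, `<eos>` (the stop token), `<sep>`, `<unk_species>`
for unannotated hosts, and `<pad>` (never a target). Vocabulary ids are
assigned deterministically: specials, then sorted species, then amino
acids alphabetically, then `a c g t`; construction is order-independent.
Records longer than the context window (default 1500 tokens) are rejected
at dataset build time rather than truncated — truncation would silently
corrupt oriV boundaries. All coordinates package-wide are 0-based,
half-open. The optional `group_label` (e.g. an incompatibility group) is
manifest metadata for subset training and is not tokenized.

## Splitting and leakage control

Train/validation splits operate on clusters, not records. Clustering is
greedy and representative-based: sequences are visited longest-first and
join the first cluster whose representative shares at least the identity
threshold (default 0.90), else found a new cluster. Identity is always
matches / alignment columns of the affine-gap global alignment, gaps in
the denominator — the same definition used for the similarity score, so
one convention serves the whole package. Whole clusters are then assigned
at random (seeded) to TRAIN/VALID at the requested fractions (default
75/25, with at least one cluster per side when two or more exist). The
near-duplicate filter for held-out sets removes a test sequence when some
training sequence contains it at >95% identity over >95% of its length
(edit-distance infix alignment; the BLAST pident/qcovs convention).

## Model

A decoder-only transformer: learned token and absolute positional
embeddings, pre-norm blocks (causal multi-head attention, GELU
feed-forward at 4x width), a final layer norm, and an output head tied to
the token embedding matrix. The reference configuration — 12 layers, 12
heads, embedding dimension 768, context 1500, vocabulary 145 — counts
86,319,360 trainable parameters (~86M); tying the head is what lands the
architecture at that size, and `count_parameters` is asserted against the
instantiated tensor sizes whenever a model is built.

The implementation is plain NumPy with hand-written backpropagation,
verified against central finite differences in the test suite. Training
uses AdamW (decoupled weight decay applied to matrices only), dropout,
and early stopping: when validation loss fails to improve for `patience`
epochs, training halts and the best-validation checkpoint is returned.
The cross-entropy objective covers every position — species and Rep
tokens included — with PAD targets masked; evaluation separately restricts
to oriV positions. Everything is seeded and reproducible on one device;
mixed precision is not used (float32 by default, float64 available for
gradient checking).

Sequence embeddings are the arithmetic mean of per-token representations.
"Token embeddings" is ambiguous between input embeddings and contextual
states; the default is final-layer hidden states (after the last layer
norm), with `kind="input"` for raw embedding rows, and the choice is part
of the function signature so downstream metadata can record it.

## Generation

Sampling supports nucleus (top-p, default 0.95) and top-k (default 4)
truncation after temperature scaling, stopping at `<eos>` or the length
cap. A layout-grammar mask is applied before truncation so every sample
decodes to a valid replicon (a species token in the species slot, `<sep>`
only between Rep proteins, the stop token only after at least one oriV
nucleotide); the full-scale models this mirrors learn that grammar from
data, but desk-scale models cannot be relied on to, and the generation
API returns parsed records.

Constraint-guided generation performs beam search over oriV continuations
with a hard exclusion rule: the forbidden motif set is first expanded
(IUPAC degenerate codes to all concrete variants) and closed under
reverse complement, so screening the forward strand covers both strands.
Each beam carries a rolling suffix window of length (max motif length -
1) spanning the prompt boundary; any candidate whose window would match a
forbidden motif is pruned before scoring. Beams are ranked by total
log-likelihood (no length normalization — the stock behavior of
mainstream beam-search implementations), ties broken by token id then
beam index; the search keeps the usual 2n-candidate refill margin and
stops when no live beam can displace the kept finished set. At least one
nucleotide must be generated beyond the prompt before the stop token is
admissible; if every beam dies first, an explicit infeasibility error is
raised rather than returning a truncated sequence. The returned origins
therefore contain zero forbidden occurrences on either strand by
construction — the test suite re-checks this with an independent naive
substring scanner.

Prompts whose seed already contains a forbidden motif are rejected and
directed to `infill_repair`, which repeatedly takes the leftmost
occurrence, tries every single-base substitution inside its span, keeps
those that clear the occurrence (preferring ones that create no new
occurrence anywhere), and applies the candidate with the highest
full-sequence autoregressive likelihood. The procedure is a fixed point
(repairing a repaired sequence changes nothing) and bounded at 3x the
sequence length before erroring.

The wild-type baseline for restriction-site removal
(`strip_restriction_sites_minimal`) instead substitutes one random base
inside a remaining site per iteration until none remain — length
preserved, substitution count reported.

## Evaluation

Next-nucleotide accuracy is teacher-forced: at every oriV position the
prediction is the argmax of the model's next-token distribution given the
true preceding tokens (species and Rep context included), pooled over all
positions of all records; the stop-token prediction is excluded as a
token-scheme artifact, and argmax ties resolve to the lowest token id.
Confidence intervals are percentile bootstrap (default 1000 resamples,
95%) resampling whole sequences, which respects within-sequence
correlation; a report built from copies of one sequence has a zero-width
interval by construction. Coverage of the interval is itself tested
(Bernoulli(0.7) per-sequence scores, 200 repetitions, coverage required
in [0.90, 0.99]).

## In-silico validation

AT content is (#a + #t)/length. Folding energy is computed on every
100-nt window (step 1) by a pluggable engine: the built-in stand-in
negates a Nussinov maximum base-pairing count (Watson-Crick pairs,
minimum loop 3) — a monotone structural proxy that is always <= 0 and
exactly 0 on homopolymers, not a thermodynamic free energy; an
RNAfold-backed engine is provided for environments with ViennaRNA
bindings, and no numeric equivalence between the two is claimed.

Motif scanning is direct PWM log-likelihood scoring: weights are log2
odds of the motif model over the background (uniform 0.25 by default),
summed across positions at every offset on both strands; a hit is any
score strictly above the threshold, default 1.0, with overlaps permitted
and palindromic sites counting once per strand. Note that a threshold of
1.0 is permissive: a sharp 17-mer PWM (0.9 consensus probability)
tolerates ~6 mismatches before dropping below it, so random sequences of
realistic length produce occasional hits; the test suite pins the
random-sequence hit rate to its binomial closed form rather than assuming
it is zero. The random baseline is i.i.d. uniform ACGT at length 357, the
median oriV length in the corpora this mirrors.

## Similarity and matched mutants

The similarity score between a generated origin and its nearest wild type
is the percent identity of the affine-gap global alignment (match +5,
mismatch -4, gap open 10.0, gap extension 0.5; a gap of length L costs
open + (L-1)*extend; end gaps penalized). The substitution scores are the
EMBOSS nucleotide defaults — the gap penalties are the conventional
values for this analysis, the substitution scores a recorded package
choice, all exposed in the function signature. Traceback is deterministic
(diagonal > up > left on ties). Candidate wild types are pre-ranked by
shared 11-mer count before the single full alignment, with an align-all
fallback when no k-mer is shared.

Matched random mutants apply exactly the query's edit spectrum — the
same number of substitutions, insertions and deletions as the alignment
reports — at seeded random positions in the wild type (deletions, then
insertions, then distinct-position substitutions, on tracked
coordinates). Re-aligning a mutant to its wild type can report a slightly
different spectrum because interacting edits shift the optimal alignment;
tests assert closeness, not equality. The coordinate-tracking variant
maps every wild-type position into the mutant so planted-element loci can
be followed through indels.

## Fitness quantification

Reads count toward a variant when they are primary alignments with MAPQ
>= 20 (secondary, supplementary and unmapped records dropped). A
pseudocount of 1e-6 is added to every count before per-sample
normalization, so frequencies are strictly positive and sum to one.
Relative fitness is W = log2(f_tx / f_t0) against the variant's starting
frequency in the matched pool lineage (same replicate; same condition
when condition-specific baselines exist). W is antisymmetric under
timepoint exchange and exactly the per-passage doubling deficit: in a
simulated 100-variant pool where one variant halves each passage, the
recovered W is -1 per passage within ~0.015 (the renormalization term
log2 of the shrinking pool total; smaller pools deviate more, which the
worked example shows deliberately). A 1:100 passage corresponds to
log2(100) = 6.64 ~ 6.6 generations of regrowth. Plating-based stability
frequencies above 1 are reported as-is with a warning flag rather than
clamped.

## Synthetic corpora: what they emulate and what they do not

The generator plants exactly the signals the in-silico metrics look for:
per family, one iteron unit (17-22 nt) in 3-5 tandem copies, one 9-nt
DnaA-box-like element, and an AT-rich block (60 nt at target AT fraction
0.85), packed with random spacing into a 357-nt template; records derive
from their family template by i.i.d. substitutions (default rate 0.02),
species labels map deterministically to families, and sharp PWMs (0.9
consensus probability) matching the planted elements are emitted with
ground-truth coordinates. Corpora are byte-reproducible from the seed.

These corpora make signal recovery *checkable*, not realistic: real oriVs
have heterogeneous lengths, diverged iteron copies, spaced rather than
strictly tandem repeats, indel variation, and base composition far from
uniform. Passing the desk-scale tests therefore demonstrates that the
pipeline recovers planted structure under controlled noise — it does not
certify performance on natural plasmid collections.

Two study-design choices for the canonical two-family evaluation corpus:
records are Rep-less (`rep_fractions=(1,0,0)`), because variable-length
Rep prefixes shift the oriV offset per record and put template recall
beyond a model trainable in about a CPU-minute, which is the budget these
tests are designed for (the mixed default stays in `SyntheticSpec`, and
Rep handling is exercised throughout the tokenizer, generation and
evaluation tests); and "destruction" of a planted element by a matched
mutant means that some planted locus — each tandem iteron copy and the
DnaA box, coordinates mapped through the mutant's indels — retains no
overlapping PWM hit above threshold. Under the permissive 1.0 threshold
whole-sequence motif counts are nearly indestructible (tandem arrays are
self-similar, and six mismatches per copy are tolerated), so the
per-locus definition is the faithful operationalization of "the planted
hit".

## Model training scale

Tests and the acceptance script train models of 1-2 layers, 2 heads, and
d_model 16-64 on corpora of tens of records for tens of epochs — sizes
chosen so the whole suite runs on a single CPU in minutes while still
exhibiting the qualitative behaviors of interest (memorization,
family-conditioned recall, constraint navigation). The reference 12x768
configuration is instantiated only as a parameter count. Default
hyperparameters in `ModelConfig` (learning rate 1e-3, batch 16, dropout
0.1, weight decay 0.1) are exposed, not tuned; the tiny-model tests pass
explicit values (typically lr 3e-3, dropout 0, batch 4-8).

## Numerical notes and degenerate inputs

Alignment DP runs in float64; with half-integer default scores all cell
values are exact, and traceback equality tests use a 1e-9 relative
tolerance so custom scoring schemes remain safe. Attention masking uses
an additive -1e9; softmax is max-shifted; the loss accumulates in
float64. Empty oriVs, empty splits, non-finite losses, prefixes
exceeding the context, thresholds outside (0,1], negative MAPQ, zero
plating totals and infeasible element packing all raise typed errors with
the offending quantity named. The twelve-motif restriction fixture ships
as package data and as `make_motif_fixture()`; both are tested to agree.

## Known limitations

* The NumPy trainer is single-device and unoptimized beyond vectorization;
  it is not intended for corpus-scale training.
* The Nussinov stand-in orders sequences by pairing potential only;
  absolute values are not comparable to thermodynamic MFE.
* Beam search with total-log-likelihood ranking favors shorter
  completions when the model's stop-token probability is diffuse; length
  normalization is deliberately not applied.
* The greedy clusterer matches the representative-threshold contract of
  standard tools but is O(n * clusters) alignments and not bit-compatible
  with any external program.
* Host-conditioning fidelity is only as good as the species labels in the
  manifest; taxonomy resolution is out of scope.
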