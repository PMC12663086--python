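"""Sampling, constrained beam decoding and infill repair.

Three decoding surfaces over a trained replicon model:

* :func:`generate` — nucleus (top-p) or top-k sampling with temperature,
  optionally conditioned on a prompt (species token, Rep tokens, oriV seed
  nucleotides).
* :func:`generate_constrained` — beam search over oriV continuations that
  provably never emits a forbidden restriction motif on either strand (the
  motif set is reverse-complement-closed, so forward-strand screening covers
  both).
* :func:`infill_repair` — post-hoc minimal repair of a sequence (e.g. a seed
  prompt) that already contains forbidden motifs, using the model's
  highest-likelihood single-base substitutions.

A layout-grammar mask constrains sampling so every emitted token sequence
decodes to a valid replicon record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .lm import DecodeState, TrainedModel, _softmax
from .records import (
    RepliconRecord,
    TokenClass,
    TokenSequence,
    UNKNOWN,
    Vocabulary,
    decode_tokens,
    encode_replicon,
)
from .similarity import find_forbidden_occurrences

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate IUPAC nucleotide motif, at least three bases long."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        for ch in self.pattern:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in motif {self.pattern!r}")
        if len(self.pattern) < 3:
            raise ValueError(f"motif {self.pattern!r} shorter than three nucleotides")
        if self.n_degenerate > 5:
            raise ValueError(
                f"motif {self.pattern!r} has more than five degenerate positions"
            )

    @property
    def n_degenerate(self) -> int:
        return sum(1 for ch in self.pattern if len(IUPAC[ch]) > 1)


def expand_motifs(patterns: Iterable[MotifPattern | str]) -> frozenset[str]:
    """Concrete ACGT expansion of degenerate motifs, closed under reverse complement."""
    out: set[str] = set()
    for pat in patterns:
        if not isinstance(pat, MotifPattern):
            pat = MotifPattern(pat)
        for combo in product(*(IUPAC[ch] for ch in pat.pattern)):
            s = "".join(combo)
            out.add(s)
            out.add(reverse_complement(s))
    return frozenset(out)


def read_motif_list(path) -> list[MotifPattern]:
    """Plain-text motif list: one IUPAC pattern per line, ``#`` comments."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                motifs.append(MotifPattern(line))
    return motifs


NUCLEUS = "NUCLEUS"
TOPK = "TOPK"
BEAM = "BEAM"


@dataclass
class GenerationConfig:
    mode: str = NUCLEUS
    top_p: float = 0.95
    top_k: int = 4
    temperature: float = 1.0
    n_beams: int = 10
    prompt: Sequence[int] | TokenSequence | None = None
    forbidden: frozenset[str] = frozenset()
    max_len: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (NUCLEUS, TOPK, BEAM):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must be in (0, 1]")


class InfeasibleGenerationError(RuntimeError):
    """Every beam was pruned before reaching a stop token."""


def nucleus_filter(probs: np.ndarray, top_p: float) -> np.ndarray:
    """Zero all but the smallest probability-mass-covering prefix, renormalize."""
    order = np.argsort(-probs, kind="stable")
    cum = np.cumsum(probs[order])
    cutoff = int(np.searchsorted(cum, top_p)) + 1
    out = np.zeros_like(probs)
    keep = order[:cutoff]
    out[keep] = probs[keep]
    return out / out.sum()


def topk_filter(probs: np.ndarray, k: int) -> np.ndarray:
    """Zero all but the k most probable tokens, renormalize."""
    if k < 1:
        raise ValueError("top_k must be >= 1")
    order = np.argsort(-probs, kind="stable")
    out = np.zeros_like(probs)
    keep = order[:k]
    out[keep] = probs[keep]
    return out / out.sum()


class _GrammarState:
    """Tracks the replicon layout grammar during left-to-right decoding."""

    def __init__(self, vocab: Vocabulary):
        self.vocab = vocab
        self.pos = 0          # tokens consumed
        self.phase = "bos"    # bos -> species -> body -> oriv
        self.cur_rep_len = 0
        self.n_nt = 0

    def clone(self) -> "_GrammarState":
        c = _GrammarState.__new__(_GrammarState)
        c.__dict__.update(self.__dict__)
        return c

    def consume(self, tok_id: int) -> None:
        v = self.vocab
        cls = v.class_of_id(tok_id)
        if self.phase == "bos":
            if tok_id != v.bos:
                raise ValueError("prompt must begin with <bos>")
            self.phase = "species"
        elif self.phase == "species":
            if not (tok_id == v.unk_species or cls is TokenClass.SPECIES):
                raise ValueError("second prompt token must be a species token")
            self.phase = "body"
        elif self.phase == "body":
            if cls is TokenClass.AMINO_ACID:
                self.cur_rep_len += 1
            elif tok_id == v.sep:
                if self.cur_rep_len == 0:
                    raise ValueError("<sep> with no preceding Rep tokens")
                self.cur_rep_len = 0
            elif cls is TokenClass.NUCLEOTIDE:
                self.phase = "oriv"
                self.n_nt = 1
            else:
                raise ValueError("invalid token in Rep/oriV body")
        elif self.phase == "oriv":
            if cls is TokenClass.NUCLEOTIDE:
                self.n_nt += 1
            elif tok_id == v.eos:
                self.phase = "done"
            else:
                raise ValueError("invalid token inside oriV")
        else:
            raise ValueError("token after <eos>")
        self.pos += 1

    def allowed(self, tokens_left: int) -> np.ndarray:
        """Boolean mask of grammar-legal next tokens that can still close
        the sequence within ``tokens_left`` further tokens."""
        v = self.vocab
        mask = np.zeros(len(v), dtype=bool)
        nt = list(v.nucleotide_ids)
        aa = list(v.ids_of_class(TokenClass.AMINO_ACID))
        if self.phase == "bos":
            mask[v.bos] = tokens_left >= 4
        elif self.phase == "species":
            if tokens_left >= 3:
                mask[v.unk_species] = True
                for i in v.ids_of_class(TokenClass.SPECIES):
                    mask[i] = True
        elif self.phase == "body":
            if tokens_left >= 3:
                mask[aa] = True
            if self.cur_rep_len >= 1 and tokens_left >= 4:
                mask[v.sep] = True
            # a nucleotide may not directly follow <sep>
            if tokens_left >= 2 and not self._pending_sep():
                mask[nt] = True
        elif self.phase == "oriv":
            if tokens_left >= 2:
                mask[nt] = True
            mask[v.eos] = True
        return mask

    def _pending_sep(self) -> bool:
        # inside body, cur_rep_len == 0 either means "no Rep started yet"
        # (nucleotides fine) or "just consumed <sep>" (must emit an amino acid)
        return self.cur_rep_len == 0 and getattr(self, "_saw_sep", False)

    def consume_tracking_sep(self, tok_id: int) -> None:
        if tok_id == self.vocab.sep:
            self._saw_sep = True
        elif self.vocab.class_of_id(tok_id) is TokenClass.AMINO_ACID:
            self._saw_sep = False
        self.consume(tok_id)


def _prompt_ids(config: GenerationConfig, vocab: Vocabulary) -> list[int]:
    if config.prompt is None:
        return [vocab.bos]
    ids = list(
        config.prompt.ids
        if isinstance(config.prompt, TokenSequence)
        else config.prompt
    )
    if not ids:
        return [vocab.bos]
    return ids


def _validate_prompt(ids: Sequence[int], vocab: Vocabulary) -> _GrammarState:
    state = _GrammarState(vocab)
    for tok in ids:
        state.consume_tracking_sep(int(tok))
    if state.phase == "done":
        raise ValueError("prompt is already a complete sequence")
    return state


def generate(
    model: TrainedModel,
    config: GenerationConfig,
    n_samples: int = 1,
) -> list[RepliconRecord]:
    """Sample replicons with nucleus or top-k truncation after temperature.

    Each output begins with the prompt verbatim; generation stops at the
    stop token or at ``max_len`` total tokens.  Identical config and seed
    give identical outputs.
    """
    if config.mode == BEAM:
        raise ValueError("use generate_constrained for BEAM mode")
    if config.forbidden:
        raise ValueError(
            "forbidden motifs require BEAM mode; call generate_constrained"
        )
    vocab = model.vocab
    prompt = _prompt_ids(config, vocab)
    proto = _validate_prompt(prompt, vocab)
    min_needed = {"bos": 4, "species": 3, "body": 2, "oriv": 1}[proto.phase]
    if config.max_len < len(prompt) + min_needed:
        raise ValueError("max_len leaves no room to complete the sequence")
    rng = np.random.default_rng(config.seed)
    B = n_samples
    state = DecodeState(model, B, capacity=config.max_len)
    logits = state.prefill(np.tile(np.asarray(prompt)[None, :], (B, 1)))
    grammars = [proto.clone() for _ in range(B)]
    seqs: list[list[int]] = [list(prompt) for _ in range(B)]
    done = np.zeros(B, dtype=bool)
    while not done.all() and state.t < config.max_len:
        probs_all = _softmax(logits.astype(np.float64) / config.temperature)
        next_tokens = np.full(B, vocab.pad, dtype=np.int64)
        for b in range(B):
            if done[b]:
                continue
            left = config.max_len - len(seqs[b])
            mask = grammars[b].allowed(left)
            p = probs_all[b] * mask
            total = p.sum()
            if total <= 0:  # grammar dead end (cannot occur for legal prompts)
                next_tokens[b] = vocab.eos
                done[b] = True
                continue
            p /= total
            if config.mode == NUCLEUS:
                p = nucleus_filter(p, config.top_p)
            else:
                p = topk_filter(p, config.top_k)
            tok = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
            tok = min(tok, len(p) - 1)
            seqs[b].append(tok)
            grammars[b].consume_tracking_sep(tok)
            next_tokens[b] = tok
            if tok == vocab.eos:
                done[b] = True
        if done.all():
            break
        logits = state.step(next_tokens)
    out = []
    for b in range(B):
        if seqs[b][-1] != vocab.eos:
            seqs[b].append(vocab.eos)  # max_len reached; grammar mask ensured >=1 nt
        out.append(decode_tokens(seqs[b], vocab, record_id=f"gen_{b:04d}"))
    return out


def _window_hits(window: str, forbidden: frozenset[str], lengths: tuple[int, ...]) -> bool:
    for L in lengths:
        if len(window) >= L and window[-L:] in forbidden:
            return True
    return False


def generate_constrained(
    model: TrainedModel,
    config: GenerationConfig,
) -> list[RepliconRecord]:
    """Beam search over oriV continuations avoiding every forbidden motif.

    Any hypothesis whose sliding suffix window (spanning the prompt boundary)
    matches a forbidden motif is pruned before scoring; beams are ranked by
    total log-likelihood with ties broken by token id then beam index.
    Returns up to ``n_beams`` completed replicons, best first.  Raises
    :class:`InfeasibleGenerationError` when every beam dies before a stop
    token.
    """
    if config.mode != BEAM:
        raise ValueError("generate_constrained requires BEAM mode")
    if not config.forbidden:
        raise ValueError("empty forbidden set: use generate() instead")
    vocab = model.vocab
    prompt = _prompt_ids(config, vocab)
    if len(prompt) < 2:
        raise ValueError(
            "constrained generation needs a prompt through the species token"
        )
    proto = _validate_prompt(prompt, vocab)
    lengths = tuple(sorted({len(m) for m in config.forbidden}))
    wmax = max(lengths) - 1
    nt_ids = vocab.nucleotide_ids
    id_to_base = {i: vocab.id_to_token[i].upper() for i in nt_ids}
    # the prompt's own oriV portion must already be motif-free
    prompt_oriv = "".join(
        vocab.id_to_token[i] for i in prompt if i in nt_ids
    )
    if find_forbidden_occurrences(prompt_oriv, config.forbidden):
        raise ValueError(
            "prompt oriV seed already contains a forbidden motif; "
            "run infill_repair on it first"
        )

    state = DecodeState(model, 1, capacity=config.max_len)
    logits = state.prefill(np.asarray(prompt)[None, :])
    logprobs = np.log(_softmax(logits.astype(np.float64)))
    beams = [
        {
            "ids": list(prompt),
            "score": 0.0,
            "window": prompt_oriv.upper()[-wmax:] if wmax else "",
            "grammar": proto.clone(),
        }
    ]
    finished: list[tuple[float, list[int]]] = []

    def worst_kept() -> float:
        if len(finished) < config.n_beams:
            return -np.inf
        return sorted(finished, key=lambda f: -f[0])[config.n_beams - 1][0]

    while beams:
        candidates = []  # (score, token_id, beam_idx, is_eos)
        for bi, beam in enumerate(beams):
            left = config.max_len - len(beam["ids"])
            allowed = beam["grammar"].allowed(left)
            for tok in (*nt_ids, vocab.eos):
                if not allowed[tok]:
                    continue
                if tok == vocab.eos and len(beam["ids"]) == len(prompt):
                    continue  # must extend the prompt by at least one base
                if tok != vocab.eos:
                    window = beam["window"] + id_to_base[tok]
                    if _window_hits(window, config.forbidden, lengths):
                        continue  # pruned before scoring
                candidates.append(
                    (beam["score"] + logprobs[bi, tok], tok, bi, tok == vocab.eos)
                )
        if not candidates:
            break
        # rank: score desc, token id asc, beam index asc; only the top
        # 2*n_beams candidates compete (the usual refill margin when some
        # of the top hypotheses finish)
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        new_beams = []
        parents = []
        tokens = []
        for score, tok, bi, is_eos in candidates[: 2 * config.n_beams]:
            if is_eos:
                finished.append((score, beams[bi]["ids"] + [tok]))
                continue
            if len(new_beams) >= config.n_beams:
                continue
            g = beams[bi]["grammar"].clone()
            g.consume_tracking_sep(tok)
            new_beams.append(
                {
                    "ids": beams[bi]["ids"] + [tok],
                    "score": score,
                    "window": (beams[bi]["window"] + id_to_base[tok])[-wmax:]
                    if wmax
                    else "",
                    "grammar": g,
                }
            )
            parents.append(bi)
            tokens.append(tok)
        # scores only decrease with length: stop once no alive beam can
        # displace the kept finished set
        if not new_beams or (
            len(finished) >= config.n_beams
            and new_beams[0]["score"] <= worst_kept()
        ):
            break
        if len(new_beams[0]["ids"]) >= config.max_len:
            # length budget exhausted: close surviving beams (motif-free)
            for beam in new_beams:
                finished.append((beam["score"], beam["ids"] + [vocab.eos]))
            break
        state.select(np.asarray(parents))
        logits = state.step(np.asarray(tokens))
        logprobs = np.log(_softmax(logits.astype(np.float64)))
        beams = new_beams
    if not finished:
        raise InfeasibleGenerationError(
            "all beams were pruned before producing a stop token"
        )
    finished.sort(key=lambda f: -f[0])
    out = []
    for rank, (_, ids) in enumerate(finished[: config.n_beams]):
        out.append(decode_tokens(ids, vocab, record_id=f"beam_{rank:03d}"))
    return out


def infill_repair(
    sequence: str,
    forbidden: frozenset[str],
    model: TrainedModel,
    species: str = UNKNOWN,
    rep_proteins: tuple[str, ...] = (),
) -> tuple[str, int]:
    """Clear forbidden motifs from an oriV by model-guided substitutions.

    While any forbidden occurrence remains: at the leftmost occurrence, try
    every single-position substitution inside its span, keep only those that
    clear the occurrence, and apply the one with the highest full-sequence
    autoregressive likelihood (preferring candidates that do not create new
    occurrences).  Returns the repaired sequence and the edit count; the
    result is a fixed point of the procedure.
    """
    vocab = model.vocab
    seq = sequence.lower()
    if find_forbidden_occurrences(seq, forbidden) == []:
        return seq, 0
    max_rounds = 3 * len(seq)
    n_edits = 0
    for _ in range(max_rounds):
        spans = find_forbidden_occurrences(seq, forbidden)
        if not spans:
            return seq, n_edits
        start, end = spans[0]
        candidates = []
        for pos in range(start, end):
            for base in "acgt":
                if base == seq[pos]:
                    continue
                cand = seq[:pos] + base + seq[pos + 1 :]
                cand_spans = find_forbidden_occurrences(cand, forbidden)
                if any(s < end and e > start for s, e in cand_spans):
                    continue  # the leftmost occurrence survives
                candidates.append((cand, len(cand_spans)))
        if not candidates:
            raise RuntimeError(
                f"no single substitution clears the motif at {start}:{end}"
            )
        min_new = min(n for _, n in candidates)
        pool = [c for c, n in candidates if n == min_new]
        # batch-score candidates by full-sequence likelihood
        arrs = [
            encode_replicon(
                RepliconRecord("cand", species, rep_proteins, c), vocab
            ).ids
            for c in pool
        ]
        ids = np.asarray(arrs, dtype=np.int64)
        logits, _ = model.net.forward(ids, train=False)
        probs = _softmax(logits[:, :-1].astype(np.float64))
        tgt = ids[:, 1:]
        lp = np.log(
            np.take_along_axis(probs, tgt[..., None], axis=-1)[..., 0]
        ).sum(-1)
        seq = pool[int(np.argmax(lp))]
        n_edits += 1
    raise RuntimeError("infill_repair failed to converge within the retry bound")
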