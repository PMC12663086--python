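"""Global alignment, nearest-wild-type search, matched mutants.

The similarity score used throughout the package is the percent identity of
an affine-gap global (Needleman-Wunsch/Gotoh) alignment: matching columns
divided by total alignment columns, gaps included in the denominator.
Default penalties follow the EMBOSS ``needle`` nucleotide setup (gap open
10.0, gap extension 0.5, match +5, mismatch -4).  A gap of length ``L``
costs ``open + (L-1)*extend``; end gaps are penalized (true global mode).

Traceback is deterministic: when several predecessors achieve the optimum,
diagonal beats up (gap in ``b``) beats left (gap in ``a``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

NEG = -np.inf
_EPS = 1e-9

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """An affine-gap global alignment of ``a`` against ``b``.

    ``n_sub``/``n_ins``/``n_del`` count the edits transforming ``b`` into
    ``a``: an insertion is a column where ``a`` has a base over a gap in
    ``b``; a deletion the converse.  ``identity`` is the fraction of
    alignment columns whose bases match.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    n_sub: int
    n_ins: int
    n_del: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identity


def global_align(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> AlignmentResult:
    """Optimal affine-gap global alignment (three-state Gotoh DP)."""
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    m, n = len(a), len(b)
    # state M: column consumes a base of both sequences
    # state X: gap in b (vertical move, consumes a)
    # state Y: gap in a (horizontal move, consumes b)
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    js = np.arange(1, n + 1)
    Y[0, 1:] = -(gap_open + (js - 1) * gap_extend)

    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    ext_k = gap_extend * np.arange(n + 1)

    with np.errstate(invalid="ignore"):
        for i in range(1, m + 1):
            sub = np.where(b_arr == a_arr[i - 1], match, mismatch)
            prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
            M[i, 1:] = sub + prev_best[:-1]
            X[i] = np.maximum(
                np.maximum(M[i - 1] - gap_open, Y[i - 1] - gap_open),
                X[i - 1] - gap_extend,
            )
            # Y[i, j] = max_{k<j} (max(M,X)[i,k] + ext*k) - open - ext*(j-1)
            mx = np.maximum(M[i], X[i]) + ext_k
            Y[i, 1:] = (
                np.maximum.accumulate(mx[:-1]) - gap_open - gap_extend * (js - 1)
            )

    # traceback, tie order diagonal (M) > up (X) > left (Y)
    def close(u: float, v: float) -> bool:
        return np.isfinite(u) and abs(u - v) <= _EPS * max(1.0, abs(v))

    finals = (M[m, n], X[m, n], Y[m, n])
    state = int(np.argmax(finals))  # argmax takes the first maximum: M > X > Y
    score = float(finals[state])
    i, j = m, n
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            target = M[i, j] - (match if a[i - 1] == b[j - 1] else mismatch)
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if close(M[i, j], target):
                state = 0
            elif close(X[i, j], target):
                state = 1
            else:
                state = 2
        elif state == 1:  # X: gap in b
            cols_a.append(a[i - 1])
            cols_b.append("-")
            target = X[i, j]
            i -= 1
            if close(M[i, j] - gap_open, target):
                state = 0
            elif close(X[i, j] - gap_extend, target):
                state = 1
            else:
                state = 2
        else:  # Y: gap in a
            cols_a.append("-")
            cols_b.append(b[j - 1])
            target = Y[i, j]
            j -= 1
            if close(M[i, j] - gap_open, target):
                state = 0
            elif close(X[i, j] - gap_open, target):
                state = 1
            else:
                state = 2
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    n_match = n_sub = n_ins = n_del = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            n_del += 1
        elif cb == "-":
            n_ins += 1
        elif ca == cb:
            n_match += 1
        else:
            n_sub += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity=n_match / len(aligned_a),
        n_sub=n_sub,
        n_ins=n_ins,
        n_del=n_del,
    )


def containment_identity(test: str, train: str) -> tuple[float, float]:
    """Identity and query coverage of the best containment of ``test`` in ``train``.

    BLAST-style pident/qcovs check: the test sequence is aligned end-to-end
    against the best-matching region of the train sequence (free end gaps on
    the train side).  Identity is matches over alignment columns; coverage
    the fraction of test bases inside the aligned region.
    """
    res = edlib.align(test.lower(), train.lower(), mode="HW", task="path")
    n_eq = n_x = n_i = n_d = 0
    for count, op in _CIGAR_RE.findall(res["cigar"] or ""):
        c = int(count)
        if op == "=":
            n_eq += c
        elif op == "X":
            n_x += c
        elif op == "I":
            n_i += c
        elif op == "D":
            n_d += c
    total = n_eq + n_x + n_i + n_d
    if total == 0:
        return 0.0, 0.0
    query_consumed = n_eq + n_x + n_i  # edlib: I consumes the query
    return n_eq / total, query_consumed / len(test)


_KMER_CACHE_MAX = 4096


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def closest_wildtype(
    query: str,
    references: dict[str, str],
    k_prefilter: int = 11,
) -> tuple[str, AlignmentResult]:
    """Nearest wild type: shared k-mer prefilter, then one global alignment.

    References are ranked by the number of k-mers shared with the query and
    the top candidate is globally aligned.  When no reference shares a k-mer
    (or the query is shorter than ``k``), every reference is aligned and the
    best score wins — the slow fallback path.
    """
    if not references:
        raise ValueError("closest_wildtype requires a non-empty reference set")
    qk = _kmers(query, k_prefilter) if len(query) >= k_prefilter else frozenset()
    best_id, best_shared = None, 0
    for rid in sorted(references):
        shared = len(qk & _kmers(references[rid], k_prefilter)) if qk else 0
        if shared > best_shared:
            best_id, best_shared = rid, shared
    if best_id is not None:
        return best_id, global_align(query, references[best_id])
    # fallback: no shared k-mers anywhere
    best: tuple[str, AlignmentResult] | None = None
    for rid in sorted(references):
        aln = global_align(query, references[rid])
        if best is None or aln.score > best[1].score:
            best = (rid, aln)
    return best


@dataclass(frozen=True)
class MutantSpec:
    """Edit spectrum for a matched random mutant."""

    n_sub: int
    n_ins: int
    n_del: int
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sub, self.n_ins, self.n_del) < 0:
            raise ValueError("edit counts must be non-negative")

    @classmethod
    def from_alignment(cls, aln: AlignmentResult, seed: int = 0) -> "MutantSpec":
        return cls(n_sub=aln.n_sub, n_ins=aln.n_ins, n_del=aln.n_del, seed=seed)


def apply_matched_mutations_tracked(
    wt: str, spec: MutantSpec
) -> tuple[str, np.ndarray]:
    """Mutate ``wt`` with exactly the spec's edit counts; track coordinates.

    Deletions, then insertions, then substitutions, at seeded random
    positions (substitution positions distinct).  Returns the mutant and an
    array mapping each wild-type position to its mutant position (-1 where
    deleted), so planted-element coordinates can be followed through.
    """
    n = len(wt)
    if spec.n_del > n:
        raise ValueError(f"cannot delete {spec.n_del} bases from length {n}")
    rng = np.random.default_rng(spec.seed)
    # origin[i] = wild-type index of mutant base i, or -1 for an insertion
    origin = list(range(n))
    seq = list(wt)
    for pos in sorted(rng.choice(n, size=spec.n_del, replace=False), reverse=True):
        del seq[pos]
        del origin[pos]
    for _ in range(spec.n_ins):
        pos = int(rng.integers(0, len(seq) + 1))
        seq.insert(pos, "acgt"[rng.integers(4)])
        origin.insert(pos, -1)
    if spec.n_sub > len(seq):
        raise ValueError(
            f"cannot place {spec.n_sub} distinct substitutions in length {len(seq)}"
        )
    for pos in rng.choice(len(seq), size=spec.n_sub, replace=False):
        alternatives = [c for c in "acgt" if c != seq[pos]]
        seq[int(pos)] = alternatives[rng.integers(3)]
    pos_map = np.full(n, -1, dtype=np.int64)
    for mut_i, wt_i in enumerate(origin):
        if wt_i >= 0:
            pos_map[wt_i] = mut_i
    return "".join(seq), pos_map


def apply_matched_mutations(wt: str, spec: MutantSpec) -> str:
    """Matched random mutant of ``wt`` (see the tracked variant)."""
    return apply_matched_mutations_tracked(wt, spec)[0]


def find_forbidden_occurrences(seq: str, forbidden: frozenset[str]) -> list[tuple[int, int]]:
    """All (start, end) spans of forbidden motifs in ``seq`` (case-insensitive).

    The forbidden set is reverse-complement-closed, so scanning the forward
    strand covers both strands.
    """
    s = seq.upper()
    spans = []
    for length in sorted({len(mo) for mo in forbidden}):
        for i in range(len(s) - length + 1):
            if s[i : i + length] in forbidden:
                spans.append((i, i + length))
    spans.sort()
    return spans


def strip_restriction_sites_minimal(
    wt: str,
    forbidden: frozenset[str],
    seed: int = 0,
    max_iters: int = 10_000,
) -> tuple[str, int]:
    """Remove every forbidden site from ``wt`` by random single substitutions.

    Iteratively: pick the leftmost remaining occurrence, substitute one
    random position inside it with a random different base, rescan.  Length
    is preserved; the number of substitution events is returned.
    """
    rng = np.random.default_rng(seed)
    seq = list(wt)
    n_subs = 0
    for _ in range(max_iters):
        spans = find_forbidden_occurrences("".join(seq), forbidden)
        if not spans:
            return "".join(seq), n_subs
        start, end = spans[0]
        pos = int(rng.integers(start, end))
        alternatives = [c for c in "acgt" if c != seq[pos].lower()]
        repl = alternatives[rng.integers(3)]
        seq[pos] = repl if seq[pos].islower() else repl.upper()
        n_subs += 1
    raise RuntimeError(
        f"could not clear forbidden sites within {max_iters} substitutions"
    )


def filter_near_duplicates(
    test: dict[str, str],
    train: dict[str, str],
    identity_cut: float = 0.95,
    coverage_cut: float = 0.95,
) -> list[str]:
    """Ids of test sequences with no near-duplicate in the train set.

    A test sequence is removed iff some train sequence contains it at
    identity > ``identity_cut`` over a region covering > ``coverage_cut``
    of the test sequence.
    """
    if not test or not train:
        raise ValueError("both test and train sets must be non-empty")
    retained = []
    for tid in test:
        dup = any(
            ident > identity_cut and cov > coverage_cut
            for ident, cov in (
                containment_identity(test[tid], tr) for tr in train.values()
            )
        )
        if not dup:
            retained.append(tid)
    return retained
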