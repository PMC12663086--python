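"""Independent oracles used by the test suite.

Each is deliberately written in the most transparent way possible —
exhaustive enumeration or plain-loop DP — and shares no code with the
package implementations it checks.
"""

from __future__ import annotations


def enumerate_alignments(a: str, b: str):
    """Yield every monotone global alignment as a list of (ca, cb) columns."""
    if not a and not b:
        yield []
        return
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest


def score_alignment(cols, gap_open=10.0, gap_extend=0.5, match=5.0, mismatch=-4.0):
    """Affine score of one alignment: a gap run of length L costs
    open + (L-1)*extend; runs in different sequences are separate."""
    score = 0.0
    prev_gap = None  # 'a' (gap in a) / 'b' (gap in b) / None
    for ca, cb in cols:
        if ca == "-":
            score -= gap_extend if prev_gap == "a" else gap_open
            prev_gap = "a"
        elif cb == "-":
            score -= gap_extend if prev_gap == "b" else gap_open
            prev_gap = "b"
        else:
            score += match if ca == cb else mismatch
            prev_gap = None
    return score


def brute_force_best_score(a: str, b: str, **kw) -> float:
    return max(score_alignment(cols, **kw) for cols in enumerate_alignments(a, b))


def plain_gotoh_score(a, b, gap_open=10.0, gap_extend=0.5, match=5.0, mismatch=-4.0):
    """Plain-loop three-state affine DP (no vectorization tricks)."""
    NEG = float("-inf")
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, n + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
            )
    return max(M[m][n], X[m][n], Y[m][n])


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def naive_motif_count(seq: str, motifs) -> int:
    """Count occurrences of any motif on either strand by direct substring
    scanning (independent of the package's rc-closed forward-only scan)."""
    fwd = seq.upper()
    rev = naive_revcomp(seq)
    total = 0
    for motif in motifs:
        motif = motif.upper()
        for strand in (fwd, rev):
            for i in range(len(strand) - len(motif) + 1):
                if strand[i : i + len(motif)] == motif:
                    total += 1
    return total


def brute_nucleus_support(probs, top_p):
    """Indices of the smallest mass-covering prefix of the sorted distribution."""
    order = sorted(range(len(probs)), key=lambda i: -probs[i])
    kept, mass = [], 0.0
    for i in order:
        kept.append(i)
        mass += probs[i]
        if mass >= top_p - 1e-12:
            break
    return set(kept)
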