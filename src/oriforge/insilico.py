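"""Biological-plausibility metrics for oriV sequences.

Wild-type plasmid origins tend to show AT-rich stretches, low predicted
folding free energy, and tandem repeats (iterons) bound by Rep proteins,
plus DnaA boxes bound by the host initiator.  This module measures those
signals on any nucleotide sequence so generated origins can be compared
against wild types and against uniform-random sequences of the training
median length (357 nt):

* AT content,
* sliding-window (100 bp) folding energy with a pluggable engine —
  the built-in stand-in negates a Nussinov maximum base-pairing count;
  an RNAfold-backed engine is available when ViennaRNA bindings are
  importable,
* PWM motif scanning on both strands with the log-likelihood > 1.0 filter,
* the uniform-random baseline generator.

PWM scores are log2 likelihood ratios of the motif model over the
background, summed over positions; a hit is any offset scoring above the
PWM's threshold (default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

_BASE_INDEX = {"a": 0, "c": 1, "g": 2, "t": 3}


def _seq_to_idx(seq: str) -> np.ndarray:
    s = seq.lower()
    try:
        return np.asarray([_BASE_INDEX[ch] for ch in s], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None


def at_content(seq: str) -> float:
    """(#a + #t) / length."""
    if not seq:
        raise ValueError("empty sequence")
    idx = _seq_to_idx(seq)
    return float(((idx == 0) | (idx == 3)).mean())


# --------------------------------------------------------------------------
# folding engines

_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1)}  # Watson-Crick a:t, c:g
_MIN_LOOP = 3


def nussinov_energy(seq: str) -> float:
    """Stand-in folding score: minus the maximum number of Watson-Crick
    pairs in a nested structure with a minimum loop of 3 (Nussinov DP).

    Always <= 0; not a thermodynamic free energy — a monotone structural
    proxy so the windowed statistic needs no external folding engine.
    """
    idx = _seq_to_idx(seq)
    n = len(idx)
    N = np.zeros((n, n), dtype=np.int64)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j - 1] + (1 if (idx[i], idx[j]) in _PAIRS else 0)
            if j > i + 1:
                ks = N[i, i:j] + N[i + 1 : j + 1, j]
                best = max(best, int(ks.max()))
            N[i, j] = best
    return -float(N[0, n - 1])


def viennarna_engine() -> Callable[[str], float]:
    """RNAfold-backed thermodynamic MFE engine (requires ViennaRNA bindings).

    DNA input is folded as RNA (t read as u), mirroring how windowed MFE is
    commonly computed on genomic windows.
    """
    import RNA  # deferred: optional dependency

    def fold(seq: str) -> float:
        return float(RNA.fold(seq.upper().replace("T", "U"))[1])

    return fold


def windowed_mfe(
    seq: str,
    window: int = 100,
    engine: Callable[[str], float] | None = None,
) -> tuple[np.ndarray, float]:
    """Folding energy of every length-``window`` substring (step 1) and the mean."""
    if len(seq) < window:
        raise ValueError(
            f"sequence length {len(seq)} shorter than the window ({window})"
        )
    if engine is None:
        engine = nussinov_energy
    values = np.asarray(
        [engine(seq[i : i + window]) for i in range(len(seq) - window + 1)]
    )
    return values, float(values.mean())


# --------------------------------------------------------------------------
# PWM scanning

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix as log2 likelihood-ratio weights (L x 4, ACGT)."""

    name: str
    weights: np.ndarray
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    score_threshold: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("PWM weights must have shape (L, 4)")
        if w.shape[0] < 4:
            raise ValueError("PWM must span at least 4 positions")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_probabilities(
        cls,
        name: str,
        probs,
        background=UNIFORM_BACKGROUND,
        score_threshold: float = 1.0,
        pseudo: float = 1e-9,
    ) -> "PWM":
        p = np.asarray(probs, dtype=np.float64)
        if not np.allclose(p.sum(1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {name!r}: probability rows must sum to 1")
        bg = np.asarray(background, dtype=np.float64)
        w = np.log2((p + pseudo) / bg)
        return cls(name, w, tuple(background), score_threshold)

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        consensus_prob: float = 0.9,
        score_threshold: float = 1.0,
    ) -> "PWM":
        """Sharp PWM: the consensus base gets ``consensus_prob``, the rest split
        the remainder evenly."""
        idx = _seq_to_idx(consensus)
        p = np.full((len(idx), 4), (1 - consensus_prob) / 3)
        p[np.arange(len(idx)), idx] = consensus_prob
        return cls.from_probabilities(name, p, score_threshold=score_threshold)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 0-based, on the forward strand
    strand: str  # '+' or '-'
    score: float

    def end(self, pwm_len: int) -> int:
        return self.start + pwm_len


def _scan_one_strand(idx: np.ndarray, w: np.ndarray) -> np.ndarray:
    L = w.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)  # (n, L)
    return w[np.arange(L), windows].sum(1)


_RC = np.array([3, 2, 1, 0])


def scan_pwm(seq: str, pwms: Sequence[PWM]) -> list[MotifHit]:
    """All above-threshold PWM hits on both strands; overlaps permitted.

    Minus-strand hits are reported in forward-strand coordinates of the
    leftmost matched base.  A PWM longer than the sequence yields no hits.
    """
    idx = _seq_to_idx(seq)
    rc = _RC[idx[::-1]]
    hits: list[MotifHit] = []
    for pwm in pwms:
        L = len(pwm)
        for strand, strand_idx in (("+", idx), ("-", rc)):
            scores = _scan_one_strand(strand_idx, pwm.weights)
            for off in np.nonzero(scores > pwm.score_threshold)[0]:
                start = int(off) if strand == "+" else len(seq) - int(off) - L
                hits.append(
                    MotifHit(pwm.name, start, strand, float(scores[off]))
                )
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def motif_presence_profile(
    seq: str, pwms: Sequence[PWM]
) -> tuple[dict[str, int], bool]:
    """Strand-summed hit counts per motif and whether every motif occurs.

    A palindromic site counts twice, once per strand.
    """
    if not pwms:
        raise ValueError("motif_presence_profile requires at least one PWM")
    hits = scan_pwm(seq, pwms)
    counts = {p.name: 0 for p in pwms}
    for h in hits:
        counts[h.motif] += 1
    return counts, all(c >= 1 for c in counts.values())


def random_baseline(n: int = 1000, length: int = 357, seed: int = 0) -> list[str]:
    """i.i.d. uniform ACGT sequences — the null model for every metric above.

    The default length (357) is the median oriV length in the training data.
    """
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n, length))
    bases = np.array(list("acgt"))
    return ["".join(row) for row in bases[draws]]


# --------------------------------------------------------------------------
# PWM file I/O: '>name' line then L rows of 4 probabilities (A C G T order)


def write_pwms(pwms: Sequence[PWM], path, probs: dict[str, np.ndarray] | None = None) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            p = (
                probs[pwm.name]
                if probs and pwm.name in probs
                else np.asarray(pwm.background) * 2.0 ** pwm.weights
            )
            for row in p:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_pwms(path, score_threshold: float = 1.0) -> list[PWM]:
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(
                        PWM.from_probabilities(name, rows, score_threshold=score_threshold)
                    )
                name, rows = line[1:], []
            else:
                rows.append([float(x) for x in line.split()])
    if name is not None:
        pwms.append(PWM.from_probabilities(name, rows, score_threshold=score_threshold))
    return pwms
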