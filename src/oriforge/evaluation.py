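"""Teacher-forced next-nucleotide accuracy with bootstrap confidence intervals.

Accuracy is measured on the oriV region only: at every oriV position the
predicted base is the argmax of the model's next-token distribution given
the *true* preceding tokens (species and Rep context included), pooled over
all positions of all records.  The stop-token prediction after the last
nucleotide is excluded.  Confidence intervals come from a seeded percentile
bootstrap resampling whole sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lm import TrainedModel, _pad_batch
from .records import RepliconRecord, TokenClass, encode_replicon


@dataclass(frozen=True)
class AccuracyReport:
    n_sequences: int
    n_positions: int
    accuracy: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "n_positions": self.n_positions,
            "accuracy": self.accuracy,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


def per_sequence_scores(
    model: TrainedModel,
    records: Sequence[RepliconRecord],
    batch_size: int = 16,
) -> list[tuple[int, int]]:
    """(n_correct, n_positions) per record at oriV positions, teacher forced."""
    if not records:
        raise ValueError("no records to evaluate")
    vocab = model.vocab
    nt_ids = set(vocab.nucleotide_ids)
    seqs = [encode_replicon(r, vocab, model.config.context_len) for r in records]
    scores: list[tuple[int, int]] = []
    for start in range(0, len(seqs), batch_size):
        batch = seqs[start : start + batch_size]
        ids = _pad_batch(batch, vocab.pad)
        logits, _ = model.net.forward(ids, train=False)
        # prediction at position t-1 targets token t; ties break to the
        # lowest token id (np.argmax convention)
        preds = logits[:, :-1].argmax(-1)
        targets = ids[:, 1:]
        for row, seq in enumerate(batch):
            n_corr = n_pos = 0
            for t in range(len(seq) - 1):
                if seq.ids[t + 1] in nt_ids:
                    n_pos += 1
                    if preds[row, t] == targets[row, t]:
                        n_corr += 1
            scores.append((n_corr, n_pos))
    return scores


def pooled_accuracy(scores: Sequence[tuple[int, int]]) -> float:
    total_pos = sum(n for _, n in scores)
    if total_pos == 0:
        raise ValueError("no oriV positions to score")
    return sum(c for c, _ in scores) / total_pos


def bootstrap_ci(
    per_sequence_scores: Sequence[tuple[int, int]],
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of pooled accuracy, resampling sequences.

    Sequences (not positions) are resampled with replacement, respecting
    within-sequence correlation of predictions.
    """
    if not per_sequence_scores:
        raise ValueError("need at least one sequence")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    arr = np.asarray(per_sequence_scores, dtype=np.float64)  # (n, 2)
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    idx = rng.integers(0, n, size=(n_resamples, n))
    corr = arr[idx, 0].sum(1)
    pos = arr[idx, 1].sum(1)
    stats = corr / np.maximum(pos, 1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return float(lo), float(hi)


def next_nucleotide_accuracy(
    model: TrainedModel,
    records: Sequence[RepliconRecord],
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> AccuracyReport:
    """Pooled oriV next-nucleotide accuracy with a bootstrap CI."""
    scores = per_sequence_scores(model, records)
    acc = pooled_accuracy(scores)
    lo, hi = bootstrap_ci(scores, n_resamples=n_resamples, level=level, seed=seed)
    return AccuracyReport(
        n_sequences=len(scores),
        n_positions=sum(n for _, n in scores),
        accuracy=acc,
        ci_low=min(lo, acc),
        ci_high=max(hi, acc),
        n_resamples=n_resamples,
        seed=seed,
    )
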