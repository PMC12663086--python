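"""Sequence-identity-aware clustering and train/validation splitting.

Leakage control for the language model: oriV sequences are first clustered
at a 90% identity threshold (greedy, longest-first, representative-based —
the CD-HIT contract without the external binary), then whole clusters are
assigned to TRAIN or VALID so near-identical origins never straddle the
split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import global_align

TRAIN = "TRAIN"
VALID = "VALID"


@dataclass(frozen=True)
class SplitAssignment:
    """record_id -> (cluster_id, partition)."""

    assignment: dict[str, tuple[int, str]]

    def partition_of(self, record_id: str) -> str:
        return self.assignment[record_id][1]

    def cluster_of(self, record_id: str) -> int:
        return self.assignment[record_id][0]

    def ids_in(self, partition: str) -> list[str]:
        return sorted(
            rid for rid, (_, p) in self.assignment.items() if p == partition
        )

    def n_clusters(self) -> int:
        return len({c for c, _ in self.assignment.values()})


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the global alignment: matches / alignment length."""
    return global_align(a, b).identity


def greedy_cluster(orivs: dict[str, str], identity_threshold: float = 0.90) -> dict[str, int]:
    """Greedy representative clustering at an identity threshold.

    Sequences are visited longest first (ties by id); each joins the first
    existing cluster whose representative shares at least the threshold
    identity, else founds a new cluster.  A length-ratio bound prunes
    alignments that cannot reach the threshold (identity <= min/max length).
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    reps: list[tuple[str, str]] = []  # (cluster representative id, sequence)
    clusters: dict[str, int] = {}
    order = sorted(orivs, key=lambda rid: (-len(orivs[rid]), rid))
    for rid in order:
        seq = orivs[rid]
        for cid, (_, rep_seq) in enumerate(reps):
            lo, hi = sorted((len(seq), len(rep_seq)))
            if lo / hi < identity_threshold:
                continue
            if pairwise_identity(seq, rep_seq) >= identity_threshold:
                clusters[rid] = cid
                break
        else:
            clusters[rid] = len(reps)
            reps.append((rid, seq))
    return clusters


def cluster_and_split(
    orivs: dict[str, str],
    identity_threshold: float = 0.90,
    valid_fraction: float = 0.25,
    seed: int = 0,
) -> SplitAssignment:
    """Cluster oriVs and assign whole clusters to TRAIN/VALID partitions."""
    if len(orivs) < 2:
        raise ValueError("cluster_and_split requires at least two sequences")
    clusters = greedy_cluster(orivs, identity_threshold)
    cluster_ids = sorted(set(clusters.values()))
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(cluster_ids))
    n_valid = int(round(valid_fraction * len(cluster_ids)))
    if valid_fraction > 0 and len(cluster_ids) >= 2:
        n_valid = min(max(n_valid, 1), len(cluster_ids) - 1)
    valid_clusters = set(int(c) for c in shuffled[:n_valid])
    assignment = {
        rid: (cid, VALID if cid in valid_clusters else TRAIN)
        for rid, cid in clusters.items()
    }
    return SplitAssignment(assignment)


def write_split_tsv(split: SplitAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tcluster\tpartition\n")
        for rid in sorted(split.assignment):
            cid, part = split.assignment[rid]
            fh.write(f"{rid}\t{cid}\t{part}\n")


def read_split_tsv(path) -> SplitAssignment:
    assignment: dict[str, tuple[int, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id"):
            raise ValueError(f"{path}: missing split header")
        for line in fh:
            rid, cid, part = line.rstrip("\n").split("\t")
            assignment[rid] = (int(cid), part)
    return SplitAssignment(assignment)
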