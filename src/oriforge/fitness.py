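"""Pooled competition assay quantification.

Read counts per origin variant per sample are turned into relative
frequencies (with a 1e-6 pseudocount so absent variants stay finite) and
log2 relative fitness

    W = log2(f_tx / f_t0)

against the variant's starting frequency in the matched pool lineage (same
replicate, same condition).  Alignment filtering follows the assay's rule:
a read counts iff it is a primary alignment with MAPQ >= 20 — secondary,
supplementary and unmapped records are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

COUNT_COLUMNS = [
    "variant_id",
    "sample_id",
    "timepoint",
    "replicate",
    "condition",
    "read_count",
]


def passes_filter(mapq: int, flags: int, min_mapq: int = 20) -> bool:
    """MAPQ >= 20 and not secondary/supplementary/unmapped."""
    if mapq < 0:
        raise ValueError(f"negative MAPQ {mapq}")
    if flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
        return False
    return mapq >= min_mapq


def count_filtered_alignments(
    alignments: Iterable[tuple[str, int, int]],
    sample_id: str = "sample",
    timepoint: int = 0,
    replicate: int = 1,
    condition: str = "none",
    known_variants: Iterable[str] = (),
) -> pd.DataFrame:
    """Tabulate reads per variant after the primary/MAPQ filter.

    ``alignments`` yields (variant_reference_name, mapq, flag) triples —
    e.g. from a SAM file via :func:`read_sam_alignments`.  Variants listed
    in ``known_variants`` appear with a zero count even if no read passes.
    """
    counts: dict[str, int] = {v: 0 for v in known_variants}
    for ref, mapq, flags in alignments:
        if passes_filter(mapq, flags):
            counts[ref] = counts.get(ref, 0) + 1
    rows = [
        {
            "variant_id": v,
            "sample_id": sample_id,
            "timepoint": timepoint,
            "replicate": replicate,
            "condition": condition,
            "read_count": c,
        }
        for v, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def read_sam_alignments(path) -> list[tuple[str, int, int]]:
    """(reference, MAPQ, flag) triples from a SAM file."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            out.append((read.reference_name or "*", read.mapping_quality, read.flag))
    return out


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (table["read_count"] < 0).any():
        raise ValueError("negative read counts")
    if table.duplicated(["variant_id", "sample_id"]).any():
        raise ValueError("duplicate (variant, sample) rows")
    return table


def variant_frequencies(table: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Per-sample relative frequencies with the pseudocount added to all counts.

    Frequencies within each sample sum to 1.
    """
    table = validate_count_table(table).copy()
    table["adjusted"] = table["read_count"].astype(float) + pseudocount
    table["f"] = table.groupby("sample_id")["adjusted"].transform(
        lambda c: c / c.sum()
    )
    return table.drop(columns="adjusted")


def relative_fitness(f_tx: float, f_t0: float):
    """W = log2(f_tx / f_t0); inputs must be positive."""
    f_tx = np.asarray(f_tx, dtype=np.float64)
    f_t0 = np.asarray(f_t0, dtype=np.float64)
    if (f_tx <= 0).any() or (f_t0 <= 0).any():
        raise ValueError(
            "non-positive frequency: the pseudocount should have prevented this"
        )
    out = np.log2(f_tx / f_t0)
    return float(out) if out.ndim == 0 else out


def fitness_table(table: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Per-(variant, sample) frequencies and W against the lineage T0.

    The matched baseline for a row is the same variant's frequency at
    timepoint 0 within the same replicate — and the same condition when that
    replicate has condition-specific T0 samples (T0 taken before the
    conditions split share one baseline row per replicate).
    """
    freqs = variant_frequencies(table, pseudocount)
    t0 = freqs[freqs["timepoint"] == 0]
    if t0.empty:
        raise ValueError("no timepoint-0 rows to normalize against")
    out_rows = []
    for _, row in freqs.iterrows():
        base = t0[(t0["variant_id"] == row["variant_id"])
                  & (t0["replicate"] == row["replicate"])]
        if len(base) > 1:
            cond = base[base["condition"] == row["condition"]]
            if len(cond) == 1:
                base = cond
        if base.empty:
            raise ValueError(
                f"variant {row['variant_id']!r} replicate {row['replicate']} "
                "has no T0 baseline"
            )
        f0 = float(base["f"].iloc[0])
        out = dict(row)
        out["W"] = relative_fitness(float(row["f"]), f0)
        out_rows.append(out)
    return pd.DataFrame(out_rows)


def generations_per_passage(dilution_factor: float) -> float:
    """Doublings needed to regrow a 1:N dilution: log2(N).

    A 1:100 passage corresponds to ~6.6 generations of growth.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return math.log2(dilution_factor)


@dataclass(frozen=True)
class StabilityResult:
    frequency: float
    warning: bool  # ratio exceeded 1 (plating noise)


def stability_frequency(n_selected: int, n_total: int) -> StabilityResult:
    """Fraction of plasmid-retaining cells: selected / total.

    Ratios above 1 (counting noise between selective and permissive plates)
    are reported as-is with the warning flag set.
    """
    if n_total <= 0:
        raise ValueError("total cell count must be positive")
    if n_selected < 0:
        raise ValueError("selected cell count must be non-negative")
    ratio = n_selected / n_total
    return StabilityResult(frequency=ratio, warning=ratio > 1.0)
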