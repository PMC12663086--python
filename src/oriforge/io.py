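"""File formats: FASTA sequences, the replicon manifest, truth tables.

The manifest is a tab-separated table with a header row::

    record_id  host_species  rep_ids  oriv_id  group_label

``rep_ids`` is a comma-separated list (empty for Rep-less replicons);
sequences live in companion FASTA files keyed by those ids.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import RepliconRecord, UNKNOWN


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=rid, description=(descriptions or {}).get(rid, ""))
        for rid, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_manifest(records: Iterable[RepliconRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\thost_species\trep_ids\toriv_id\tgroup_label\n")
        for rec in records:
            rep_ids = ",".join(
                f"{rec.record_id}_rep{k + 1}" for k in range(len(rec.rep_proteins))
            )
            fh.write(
                f"{rec.record_id}\t{rec.host_species}\t{rep_ids}\t"
                f"{rec.record_id}_oriv\t{rec.group_label or ''}\n"
            )


def write_corpus(records: Iterable[RepliconRecord], directory) -> None:
    """Manifest + oriV FASTA + Rep FASTA for a record collection."""
    records = list(records)
    os.makedirs(directory, exist_ok=True)
    write_manifest(records, os.path.join(directory, "manifest.tsv"))
    write_fasta(
        {f"{r.record_id}_oriv": r.oriv for r in records},
        os.path.join(directory, "oriv.fasta"),
    )
    reps = {
        f"{r.record_id}_rep{k + 1}": rep
        for r in records
        for k, rep in enumerate(r.rep_proteins)
    }
    write_fasta(reps, os.path.join(directory, "reps.fasta"))


def read_corpus(directory) -> list[RepliconRecord]:
    """Load records from a manifest + FASTA directory."""
    orivs = read_fasta(os.path.join(directory, "oriv.fasta"))
    reps_path = os.path.join(directory, "reps.fasta")
    reps = read_fasta(reps_path) if os.path.exists(reps_path) else {}
    records = []
    with open(os.path.join(directory, "manifest.tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["record_id", "host_species", "rep_ids", "oriv_id"]:
            raise ValueError("malformed manifest header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid, species, rep_ids, oriv_id = parts[:4]
            group = parts[4] if len(parts) > 4 and parts[4] else None
            rep_seqs = tuple(
                reps[r] for r in rep_ids.split(",") if r
            )
            records.append(
                RepliconRecord(
                    record_id=rid,
                    host_species=species or UNKNOWN,
                    rep_proteins=rep_seqs,
                    oriv=orivs[oriv_id].lower(),
                    group_label=group,
                )
            )
    return records


def write_truth(truth: dict[str, list[tuple[str, int, int]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\telement\tstart\tend\n")
        for rid in sorted(truth):
            for name, start, end in truth[rid]:
                fh.write(f"{rid}\t{name}\t{start}\t{end}\n")
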