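"""Replicon records, vocabulary construction and tokenization.

A replicon training unit couples a bacterial host species label, zero or
more replication-initiation (Rep) protein sequences, and the nucleotide
sequence of the origin of vegetative replication (oriV).  Rep proteins use
the 20 uppercase amino-acid letters; oriV uses lowercase ``acgt`` so the two
alphabets never collide and a flat token stream parses unambiguously.

Token layout of one replicon::

    <bos> SPECIES [rep1...] [<sep> rep2...] oriv... <eos>

``<sep>`` appears only *between* consecutive Rep proteins.  A record whose
host is unknown carries the ``<unk_species>`` token in the species slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "acgt"

#: Sentinel host label for records without a species annotation.
UNKNOWN = "UNKNOWN"

BOS = "<bos>"
EOS = "<eos>"
REP_SEP = "<sep>"
UNKNOWN_SPECIES = "<unk_species>"
PAD = "<pad>"

SPECIAL_TOKENS = (BOS, EOS, REP_SEP, UNKNOWN_SPECIES, PAD)

#: Default maximum encoded length (tokens), matching the model context.
DEFAULT_CONTEXT = 1500


class TokenClass(Enum):
    SPECIAL = "SPECIAL"
    SPECIES = "SPECIES"
    AMINO_ACID = "AMINO_ACID"
    NUCLEOTIDE = "NUCLEOTIDE"


class LayoutError(ValueError):
    """A token sequence violates the replicon layout grammar."""


def _check_alphabet(seq: str, alphabet: str, record_id: str, what: str) -> None:
    allowed = set(alphabet)
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {record_id!r}: invalid {what} character {ch!r} at offset {i}"
            )


@dataclass(frozen=True)
class RepliconRecord:
    """One replicon: host label, ordered Rep proteins, oriV sequence."""

    record_id: str
    host_species: str
    rep_proteins: tuple[str, ...]
    oriv: str
    group_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rep_proteins", tuple(self.rep_proteins))
        if not self.oriv:
            raise ValueError(f"record {self.record_id!r}: empty oriV")
        _check_alphabet(self.oriv, NUCLEOTIDES, self.record_id, "oriV")
        for rep in self.rep_proteins:
            if not rep:
                raise ValueError(f"record {self.record_id!r}: empty Rep protein")
            _check_alphabet(rep, AMINO_ACIDS, self.record_id, "Rep")


@dataclass(frozen=True)
class TokenSequence:
    """Encoded replicon: integer token ids in layout order."""

    ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(int(i) for i in self.ids))

    def __len__(self) -> int:
        return len(self.ids)


class Vocabulary:
    """Bijective token<->id map over special/species/amino-acid/nucleotide tokens.

    Id order is deterministic: the five special tokens first, then the
    corpus's distinct host labels sorted lexicographically, then the 20
    amino acids alphabetically, then nucleotides in ``a c g t`` order.
    """

    def __init__(self, species: Sequence[str]):
        species = sorted(set(species) - {UNKNOWN})
        for s in species:
            if len(s) == 1 and (s in AMINO_ACIDS or s in NUCLEOTIDES):
                raise ValueError(
                    f"species label {s!r} collides with a residue token"
                )
            if s in SPECIAL_TOKENS:
                raise ValueError(f"species label {s!r} collides with a special token")
        tokens: list[str] = list(SPECIAL_TOKENS)
        classes: list[TokenClass] = [TokenClass.SPECIAL] * len(SPECIAL_TOKENS)
        tokens += species
        classes += [TokenClass.SPECIES] * len(species)
        tokens += list(AMINO_ACIDS)
        classes += [TokenClass.AMINO_ACID] * len(AMINO_ACIDS)
        tokens += list(NUCLEOTIDES)
        classes += [TokenClass.NUCLEOTIDE] * len(NUCLEOTIDES)
        self.id_to_token: tuple[str, ...] = tuple(tokens)
        self.token_to_id: dict[str, int] = {t: i for i, t in enumerate(tokens)}
        self.class_of: dict[str, TokenClass] = dict(zip(tokens, classes))
        if len(self.token_to_id) != len(tokens):  # pragma: no cover
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id[token]

    def class_of_id(self, idx: int) -> TokenClass:
        return self.class_of[self.id_to_token[idx]]

    def ids_of_class(self, cls: TokenClass) -> tuple[int, ...]:
        return tuple(
            i for i, t in enumerate(self.id_to_token) if self.class_of[t] is cls
        )

    # -- special-token ids, used pervasively ------------------------------
    @property
    def bos(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos(self) -> int:
        return self.token_to_id[EOS]

    @property
    def sep(self) -> int:
        return self.token_to_id[REP_SEP]

    @property
    def unk_species(self) -> int:
        return self.token_to_id[UNKNOWN_SPECIES]

    @property
    def pad(self) -> int:
        return self.token_to_id[PAD]

    @property
    def nucleotide_ids(self) -> tuple[int, ...]:
        return self.ids_of_class(TokenClass.NUCLEOTIDE)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w") as fh:
            for tok in self.id_to_token:
                fh.write(tok + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        specials = tuple(tokens[: len(SPECIAL_TOKENS)])
        if specials != SPECIAL_TOKENS:
            raise ValueError(f"vocabulary file {path} has unexpected special tokens")
        n_tail = len(AMINO_ACIDS) + len(NUCLEOTIDES)
        species = tokens[len(SPECIAL_TOKENS) : len(tokens) - n_tail]
        vocab = cls(species)
        if tuple(tokens) != vocab.id_to_token:
            raise ValueError(f"vocabulary file {path} is not in canonical order")
        return vocab


def build_vocabulary(records: Iterable[RepliconRecord]) -> Vocabulary:
    """Construct the vocabulary for a corpus.

    Deterministic and order-independent: the id map depends only on the set
    of distinct host labels.  The UNKNOWN sentinel never becomes a species
    token; such records encode via ``<unk_species>``.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a vocabulary from an empty record list")
    return Vocabulary([r.host_species for r in records])


def encode_replicon(
    record: RepliconRecord,
    vocab: Vocabulary,
    context_len: int = DEFAULT_CONTEXT,
) -> TokenSequence:
    """Encode a record as ``<bos> species reps oriv <eos>``.

    Records longer than ``context_len`` are rejected (silent truncation
    would corrupt oriV boundaries).
    """
    ids = [vocab.bos]
    if record.host_species == UNKNOWN or record.host_species not in vocab.token_to_id:
        ids.append(vocab.unk_species)
    else:
        ids.append(vocab[record.host_species])
    for k, rep in enumerate(record.rep_proteins):
        if k > 0:
            ids.append(vocab.sep)
        ids.extend(vocab[aa] for aa in rep)
    ids.extend(vocab[nt] for nt in record.oriv)
    ids.append(vocab.eos)
    if len(ids) > context_len:
        raise ValueError(
            f"record {record.record_id!r} encodes to {len(ids)} tokens, "
            f"exceeding the context window of {context_len}"
        )
    return TokenSequence(tuple(ids))


def decode_tokens(
    tokens: TokenSequence | Sequence[int],
    vocab: Vocabulary,
    record_id: str = "decoded",
) -> RepliconRecord:
    """Inverse of :func:`encode_replicon` on its image.

    Raises :class:`LayoutError` with the offending position when the token
    stream violates the layout grammar.
    """
    ids = tuple(tokens.ids if isinstance(tokens, TokenSequence) else tokens)
    if not ids or ids[0] != vocab.bos:
        raise LayoutError("position 0: expected <bos>")
    if len(ids) < 2:
        raise LayoutError("position 1: expected a species token")
    cls1 = vocab.class_of_id(ids[1])
    if ids[1] == vocab.unk_species:
        species = UNKNOWN
    elif cls1 is TokenClass.SPECIES:
        species = vocab.id_to_token[ids[1]]
    else:
        raise LayoutError(f"position 1: expected a species token, got "
                          f"{vocab.id_to_token[ids[1]]!r}")
    reps: list[str] = []
    cur_rep: list[str] = []
    oriv: list[str] = []
    phase = "rep"  # rep -> oriv
    for pos in range(2, len(ids)):
        tok = vocab.id_to_token[ids[pos]]
        cls = vocab.class_of[tok]
        if tok == EOS:
            if pos != len(ids) - 1:
                raise LayoutError(f"position {pos}: <eos> before end of sequence")
            break
        if phase == "rep":
            if cls is TokenClass.AMINO_ACID:
                cur_rep.append(tok)
            elif tok == REP_SEP:
                if not cur_rep:
                    raise LayoutError(f"position {pos}: <sep> with no preceding Rep")
                reps.append("".join(cur_rep))
                cur_rep = []
            elif cls is TokenClass.NUCLEOTIDE:
                if reps and not cur_rep:
                    raise LayoutError(
                        f"position {pos}: <sep> not followed by a Rep protein"
                    )
                if cur_rep:
                    reps.append("".join(cur_rep))
                    cur_rep = []
                phase = "oriv"
                oriv.append(tok)
            else:
                raise LayoutError(f"position {pos}: unexpected token {tok!r}")
        else:
            if cls is TokenClass.NUCLEOTIDE:
                oriv.append(tok)
            else:
                raise LayoutError(
                    f"position {pos}: unexpected token {tok!r} inside oriV"
                )
    else:
        raise LayoutError(f"position {len(ids) - 1}: missing <eos>")
    if ids[-1] != vocab.eos:
        raise LayoutError(f"position {len(ids) - 1}: missing <eos>")
    if cur_rep:
        # amino acids with no oriV after them
        raise LayoutError(f"position {len(ids) - 1}: Rep tokens but no oriV")
    if not oriv:
        raise LayoutError(f"position {len(ids) - 1}: empty oriV")
    return RepliconRecord(
        record_id=record_id,
        host_species=species,
        rep_proteins=tuple(reps),
        oriv="".join(oriv),
    )
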