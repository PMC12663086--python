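"""Family-structured synthetic replicon corpora with planted, verifiable signal.

Real oriV corpora are families of related origins carrying functional
elements: tandemly repeated iterons, a DnaA box, and an AT-rich stretch.
The generator emulates exactly that structure at a scale a CPU-trainable
model can learn in minutes: each family has a template (default length 357,
the median oriV length in the training data) carrying

* one iteron unit (17-22 nt) repeated in 3-5 tandem copies,
* one DnaA-box-like 9-mer,
* one AT-rich block (target AT fraction 0.85 over 60 nt),

and every record derives from its family template by i.i.d. substitutions.
Species labels map deterministically to families, so host conditioning is
learnable.  Ground-truth element coordinates and sharp PWMs (0.9 consensus
probability) matching the planted elements are returned alongside, making
every downstream stage independently checkable.

No claim is made that these corpora match natural oriV base statistics;
they exist so the pipeline's signal-recovery behavior is testable without
external datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .generation import MotifPattern
from .insilico import PWM
from .records import RepliconRecord

_BASES = np.array(list("acgt"))

#: The twelve common E. coli type II restriction-site motifs used for
#: constraint-guided generation (IUPAC, each >= 3 nt, <= 5 degenerate
#: positions).
RESTRICTION_MOTIFS = (
    "GATC",
    "CCWGG",
    "GGTCTC",
    "GAAABCC",
    "GRGCYC",
    "CCGCGG",
    "CTGCAG",
    "CCNGG",
    "GGYRCC",
    "CRARCAG",
    "GAATTC",
    "CCTNAGG",
)


def make_motif_fixture() -> list[MotifPattern]:
    """The twelve-restriction-motif avoidance list as validated patterns."""
    return [MotifPattern(p) for p in RESTRICTION_MOTIFS]


def restriction_motif_fixture_path():
    """Path of the shipped plain-text motif list."""
    return resources.files("oriforge.data") / "restriction_motifs.txt"


@dataclass(frozen=True)
class SyntheticSpec:
    n_families: int = 5
    n_records_per_family: int = 50
    template_length: int = 357
    iteron_unit_range: tuple[int, int] = (17, 22)
    iteron_copy_range: tuple[int, int] = (3, 5)
    dnaa_length: int = 9
    at_block_length: int = 60
    at_fraction: float = 0.85
    mutation_rate: float = 0.02
    rep_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)  # 0/1/2 Reps
    rep_length_range: tuple[int, int] = (30, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation rate must be in [0, 0.2]")
        for name in ("n_families", "n_records_per_family", "template_length",
                     "dnaa_length", "at_block_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.rep_fractions) - 1.0) > 1e-9:
            raise ValueError("rep_fractions must sum to 1")


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its ground truth.

    ``truth`` maps record_id to planted-element intervals
    (element_name, start, end), 0-based half-open, valid for every record of
    a family because records differ from the template by substitutions only.
    """

    records: list[RepliconRecord]
    truth: dict[str, list[tuple[str, int, int]]]
    pwms: list[PWM]
    templates: dict[int, str]
    pwm_probs: dict[str, np.ndarray] = field(default_factory=dict)

    def family_of(self, record_id: str) -> int:
        return int(record_id.split("_")[0][1:])

    def species_of_family(self, family: int) -> str:
        return f"Species_{family:02d}"

    def pwms_of_family(self, family: int) -> list[PWM]:
        return [p for p in self.pwms if p.name.startswith(f"family{family}_")]


AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "acgt" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def make_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Build a seeded family-structured corpus with planted elements.

    Raises when the planted elements cannot fit the template length.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[RepliconRecord] = []
    truth: dict[str, list[tuple[str, int, int]]] = {}
    pwms: list[PWM] = []
    pwm_probs: dict[str, np.ndarray] = {}
    templates: dict[int, str] = {}
    for fam in range(spec.n_families):
        unit_len = int(rng.integers(spec.iteron_unit_range[0], spec.iteron_unit_range[1] + 1))
        n_copies = int(rng.integers(spec.iteron_copy_range[0], spec.iteron_copy_range[1] + 1))
        unit = _random_seq(rng, unit_len)
        dnaa = _random_seq(rng, spec.dnaa_length)
        at_block = "".join(
            ("at"[rng.integers(2)] if rng.random() < spec.at_fraction else "cg"[rng.integers(2)])
            for _ in range(spec.at_block_length)
        )
        elements = [
            ("iteron_array", unit * n_copies),
            ("dnaa", dnaa),
            ("at_block", at_block),
        ]
        order = rng.permutation(len(elements))
        elements = [elements[i] for i in order]
        total = sum(len(s) for _, s in elements)
        if total > spec.template_length:
            raise ValueError(
                f"family {fam}: planted elements span {total} nt, exceeding "
                f"the template length {spec.template_length}"
            )
        # distribute the slack over the gaps before/between/after elements
        slack = spec.template_length - total
        cuts = np.sort(rng.integers(0, slack + 1, size=len(elements)))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
        parts: list[str] = []
        coords: list[tuple[str, int, int]] = []
        pos = 0
        for (name, elem), gap in zip(elements, gaps[:-1]):
            filler = _random_seq(rng, int(gap))
            parts.append(filler)
            pos += len(filler)
            if name == "iteron_array":
                for c in range(n_copies):
                    coords.append(("iteron", pos + c * unit_len, pos + (c + 1) * unit_len))
            else:
                coords.append((name, pos, pos + len(elem)))
            parts.append(elem)
            pos += len(elem)
        parts.append(_random_seq(rng, int(gaps[-1])))
        template = "".join(parts)
        assert len(template) == spec.template_length
        templates[fam] = template

        for tag, consensus in (("iteron", unit), ("dnaa", dnaa)):
            name = f"family{fam}_{tag}"
            pwm = PWM.from_consensus(name, consensus, consensus_prob=0.9)
            pwms.append(pwm)
            idx = np.array([{"a": 0, "c": 1, "g": 2, "t": 3}[b] for b in consensus])
            p = np.full((len(idx), 4), 0.1 / 3)
            p[np.arange(len(idx)), idx] = 0.9
            pwm_probs[name] = p

        rep_templates = [
            "".join(AMINO[rng.integers(0, 20, size=rng.integers(*spec.rep_length_range))])
            for _ in range(2)
        ]
        species = f"Species_{fam:02d}"
        for i in range(spec.n_records_per_family):
            rid = f"f{fam}_r{i:03d}"
            oriv = _mutate(rng, template, spec.mutation_rate)
            n_reps = int(rng.choice(3, p=spec.rep_fractions))
            reps = tuple(rep_templates[:n_reps])
            records.append(
                RepliconRecord(
                    record_id=rid,
                    host_species=species,
                    rep_proteins=reps,
                    oriv=oriv,
                    group_label=f"family{fam}",
                )
            )
            truth[rid] = list(coords)
    return SyntheticCorpus(records, truth, pwms, templates, pwm_probs)
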