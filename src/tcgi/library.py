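"""In-silico design of the dual-guide tRNA-spaced library.

A library is the cross product of a small position-1 manifest (a few guides
against the anchor gene plus one non-targeting control) and a genome-scale
position-2 manifest (several guides per gene plus scrambled controls).  Each
member therefore measures either a double knockout, a single knockout with a
control partner, or pure background (control-control).
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .sequences import (
    OligoComponents,
    find_bsmbi_sites,
    revcomp,
    validate_dna,
)

#: Reserved target token marking a non-targeting (scrambled) guide.
CONTROL = "CONTROL"

#: Separator used to build construct ids from the two guide ids.
ID_SEP = "__"


class Category(str, enum.Enum):
    """What a dual construct knocks out."""

    DOUBLE_KO = "DOUBLE_KO"
    SINGLE_KO_POS1 = "SINGLE_KO_POS1"  # targeting guide in position 1, control in position 2
    SINGLE_KO_POS2 = "SINGLE_KO_POS2"  # control in position 1, targeting guide in position 2
    CTRL_CTRL = "CTRL_CTRL"


@dataclass(frozen=True)
class Guide:
    """One protospacer assigned to a cassette slot.

    ``target`` is a gene symbol or the reserved token :data:`CONTROL`.
    The protospacer is stored in the sense strand of the cassette.
    """

    id: str
    target: str
    protospacer: str
    slot: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("guide id is empty")
        if ID_SEP in self.id:
            raise ValueError(f"guide id {self.id!r} may not contain {ID_SEP!r}")
        if self.slot not in (1, 2):
            raise ValueError(f"guide {self.id}: slot must be 1 or 2, got {self.slot}")
        object.__setattr__(
            self, "protospacer", validate_dna(self.protospacer, name=f"guide {self.id} protospacer")
        )

    @property
    def is_control(self) -> bool:
        return self.target == CONTROL


@dataclass(frozen=True)
class DualConstruct:
    """One library member: a position-1 and a position-2 guide.

    ``cassette`` is filled in only when sequences are requested; the
    genome-scale cross product is usually handled id-only.
    """

    id: str
    guide1: Guide
    guide2: Guide
    category: Category
    cassette: str | None = None

    def with_cassette(self, components: OligoComponents) -> "DualConstruct":
        a, b = design_half_oligos(self.guide1, components), design_half_oligos(self.guide2, components)
        cassette = assemble_full_cassette(a[0], b[1], junction=components.junction)
        return replace(self, cassette=cassette)


def categorize(guide1: Guide, guide2: Guide) -> Category:
    if guide1.is_control and guide2.is_control:
        return Category.CTRL_CTRL
    if guide1.is_control:
        return Category.SINGLE_KO_POS2
    if guide2.is_control:
        return Category.SINGLE_KO_POS1
    return Category.DOUBLE_KO


def _check_manifest(guides: Sequence[Guide], slot: int) -> None:
    if not guides:
        raise ValueError(f"position-{slot} manifest is empty")
    seen: set[str] = set()
    for g in guides:
        if g.slot != slot:
            raise ValueError(f"guide {g.id} has slot {g.slot}, expected {slot}")
        if g.id in seen:
            raise ValueError(f"duplicate guide id in position-{slot} manifest: {g.id!r}")
        seen.add(g.id)


def build_cross_library(
    pos1: Sequence[Guide],
    pos2: Sequence[Guide],
    components: OligoComponents | None = None,
) -> list[DualConstruct]:
    """Cross every position-1 guide with every position-2 guide.

    Order is deterministic: position-1 major, manifest order within.  When
    ``components`` is given, full cassette sequences are assembled for every
    member (costly at genome scale; omit for id-level work).
    """
    _check_manifest(pos1, 1)
    _check_manifest(pos2, 2)
    out: list[DualConstruct] = []
    for g1 in pos1:
        for g2 in pos2:
            c = DualConstruct(
                id=f"{g1.id}{ID_SEP}{g2.id}",
                guide1=g1,
                guide2=g2,
                category=categorize(g1, g2),
            )
            if components is not None:
                c = c.with_cassette(components)
            out.append(c)
    return out


def design_half_oligos(guide: Guide, components: OligoComponents) -> tuple[str, str]:
    """Half-oligos for a guide: (slot-1 oligo A, slot-2 oligo B).

    Oligo A is ``adapter5-protospacer-trcRNA-tRNA5'`` and oligo B is
    ``trcRNA3'-tRNA-protospacer-adapter3``; for a 20-nt protospacer each is
    ``components.half_oligo_length`` (129 by default).
    """
    proto = validate_dna(guide.protospacer, name=f"guide {guide.id} protospacer")
    if len(proto) != 20:
        raise ValueError(
            f"guide {guide.id}: half-oligo design requires a 20-nt protospacer, got {len(proto)}"
        )
    k = components.trna_bases_on_oligo_a()
    m = components.trcrna_bases_on_oligo_b()
    if k <= 0 or m <= 0:
        achieved_a = len(components.bsmbi_adapter_5) + 20 + len(components.trcrna)
        achieved_b = len(components.bsmbi_adapter_3) + 20 + len(components.trna)
        raise ValueError(
            "component lengths cannot reach the target half-oligo length "
            f"{components.half_oligo_length} (fixed parts alone: slot1={achieved_a}, "
            f"slot2={achieved_b})"
        )
    oligo_a = components.bsmbi_adapter_5 + proto + components.trcrna + components.trna[:k]
    oligo_b = components.trcrna[-m:] + components.trna + proto + components.bsmbi_adapter_3
    return oligo_a, oligo_b


def assemble_full_cassette(
    oligo_a: str,
    oligo_b: str,
    junction: str | None = None,
    min_overlap: int = 15,
) -> str:
    """Merge two half-oligos across their shared trcRNA/tRNA junction.

    Models overlap PCR: the suffix of ``oligo_a`` must exactly equal the
    prefix of ``oligo_b`` over the junction.  When ``junction`` is given the
    overlap must be exactly that sequence; otherwise the longest exact
    suffix/prefix overlap of at least ``min_overlap`` bases is used.
    """
    oligo_a = validate_dna(oligo_a, name="oligo A")
    oligo_b = validate_dna(oligo_b, name="oligo B")
    if junction is not None:
        if not oligo_a.endswith(junction) or not oligo_b.startswith(junction):
            raise ValueError(
                "half-oligos do not share the expected junction "
                f"({len(junction)} nt): overlap PCR would fail"
            )
        overlap = len(junction)
    else:
        overlap = 0
        for n in range(min(len(oligo_a), len(oligo_b)), min_overlap - 1, -1):
            if oligo_a[-n:] == oligo_b[:n]:
                overlap = n
                break
        if overlap == 0:
            raise ValueError(
                f"no exact suffix/prefix overlap of >= {min_overlap} nt between half-oligos"
            )
    product = oligo_a + oligo_b[overlap:]
    if product.count(oligo_a[-overlap:]) != 1:
        raise ValueError("junction sequence is ambiguous in the assembled product")
    return product


def internal_bsmbi_positions(cassette: str, components: OligoComponents) -> list[int]:
    """BsmBI sites outside the two intended adapter sites.

    An internal recognition site would cut the cassette during Golden-Gate
    cloning, so designs carrying one should be flagged or excluded.
    """
    n5 = len(components.bsmbi_adapter_5)
    n3 = len(components.bsmbi_adapter_3)
    return [p for p in find_bsmbi_sites(cassette) if not (p < n5 or p >= len(cassette) - n3)]


class KmerIndex:
    """Exact k-mer index over both strands of a reference sequence set.

    Used to check that scrambled control guides are absent from the genome
    (forward or reverse complement).
    """

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._kmers: set[str] = set()

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], k: int) -> "KmerIndex":
        idx = cls(k)
        for seq in sequences:
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                idx._kmers.add(kmer)
                idx._kmers.add(revcomp(kmer))
        return idx

    @classmethod
    def from_fasta(cls, path, k: int) -> "KmerIndex":
        from Bio import SeqIO

        return cls.from_sequences((str(r.seq) for r in SeqIO.parse(str(path), "fasta")), k)

    def __contains__(self, seq: str) -> bool:
        return seq.upper() in self._kmers

    def __len__(self) -> int:
        return len(self._kmers)


def generate_scrambled_controls(
    n: int,
    length: int = 20,
    exclusion_index: KmerIndex | None = None,
    seed: int = 0,
    slot: int = 2,
    id_prefix: str = "CTRL",
    max_attempts_per_guide: int = 10_000,
) -> list[Guide]:
    """Draw ``n`` distinct random sequences absent from the exclusion index.

    Sequences are uniform over ACGT, rejected if present (either strand) in
    ``exclusion_index`` or already drawn; deterministic for a fixed seed.
    Without an index the guides are generated unchecked (desk-scale use).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    if exclusion_index is not None and exclusion_index.k != length:
        raise ValueError(
            f"exclusion index k ({exclusion_index.k}) must equal the guide length ({length})"
        )
    rng = random.Random(seed)
    out: list[Guide] = []
    seen: set[str] = set()
    attempts = 0
    budget = max(1, n) * max_attempts_per_guide
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not find {n} scrambled controls after {attempts} draws; "
                "exclusion index too dense for this length"
            )
        attempts += 1
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        if seq in seen:
            continue
        if exclusion_index is not None and seq in exclusion_index:
            continue
        seen.add(seq)
        out.append(
            Guide(
                id=f"{id_prefix}_{len(out) + 1:04d}",
                target=CONTROL,
                protospacer=seq,
                slot=slot,
            )
        )
    return out
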