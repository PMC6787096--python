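"""Cassette component sequences and small DNA utilities.

The dual-guide cassette has the architecture

    adapter5 - gRNA1 - trcRNA - tRNA - gRNA2 - adapter3

where ``trcRNA`` is the Cas9 single-guide scaffold and ``tRNA`` is the
spacer whose excision by endogenous RNase P/Z releases both guides from a
single Pol III transcript.  The cassette is synthesised as two overlapping
half-oligos (slot 1: adapter5-gRNA1-trcRNA-tRNA5'; slot 2:
trcRNA3'-tRNA-gRNA2-adapter3) that are fused by overlap PCR across the
trcRNA/tRNA junction.

Component sequences are configuration, not constants: they are read from a
FASTA file, with packaged defaults.  The packaged tRNA spacer is a synthetic
stand-in sized so that a 20-nt protospacer yields 129-nt half-oligos and a
227-nt assembled cassette, matching the published oligo arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: BsmBI recognition sequence and its reverse complement.
BSMBI_SITES = ("CGTCTC", "GAGACG")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, name: str = "sequence", allow_n: bool = False) -> str:
    """Uppercase and validate a DNA string, raising ``ValueError`` on junk."""
    s = seq.upper()
    alphabet = DNA_ALPHABET | {"N"} if allow_n else DNA_ALPHABET
    bad = set(s) - alphabet
    if not s:
        raise ValueError(f"{name} is empty")
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return s


def find_bsmbi_sites(seq: str) -> list[int]:
    """0-based start positions of BsmBI recognition sites on either strand."""
    hits: list[int] = []
    for site in BSMBI_SITES:
        start = 0
        while (pos := seq.find(site, start)) != -1:
            hits.append(pos)
            start = pos + 1
    return sorted(hits)


@dataclass(frozen=True)
class OligoComponents:
    """Fixed sequences shared by every library member.

    Parameters
    ----------
    bsmbi_adapter_5, bsmbi_adapter_3:
        Amplification adapters flanking the cassette; each carries the BsmBI
        site used for Golden-Gate cloning.
    trcrna:
        Guide scaffold placed downstream of gRNA1.
    trna:
        tRNA spacer between the scaffold and gRNA2.
    primers:
        The four pool-amplification primers, keyed ``bsmbi_f``,
        ``trc_trna_r``, ``trc_trna_f``, ``bsmbi_r``.
    half_oligo_length:
        Target synthesis length of each half-oligo for a 20-nt protospacer.
    """

    bsmbi_adapter_5: str
    bsmbi_adapter_3: str
    trcrna: str
    trna: str
    primers: dict[str, str] = field(default_factory=dict)
    half_oligo_length: int = 129

    def __post_init__(self) -> None:
        for attr in ("bsmbi_adapter_5", "bsmbi_adapter_3", "trcrna", "trna"):
            object.__setattr__(self, attr, validate_dna(getattr(self, attr), name=attr))

    # -- derived split points -------------------------------------------------
    @property
    def _fixed(self) -> int:
        # adapter + 20-nt protospacer on each half-oligo
        return 20

    def trna_bases_on_oligo_a(self) -> int:
        """Number of 5' tRNA bases carried by the slot-1 half-oligo."""
        k = (
            self.half_oligo_length
            - len(self.bsmbi_adapter_5)
            - self._fixed
            - len(self.trcrna)
        )
        return k

    def trcrna_bases_on_oligo_b(self) -> int:
        """Number of 3' trcRNA bases carried by the slot-2 half-oligo."""
        m = (
            self.half_oligo_length
            - len(self.bsmbi_adapter_3)
            - self._fixed
            - len(self.trna)
        )
        return m

    @property
    def junction(self) -> str:
        """The overlap shared by the two half-oligos (trcRNA 3' + tRNA 5')."""
        k = self.trna_bases_on_oligo_a()
        m = self.trcrna_bases_on_oligo_b()
        if k <= 0 or m <= 0:
            raise ValueError(
                "component lengths leave no overlap across the trcRNA/tRNA "
                f"junction (tRNA share {k}, trcRNA share {m})"
            )
        return self.trcrna[-m:] + self.trna[:k]

    def cassette_length(self, protospacer_length: int = 20) -> int:
        return (
            len(self.bsmbi_adapter_5)
            + len(self.bsmbi_adapter_3)
            + len(self.trcrna)
            + len(self.trna)
            + 2 * protospacer_length
        )


def load_components(path: str | Path | None = None, half_oligo_length: int = 129) -> OligoComponents:
    """Read an :class:`OligoComponents` set from FASTA (packaged defaults if ``path`` is None).

    Required record ids: ``bsmbi_adapter_5``, ``bsmbi_adapter_3``, ``trcRNA``,
    ``tRNA``; records prefixed ``primer_`` populate the primer table.
    """
    if path is None:
        ref = resources.files("tcgi.data") / "components.fasta"
        with resources.as_file(ref) as p:
            return load_components(p, half_oligo_length)
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    missing = {"bsmbi_adapter_5", "bsmbi_adapter_3", "trcRNA", "tRNA"} - set(records)
    if missing:
        raise ValueError(f"components FASTA {path} lacks records: {sorted(missing)}")
    primers = {
        key[len("primer_"):]: seq for key, seq in records.items() if key.startswith("primer_")
    }
    return OligoComponents(
        bsmbi_adapter_5=records["bsmbi_adapter_5"],
        bsmbi_adapter_3=records["bsmbi_adapter_3"],
        trcrna=records["trcRNA"],
        trna=records["tRNA"],
        primers=primers,
        half_oligo_length=half_oligo_length,
    )
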