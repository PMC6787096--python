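"""Amplicon editing quantification: align, classify, summarise cleavage.

Reads from a ~100-bp amplicon around a Cas9 target site are globally
aligned to the wild-type reference with affine gap penalties; each read is
classified as WT, DELETION, INSERTION or SUBSTITUTION according to the
events overlapping a window around the expected cut site (3 nt upstream of
the PAM); the cleavage rate is the edited fraction of aligned reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .sequences import validate_dna


@dataclass(frozen=True)
class AmpliconReference:
    """Wild-type amplicon window with the expected Cas9 cut position."""

    sequence: str
    cut_site: int
    window_halfwidth: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, name="reference"))
        if not 0 <= self.cut_site < len(self.sequence):
            raise ValueError("cut_site outside reference")


@dataclass(frozen=True)
class AlignScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class AmpliconAlignment:
    """A read-to-reference global alignment as gap-aware coordinate blocks."""

    read_id: str
    score: float
    identity: float
    ref_blocks: list[tuple[int, int]]
    read_blocks: list[tuple[int, int]]
    read_seq: str
    ref_seq: str


CLASSES = ("WT", "DELETION", "INSERTION", "SUBSTITUTION", "UNALIGNED")


@dataclass(frozen=True)
class EditCall:
    read_id: str
    klass: str  # one of CLASSES
    span: tuple[int, int] | None = None  # reference coordinates, 0-based half-open
    length: int = 0


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_to_amplicon(
    read: str,
    reference: str,
    scoring: AlignScoring = AlignScoring(),
    min_identity: float = 0.6,
    read_id: str = "read",
) -> AmpliconAlignment | None:
    """Global affine-gap alignment; ``None`` when identity is below the floor.

    Identity is matching columns over alignment columns (gap columns count
    against it).  Ties between co-optimal alignments are broken
    deterministically by taking the aligner's first reported alignment.
    """
    read = validate_dna(read, name="read", allow_n=True)
    reference = validate_dna(reference, name="reference")
    aligner = _make_aligner(scoring)
    aln = aligner.align(reference, read)[0]
    ref_blocks = [tuple(map(int, b)) for b in aln.aligned[0]]
    read_blocks = [tuple(map(int, b)) for b in aln.aligned[1]]
    matches = 0
    columns = 0
    # gap columns
    prev_r, prev_q = 0, 0
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        columns += (rs - prev_r) + (qs - prev_q)
        for i in range(re - rs):
            columns += 1
            if reference[rs + i] == read[qs + i]:
                matches += 1
        prev_r, prev_q = re, qe
    columns += (len(reference) - prev_r) + (len(read) - prev_q)
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    return AmpliconAlignment(
        read_id=read_id,
        score=float(aln.score),
        identity=identity,
        ref_blocks=ref_blocks,
        read_blocks=read_blocks,
        read_seq=read,
        ref_seq=reference,
    )


def classify_edits(alignment: AmpliconAlignment | None, reference: AmpliconReference) -> EditCall:
    """Classify one aligned read by the events in the cut-site window.

    The largest indel overlapping ``[cut - w, cut + w]`` wins (deletion on
    ties); a window substitution with no window indel gives SUBSTITUTION;
    otherwise WT.  Events outside the window are ignored.
    """
    if alignment is None:
        return EditCall(read_id="read", klass="UNALIGNED")
    lo = reference.cut_site - reference.window_halfwidth
    hi = reference.cut_site + reference.window_halfwidth  # inclusive

    best: tuple[int, int, tuple[int, int], str] | None = None  # (length, pref, span, klass)
    subs_in_window = False
    prev_r, prev_q = None, None
    for (rs, re), (qs, qe) in zip(alignment.ref_blocks, alignment.read_blocks):
        if prev_r is not None:
            dlen = rs - prev_r  # reference bases skipped -> deletion in the read
            ilen = qs - prev_q  # read bases inserted
            if dlen > 0 and prev_r <= hi and rs - 1 >= lo:
                cand = (dlen, 1, (prev_r, rs), "DELETION")
                if best is None or cand[:2] > best[:2]:
                    best = cand
            if ilen > 0 and lo <= prev_r <= hi:
                cand = (ilen, 0, (prev_r, prev_r), "INSERTION")
                if best is None or cand[:2] > best[:2]:
                    best = cand
        for i in range(re - rs):
            rpos = rs + i
            if lo <= rpos <= hi and alignment.ref_seq[rpos] != alignment.read_seq[qs + i]:
                subs_in_window = True
        prev_r, prev_q = re, qe
    if best is not None:
        length, _, span, klass = best
        return EditCall(read_id=alignment.read_id, klass=klass, span=span, length=length)
    if subs_in_window:
        return EditCall(read_id=alignment.read_id, klass="SUBSTITUTION")
    return EditCall(read_id=alignment.read_id, klass="WT")


def cleavage_rate(
    calls: Sequence[EditCall], include_substitutions: bool = True
) -> tuple[float, dict[str, int]]:
    """Edited fraction of aligned reads, plus per-class counts.

    Unaligned reads are excluded from the denominator and reported in the
    counts.  With ``include_substitutions=False`` only indels count as
    cleavage events.
    """
    counts = Counter(c.klass for c in calls)
    for k in CLASSES:
        counts.setdefault(k, 0)
    aligned = sum(counts[k] for k in ("WT", "DELETION", "INSERTION", "SUBSTITUTION"))
    if aligned == 0:
        raise ValueError("no aligned reads; cleavage rate undefined")
    edited = counts["DELETION"] + counts["INSERTION"]
    if include_substitutions:
        edited += counts["SUBSTITUTION"]
    return edited / aligned, dict(counts)


def quantify_amplicon(
    reads: Sequence[tuple[str, str]],
    reference: AmpliconReference,
    scoring: AlignScoring = AlignScoring(),
    min_identity: float = 0.6,
    include_substitutions: bool = True,
) -> tuple[float, dict[str, int], list[EditCall]]:
    """Align and classify every read; return (rate, class counts, calls)."""
    calls = []
    for rid, seq in reads:
        aln = align_to_amplicon(seq, reference.sequence, scoring, min_identity, read_id=rid)
        calls.append(classify_edits(aln, reference) if aln else EditCall(rid, "UNALIGNED"))
    rate, counts = cleavage_rate(calls, include_substitutions)
    return rate, counts, calls
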