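"""Paired-read deconvolution: from screen FASTQ to a construct count matrix.

Each mate carries one protospacer followed by fixed cassette sequence: the
forward mate reads gRNA1 then the trcRNA scaffold; the reverse mate reads
back from the scaffold downstream of gRNA2, so it starts with the reverse
complement of gRNA2 and runs into the reverse complement of the tRNA
spacer.  Reads are trimmed at the scaffold anchor, truncated to 19 usable
protospacer bases, reverse mates are flipped into cassette sense, and the
resulting key pair is looked up in the library (exact 19-mer hash match by
default, optional 1-mismatch expansion).

Key convention: a slot-1 guide is keyed by the first 19 bases of its
protospacer and a slot-2 guide by its last 19 bases — in both cases the 19
bases at the end where the read enters the protospacer, dropping the base
adjacent to the trimmed scaffold.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .library import DualConstruct, ID_SEP
from .sequences import OligoComponents, load_components, revcomp

KEY_LENGTH = 19

REJECT = None  # sentinel: read yields no usable key


def guide_key(protospacer: str, slot: int) -> str:
    """The 19-mer identifying a guide in its slot (cassette sense)."""
    if len(protospacer) < KEY_LENGTH:
        raise ValueError(f"protospacer shorter than {KEY_LENGTH} nt")
    return protospacer[:KEY_LENGTH] if slot == 1 else protospacer[-KEY_LENGTH:]


@dataclass(frozen=True)
class TrimConfig:
    """How to locate the protospacer within a read.

    ``anchor1``/``anchor2`` are the fixed sequences immediately following
    the protospacer in each mate's own orientation (defaults derived from
    the cassette components).  If an anchor is not found, ``on_missing``
    selects positional truncation (``"positional"``: take the window
    starting at ``offset``) or rejection (``"reject"``).
    """

    anchor1: str
    anchor2: str
    offset: int = 0
    on_missing: str = "reject"  # or "positional"
    anchor_length: int = 12

    @classmethod
    def from_components(cls, components: OligoComponents | None = None, **kw) -> "TrimConfig":
        comp = components or load_components()
        n = kw.pop("anchor_length", 12)
        return cls(
            anchor1=comp.trcrna[:n],
            anchor2=revcomp(comp.trna)[:n],
            anchor_length=n,
            **kw,
        )


def extract_guide_key(read: str, mate: int, trim: TrimConfig):
    """Trim the scaffold, truncate to 19 bases, orient into cassette sense.

    Returns the 19-mer key or :data:`REJECT` when fewer than 19 usable
    bases remain (or the anchor is absent under the "reject" policy).
    """
    if mate not in (1, 2):
        raise ValueError("mate must be 1 or 2")
    seq = read.upper()
    anchor = trim.anchor1 if mate == 1 else trim.anchor2
    pos = seq.find(anchor)
    if pos == -1:
        if trim.on_missing == "positional":
            region = seq[trim.offset : trim.offset + KEY_LENGTH + 1]
        else:
            return REJECT
    else:
        region = seq[:pos]
    if len(region) < KEY_LENGTH + 1:
        # fewer than 20 bases before the scaffold: fall back to the last 19
        if len(region) < KEY_LENGTH:
            return REJECT
        core = region[-KEY_LENGTH:]
        return core if mate == 1 else revcomp(core)
    core = region[-(KEY_LENGTH + 1):]  # 20 protospacer bases next to the junction
    if mate == 1:
        return core[:KEY_LENGTH]
    sense = revcomp(core)  # reverse mate: flip into cassette sense
    return sense[-KEY_LENGTH:]


def _fastq_reader(path: str | Path) -> Iterator[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield seq


def _mismatch_variants(key: str) -> Iterator[str]:
    for i, old in enumerate(key):
        for b in "ACGT":
            if b != old:
                yield key[:i] + b + key[i + 1:]


def build_key_tables(library: Sequence[DualConstruct]) -> tuple[dict[str, str], dict[str, str]]:
    """Map 19-mer keys to guide ids per slot; error on colliding keys."""
    tables: tuple[dict[str, str], dict[str, str]] = ({}, {})
    for slot, pick in ((1, lambda c: c.guide1), (2, lambda c: c.guide2)):
        table = tables[slot - 1]
        collisions: dict[str, set[str]] = {}
        for c in library:
            g = pick(c)
            key = guide_key(g.protospacer, slot)
            prev = table.get(key)
            if prev is not None and prev != g.id:
                collisions.setdefault(key, {prev}).add(g.id)
            table[key] = g.id
        if collisions:
            listing = "; ".join(f"{k}: {sorted(v)}" for k, v in sorted(collisions.items()))
            raise ValueError(f"duplicate {KEY_LENGTH}-mer keys in slot {slot}: {listing}")
    return tables


def _lookup(key: str | None, table: dict[str, str], tolerance: int) -> str | None:
    if key is None:
        return None
    hit = table.get(key)
    if hit is not None or tolerance == 0:
        return hit
    hits = {table[v] for v in _mismatch_variants(key) if v in table}
    if len(hits) == 1:
        return hits.pop()
    return None  # ambiguous or absent


def count_sample(
    fastq_1: str | Path,
    fastq_2: str | Path,
    library: Sequence[DualConstruct],
    trim: TrimConfig | None = None,
    tolerance: int = 0,
    g1_mate: int = 1,
    key_tables: tuple[dict[str, str], dict[str, str]] | None = None,
    construct_ids: set[str] | None = None,
) -> tuple[Counter, dict[str, int]]:
    """Count one sample's read pairs; returns (per-construct counts, totals).

    Totals satisfy ``mapped + unmapped + discordant == total_pairs``:
    a pair is *mapped* when both keys resolve and their construct exists in
    the library, *discordant* when both keys resolve to guides whose
    combination is not a library member, otherwise *unmapped*.
    """
    if trim is None:
        trim = TrimConfig.from_components()
    if key_tables is None:
        key_tables = build_key_tables(library)
    slot1, slot2 = key_tables
    if construct_ids is None:
        construct_ids = {c.id for c in library}
    counts: Counter = Counter()
    totals = {"total_pairs": 0, "mapped": 0, "unmapped": 0, "discordant": 0}
    it1, it2 = _fastq_reader(fastq_1), _fastq_reader(fastq_2)
    for r1 in it1:
        try:
            r2 = next(it2)
        except StopIteration:
            raise ValueError("mate files have unequal record counts") from None
        totals["total_pairs"] += 1
        if g1_mate == 2:
            r1, r2 = r2, r1
        id1 = _lookup(extract_guide_key(r1, 1, trim), slot1, tolerance)
        id2 = _lookup(extract_guide_key(r2, 2, trim), slot2, tolerance)
        if id1 is None or id2 is None:
            totals["unmapped"] += 1
            continue
        cid = f"{id1}{ID_SEP}{id2}"
        if cid in construct_ids:
            counts[cid] += 1
            totals["mapped"] += 1
        else:
            totals["discordant"] += 1
    if next(it2, None) is not None:
        raise ValueError("mate files have unequal record counts")
    return counts, totals


def count_constructs(
    sample_sheet: pd.DataFrame,
    library: Sequence[DualConstruct],
    trim: TrimConfig | None = None,
    tolerance: int = 0,
    g1_mate: int = 1,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Count all samples in a sample sheet into a construct x sample matrix."""
    if trim is None:
        trim = TrimConfig.from_components()
    key_tables = build_key_tables(library)
    ids = [c.id for c in library]
    id_set = set(ids)
    data = {}
    stats: dict[str, dict[str, int]] = {}
    for row in sample_sheet.to_dict("records"):
        counter, totals = count_sample(
            row["fastq_1"],
            row["fastq_2"],
            library,
            trim=trim,
            tolerance=tolerance,
            g1_mate=g1_mate,
            key_tables=key_tables,
            construct_ids=id_set,
        )
        data[row["sample_id"]] = [counter.get(cid, 0) for cid in ids]
        stats[row["sample_id"]] = totals
    counts = pd.DataFrame(data, index=pd.Index(ids, name="construct_id"), dtype=int)
    return counts, stats


def replicate_correlation(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "pearson-log10",
    pseudocount: float = 1.0,
) -> float:
    """Between-replicate agreement on counts.

    ``pearson-log10`` correlates log10(x + pseudocount); ``spearman`` is
    rank-based on the raw values.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson-log10":
        return float(sps.pearsonr(np.log10(x + pseudocount), np.log10(y + pseudocount)).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
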