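"""Readers and writers for the tab-separated manifests used across the pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .library import CONTROL, Category, DualConstruct, Guide

GUIDE_COLUMNS = ["id", "target", "protospacer", "slot"]
LIBRARY_COLUMNS = [
    "construct_id",
    "guide1_id",
    "guide2_id",
    "target1",
    "target2",
    "category",
    "cassette",
]


def read_guide_manifest(path: str | Path, slot: int | None = None) -> list[Guide]:
    """Read guides from TSV (columns id, target, protospacer, slot) or FASTA.

    FASTA headers are parsed as ``id [target]``; a missing target means a
    non-targeting control.  ``slot`` overrides/supplies the slot column.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        guides = []
        for rec in SeqIO.parse(str(path), "fasta"):
            target = rec.description.split()[1] if len(rec.description.split()) > 1 else CONTROL
            guides.append(
                Guide(id=rec.id, target=target, protospacer=str(rec.seq), slot=slot or 2)
            )
        return guides
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GUIDE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"guide manifest {path} lacks columns: {sorted(missing)}")
    return [
        Guide(
            id=row["id"],
            target=row["target"],
            protospacer=row["protospacer"],
            slot=slot if slot is not None else int(row["slot"]),
        )
        for row in df.to_dict("records")
    ]


def write_guide_manifest(guides: Sequence[Guide], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": g.id, "target": g.target, "protospacer": g.protospacer, "slot": g.slot} for g in guides]
    ).to_csv(path, sep="\t", index=False)


def write_library_manifest(library: Sequence[DualConstruct], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "construct_id": c.id,
                "guide1_id": c.guide1.id,
                "guide2_id": c.guide2.id,
                "target1": c.guide1.target,
                "target2": c.guide2.target,
                "protospacer1": c.guide1.protospacer,
                "protospacer2": c.guide2.protospacer,
                "category": c.category.value,
                "cassette": c.cassette or "",
            }
            for c in library
        ]
    ).to_csv(path, sep="\t", index=False)


def read_library_manifest(path: str | Path) -> list[DualConstruct]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.to_dict("records"):
        g1 = Guide(row["guide1_id"], row["target1"], row["protospacer1"], 1)
        g2 = Guide(row["guide2_id"], row["target2"], row["protospacer2"], 2)
        out.append(
            DualConstruct(
                id=row["construct_id"],
                guide1=g1,
                guide2=g2,
                category=Category(row["category"]),
                cassette=row.get("cassette") or None,
            )
        )
    return out


def write_half_oligo_pools(
    library_guides: Sequence[Guide], components, pool1_path: str | Path, pool2_path: str | Path
) -> None:
    """Emit the two synthesis pools (slot-1 / slot-2 half-oligos) as FASTA."""
    from .library import design_half_oligos

    with open(pool1_path, "w") as f1, open(pool2_path, "w") as f2:
        for g in library_guides:
            a, b = design_half_oligos(g, components)
            if g.slot == 1:
                f1.write(f">{g.id}\n{a}\n")
            else:
                f2.write(f">{g.id}\n{b}\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Construct x sample count matrix; first column holds construct ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="construct_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: sample_id, fastq_1, fastq_2, replicate, timepoint."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fastq_1", "fastq_2", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    return df
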