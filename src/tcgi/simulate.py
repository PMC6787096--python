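"""Synthetic pooled dual-guide screens with a known truth table.

The generator emulates a differential-growth screen: a plasmid pool with
log-normal abundance spread is "transduced", sampled at T0, grown for a
configurable number of population doublings and sampled again at T14, in
two biological replicates.  Each construct's per-doubling log2 growth
deficit is additive in the single-gene effects of its two targets (scaled
by per-guide efficiency) plus a pairwise interaction term for anchor-gene
pairs.  Sequencing is modelled as multinomial sampling at a configured
depth, optionally with negative-binomial overdispersion.

Everything downstream (deconvolution, normalization, differential
abundance, interaction calling) can therefore be tested against planted
truth without any external data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import CONTROL, Category, DualConstruct, Guide, build_cross_library
from .sequences import OligoComponents, load_components, revcomp


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic screen.

    Defaults mirror the screen layout this package models: 3 anchor guides
    plus 1 scrambled control in position 1, 3 guides per gene plus scrambled
    controls in position 2, two biological replicates sampled at T0 and T14.
    Growth and noise parameters are the package's own choices (see the
    methods note): 10 population doublings over the 14-day window, mean
    sequencing depth of 500 read pairs per construct, and a count
    overdispersion of 0.02 (biological-replicate scale).
    """

    n_genes: int = 50
    guides_per_gene: int = 3
    n_controls_pos2: int = 30
    anchor_guides: int = 3
    anchor_gene: str = "TAZ"
    doublings: float = 10.0
    depth: int | None = None  # reads per sample; None -> depth_per_construct * |library|
    depth_per_construct: int = 500
    replicates: int = 2
    dispersion: float = 0.02
    plasmid_sigma: float = 1.0
    essential_fraction: float = 0.05
    essential_mean: float = -0.15
    effect_sd: float = 0.05
    anchor_fitness: float = -0.005
    interaction_set: list[tuple[str, float]] = field(default_factory=list)
    single_effect_set: list[tuple[str, float]] = field(default_factory=list)
    guide_efficiency_range: tuple[float, float] = (0.7, 1.0)
    multinomial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.guides_per_gene, self.anchor_guides) < 0:
            raise ValueError("counts must be >= 0")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.depth is None and self.depth_per_construct <= 0:
            raise ValueError("depth_per_construct must be > 0")
        lo, hi = self.guide_efficiency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("guide_efficiency_range must be within [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene fitness, anchor interactions, guide efficiency."""

    single_effects: dict[str, float]
    interactions: dict[str, float]
    guide_efficiency: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.single_effects) | set(self.interactions))
        return pd.DataFrame(
            {
                "gene": genes,
                "single_effect": [self.single_effects.get(g, 0.0) for g in genes],
                "interaction": [self.interactions.get(g, 0.0) for g in genes],
            }
        ).set_index("gene")


def build_screen_library(config: SimulationConfig) -> tuple[list[Guide], list[Guide], list[DualConstruct]]:
    """Deterministic guide manifests and cross-product library for a config."""
    rng = np.random.default_rng(config.seed)

    def random_proto() -> str:
        return "".join(rng.choice(list("ACGT"), size=20))

    pos1 = [
        Guide(f"g{config.anchor_gene}_{i + 1}", config.anchor_gene, random_proto(), 1)
        for i in range(config.anchor_guides)
    ]
    pos1.append(Guide("gCtrl_1", CONTROL, random_proto(), 1))
    pos2: list[Guide] = []
    for gi in range(config.n_genes):
        gene = f"GENE{gi + 1:04d}"
        for j in range(config.guides_per_gene):
            pos2.append(Guide(f"{gene}_g{j + 1}", gene, random_proto(), 2))
    for c in range(config.n_controls_pos2):
        pos2.append(Guide(f"Ctrl2_{c + 1:04d}", CONTROL, random_proto(), 2))
    # protospacer collisions would break deconvolution keys; regenerate clashes
    seen: dict[str, int] = {}
    all_guides = pos1 + pos2
    for idx, g in enumerate(all_guides):
        while g.protospacer in seen:
            g = Guide(g.id, g.target, random_proto(), g.slot)
            all_guides[idx] = g
        seen[g.protospacer] = idx
    pos1 = all_guides[: len(pos1)]
    pos2 = all_guides[len(pos1):]
    return pos1, pos2, build_cross_library(pos1, pos2)


def _sample_counts(
    rng: np.random.Generator, proportions: np.ndarray, depth: int, dispersion: float, multinomial: bool
) -> np.ndarray:
    if multinomial or dispersion == 0:
        return rng.multinomial(depth, proportions)
    mean = depth * proportions
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(n, p)
    out[mean == 0] = 0
    return out


def simulate_screen(
    config: SimulationConfig, library: Sequence[DualConstruct] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate counts for samples {plasmid, T0 x reps, T14 x reps}.

    Returns ``(counts, sample_sheet, truth)``; ``counts`` is a construct x
    sample integer DataFrame, ``sample_sheet`` records replicate and
    timepoint per sample.  Identical config (and library) -> identical
    output.
    """
    if library is None:
        _, _, library = build_screen_library(config)
    if not library:
        raise ValueError("library is empty")
    rng = np.random.default_rng(config.seed + 1)

    genes = sorted({g.target for c in library for g in (c.guide1, c.guide2)} - {CONTROL})
    # sparse fitness landscape: a neutral majority plus an "essential" tail
    # of genes whose loss costs growth, the bimodal shape of genome-wide data
    single = {g: 0.0 for g in genes}
    for g in genes:
        if g == config.anchor_gene:
            single[g] = config.anchor_fitness
        elif rng.random() < config.essential_fraction:
            single[g] = float(rng.normal(config.essential_mean, config.effect_sd))
    overrides = dict(config.single_effect_set)
    unknown_s = set(overrides) - set(genes)
    if unknown_s:
        raise ValueError(f"single-effect genes absent from library: {sorted(unknown_s)}")
    single.update(overrides)
    interactions = dict(config.interaction_set)
    unknown = set(interactions) - set(genes)
    if unknown:
        raise ValueError(f"interaction genes absent from library: {sorted(unknown)}")

    guide_ids = sorted({g.id for c in library for g in (c.guide1, c.guide2)})
    lo, hi = config.guide_efficiency_range
    efficiency = {gid: float(rng.uniform(lo, hi)) for gid in guide_ids}
    truth = TruthTable(single, interactions, efficiency)

    n = len(library)
    fitness = np.zeros(n)
    for i, c in enumerate(library):
        f = 0.0
        if not c.guide1.is_control:
            f += efficiency[c.guide1.id] * single[c.guide1.target]
        if not c.guide2.is_control:
            f += efficiency[c.guide2.id] * single[c.guide2.target]
        if c.guide1.target == config.anchor_gene and c.guide2.target in interactions:
            f += interactions[c.guide2.target]
        fitness[i] = f

    abundance = rng.lognormal(mean=0.0, sigma=config.plasmid_sigma, size=n)
    p0 = abundance / abundance.sum()
    growth = np.power(2.0, fitness * config.doublings)
    p14 = p0 * growth
    p14 = p14 / p14.sum()

    depth = config.depth if config.depth is not None else config.depth_per_construct * n
    if depth <= 0:
        raise ValueError("sequencing depth must be > 0")

    columns: dict[str, np.ndarray] = {}
    meta = []
    columns["plasmid"] = _sample_counts(rng, p0, depth, config.dispersion, config.multinomial)
    meta.append({"sample_id": "plasmid", "replicate": 0, "timepoint": "plasmid"})
    for t, props in (("T0", p0), ("T14", p14)):
        for r in range(1, config.replicates + 1):
            name = f"{t}_rep{r}"
            columns[name] = _sample_counts(rng, props, depth, config.dispersion, config.multinomial)
            meta.append({"sample_id": name, "replicate": r, "timepoint": t})

    counts = pd.DataFrame(columns, index=pd.Index([c.id for c in library], name="construct_id"))
    sample_sheet = pd.DataFrame(meta)
    return counts, sample_sheet, truth


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

_QUAL = "I"


def _inject_errors(reads: list[str], rng: np.random.Generator, error_rate: float) -> list[str]:
    if error_rate == 0 or not reads:
        return reads
    read_len = len(reads[0])
    total = len(reads) * read_len
    n_err = rng.binomial(total, error_rate)
    if n_err == 0:
        return reads
    positions = rng.choice(total, size=n_err, replace=False)
    bases = "ACGT"
    for pos in sorted(positions.tolist()):
        ri, bi = divmod(pos, read_len)
        old = reads[ri][bi]
        new = bases[(bases.index(old) + rng.integers(1, 4)) % 4] if old in bases else "A"
        reads[ri] = reads[ri][:bi] + new + reads[ri][bi + 1:]
    return reads


def emit_fastq(
    counts: pd.DataFrame,
    library: Sequence[DualConstruct],
    out_dir: str | Path,
    read_len: int = 40,
    error_rate: float = 0.0,
    seed: int = 0,
    components: OligoComponents | None = None,
) -> dict[str, tuple[Path, Path]]:
    """Write paired gzip FASTQ per sample, one read pair per counted read.

    The forward mate covers gRNA1 in cassette sense followed by the trcRNA
    scaffold; the reverse mate reads back from the scaffold downstream of
    gRNA2, i.e. it begins with the reverse complement of gRNA2 followed by
    the reverse complement of the tRNA spacer.
    """
    if components is None:
        components = load_components()
    if read_len < 20:
        raise ValueError(f"read_len {read_len} too short to cover a 20-nt guide")
    lib_by_id = {c.id: c for c in library}
    missing = set(counts.index) - set(lib_by_id)
    if missing:
        raise ValueError(f"constructs in counts absent from library: {sorted(missing)[:5]} ...")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ctx1 = components.trcrna + components.trna
    ctx2 = revcomp(components.trna)
    templates: dict[str, tuple[str, str]] = {}
    for cid in counts.index:
        c = lib_by_id[cid]
        r1 = (c.guide1.protospacer + ctx1)[:read_len]
        r2 = (revcomp(c.guide2.protospacer) + ctx2)[:read_len]
        if len(r1) < read_len or len(r2) < read_len:
            raise ValueError("scaffold context shorter than read length")
        templates[cid] = (r1, r2)

    paths: dict[str, tuple[Path, Path]] = {}
    for sample in counts.columns:
        col = counts[sample]
        r1_reads: list[str] = []
        r2_reads: list[str] = []
        ids: list[str] = []
        for cid, n in col.items():
            n = int(n)
            if n <= 0:
                continue
            t1, t2 = templates[cid]
            r1_reads.extend([t1] * n)
            r2_reads.extend([t2] * n)
            ids.extend(f"{sample}:{cid}:{i}" for i in range(n))
        r1_reads = _inject_errors(r1_reads, rng, error_rate)
        r2_reads = _inject_errors(r2_reads, rng, error_rate)
        p1 = out_dir / f"{sample}_R1.fastq.gz"
        p2 = out_dir / f"{sample}_R2.fastq.gz"
        qual = _QUAL * read_len
        for path, reads in ((p1, r1_reads), (p2, r2_reads)):
            with gzip.open(path, "wt") as fh:
                fh.write(
                    "".join(
                        f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq in zip(ids, reads)
                    )
                )
        paths[sample] = (p1, p2)
    return paths


# ---------------------------------------------------------------------------
# Amplicon editing simulation
# ---------------------------------------------------------------------------

DEFAULT_EDIT_SPECTRUM = {
    "deletion": (0.55, list(range(1, 11))),
    "insertion": (0.30, list(range(1, 6))),
    "substitution": (0.15, [1]),
}


def simulate_amplicon_reads(
    reference: str,
    cut_site: int,
    edit_fraction: float,
    n_reads: int,
    seed: int = 0,
    edit_spectrum: dict | None = None,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], dict]:
    """Reads from an edited amplicon population.

    Each read is the full reference or carries a single edit centred at the
    cut site, drawn from ``edit_spectrum`` (class probabilities and length
    menus).  Returns ``(reads, truth)`` where reads are ``(id, sequence)``
    pairs and truth records the realized per-class counts.
    """
    if not 0.0 <= edit_fraction <= 1.0:
        raise ValueError("edit_fraction must be in [0, 1]")
    if not 0 <= cut_site < len(reference):
        raise ValueError("cut_site outside reference")
    spectrum = edit_spectrum or DEFAULT_EDIT_SPECTRUM
    classes = list(spectrum)
    probs = np.array([spectrum[c][0] for c in classes], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth = {"wt": 0, "deletion": 0, "insertion": 0, "substitution": 0}
    bases = "ACGT"
    for i in range(n_reads):
        if rng.random() >= edit_fraction:
            seq = reference
            truth["wt"] += 1
        else:
            klass = classes[rng.choice(len(classes), p=probs)]
            length = int(rng.choice(spectrum[klass][1]))
            if klass == "deletion":
                start = max(0, cut_site - length // 2)
                if start + length > len(reference):
                    raise ValueError("deletion length exceeds reference span")
                seq = reference[:start] + reference[start + length:]
            elif klass == "insertion":
                ins = "".join(rng.choice(list(bases), size=length))
                seq = reference[:cut_site] + ins + reference[cut_site:]
            else:
                pos = cut_site
                old = reference[pos]
                new = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
                seq = reference[:pos] + new + reference[pos + 1:]
            truth[klass] += 1
        if error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < error_rate:
                    chars[j] = bases[(bases.index(chars[j]) + int(rng.integers(1, 4))) % 4]
            seq = "".join(chars)
        reads.append((f"read_{i}", seq))
    truth["edited_fraction"] = (
        (n_reads - truth["wt"]) / n_reads if n_reads else 0.0
    )
    return reads, truth


def write_fasta(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Drug-combination viability simulation
# ---------------------------------------------------------------------------


def hill_inhibition(dose: np.ndarray, ec50: float, slope: float, emax: float = 1.0) -> np.ndarray:
    """Fractional inhibition of a single agent at the given doses."""
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    nz = dose > 0
    out[nz] = emax * dose[nz] ** slope / (ec50 ** slope + dose[nz] ** slope)
    return out


def simulate_viability_matrix(
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    hill_a: tuple[float, float],
    hill_b: tuple[float, float],
    excess: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Inhibition matrix under Bliss independence plus a planted excess.

    Rows are doses of drug A, columns doses of drug B; the zero-dose row and
    column carry the single-agent Hill curves.  ``excess`` is added to every
    interior (both-drug) cell before clipping to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if (doses_a < 0).any() or (doses_b < 0).any():
        raise ValueError("doses must be non-negative")
    ia = hill_inhibition(doses_a, *hill_a)
    ib = hill_inhibition(doses_b, *hill_b)
    expected = ia[:, None] + ib[None, :] - ia[:, None] * ib[None, :]
    interior = (doses_a[:, None] > 0) & (doses_b[None, :] > 0)
    obs = expected + np.where(interior, excess, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=obs.shape)
        noise[0, 0] = 0.0
        obs = obs + noise
    obs[0, 0] = 0.0
    obs = np.clip(obs, 0.0, 1.0)
    return pd.DataFrame(obs, index=pd.Index(doses_a, name="dose_a"), columns=pd.Index(doses_b, name="dose_b"))
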