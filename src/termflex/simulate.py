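"""Seeded simulation of toy genomes and small-RNA-seq libraries.

The generator emulates the data every other module consumes: short
(16-50 nt) fragments cleaved from defined genomic loci on both strands,
optionally carrying

- templated continuations (longer, still perfectly genomic reads),
- homopolymeric (A-rich) tails,
- random N-mer 3' extensions of configurable length,
- a chimeric attachment of a fixed nanomere (GCCAAGGCG by default),
- internal substitution/indel noise, and
- 3'-adapter remnants beginning with ATCACCGACTGCCCA.

Per-condition abundance factors plant differential secretion between
two strains (wild-type / mutant) and two fractions (cell / secretome).
Every emitted read has exactly one ground-truth row. A single
pseudo-random stream per run makes output byte-identical for a fixed
seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from termflex.io import Genome, Read
from termflex.mapper import revcomp
from termflex.preprocess import DEFAULT_ADAPTER_PREFIX
from termflex.classify import CORRECT, classify_extension
from termflex.randext import flank_diverges

#: The chimeric nanomere observed attaching to processed RNA fragments.
DEFAULT_NANOMERE = "GCCAAGGCG"

#: The shared 5'-terminal 19-mer of the four identical leucine tRNAs
#: (written here in the DNA alphabet).
LEU_19MER = "GCGAAGGTGGCGGAATTGG"

BASES = np.array(list("ACGT"))

EXTENSION_MODELS = ("none", "templated", "homopolymer", "random", "chimera")


@dataclass
class PlantedLocus:
    """One fragment source with a known extension behaviour.

    ``position`` is the 1-based 5'-end of the fragment (biological 5'
    terminus on either strand). ``condition_factors`` scales ``depth``
    per library condition (e.g. {"wt_exo": 3.0, "mut_exo": 1.0} plants
    a 3-fold secretion difference); unlisted conditions default to 1.
    """

    position: int
    strand: str = "+"
    fragment_length: int = 19
    depth: int = 100
    extension_model: str = "none"
    ext_len: int = 4
    guarantee_divergent: bool = False
    condition_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.extension_model not in EXTENSION_MODELS:
            raise ValueError(f"unknown extension model {self.extension_model!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class SimConfig:
    """Everything a simulation run needs; fully determined by ``seed``."""

    seed: int
    genome_length: int = 10_000
    loci: list[PlantedLocus] = field(default_factory=list)
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    adapter_fraction: float = 0.0
    adapter_prefix: str = DEFAULT_ADAPTER_PREFIX
    nanomere: str = DEFAULT_NANOMERE
    homopolymer_a_fraction: float = 0.8
    embed: dict[int, str] = field(default_factory=dict)  # 1-based pos -> motif

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.indel_rate, self.adapter_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for locus in self.loci:
            if not 1 <= locus.position <= self.genome_length:
                raise ValueError(f"locus position {locus.position} outside genome")


def make_genome(cfg: SimConfig, genome_id: str = "sim_genome") -> Genome:
    """Uniform-random genome with optional embedded literal motifs."""
    rng = np.random.default_rng(cfg.seed)
    seq = rng.choice(BASES, size=cfg.genome_length)
    occupied: list[tuple[int, int]] = []
    for pos, motif in sorted(cfg.embed.items()):
        end = pos + len(motif) - 1
        if pos < 1 or end > cfg.genome_length:
            raise ValueError(f"embedded motif at {pos} extends past the genome")
        for a, b in occupied:
            if pos <= b and end >= a:
                raise ValueError(f"embedded motifs at {a} and {pos} overlap")
        occupied.append((pos, end))
        seq[pos - 1:end] = list(motif)
    return Genome(id=genome_id, seq="".join(seq))


def _fragment(genome: Genome, locus: PlantedLocus) -> str:
    p, n = locus.position, locus.fragment_length
    if locus.strand == "+":
        frag = genome.fetch(p, p + n - 1)
    else:
        frag = revcomp(genome.fetch(p - n + 1, p))
    if len(frag) != n:
        raise ValueError(f"fragment at {p}{locus.strand} extends past the genome")
    return frag


def _continuation(genome: Genome, locus: PlantedLocus, length: int) -> str:
    """Templated sequence 3'-ward of the fragment (may be truncated)."""
    p, n = locus.position, locus.fragment_length
    if locus.strand == "+":
        start = p + n
        return genome.fetch(start, start + length - 1)
    end = p - n
    return revcomp(genome.fetch(end - length + 1, end))


def _draw_extension(rng, genome: Genome, locus: PlantedLocus,
                    cfg: SimConfig) -> str:
    model = locus.extension_model
    if model == "none":
        return ""
    if model == "templated":
        return _continuation(genome, locus, locus.ext_len)
    if model == "chimera":
        return cfg.nanomere
    if model == "homopolymer":
        length = min(int(rng.geometric(0.5)), 10)
        probs = [cfg.homopolymer_a_fraction, 1 - cfg.homopolymer_a_fraction]
        return "".join(rng.choice(["A", "C"], size=length, p=probs))
    # random N-mer, optionally guaranteed to pass the divergence rule
    cont = _continuation(genome, locus, locus.ext_len)
    while True:
        ext = "".join(rng.choice(BASES, size=locus.ext_len))
        if not locus.guarantee_divergent or flank_diverges(ext, cont):
            return ext


def _apply_noise(rng, seq: str, cfg: SimConfig) -> str:
    if cfg.sub_rate == 0 and cfg.indel_rate == 0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r < cfg.sub_rate:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
        elif r < cfg.sub_rate + cfg.indel_rate:
            if rng.random() < 0.5:
                out.append(base)
                out.append(rng.choice(BASES))  # insertion after this base
            # else deletion: emit nothing
        else:
            out.append(base)
    return "".join(out)


def simulate_library(cfg: SimConfig, genome: Genome,
                     condition: str = "wt_in", replicate: int = 0,
                     default_qual: int = 30) -> tuple[list[Read], pd.DataFrame]:
    """Emit one library for one condition, with its ground-truth table.

    Each planted locus contributes ``round(depth * factor)`` reads,
    where ``factor`` is its condition factor for ``condition``. The
    truth table holds one row per read: origin, strand, the planted
    extension and its category, condition, and fraction (cell or
    secretome, parsed from the condition name suffix). The random
    stream is derived from (seed, condition, replicate) with a stable
    checksum, so libraries are reproducible across processes.
    """
    stream = zlib.crc32(condition.encode()) % (2**31)
    rng = np.random.default_rng((cfg.seed, stream, replicate))
    reads: list[Read] = []
    truth_rows = []
    fraction = "secretome" if condition.endswith("exo") else "cell"
    for li, locus in enumerate(cfg.loci):
        factor = locus.condition_factors.get(condition, 1.0)
        n_reads = int(round(locus.depth * factor))
        frag = _fragment(genome, locus)
        for i in range(n_reads):
            ext = _draw_extension(rng, genome, locus, cfg)
            seq = _apply_noise(rng, frag + ext, cfg)
            if cfg.adapter_fraction and rng.random() < cfg.adapter_fraction:
                tail_len = int(rng.integers(0, 6))
                seq = seq + cfg.adapter_prefix + "".join(
                    rng.choice(BASES, size=tail_len))
            read_id = f"{condition}_r{replicate}_L{li}_{i}"
            reads.append(Read(id=read_id, seq=seq,
                              quals=[default_qual] * len(seq)))
            category = CORRECT if not ext or locus.extension_model == "templated" \
                else classify_extension(ext)
            truth_rows.append({
                "read_id": read_id, "locus": li,
                "position": locus.position, "strand": locus.strand,
                "extension": ext, "category": category,
                "condition": condition, "fraction": fraction,
            })
    truth = pd.DataFrame(truth_rows, columns=["read_id", "locus", "position",
                                              "strand", "extension", "category",
                                              "condition", "fraction"])
    return reads, truth


def simulate_conditions(cfg: SimConfig, genome: Genome,
                        conditions: Sequence[str] = ("wt_in", "mut_in",
                                                     "wt_exo", "mut_exo"),
                        replicates: int = 1):
    """Libraries for a full two-strain, two-fraction design.

    Returns {condition: [(reads, truth), ...]} with ``replicates``
    independent libraries per condition (replicate index folded into
    the stream seed, so each library is distinct but reproducible).
    """
    out = {}
    for cond in conditions:
        libs = []
        for rep in range(replicates):
            reads, truth = simulate_library(cfg, genome, cond, replicate=rep)
            truth["replicate"] = rep
            libs.append((reads, truth))
        out[cond] = libs
    return out
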