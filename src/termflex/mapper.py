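"""Exact 5'-end mapping with fractional multi-locus attribution.

Reads are required to match the genome exactly (no mismatches, no
indels). Only the 5'-end coordinate of each match is recorded, so reads
of different lengths sharing a 5' terminus accumulate at one position.
A read matching several genomic loci contributes 1/n of a read to each
of the n loci. Coordinate conventions:

- plus strand: the 5' end is the leftmost genomic base of the match;
- minus strand (the read equals the reverse complement of a genomic
  interval): the 5' end is the *rightmost* genomic base of the interval,
  which is the biological 5' terminus of the fragment.

Profiles are normalised per one million quality-controlled reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from termflex.io import Genome, Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """All 0-based start offsets of ``needle`` in ``haystack``, overlaps included."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass
class MappingHit:
    """All exact genomic placements of one read, weighted equally."""

    read_id: str
    positions: list[tuple[int, str]]  # (1-based 5'-end position, strand)

    @property
    def weight_each(self) -> float:
        return 1.0 / len(self.positions)


def map_read(read: Read, genome: Genome) -> MappingHit | None:
    """Exact-match a read against both genome strands.

    Returns ``None`` when the read has no exact occurrence (or contains
    N, which cannot match unambiguously).
    """
    seq = read.seq
    if "N" in seq:
        return None
    m = len(seq)
    positions: list[tuple[int, str]] = []
    for i in find_occurrences(seq, genome.seq):
        positions.append((i + 1, "+"))  # leftmost base, 1-based
    for i in find_occurrences(revcomp(seq), genome.seq):
        positions.append((i + m, "-"))  # rightmost base = biological 5' end
    if not positions:
        return None
    return MappingHit(read_id=read.id, positions=positions)


@dataclass
class FivePrimeProfile:
    """Per-strand, per-position fractional tallies of read 5'-ends."""

    genome_id: str
    strand_plus: np.ndarray
    strand_minus: np.ndarray
    n_qc: int
    normalized: bool = False

    def total_weight(self) -> float:
        return float(self.strand_plus.sum() + self.strand_minus.sum())

    def values(self, strand: str) -> np.ndarray:
        return self.strand_plus if strand == "+" else self.strand_minus


def build_profile(reads: Sequence[Read], genome: Genome, n_qc: int,
                  normalize: bool = True) -> FivePrimeProfile:
    """Map every read and accumulate fractional 5'-end weights.

    The sum of raw weights equals the number of mapped reads (each read
    distributes exactly one unit over its loci). With ``normalize`` the
    tallies are scaled by 1e6 / n_qc.
    """
    if n_qc <= 0:
        raise ValueError("n_qc must be positive")
    plus = np.zeros(genome.length)
    minus = np.zeros(genome.length)
    # identical sequences share one placement lookup
    cache: dict[str, list[tuple[int, str]] | None] = {}
    for read in reads:
        if read.seq not in cache:
            hit = map_read(read, genome)
            cache[read.seq] = hit.positions if hit else None
        positions = cache[read.seq]
        if positions is None:
            continue
        w = 1.0 / len(positions)
        for pos, strand in positions:
            (plus if strand == "+" else minus)[pos - 1] += w
    if normalize:
        scale = 1e6 / n_qc
        plus *= scale
        minus *= scale
    return FivePrimeProfile(
        genome_id=genome.id, strand_plus=plus, strand_minus=minus,
        n_qc=n_qc, normalized=normalize,
    )


def pearson_r(a: FivePrimeProfile, b: FivePrimeProfile) -> float:
    """Pearson product-moment correlation between two profiles.

    Computed over the concatenated per-position values of both strands.
    Returns NaN when either profile has zero variance (the coefficient
    is undefined there).
    """
    if a.strand_plus.shape != b.strand_plus.shape:
        raise ValueError("profiles cover genomes of different length")
    if a.normalized != b.normalized:
        raise ValueError("profiles differ in normalization state")
    x = np.concatenate([a.strand_plus, a.strand_minus])
    y = np.concatenate([b.strand_plus, b.strand_minus])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
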