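"""RandExt: detection of genomic positions emitting randomly 3'-extended RNAs.

For a given anchor k-mer length ``k`` and flank length ``L``, the
algorithm considers reads of exactly ``k + L`` nucleotides and keeps a
read when:

(a) it does not occur anywhere in the genome (either strand) as a
    full-length exact match — perfectly templated reads carry no
    information about non-templated ends;
(b) its 5'-terminal k-mer occurs in the genome (the fragment has a
    defined origin);
(c) at one or more k-mer occurrences, its L-nt 3' flank diverges from
    the templated continuation: at most L-4 positional matches are
    allowed (for L = 4, complete divergence).

Qualifying reads are grouped per (position, strand, k, L); copy numbers
of unique read sequences in each group are summarised with the Shannon
index H = -sum(p_i ln p_i) in nats. Because H depends non-linearly on
the read profile, values from different (k, L) runs are never averaged:
a grid scan keeps, per position, the maximum H over all runs. Positions
exceeding a diversity floor (H > 2.0 by default) are flagged as
variable loci.

A read whose k-mer occurs at several loci is attributed, at full
weight, to every occurrence whose flank diverges; groups sharing at
least half of their qualifying reads with another group are annotated
as potentially cross-contributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from termflex.io import Genome, Read
from termflex.mapper import revcomp, find_occurrences
from termflex.preprocess import QCParams, trim_adapter


@dataclass
class RandExtParams:
    """One grid cell: anchor k-mer length, flank length, diversity floor."""

    k: int
    L: int
    h_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.L < 4:
            raise ValueError("the divergence rule is defined for L >= 4")


def shannon_index(counts: Mapping[str, int]) -> float:
    """Shannon diversity H = -sum(p_i ln p_i) of a copy-number table, in nats.

    ``p_i`` is the frequency of each unique sequence; a single unique
    sequence gives H = 0 regardless of its copy number.
    """
    if not counts:
        raise ValueError("empty copy-number table")
    if any(c < 1 for c in counts.values()):
        raise ValueError("copy numbers must be >= 1")
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log(p)
    return h


def flank_diverges(ext: str, genomic_continuation: str) -> bool:
    """Divergence rule for an L-nt flank against the templated continuation.

    True iff positional matches <= L - 4 (equivalently >= 4 mismatches).
    A continuation truncated at a genome end may be shorter than the
    flank; every missing base counts as a mismatch.
    """
    L = len(ext)
    if len(genomic_continuation) > L:
        raise ValueError("continuation longer than the flank")
    matches = sum(a == b for a, b in zip(ext, genomic_continuation))
    return matches <= L - 4


def kmer_occurrences(kmer: str, genome: Genome) -> list[tuple[int, str]]:
    """All (1-based 5'-end position, strand) occurrences of a k-mer.

    Minus-strand occurrences (k-mer equals the reverse complement of a
    genomic interval) report the rightmost genomic base, the biological
    5' end.
    """
    k = len(kmer)
    occ = [(i + 1, "+") for i in find_occurrences(kmer, genome.seq)]
    occ += [(i + k, "-") for i in find_occurrences(revcomp(kmer), genome.seq)]
    return occ


def continuation_after(genome: Genome, pos: int, strand: str, k: int,
                       L: int) -> str:
    """Templated L-nt continuation 3'-ward of a k-mer at (pos, strand).

    Truncated (possibly to empty) at the genome end.
    """
    if strand == "+":
        start = pos + k
        return genome.fetch(start, start + L - 1)
    end = pos - k
    return revcomp(genome.fetch(end - L + 1, end))


@dataclass
class ExtensionGroup:
    """Unique extended reads anchored at one genomic position."""

    genome_pos: int
    strand: str
    k: int
    L: int
    counts: dict[str, int] = field(default_factory=dict)
    cross_contributed: bool = False

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def H(self) -> float:
        return shannon_index(self.counts)


def run_randext(reads: Sequence[Read], genome: Genome, p: RandExtParams,
                qc: QCParams | None = None) -> dict[tuple[int, str], ExtensionGroup]:
    """One RandExt run: filter, anchor and group reads of length k + L.

    Adapter-remnant trimming is re-applied defensively before length
    selection. Returns groups keyed by (position, strand).
    """
    qc = qc or QCParams()
    target_len = p.k + p.L
    rc_genome = revcomp(genome.seq)
    groups: dict[tuple[int, str], ExtensionGroup] = {}
    # read sequence -> set of group keys, for cross-contribution checks
    attribution: dict[str, list[tuple[int, str]]] = {}
    seen_counts: dict[str, int] = {}

    for read in reads:
        trimmed = trim_adapter(read, qc)
        if trimmed is None or len(trimmed) != target_len:
            continue
        seq = trimmed.seq
        if seq in seen_counts:
            seen_counts[seq] += 1
            continue
        seen_counts[seq] = 1
        if seq in genome.seq or seq in rc_genome:
            attribution[seq] = []          # (a) perfectly templated
            continue
        kmer = seq[:p.k]
        ext = seq[p.k:]
        keys = []
        for pos, strand in kmer_occurrences(kmer, genome):  # (b)
            cont = continuation_after(genome, pos, strand, p.k, p.L)
            if flank_diverges(ext, cont):                   # (c)
                keys.append((pos, strand))
        attribution[seq] = keys

    for seq, n in seen_counts.items():
        for key in attribution[seq]:
            group = groups.setdefault(
                key, ExtensionGroup(genome_pos=key[0], strand=key[1],
                                    k=p.k, L=p.L))
            group.counts[seq] = n

    _annotate_cross_contribution(groups, attribution)
    return groups


def _annotate_cross_contribution(groups, attribution) -> None:
    """Flag groups sharing >= 50% of their qualifying reads with another."""
    for group in groups.values():
        shared = sum(n for seq, n in group.counts.items()
                     if len(attribution[seq]) > 1)
        if group.n_reads and shared / group.n_reads >= 0.5:
            group.cross_contributed = True


def randext_filter(reads: Sequence[Read], genome: Genome, p: RandExtParams,
                   qc: QCParams | None = None) -> list[Read]:
    """Reads that qualify under the (a)/(b)/(c) filter for this (k, L)."""
    groups = run_randext(reads, genome, p, qc=qc)
    qualifying = set()
    for g in groups.values():
        qualifying.update(g.counts)
    qc = qc or QCParams()
    out = []
    for r in reads:
        t = trim_adapter(r, qc)
        if t is not None and t.seq in qualifying:
            out.append(t)
    return out


@dataclass
class HPosition:
    """Per-position aggregate over a (k, L) grid scan."""

    genome_pos: int
    strand: str
    max_H: float
    best_k: int
    best_L: int
    n_reads: int
    n_unique: int
    flagged: bool
    cross_contributed: bool


@dataclass
class HProfile:
    """Maximum Shannon diversity per genomic position over all grid runs."""

    h_threshold: float
    positions: dict[tuple[int, str], HPosition] = field(default_factory=dict)

    def flagged(self) -> list[HPosition]:
        return [p for p in self.positions.values() if p.flagged]


def grid_scan(reads: Sequence[Read], genome: Genome,
              k_range: Iterable[int] = range(13, 23),
              L_range: Iterable[int] = range(4, 11),
              h_threshold: float = 2.0,
              qc: QCParams | None = None) -> HProfile:
    """Scan the (k, L) grid and aggregate per-position maxima of H.

    H values from different runs are never averaged, only maximised;
    on ties the lexicographically smallest (k, L) is reported.
    """
    grid = [(k, L) for k in k_range for L in L_range]
    if not grid:
        raise ValueError("empty parameter grid")
    profile = HProfile(h_threshold=h_threshold)
    for k, L in sorted(grid):
        params = RandExtParams(k=k, L=L, h_threshold=h_threshold)
        for key, group in run_randext(reads, genome, params, qc=qc).items():
            h = group.H
            prev = profile.positions.get(key)
            if prev is None or h > prev.max_H:
                profile.positions[key] = HPosition(
                    genome_pos=key[0], strand=key[1], max_H=h,
                    best_k=k, best_L=L, n_reads=group.n_reads,
                    n_unique=group.n_unique, flagged=h > h_threshold,
                    cross_contributed=group.cross_contributed,
                )
    return profile


def hprofile_table(profile: HProfile):
    """Tabulate a grid-scan result, one row per (position, strand)."""
    import pandas as pd

    rows = [
        {
            "position": p.genome_pos, "strand": p.strand, "max_H": p.max_H,
            "best_k": p.best_k, "best_L": p.best_L, "n_reads": p.n_reads,
            "n_unique": p.n_unique, "flagged": p.flagged,
            "cross_contributed": p.cross_contributed,
        }
        for p in sorted(profile.positions.values(),
                        key=lambda q: (q.strand, q.genome_pos))
    ]
    return pd.DataFrame(rows, columns=["position", "strand", "max_H", "best_k",
                                       "best_L", "n_reads", "n_unique",
                                       "flagged", "cross_contributed"])
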