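"""Anchor-based read collection and deviation classification.

Reads sharing a 5' terminus with a locus of interest are collected by an
exact anchor prefix (12-14 nt by default): the anchor equals the genomic
sequence starting at the locus's 5'-end position, and a read is collected
when its first ``len(anchor)`` bases match it exactly. The post-anchor
portion of each collected read is then aligned to the genomic
continuation by a banded edit-distance (band 3, unit costs), and the
deviations are classified into four categories:

1. non-template additions — 3' extensions of 1-3 nt of any sequence, or
   longer extensions containing only 1-2 distinct nucleotides;
2. chimeras — 3' extensions of >= 4 nt containing >= 3 distinct
   nucleotides (interpreted as a ligated foreign oligonucleotide);
3. insertions/deletions (indels);
4. base substitutions (mismatches) outside the read's terminal triplets.

The 3' extension is the maximal trailing segment of read bases that is
better explained as non-templated than as templated sequence: a
changepoint split of the aligned columns in which the templated prefix
rewards matches and the extension suffix rewards non-matches. This is
robust to the coincidental base matches that any genuinely random tail
shows against the genomic continuation (a quarter of positions, in
expectation), where a naive "suffix after the last matched base" rule
truncates arbitrarily. Each read is tallied once (the extension
category takes precedence) even when it carries several deviation
types; every individual deviation is still recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from termflex.io import Genome, Read
from termflex.mapper import revcomp

CORRECT = "correct"
NONTEMPLATE = "nontemplate_addition"
CHIMERA = "chimera"
INDEL = "indel"
MISMATCH = "mismatch"


@dataclass
class Anchor:
    """An exact genomic prefix assigning reads to a locus by their 5' end."""

    seq: str
    genome_pos: int  # 1-based 5'-end position
    strand: str

    def __len__(self) -> int:
        return len(self.seq)


def anchor_from_genome(genome: Genome, pos: int, strand: str,
                       length: int = 13) -> Anchor:
    """Build the anchor for a (position, strand) locus from the genome.

    On the plus strand the anchor is the genomic sequence starting at
    ``pos``; on the minus strand it is the reverse complement of the
    interval ending at ``pos`` (``pos`` being the biological 5' end).
    """
    if strand == "+":
        seq = genome.fetch(pos, pos + length - 1)
    else:
        seq = revcomp(genome.fetch(pos - length + 1, pos))
    if len(seq) != length:
        raise ValueError(f"anchor at {pos}{strand} would extend past the genome")
    return Anchor(seq=seq, genome_pos=pos, strand=strand)


def genomic_continuation(genome: Genome, anchor: Anchor, length: int) -> str:
    """Templated sequence 3'-ward of the anchor, truncated at the genome end."""
    k = len(anchor)
    if anchor.strand == "+":
        start = anchor.genome_pos + k
        return genome.fetch(start, start + length - 1)
    end = anchor.genome_pos - k
    return revcomp(genome.fetch(end - length + 1, end))


def collect_by_anchor(reads: Sequence[Read], anchor: Anchor) -> list[Read]:
    """Reads whose 5'-terminal ``len(anchor)`` bases equal the anchor exactly.

    Collection is independent of genome mapping: reads whose downstream
    portion deviates arbitrarily (including unmappable ones) are kept.
    """
    return [r for r in reads if r.seq.startswith(anchor.seq)]


@dataclass
class DeviationRecord:
    """Classification outcome for one collected read."""

    read_id: str
    category: str
    extension: str = ""
    internal_deviations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_deviation_types(self) -> int:
        kinds = set(t for t, _ in self.internal_deviations)
        if self.extension:
            kinds.add("extension")
        return len(kinds)


def classify_extension(ext: str) -> str:
    """Categorise a non-empty 3' extension.

    1-3 nt of any sequence -> non-template addition; >= 4 nt with at
    most 2 distinct nucleotides -> non-template addition (homopolymeric
    or near-homopolymeric tail); >= 4 nt with >= 3 distinct nucleotides
    -> chimera.
    """
    if not ext:
        raise ValueError("empty extension cannot be classified")
    if len(ext) <= 3 or len(set(ext)) <= 2:
        return NONTEMPLATE
    return CHIMERA


def _banded_align(tail: str, cont: str, band: int = 3):
    """Banded global alignment of ``tail`` against a prefix of ``cont``.

    Unit costs (match 0, substitution 1, gap 1); the end of ``cont`` is
    free (semi-global). Returns alignment columns as (op, i, j) with op
    in {match, sub, ins, del}: ins consumes a tail base without genome,
    del a genome base without tail. Traceback prefers the diagonal at
    equal cost, then ins, then del — a fixed, documented tie-break that
    keeps the output deterministic.
    """
    n, m = len(tail), len(cont)
    INF = float("inf")

    def bounds(i: int) -> tuple[int, int]:
        return max(0, i - band), min(m, i + band)

    D = [dict() for _ in range(n + 1)]
    for j in range(0, min(m, band) + 1):
        D[0][j] = j  # leading genome deletions
    for i in range(1, n + 1):
        lo, hi = bounds(i)
        for j in range(lo, hi + 1):
            best = INF
            if j > 0 and (j - 1) in D[i - 1]:
                best = min(best, D[i - 1][j - 1] + (tail[i - 1] != cont[j - 1]))
            if j in D[i - 1]:
                best = min(best, D[i - 1][j] + 1)  # ins
            if j > lo and (j - 1) in D[i]:
                best = min(best, D[i][j - 1] + 1)  # del
            D[i][j] = best

    # free genome end: best terminal column, largest j on ties so that
    # templated bases are consumed before the alignment is closed
    end_j = max(D[n], key=lambda j: (-D[n][j], j))
    cols: list[tuple[str, int, int]] = []
    i, j = n, end_j
    while i > 0 or j > 0:
        here = D[i][j]
        if i > 0 and j > 0 and (j - 1) in D[i - 1] and \
                D[i - 1][j - 1] + (tail[i - 1] != cont[j - 1]) == here:
            op = "match" if tail[i - 1] == cont[j - 1] else "sub"
            cols.append((op, i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and j in D[i - 1] and D[i - 1][j] + 1 == here:
            cols.append(("ins", i - 1, -1))
            i -= 1
        else:
            cols.append(("del", -1, j - 1))
            j -= 1
    cols.reverse()
    return cols


def _split_columns(cols) -> tuple[int, int]:
    """Changepoint split of alignment columns into templated prefix and
    non-templated suffix; returns (split index, score).

    The prefix scores +1 per match and -1 per substitution or gap; the
    suffix scores +1 per substitution or read insertion, -1 per match
    and 0 per genome deletion. The split maximising the total is the
    extension boundary; on ties the earliest split wins, giving the
    maximal extension.
    """
    pre = {"match": 1, "sub": -1, "ins": -1, "del": -1}
    suf = {"match": -1, "sub": 1, "ins": 1, "del": 0}
    n = len(cols)
    # suffix sums from each split point
    suffix_score = [0] * (n + 1)
    for idx in range(n - 1, -1, -1):
        suffix_score[idx] = suffix_score[idx + 1] + suf[cols[idx][0]]
    best_split, best_score, acc = None, None, 0
    for split in range(n + 1):
        score = acc + suffix_score[split]
        if best_score is None or score > best_score:
            best_split, best_score = split, score
        if split < n:
            acc += pre[cols[split][0]]
    return best_split, best_score


def classify_read(read: Read, anchor: Anchor, genome: Genome,
                  band: int = 3) -> DeviationRecord:
    """Classify one anchor-collected read against the genomic continuation.

    The post-anchor portion is compared to the templated continuation
    under two interpretations — a gap-free position-by-position
    comparison and a banded edit-distance alignment (band ``band``,
    unit costs) that can explain a shifted 3' segment as an indel —
    and each is split by changepoint into a templated prefix and a 3'
    extension. The interpretation with the higher changepoint score
    wins (the gap-free one on ties), so a cheap genomic explanation
    (one indel) beats calling a long extension, while a genuinely
    random tail is not realigned into spurious gap-bought matches.
    Substitutions in the templated prefix outside the read's terminal
    triplets count as mismatches; deviations at the read termini are
    absorbed into the terminal-extension/anchor logic. Anchor-based
    collection fixes the 5' end, so only 3' extensions are scored.
    """
    if not read.seq.startswith(anchor.seq):
        raise ValueError(f"read {read.id!r} was not collected by this anchor")
    k = len(anchor)
    tail = read.seq[k:]
    if not tail:
        return DeviationRecord(read_id=read.id, category=CORRECT)

    cont = genomic_continuation(genome, anchor, len(tail) + band)

    # gap-free positional comparison; continuation truncated at a genome
    # end leaves trailing read bases non-templated by absence
    cols = [("match" if i < len(cont) and base == cont[i] else "sub", i, i)
            for i, base in enumerate(tail)]
    split, score = _split_columns(cols)
    dp_cols = _banded_align(tail, cont, band=band)
    dp_split, dp_score = _split_columns(dp_cols)
    if dp_score > score:
        cols, split = dp_cols, dp_split

    ext = "".join(tail[i] for op, i, _ in cols[split:] if i >= 0)

    internal: list[tuple[str, int]] = []
    n_read = len(read.seq)
    for op, i, _ in cols[:split]:
        offset = k + i  # 0-based offset in the full read
        if op == "sub":
            # terminal triplets: first and last 3 bases of the read
            if 3 <= offset <= n_read - 4:
                internal.append((MISMATCH, offset))
        elif op == "ins":
            internal.append(("insertion", offset))
        elif op == "del":
            # genome base skipped; attach to the following read offset
            internal.append(("deletion", offset if i >= 0 else k))

    if ext:
        category = classify_extension(ext)
    elif any(t in ("insertion", "deletion") for t, _ in internal):
        category = INDEL
    elif any(t == MISMATCH for t, _ in internal):
        category = MISMATCH
    else:
        category = CORRECT
    return DeviationRecord(read_id=read.id, category=category,
                           extension=ext, internal_deviations=internal)


@dataclass
class FrequencySummary:
    """Per-category percentages under the replicate-frequency policy."""

    percentages: dict[str, float] | None
    replicate_policy_applied: str  # mean_of_two | pooled | ignored
    n_reads: tuple[int, int]


def _category_percentages(records: Sequence[DeviationRecord]) -> dict[str, float]:
    n = len(records)
    cats = [CORRECT, NONTEMPLATE, CHIMERA, INDEL, MISMATCH]
    counts = {c: 0 for c in cats}
    for r in records:
        counts[r.category] += 1
    return {c: 100.0 * counts[c] / n for c in cats}


def summarize_frequencies(rep1: Sequence[DeviationRecord],
                          rep2: Sequence[DeviationRecord],
                          min_each: int = 100,
                          min_total: int = 80) -> FrequencySummary:
    """Combine two replicates under the read-count policy.

    Both replicates at or above ``min_each`` reads: per-category
    percentages are computed per replicate and averaged. Otherwise, if
    the pooled count reaches ``min_total``, percentages come from the
    pooled records. Below that the sample is ignored (no percentages).
    """
    n1, n2 = len(rep1), len(rep2)
    if n1 >= min_each and n2 >= min_each:
        p1 = _category_percentages(rep1)
        p2 = _category_percentages(rep2)
        pct = {c: (p1[c] + p2[c]) / 2 for c in p1}
        return FrequencySummary(pct, "mean_of_two", (n1, n2))
    if n1 + n2 >= min_total:
        pooled = list(rep1) + list(rep2)
        return FrequencySummary(_category_percentages(pooled), "pooled", (n1, n2))
    return FrequencySummary(None, "ignored", (n1, n2))
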