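"""Extension-rate and motif-richness summaries of classified reads.

Motif richness for extension length l is the percentage of observed
unique extension sequences relative to the full motif space of that
length: 4, 16, 64 and 256 possible motifs for mono-, di-, tri- and
tetranucleotide extensions. Only extensions of exactly length l count
toward length-l richness — a 5-mer does not contribute its 4-mer
prefix. The extension rate is the percentage of collected reads whose
3' end carries any non-templated nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from termflex.classify import DeviationRecord


@dataclass
class RichnessEntry:
    length: int
    observed_unique: int
    space: int
    richness_pct: float


def motif_richness(records: Sequence[DeviationRecord], length: int) -> RichnessEntry:
    """Unique extension motifs of exactly ``length`` nt, as % of 4^length."""
    if length not in (1, 2, 3, 4):
        raise ValueError("motif richness is defined for lengths 1-4")
    space = 4 ** length
    unique = {r.extension for r in records if len(r.extension) == length}
    return RichnessEntry(
        length=length, observed_unique=len(unique), space=space,
        richness_pct=100.0 * len(unique) / space,
    )


def extension_rate(records: Sequence[DeviationRecord]) -> float:
    """Percent of collected reads with non-templated 3' nucleotides."""
    if not records:
        raise ValueError("no records to summarise")
    extended = sum(1 for r in records if r.extension)
    return 100.0 * extended / len(records)


def richness_summary(records: Sequence[DeviationRecord]):
    """One row per extension length 1-4, plus the overall extension rate."""
    import pandas as pd

    entries = [motif_richness(records, l) for l in (1, 2, 3, 4)]
    df = pd.DataFrame(
        [
            {"length": e.length, "observed_unique": e.observed_unique,
             "space": e.space, "richness_pct": e.richness_pct}
            for e in entries
        ]
    )
    df.attrs["extension_rate_pct"] = extension_rate(records) if records else 0.0
    return df
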