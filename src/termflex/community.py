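"""Taxon-response statistics for oligonucleotide-treated communities.

Input is a genus x sample count matrix (e.g. a Kraken2-style abundance
export). Zero cells receive one pseudocount; counts become per-sample
percentages; a genus enters the analysis when the direction-relevant
sample reaches 0.01% relative abundance in at least four of five
subject pairs. Per subject, the fold-change ratio (FCR) is the treated
percentage over the paired control percentage; across subjects the FCRs
are averaged and tested against the null FCR = 1 with a Z-score
z = (mean - 1) / (sd / sqrt(n)) using the sample standard deviation
(n - 1 denominator, spreadsheet convention) and a one-sided standard
normal tail probability. The mean absolute deviation (MAD, around the
mean) summarises the consistency of pooled FCRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

INCREASED = "increased"
SUPPRESSED = "suppressed"


def add_pseudocounts(counts: pd.DataFrame) -> pd.DataFrame:
    """Replace zero cells by one pseudocount (division-by-zero guard).

    Never changes the ordering of nonzero counts within a sample.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    return counts.where(counts > 0, 1)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percentages of total reads, after pseudocounting."""
    pseudo = add_pseudocounts(counts)
    totals = pseudo.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total reads")
    return 100.0 * pseudo / totals


def include_genus(pcts_treated: Sequence[float], pcts_control: Sequence[float],
                  direction: str, min_pct: float = 0.01,
                  min_pairs: int = 4) -> bool:
    """Low-abundance inclusion filter.

    For genera showing increased abundance the treated sample must hold
    >= ``min_pct`` percent; for suppressed genera the control sample
    must. The threshold must be met in at least ``min_pairs`` of the
    subject pairs.
    """
    if len(pcts_treated) != len(pcts_control):
        raise ValueError("paired percentage vectors differ in length")
    relevant = pcts_treated if direction == INCREASED else pcts_control
    return sum(p >= min_pct for p in relevant) >= min_pairs


@dataclass
class ResponseStat:
    """Fold-change-ratio summary for one genus."""

    fcrs: list[float]
    n: int
    mean_fcr: float
    std: float
    z: float | None
    p: float | None
    log_p: float | None
    direction: str

    @property
    def degenerate(self) -> bool:
        return self.z is None


def response_stat(fcrs: Sequence[float], min_n: int = 4) -> ResponseStat:
    """Z-score of per-subject FCRs against the null hypothesis FCR = 1.

    Uses the sample standard deviation (n - 1) and a one-sided normal
    tail p = P(Z > |z|), evaluated in log space as well so extreme
    Z-scores do not underflow to an uninformative zero.
    """
    fcrs = [float(f) for f in fcrs]
    n = len(fcrs)
    if n < min_n:
        raise ValueError(f"need at least {min_n} replicate FCRs, got {n}")
    mean = float(np.mean(fcrs))
    std = float(np.std(fcrs, ddof=1))
    direction = INCREASED if mean >= 1 else SUPPRESSED
    if std == 0:
        return ResponseStat(fcrs, n, mean, std, None, None, None, direction)
    z = (mean - 1.0) / (std / math.sqrt(n))
    log_p = float(norm.logsf(abs(z)))
    p = float(norm.sf(abs(z)))
    return ResponseStat(fcrs, n, mean, std, z, p, log_p, direction)


def mad(values: Sequence[float]) -> float:
    """Mean absolute deviation around the mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty set")
    return float(np.mean(np.abs(values - values.mean())))


def analyze_table(counts: pd.DataFrame,
                  pairs: Sequence[tuple[str, str]],
                  min_pct: float = 0.01, min_pairs: int = 4,
                  min_n: int = 4) -> pd.DataFrame:
    """Volcano-plot statistics for every qualifying genus.

    ``pairs`` lists (treated_sample, control_sample) column names, one
    per subject. Output columns: n, mean_fcr, log2_fcr, z, p, direction.
    Genera failing the inclusion filter in their own direction, or with
    degenerate (zero-variance) FCRs, are omitted.
    """
    pcts = relative_abundance(counts)
    rows = []
    for genus in pcts.index:
        treated = [pcts.at[genus, t] for t, _ in pairs]
        control = [pcts.at[genus, c] for _, c in pairs]
        fcrs = [t / c for t, c in zip(treated, control)]
        direction = INCREASED if float(np.mean(fcrs)) >= 1 else SUPPRESSED
        if not include_genus(treated, control, direction,
                             min_pct=min_pct, min_pairs=min_pairs):
            continue
        stat = response_stat(fcrs, min_n=min_n)
        if stat.degenerate:
            continue
        rows.append({
            "genus": genus, "n": stat.n, "mean_fcr": stat.mean_fcr,
            "log2_fcr": math.log2(stat.mean_fcr), "std": stat.std,
            "z": stat.z, "p": stat.p, "direction": stat.direction,
        })
    return pd.DataFrame(rows, columns=["genus", "n", "mean_fcr", "log2_fcr",
                                       "std", "z", "p", "direction"])
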