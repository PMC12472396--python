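"""Sliding-window differential screen for condition-dependent secretion.

The screen compares four sample types — wild-type and mutant, each with
an intracellular (transcriptome) and an extracellular (secretome)
fraction — on normalised 5'-end profiles. Per strand, coverage is summed
in sliding windows (default 5 bp, 1 bp step), replicate windows are
averaged, and a window qualifies as a candidate when:

1. the larger of the two secretome window means reaches the read floor
   (default 25 normalised reads);
2. secretome abundance drops at least ``fold`` (default 1.5) in the
   mutant: wt_exo / mut_exo >= fold;
3. intracellular abundance is comparable or elevated in the mutant:
   mut_in / wt_in >= intracellular_min_ratio * (1 - intracellular_tolerance).
   "Comparable" cannot be a strict inequality on counted reads — at true
   parity, replicate counting noise puts the measured ratio below 1 half
   the time — so parity is asserted with a 10% tolerance by default.

Runs of overlapping qualifying windows on one strand merge into a
candidate locus whose borders are the union extent and whose peak is
the position of maximum per-position wild-type secretome coverage
(leftmost on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from termflex.mapper import FivePrimeProfile

WindowMap = dict[tuple[int, str], float]


@dataclass
class ScreenParams:
    window: int = 5
    step: int = 1
    min_reads: float = 25.0
    fold: float = 1.5
    intracellular_min_ratio: float = 1.0
    intracellular_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")
        if self.min_reads <= 0:
            raise ValueError("min_reads must be positive")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if not 0 <= self.intracellular_tolerance < 1:
            raise ValueError("intracellular_tolerance must be in [0, 1)")

    @property
    def intracellular_floor(self) -> float:
        return self.intracellular_min_ratio * (1 - self.intracellular_tolerance)


@dataclass
class CandidateLocus:
    """A merged run of qualifying windows on one strand."""

    strand: str
    left: int    # 1-based inclusive
    right: int   # 1-based inclusive
    peak: int    # 1-based position of maximum wt secretome coverage
    means: tuple[float, float, float, float]  # wt_in, mut_in, wt_exo, mut_exo
    exo_ratio: float   # wt_exo / mut_exo (inf when mut_exo == 0)
    in_ratio: float    # mut_in / wt_in (inf when wt_in == 0)


def _ratio(num: float, den: float) -> float:
    """num/den with a +inf marker for zero denominators (passes any >= test)."""
    if den == 0:
        return math.inf
    return num / den


def window_sums(profile: FivePrimeProfile, p: ScreenParams) -> WindowMap:
    """Sum per-position values in sliding windows, keyed by (start, strand).

    Window [s, s+window-1] in 1-based coordinates; windows that would
    extend past the genome end are dropped.
    """
    out: WindowMap = {}
    for strand in ("+", "-"):
        values = profile.values(strand)
        n = len(values)
        if n < p.window:
            continue
        kernel = np.ones(p.window)
        sums = np.convolve(values, kernel, mode="valid")  # length n-window+1
        for start0 in range(0, n - p.window + 1, p.step):
            out[(start0 + 1, strand)] = float(sums[start0])
    return out


def mean_windows(replicate_windows: Sequence[WindowMap]) -> WindowMap:
    """Arithmetic mean of window sums across replicates (keys must agree)."""
    if not replicate_windows:
        return {}
    keys = set(replicate_windows[0])
    for wm in replicate_windows[1:]:
        if set(wm) != keys:
            raise ValueError("replicate window maps have mismatched keys")
    n = len(replicate_windows)
    return {k: sum(wm[k] for wm in replicate_windows) / n for k in replicate_windows[0]}


def select_candidates(
    wt_in: WindowMap, mut_in: WindowMap, wt_exo: WindowMap, mut_exo: WindowMap,
    p: ScreenParams,
    wt_exo_positions: Mapping[str, np.ndarray] | None = None,
    window: int | None = None,
) -> list[CandidateLocus]:
    """Apply the differential-secretion criteria and merge qualifying windows.

    ``wt_exo_positions`` optionally supplies per-position wild-type
    secretome coverage (one array per strand) used to pinpoint the peak
    inside each locus; without it the peak falls back to the start of
    the locus's best qualifying window.
    """
    window = window or p.window
    keys = set(wt_exo)
    if not (set(wt_in) == set(mut_in) == keys == set(mut_exo)):
        raise ValueError("the four window maps must share keys")

    qualifying: dict[str, list[int]] = {"+": [], "-": []}
    for (start, strand) in keys:
        we, me = wt_exo[(start, strand)], mut_exo[(start, strand)]
        if max(we, me) < p.min_reads:
            continue
        if _ratio(we, me) < p.fold:
            continue
        if _ratio(mut_in[(start, strand)], wt_in[(start, strand)]) < p.intracellular_floor:
            continue
        qualifying[strand].append(start)

    loci: list[CandidateLocus] = []
    for strand, starts in qualifying.items():
        starts.sort()
        run: list[int] = []
        for s in starts:
            if run and s > run[-1] + window - 1:
                # next window does not overlap the previous one's extent
                loci.append(_emit_locus(run, strand, window, wt_in, mut_in,
                                        wt_exo, mut_exo, wt_exo_positions))
                run = []
            run.append(s)
        if run:
            loci.append(_emit_locus(run, strand, window, wt_in, mut_in,
                                    wt_exo, mut_exo, wt_exo_positions))
    loci.sort(key=lambda c: (c.strand, c.left))
    return loci


def _emit_locus(run, strand, window, wt_in, mut_in, wt_exo, mut_exo,
                wt_exo_positions) -> CandidateLocus:
    left = run[0]
    right = run[-1] + window - 1
    # report abundances at the qualifying window with maximal wt secretome
    # signal (leftmost on ties) — the locus's peak window
    best = max(run, key=lambda s: (wt_exo[(s, strand)], -s))
    means = (
        wt_in[(best, strand)], mut_in[(best, strand)],
        wt_exo[(best, strand)], mut_exo[(best, strand)],
    )
    if wt_exo_positions is not None:
        values = wt_exo_positions[strand]
        segment = values[left - 1:right]
        peak = left + int(np.argmax(segment))  # argmax is leftmost-tie
    else:
        peak = best
    return CandidateLocus(
        strand=strand, left=left, right=right, peak=peak, means=means,
        exo_ratio=_ratio(means[2], means[3]),
        in_ratio=_ratio(means[1], means[0]),
    )


def screen(
    wt_in: Sequence[FivePrimeProfile], mut_in: Sequence[FivePrimeProfile],
    wt_exo: Sequence[FivePrimeProfile], mut_exo: Sequence[FivePrimeProfile],
    p: ScreenParams | None = None,
) -> list[CandidateLocus]:
    """Full screen from replicate profiles: windows, replicate means, selection."""
    p = p or ScreenParams()
    for profs in (wt_in, mut_in, wt_exo, mut_exo):
        for prof in profs:
            if not prof.normalized:
                raise ValueError("screen requires normalized profiles")
    maps = [mean_windows([window_sums(prof, p) for prof in profs])
            for profs in (wt_in, mut_in, wt_exo, mut_exo)]
    wt_exo_positions = {
        strand: np.mean([prof.values(strand) for prof in wt_exo], axis=0)
        for strand in ("+", "-")
    }
    return select_candidates(*maps, p, wt_exo_positions=wt_exo_positions)


def candidates_table(loci: Sequence[CandidateLocus]):
    """Tabulate candidate loci (peak, strand, four abundances, borders)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "peak": c.peak, "strand": c.strand,
                "wt_in": c.means[0], "mut_in": c.means[1],
                "wt_exo": c.means[2], "mut_exo": c.means[3],
                "exo_ratio": c.exo_ratio, "in_ratio": c.in_ratio,
                "left": c.left, "right": c.right,
            }
            for c in loci
        ],
        columns=["peak", "strand", "wt_in", "mut_in", "wt_exo", "mut_exo",
                 "exo_ratio", "in_ratio", "left", "right"],
    )
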