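"""Quality filtering, 3'-adapter-remnant trimming and length selection.

The pipeline order is fixed: quality filter, then adapter trimming, then
length selection. The read count surviving length selection is the
library's quality-controlled read count (N_qc) used downstream to
normalise coverage profiles per million QC reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from termflex.io import Read

logger = logging.getLogger(__name__)

#: 5'-terminal sequence of the sequencing adapter whose remnants mark
#: read-through into the 3' adapter.
DEFAULT_ADAPTER_PREFIX = "ATCACCGACTGCCCA"


@dataclass
class QCParams:
    """Quality-control thresholds.

    q_threshold
        Per-base Phred floor; a base "passes" when its score is >= this.
    min_fraction
        Minimum fraction of passing bases for the read to survive.
    adapter_prefix
        Exact motif marking the start of 3'-adapter remnants; everything
        from its first occurrence onward is removed.
    len_min, len_max
        Inclusive insert-length window retained after trimming.
    """

    q_threshold: int = 20
    min_fraction: float = 0.90
    adapter_prefix: str = DEFAULT_ADAPTER_PREFIX
    len_min: int = 16
    len_max: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.len_min > self.len_max:
            raise ValueError("len_min must not exceed len_max")
        if not self.adapter_prefix:
            raise ValueError("adapter_prefix must be non-empty")


def quality_filter(reads: Sequence[Read], p: QCParams) -> list[Read]:
    """Retain reads whose fraction of bases at or above Q threshold passes.

    Reads without quality scores (FASTA input) pass unchanged with a
    logged warning, since the criterion cannot be evaluated.
    """
    kept = []
    warned = False
    for r in reads:
        if r.quals is None:
            if not warned:
                logger.warning("reads without quality scores pass the quality filter unchecked")
                warned = True
            kept.append(r)
            continue
        n_ok = sum(q >= p.q_threshold for q in r.quals)
        if n_ok / len(r) >= p.min_fraction:
            kept.append(r)
    return kept


def trim_adapter(read: Read, p: QCParams) -> Read | None:
    """Cut the read immediately before the first adapter-motif occurrence.

    Returns ``None`` (discard) when the motif starts at the very 5' end,
    i.e. the insert is empty. Reads without the motif are returned as-is.
    """
    idx = read.seq.find(p.adapter_prefix)
    if idx == -1:
        return read
    if idx == 0:
        return None
    return Read(
        id=read.id,
        seq=read.seq[:idx],
        quals=read.quals[:idx] if read.quals is not None else None,
    )


def length_select(reads: Sequence[Read], p: QCParams) -> list[Read]:
    """Retain reads with len_min <= length <= len_max (inclusive)."""
    return [r for r in reads if p.len_min <= len(r) <= p.len_max]


def preprocess(reads: Sequence[Read], p: QCParams | None = None):
    """Run the full QC pipeline; returns (reads, stage counts).

    The counts dict mirrors a library-statistics table: raw input,
    after quality filtering, after adapter trimming, and the final
    16-50 nt (by default) selection, whose count defines ``n_qc``.
    """
    p = p or QCParams()
    counts = {"raw": len(reads)}
    stage = quality_filter(reads, p)
    counts["after_quality"] = len(stage)
    stage = [t for r in stage if (t := trim_adapter(r, p)) is not None]
    counts["after_adapter"] = len(stage)
    stage = length_select(stage, p)
    counts["after_length"] = len(stage)
    counts["n_qc"] = len(stage)
    return stage, counts
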