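"""On-disk artifacts: FASTA genomes, FASTQ/FASTA read sets, profile tables.

All sequences are normalised to the uppercase DNA alphabet at ingest;
``U`` is transliterated to ``T`` so that RNA-alphabet inputs (synthetic
oligonucleotide designs are conventionally written as RNA) and the DNA
genome live in one alphabet. External coordinates are 1-based inclusive
throughout the package; bedGraph output converts to the format's 0-based
half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class Genome:
    """A reference sequence with 1-based inclusive external coordinates."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        bad = set(self.seq) - GENOME_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Return the plus-strand sequence of [start, end], 1-based inclusive.

        Coordinates outside the genome are clipped.
        """
        if end < start:
            return ""
        return self.seq[max(start - 1, 0):end]


@dataclass
class Read:
    """A sequencing read; ``quals`` are Phred scores when the source is FASTQ."""

    id: str
    seq: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if not self.seq:
            raise FormatError(f"read {self.id!r}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(seq: str) -> str:
    """Uppercase and transliterate RNA (U) to DNA (T)."""
    return str(seq).upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a FASTA file into :class:`Genome` records, in file order."""
    genomes = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {i} ({rec.id!r}) is empty")
        genomes.append(Genome(id=rec.id, seq=str(rec.seq)))
    if not genomes:
        raise FormatError(f"{path}: no FASTA records found")
    return genomes


def read_reads(path: str | Path, fmt: str = "fastq") -> list[Read]:
    """Read a FASTQ (Sanger/+33 qualities) or FASTA read set, order preserved."""
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"unsupported read format {fmt!r}")
    reads = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            quals = None
            if fmt == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            reads.append(Read(id=rec.id, seq=str(rec.seq), quals=quals))
    except ValueError as exc:  # Bio.SeqIO signals malformed records this way
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_reads(reads: Iterable[Read], path: str | Path, fmt: str = "fastq",
                default_qual: int = 30) -> None:
    """Write reads as FASTQ or FASTA; reads lacking qualities get a constant."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        if fmt == "fastq":
            quals = r.quals if r.quals is not None else [default_qual] * len(r.seq)
            rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def write_profile(profile, path: str | Path, fmt: str = "tsv") -> None:
    """Write a 5'-end profile as TSV (position, strand, value) or bedGraph.

    bedGraph intervals are 0-based half-open: a single-base feature at
    1-based position p covers [p-1, p). One track section per strand;
    zero positions are omitted.
    """
    path = Path(path)
    if fmt == "tsv":
        rows = []
        for strand, values in (("+", profile.strand_plus), ("-", profile.strand_minus)):
            for pos0, v in enumerate(values):
                if v != 0:
                    # repr round-trips a float exactly through text
                    rows.append((pos0 + 1, strand, repr(float(v))))
        df = pd.DataFrame(rows, columns=["position", "strand", "value"])
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bedgraph":
        with open(path, "w") as fh:
            for strand, values in (("+", profile.strand_plus), ("-", profile.strand_minus)):
                fh.write(
                    f'track type=bedGraph name="{profile.genome_id}_5p_{strand}"\n'
                )
                for pos0, v in enumerate(values):
                    if v != 0:
                        fh.write(f"{profile.genome_id}\t{pos0}\t{pos0 + 1}\t{float(v):g}\n")
    else:
        raise ValueError(f"unsupported profile format {fmt!r}")


def read_profile_tsv(path: str | Path, genome_id: str, genome_length: int,
                     n_qc: int, normalized: bool = True):
    """Read a TSV profile written by :func:`write_profile` back into memory."""
    from termflex.mapper import FivePrimeProfile  # deferred: avoid cycle
    import numpy as np

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    plus = np.zeros(genome_length)
    minus = np.zeros(genome_length)
    for pos, strand, value in df.itertuples(index=False):
        if not 1 <= pos <= genome_length:
            raise FormatError(f"{path}: position {pos} outside genome")
        (plus if strand == "+" else minus)[pos - 1] = value
    return FivePrimeProfile(
        genome_id=genome_id, strand_plus=plus, strand_minus=minus,
        n_qc=n_qc, normalized=normalized,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with a header line."""
    df.to_csv(path, sep="\t", index=False)
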