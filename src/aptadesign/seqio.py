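"""Core sequence types and FASTA / peak-table readers and writers.

Coordinates are 0-based, half-open everywhere in this package. DNA-style
input (T) is auto-converted to U with a warning rather than rejected,
because aptamer vendors and CLIP pipelines routinely emit DNA alphabets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
RNA_BASES = set("ACGU")


class AlphabetError(ValueError):
    """A sequence contains letters outside its declared alphabet."""


class PeakTableError(ValueError):
    """A peak table violates the expected schema or value constraints."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 canonical amino-acid letters."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"protein sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise AlphabetError(
                f"protein sequence {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RNASequence:
    """An RNA sequence over {A, C, G, U}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise AlphabetError(f"RNA sequence {self.id!r} is empty")
        bad = set(self.bases) - RNA_BASES
        if bad:
            raise AlphabetError(
                f"RNA sequence {self.id!r} contains non-RNA letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PeakRecord:
    """A single crosslink peak: transcript, 0-based position, read count."""

    transcript_id: str
    position: int
    reads: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise PeakTableError(f"peak position must be >= 0, got {self.position}")
        if self.reads < 0:
            raise PeakTableError(
                f"peak at {self.transcript_id}:{self.position} has negative reads ({self.reads})"
            )


def _normalize_rna(raw: str, record_id: str) -> str:
    s = raw.upper()
    if "T" in s:
        log.warning("sequence %r contains T; converting to U (DNA-style input)", record_id)
        s = s.replace("T", "U")
    return s


def read_fasta(
    path: Union[str, Path], alphabet: Literal["protein", "rna"]
) -> list[Union[ProteinSequence, RNASequence]]:
    """Read a multi-record FASTA file, order preserved.

    For the ``rna`` alphabet, lowercase is upcased and T is converted to U
    (with a warning). Letters outside the alphabet after normalization raise
    :class:`AlphabetError` naming the offending record.
    """
    if alphabet not in ("protein", "rna"):
        raise ValueError(f"alphabet must be 'protein' or 'rna', got {alphabet!r}")
    out: list[Union[ProteinSequence, RNASequence]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if alphabet == "rna":
            out.append(RNASequence(id=rec.id, bases=_normalize_rna(raw, rec.id)))
        else:
            out.append(ProteinSequence(id=rec.id, residues=raw.upper()))
    return out


def write_fasta(
    records: Iterable[Union[ProteinSequence, RNASequence]], path: Union[str, Path]
) -> None:
    """Write sequences as unwrapped FASTA (one line per sequence)."""
    seqrecs = []
    for r in records:
        letters = r.bases if isinstance(r, RNASequence) else r.residues
        seqrecs.append(SeqRecord(Seq(letters), id=r.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqrecs)


PEAK_COLUMNS = ["transcript_id", "position", "reads"]


def read_peaks(path: Union[str, Path]) -> list[PeakRecord]:
    """Read a tab-separated peak table with header transcript_id/position/reads.

    Rows with ``reads == 0`` are retained: a recorded zero-read position still
    counts as an interacting nucleotide for region contiguity.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"peak table {path} is missing columns: {missing}")
    peaks = [
        PeakRecord(str(t), int(p), int(r))
        for t, p, r in zip(df["transcript_id"], df["position"], df["reads"])
    ]
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEAK_COLUMNS) + "\n")
        for p in peaks:
            fh.write(f"{p.transcript_id}\t{p.position}\t{p.reads}\n")


def read_peaks_bed6(path: Union[str, Path]) -> list[PeakRecord]:
    """Import shim for BED6 peaks: chrom -> transcript_id, chromStart -> position,
    score -> reads. Single-nucleotide intervals expected (chromEnd = chromStart + 1)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )
    return [
        PeakRecord(str(c), int(s), int(sc))
        for c, s, sc in zip(df["chrom"], df["chromStart"], df["score"])
    ]
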