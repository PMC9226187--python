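"""Seedable synthetic data: iCLIP-like peak tables, transcripts, toy complexes.

The generator emulates the input of a CLIP-guided aptamer design run at toy
scale: a transcriptome of uniform-random RNA carrying GU-dinucleotide-enriched
"islands" that are densely covered by high-read peaks, over a sparse low-read
background. Ground-truth island intervals are returned so recovery can be
measured against the generator itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from aptadesign.seqio import PeakRecord, ProteinSequence, RNASequence, write_fasta, write_peaks
from aptadesign.structure import ATOM_COLUMNS, StructureComplex

RNA_ALPHABET = "ACGU"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic iCLIP fixture.

    Read rates are mean reads per covered nucleotide (a covered nucleotide
    always reports at least one read); coverage fractions control which
    nucleotides are covered at all. Islands are fully covered by default,
    reflecting the dense crosslinking of genuine binding regions, while the
    background is sparse.
    """

    n_transcripts: int = 8
    transcript_length: int = 1500
    n_islands: int = 8
    island_length: int = 60
    island_gu_fraction: float = 0.9
    background_read_rate: float = 0.5
    island_read_rate: float = 5.0
    background_coverage: float = 0.02
    island_coverage: float = 1.0
    seed: int = 0
    read_distribution: str = "poisson"

    def __post_init__(self) -> None:
        if self.island_read_rate <= self.background_read_rate:
            raise ValueError("island_read_rate must exceed background_read_rate")
        if not 0.0 <= self.island_gu_fraction <= 1.0:
            raise ValueError("island_gu_fraction must be in [0, 1]")
        if self.island_length < 50:
            raise ValueError("island_length must be >= 50 (minimum region size)")
        if self.read_distribution != "poisson":
            raise ValueError("only the poisson read model is implemented")


@dataclass
class Fixture:
    """Generated fixture plus its ground truth and full metadata."""

    spec: FixtureSpec
    transcripts: dict[str, RNASequence]
    peaks: list[PeakRecord]
    islands: pd.DataFrame  # transcript_id, start, end
    protein: ProteinSequence = field(default=None)  # type: ignore[assignment]

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(list(self.transcripts.values()), outdir / "transcripts.fasta")
        write_peaks(self.peaks, outdir / "peaks.tsv")
        self.islands.to_csv(outdir / "truth_islands.tsv", sep="\t", index=False)
        if self.protein is not None:
            write_fasta([self.protein], outdir / "protein.fasta")
        with open(outdir / "fixture_meta.json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _place_islands(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """(transcript index, start) for each island, non-overlapping with margins."""
    margin = 60  # keep transcript ends island-free so peak-free stretches exist
    placements: list[tuple[int, int]] = []
    per_tx: dict[int, list[tuple[int, int]]] = {}
    for k in range(spec.n_islands):
        tx = k % spec.n_transcripts
        lo, hi = margin, spec.transcript_length - margin - spec.island_length
        if hi < lo:
            raise ValueError("transcript too short to place an island with margins")
        for _ in range(200):
            start = int(rng.integers(lo, hi + 1))
            occupied = per_tx.get(tx, [])
            if all(start + spec.island_length + 10 <= s or start >= e + 10 for s, e in occupied):
                per_tx.setdefault(tx, []).append((start, start + spec.island_length))
                placements.append((tx, start))
                break
        else:
            raise ValueError("could not place islands without overlap; spec too dense")
    return placements


def _enrich_gu(seq: list[str], start: int, length: int, fraction: float,
               rng: np.random.Generator) -> None:
    """Plant GU dinucleotides at random even offsets until the target fraction
    of island nucleotides is covered by planted GUs (preserves length)."""
    slots = list(range(0, length - 1, 2))
    n_plant = min(len(slots), math.ceil(fraction * length / 2))
    chosen = rng.choice(len(slots), size=n_plant, replace=False)
    for c in sorted(chosen):
        off = start + slots[c]
        seq[off] = "G"
        seq[off + 1] = "U"


def _covered_reads(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.maximum(1, rng.poisson(rate, size=n))


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate transcripts, peaks and ground-truth islands from a spec.

    Fully determined by (spec, spec.seed): the same spec regenerates
    byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    placements = _place_islands(spec, rng)

    tx_seqs: list[list[str]] = [
        list(rng.choice(list(RNA_ALPHABET), size=spec.transcript_length))
        for _ in range(spec.n_transcripts)
    ]
    island_rows = []
    for tx, start in placements:
        _enrich_gu(tx_seqs[tx], start, spec.island_length, spec.island_gu_fraction, rng)
        island_rows.append(
            {"transcript_id": f"tx{tx}", "start": start, "end": start + spec.island_length}
        )

    transcripts = {
        f"tx{i}": RNASequence(id=f"tx{i}", bases="".join(s)) for i, s in enumerate(tx_seqs)
    }

    peaks: list[PeakRecord] = []
    for i in range(spec.n_transcripts):
        tx_id = f"tx{i}"
        in_island = np.zeros(spec.transcript_length, dtype=bool)
        for tx, start in placements:
            if tx == i:
                in_island[start : start + spec.island_length] = True
        covered = np.where(
            in_island,
            rng.random(spec.transcript_length) < spec.island_coverage,
            rng.random(spec.transcript_length) < spec.background_coverage,
        )
        positions = np.flatnonzero(covered)
        rates = np.where(in_island[positions], spec.island_read_rate, spec.background_read_rate)
        reads = np.maximum(1, rng.poisson(rates))
        peaks.extend(
            PeakRecord(tx_id, int(p), int(r)) for p, r in zip(positions, reads)
        )

    islands = pd.DataFrame(island_rows, columns=["transcript_id", "start", "end"])
    protein = synthetic_protein(seed=spec.seed)
    return Fixture(spec=spec, transcripts=transcripts, peaks=peaks,
                   islands=islands, protein=protein)


AROMATIC = "FYW"
NON_AROMATIC = "ACDEGHIKLMNPQRSTV"


def synthetic_protein(seed: int = 0, length: int = 80, n_aromatic: int = 8) -> ProteinSequence:
    """Synthetic RRM-like target protein with aromatics concentrated in the
    N-terminal quarter, the architecture the positional reference scorer is
    sensitive to. Labelled synthetic; not a real protein sequence."""
    rng = np.random.default_rng(seed)
    res = list(rng.choice(list(NON_AROMATIC), size=length))
    slots = rng.choice(max(length // 4, n_aromatic), size=n_aromatic, replace=False)
    for s in slots:
        res[s] = str(rng.choice(list(AROMATIC)))
    return ProteinSequence(id=f"synthetic_rbp_{seed}", residues="".join(res))


def generate_toy_complex(
    n_contacting: int, n_total: int, cutoff: float = 4.0, seed: int = 0
) -> tuple[StructureComplex, int]:
    """Toy protein-RNA complex with a known contact count.

    Places ``n_total`` single-atom RNA nucleotides so that exactly
    ``n_contacting`` lie strictly within ``cutoff`` of a protein atom; the
    construction is its own oracle for the contact operator.
    """
    if n_contacting > n_total:
        raise ValueError("n_contacting cannot exceed n_total")
    if n_total < 0 or cutoff <= 0:
        raise ValueError("need n_total >= 0 and cutoff > 0")
    rng = np.random.default_rng(seed)
    rows = []
    # small protein: three residues near the origin
    for i, (dx, name) in enumerate([(0.0, "GLY"), (1.5, "ALA"), (3.0, "SER")]):
        rows.append({"chain": "A", "resid": i + 1, "resname": name, "atom_name": "CA",
                     "element": "C", "x": dx, "y": 0.0, "z": 0.0})
    prot_xyz = np.array([[r["x"], r["y"], r["z"]] for r in rows])
    names = ["A", "U", "G", "C"]
    for k in range(n_total):
        if k < n_contacting:
            for _ in range(500):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = cutoff * rng.uniform(0.4, 0.9)
                anchor = prot_xyz[int(rng.integers(len(prot_xyz)))]
                xyz = anchor + dist * direction
                if np.min(np.linalg.norm(prot_xyz - xyz, axis=1)) < cutoff * 0.95:
                    break
            else:
                raise ValueError("could not place contacting nucleotide")
        else:
            xyz = np.array([10.0 * cutoff + 2.0 * cutoff * k, 0.0, 0.0])
        rows.append({"chain": "B", "resid": k + 1, "resname": names[k % 4],
                     "atom_name": "P", "element": "P",
                     "x": float(xyz[0]), "y": float(xyz[1]), "z": float(xyz[2])})
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return StructureComplex(atoms, {"A": "protein", "B": "rna"}), n_contacting
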