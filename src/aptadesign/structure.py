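"""Static protein-RNA contact analysis and a single-strandedness heuristic.

A residue-level contact is declared when any atom of an amino acid lies at a
distance strictly below the cutoff (default 4 A) from any atom of a
nucleotide. Counting the distinct contacted nucleotides of a deposited
protein-RNA complex is how the design window length is anchored to structure:
the number of nucleotides the protein actually engages bounds the useful
aptamer length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from aptadesign.seqio import RNASequence

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine, common in deposited structures
}
RNA_RESNAMES = {
    "A", "C", "G", "U", "RA", "RC", "RG", "RU", "ADE", "CYT", "GUA", "URA",
}
WATER_RESNAMES = {"HOH", "WAT", "DOD"}

ATOM_COLUMNS = ["chain", "resid", "resname", "atom_name", "element", "x", "y", "z"]


class ChainTypingError(ValueError):
    """A chain contains residues that are neither protein nor RNA."""


ResidueKey = tuple[str, int, str]  # (chain id, residue index, residue name)


@dataclass
class StructureComplex:
    """Flat atom table of one model of a protein-RNA complex.

    ``atoms`` has columns chain/resid/resname/atom_name/element/x/y/z
    (coordinates in Angstrom); ``chain_types`` maps each chain id to
    "protein" or "rna".
    """

    atoms: pd.DataFrame
    chain_types: dict[str, str]
    model: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        coords = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")

    def _typed(self, kind: str, heavy_only: bool) -> pd.DataFrame:
        chains = [c for c, t in self.chain_types.items() if t == kind]
        sub = self.atoms[self.atoms["chain"].isin(chains)]
        if heavy_only:
            sub = sub[sub["element"].str.upper() != "H"]
        return sub

    def rna_residues(self) -> list[ResidueKey]:
        sub = self._typed("rna", heavy_only=False)
        keys = sub[["chain", "resid", "resname"]].drop_duplicates()
        return [tuple(r) for r in keys.itertuples(index=False)]


def _type_residue(resname: str) -> str | None:
    name = resname.strip().upper()
    if name in WATER_RESNAMES:
        return None
    if name in PROTEIN_RESNAMES:
        return "protein"
    if name in RNA_RESNAMES:
        return "rna"
    raise ChainTypingError(f"unrecognized residue name {resname!r}")


def _complex_from_model(model, model_index: int) -> StructureComplex:
    rows = []
    chain_types: dict[str, str] = {}
    for chain in model:
        kinds = set()
        for residue in chain:
            kind = _type_residue(residue.get_resname())
            if kind is None:
                continue
            kinds.add(kind)
            for atom in residue:  # disordered atoms: highest-occupancy altloc
                x, y, z = atom.coord
                rows.append(
                    {
                        "chain": chain.id,
                        "resid": residue.id[1],
                        "resname": residue.get_resname().strip(),
                        "atom_name": atom.get_name(),
                        "element": (atom.element or "").strip() or atom.get_name()[0],
                        "x": float(x), "y": float(y), "z": float(z),
                    }
                )
        if len(kinds) > 1:
            raise ChainTypingError(f"chain {chain.id!r} mixes protein and RNA residues")
        if kinds:
            chain_types[chain.id] = kinds.pop()
    if not rows:
        raise ChainTypingError("no protein or RNA residues found in model")
    return StructureComplex(pd.DataFrame(rows, columns=ATOM_COLUMNS), chain_types, model_index)


def read_structure(path: Union[str, Path], model: int = 1) -> StructureComplex:
    """Parse one model of a PDB file into a typed atom table.

    ``model`` is 1-based; a single-model file satisfies any ``model <= 1``.
    Waters are dropped; alternate locations resolve to the highest-occupancy
    conformer (first on tie, the parser default).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", str(path))
    models = list(structure)
    if model < 1 or model > len(models):
        raise ValueError(
            f"model {model} not present; file has models 1..{len(models)}"
        )
    return _complex_from_model(models[model - 1], model)


def read_all_models(path: Union[str, Path]) -> list[StructureComplex]:
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", str(path))
    return [_complex_from_model(m, i + 1) for i, m in enumerate(structure)]


def residue_contacts(
    complex: StructureComplex, cutoff: float = 4.0, heavy_only: bool = False
) -> dict[tuple[ResidueKey, ResidueKey], float]:
    """Residue-level protein-RNA contacts with minimal interatomic distance.

    A (amino acid, nucleotide) pair is a contact iff the minimum distance over
    all atom pairs is strictly below ``cutoff``. Returns contact pairs mapped
    to that minimal distance. ``heavy_only`` excludes hydrogens on both sides.
    """
    prot = complex._typed("protein", heavy_only)
    rna = complex._typed("rna", heavy_only)
    if prot.empty or rna.empty:
        raise ChainTypingError("contact analysis requires >= 1 protein and >= 1 RNA chain")
    p_xyz = prot[["x", "y", "z"]].to_numpy(float)
    r_xyz = rna[["x", "y", "z"]].to_numpy(float)
    p_keys = list(zip(prot["chain"], prot["resid"], prot["resname"]))
    r_keys = list(zip(rna["chain"], rna["resid"], rna["resname"]))

    tree = cKDTree(p_xyz)
    contacts: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for ri, neighbors in enumerate(tree.query_ball_point(r_xyz, cutoff)):
        for pi in neighbors:
            d = float(np.linalg.norm(r_xyz[ri] - p_xyz[pi]))
            if d >= cutoff:  # KD-tree ball includes the boundary; contact is strict
                continue
            key = (p_keys[pi], r_keys[ri])
            if key not in contacts or d < contacts[key]:
                contacts[key] = d
    return contacts


def contacted_nucleotides(
    complex: StructureComplex, cutoff: float = 4.0, heavy_only: bool = False
) -> int:
    """Number of distinct RNA nucleotides in at least one protein contact."""
    pairs = residue_contacts(complex, cutoff=cutoff, heavy_only=heavy_only)
    return len({rna_key for _, rna_key in pairs})


def ensemble_contacted_nucleotides(
    models: list[StructureComplex],
    cutoff: float = 4.0,
    heavy_only: bool = False,
    consensus: float = 0.5,
) -> int:
    """Nucleotides contacted in at least ``consensus`` of ensemble models."""
    if not models:
        raise ValueError("empty model list")
    counts: dict[ResidueKey, int] = {}
    for m in models:
        contacted = {rk for _, rk in residue_contacts(m, cutoff=cutoff, heavy_only=heavy_only)}
        for rk in contacted:
            counts[rk] = counts.get(rk, 0) + 1
    return sum(1 for v in counts.values() if v / len(models) >= consensus)


def contacts_frame(
    complex: StructureComplex, cutoff: float = 4.0, heavy_only: bool = False
) -> pd.DataFrame:
    rows = [
        {
            "protein_chain": pk[0], "protein_resid": pk[1], "protein_resname": pk[2],
            "rna_chain": rk[0], "rna_resid": rk[1], "rna_resname": rk[2],
            "min_distance": d,
        }
        for (pk, rk), d in sorted(residue_contacts(complex, cutoff, heavy_only).items())
    ]
    return pd.DataFrame(rows, columns=[
        "protein_chain", "protein_resid", "protein_resname",
        "rna_chain", "rna_resid", "rna_resname", "min_distance",
    ])


_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def self_structure_flag(s: RNASequence, min_stem: int = 4) -> str:
    """Heuristic hairpin-capability flag: "structured" iff the sequence holds
    two non-overlapping reverse-complementary stretches of length >= min_stem
    separated by at least 3 nt (a foldable stem-loop); otherwise
    "single_stranded". A pairing screen, not a thermodynamic folding
    prediction."""
    b = s.bases
    k = min_stem
    if len(b) < 2 * k + 3:
        return "single_stranded"
    for i in range(len(b) - 2 * k - 3 + 1):
        stem5 = b[i : i + k]
        target = "".join(_RC[c] for c in reversed(stem5))
        for j in range(i + k + 3, len(b) - k + 1):
            if b[j : j + k] == target:
                return "structured"
    return "single_stranded"


def write_pdb(complex: StructureComplex, path: Union[str, Path]) -> None:
    """Write the atom table as a minimal single-model PDB file."""
    with open(path, "w") as fh:
        fh.write(f"MODEL     {complex.model:4d}\n")
        for i, row in enumerate(complex.atoms.itertuples(index=False), start=1):
            record = "ATOM  "
            name = row.atom_name if len(row.atom_name) >= 4 else f" {row.atom_name:<3s}"
            fh.write(
                f"{record}{i:5d} {name:<4s} {row.resname:>3s} {row.chain:1s}"
                f"{row.resid:4d}    {row.x:8.3f}{row.y:8.3f}{row.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {row.element:>2s}\n"
            )
        fh.write("ENDMDL\nEND\n")
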