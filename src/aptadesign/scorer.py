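"""Interaction-propensity scorer contract and reference implementations.

A scorer maps (protein sequence, RNA sequence) to a real interaction
propensity pi; the fitness machinery downstream is scorer-agnostic, so
externally computed propensities (e.g. from a trained protein-RNA
interaction predictor) plug in through :func:`table_scorer`. The reference
scorers here capture the target's documented preference for single-stranded
GU-rich RNA; they are test instruments, not trained predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Union

import pandas as pd

from aptadesign.seqio import ProteinSequence, RNASequence


class ScoreTableError(ValueError):
    pass


class MissingScoreError(KeyError):
    pass


@dataclass(frozen=True)
class PropensityScorer:
    """Deterministic (protein, RNA) -> propensity contract.

    ``positivity_threshold`` is the propensity above which a pair counts as
    "interacting" for candidate selection; the sign convention of an external
    scorer is its own, so the threshold is configurable per scorer.
    """

    name: str
    fn: Callable[[ProteinSequence, RNASequence], float] = field(repr=False)
    positivity_threshold: float = 0.0

    def score(self, protein: ProteinSequence, rna: RNASequence) -> float:
        return float(self.fn(protein, rna))


def _gu_count(bases: str) -> int:
    return sum(1 for i in range(len(bases) - 1) if bases[i] == "G" and bases[i + 1] == "U")


def gu_motif_scorer(gu_weight: float = 1.0, u_weight: float = 0.25) -> PropensityScorer:
    """Protein-independent GU-motif propensity: pi = gu_weight * (#GU) +
    u_weight * (#U) - 0.5.

    Captures GU-dinucleotide preference for unit tests and oracles; because it
    ignores the protein argument, the protein-shuffle fitness is identically
    zero under it (every shuffle ties).
    """

    def fn(protein: ProteinSequence, rna: RNASequence) -> float:
        return gu_weight * _gu_count(rna.bases) + u_weight * rna.bases.count("U") - 0.5

    return PropensityScorer(name="gu", fn=fn)


def gu_aromatic_scorer(
    gu_weight: float = 1.0, u_weight: float = 0.25, alpha: float = 1.0
) -> PropensityScorer:
    """GU-motif propensity modulated by protein residue order.

    pi = (gu_weight * #GU + u_weight * #U - 0.5) * (1 + alpha * f), where f is
    the fraction of aromatic residues (F/Y/W) located in the N-terminal half
    of the protein. RNA-recognition-motif domains stack conserved aromatics
    against single-stranded bases, and in the tandem-RRM architecture the
    RNA-facing aromatics sit toward the N-terminal domain, so shuffling the
    chain typically disperses them and lowers the score. This gives a
    non-degenerate protein-shuffle fitness while remaining a transparent test
    instrument, not a trained predictor.
    """

    def fn(protein: ProteinSequence, rna: RNASequence) -> float:
        res = protein.residues
        n_arom = sum(res.count(a) for a in "FYW")
        if n_arom == 0:
            f = 0.0
        else:
            half = res[: len(res) // 2]
            f = sum(half.count(a) for a in "FYW") / n_arom
        rna_part = gu_weight * _gu_count(rna.bases) + u_weight * rna.bases.count("U") - 0.5
        return rna_part * (1.0 + alpha * f)

    return PropensityScorer(name="gu_aromatic", fn=fn)


def table_scorer(path: Union[str, Path], positivity_threshold: float = 0.0) -> PropensityScorer:
    """Scorer backed by a precomputed table of (protein_id, rna_sequence, score).

    Bridges externally computed propensities into the pipeline. A queried pair
    absent from the table raises :class:`MissingScoreError` -- never a silent
    default -- because a fabricated propensity would corrupt the rank-based
    fitness scores downstream.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str, "rna_sequence": str})
    required = ["protein_id", "rna_sequence", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScoreTableError(f"score table {path} is missing columns: {missing}")
    dup = df.duplicated(subset=["protein_id", "rna_sequence"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ScoreTableError(
            f"duplicate score-table key ({first['protein_id']!r}, {first['rna_sequence']!r})"
        )
    lookup = {
        (str(p), str(r)): float(s)
        for p, r, s in zip(df["protein_id"], df["rna_sequence"], df["score"])
    }

    def fn(protein: ProteinSequence, rna: RNASequence) -> float:
        key = (protein.id, rna.bases)
        if key not in lookup:
            raise MissingScoreError(
                f"no stored score for protein {protein.id!r} x RNA {rna.bases!r}"
            )
        return lookup[key]

    return PropensityScorer(
        name=f"table:{path}", fn=fn, positivity_threshold=positivity_threshold
    )


def write_score_table(rows: list[tuple[str, str, float]], path: Union[str, Path]) -> None:
    """Write (protein_id, rna_sequence, score) rows as a scorer table TSV."""
    pd.DataFrame(rows, columns=["protein_id", "rna_sequence", "score"]).to_csv(
        path, sep="\t", index=False
    )


def get_scorer(spec: str) -> PropensityScorer:
    """Resolve a CLI scorer spec: ``gu``, ``gu_aromatic`` or ``table:<path>``."""
    if spec == "gu":
        return gu_motif_scorer()
    if spec == "gu_aromatic":
        return gu_aromatic_scorer()
    if spec.startswith("table:"):
        return table_scorer(spec.split(":", 1)[1])
    raise ValueError(f"unknown scorer spec {spec!r}; use gu, gu_aromatic or table:<path>")
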