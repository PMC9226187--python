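"""Fragment generation, mutational fitness scores, candidate selection.

The two scores at the heart of the pipeline are rank statistics over pools of
perturbed inputs, with theta the strict Heaviside step:

* RNA fitness     = l^-1 sum_i theta[pi(s, P) - pi(m_i, P)] over point mutants
                    m_i of the candidate s -- 1 means no sampled single or
                    double mutation improves binding to protein P.
* Protein fitness = l^-1 sum_i theta[pi(s, P) - pi(s, P_i)] over
                    composition-preserving shuffles P_i of P -- a specificity
                    score: how much the candidate prefers the true residue
                    order over a random chain of the same composition.

Both are means of indicators and hence always in [0, 1]; both are invariant
under strictly increasing transforms of the scorer.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations, permutations, product
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from aptadesign.iclip import (
    CLIPRegion,
    merge_peaks_to_regions,
    rank_regions,
    regions_to_frame,
)
from aptadesign.scorer import PropensityScorer
from aptadesign.seqio import PeakRecord, ProteinSequence, RNASequence, write_fasta

log = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"


def heaviside(x: float) -> int:
    """Strict Heaviside step: 1 if x > 0, else 0."""
    return 1 if x > 0 else 0


@dataclass(frozen=True)
class Fragment:
    """A window-length candidate slice of a parent region."""

    parent_region_id: str
    offset: int
    sequence: str

    @property
    def fragment_id(self) -> str:
        return f"{self.parent_region_id}+{self.offset}"

    def to_rna(self) -> RNASequence:
        return RNASequence(id=self.fragment_id, bases=self.sequence)


@dataclass(frozen=True)
class FitnessConfig:
    """Pool sizes and seeding for the fitness scores.

    ``ell`` is the pool size l of both scores (default 100, mutants sampled
    without replacement; shuffles drawn independently). ``exhaustive`` uses
    the full mutant pool / all distinct permutations instead of sampling.
    """

    ell: int = 100
    seed: int = 0
    mutation_orders: tuple[int, ...] = (1, 2)
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.ell < 1:
            raise ValueError("ell must be >= 1")
        if not set(self.mutation_orders) <= {1, 2}:
            raise ValueError("mutation_orders must be a subset of {1, 2}")


@dataclass(frozen=True)
class FitnessResult:
    fragment: Fragment
    propensity: float
    rna_fitness: float
    protein_fitness: float
    pool_sizes: tuple[int, int]  # (mutant pool used, shuffle pool used)


@dataclass(frozen=True)
class CandidateAptamer:
    name: str
    sequence: str
    propensity: float
    rna_fitness: float
    protein_fitness: float
    parent_region_id: str = ""
    offset: int = 0


def substream(seed: int, *key: Union[str, int]) -> np.random.Generator:
    """Deterministic per-item RNG substream, independent of evaluation order.

    Key parts are hashed with CRC32 so the stream depends only on (seed, key),
    not on Python's per-process string hashing.
    """
    parts = [seed & 0x7FFFFFFF]
    for k in key:
        parts.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(parts))


def fragment_region(region: CLIPRegion, window: int = 10, step: int = 1) -> list[Fragment]:
    """Slide a window 5'->3' across a region; offsets 0, step, 2*step, ..."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if region.length < window:
        warnings.warn(
            f"region {region.region_id} shorter than window {window}; no fragments"
        )
        return []
    return [
        Fragment(region.region_id, off, region.sequence[off : off + window])
        for off in range(0, region.length - window + 1, step)
    ]


def enumerate_point_mutants(
    s: RNASequence, orders: Sequence[int] = (1, 2)
) -> list[RNASequence]:
    """All distinct single and/or double point mutants of ``s`` (s excluded).

    A 10-mer has 30 singles and C(10,2)*9 = 405 doubles. Mutants at distinct
    position sets are distinct sequences, so no deduplication is needed.
    """
    orders = sorted(set(orders))
    if not set(orders) <= {1, 2}:
        raise ValueError("orders must be a subset of {1, 2}")
    b = s.bases
    out: list[RNASequence] = []
    if 1 in orders:
        for i in range(len(b)):
            for alt in RNA_ALPHABET:
                if alt != b[i]:
                    out.append(RNASequence(f"{s.id}|m{i}{alt}", b[:i] + alt + b[i + 1 :]))
    if 2 in orders:
        if len(b) < 2:
            raise ValueError("double mutants require length >= 2")
        for i, j in combinations(range(len(b)), 2):
            for ai, aj in product(RNA_ALPHABET, RNA_ALPHABET):
                if ai != b[i] and aj != b[j]:
                    mut = b[:i] + ai + b[i + 1 : j] + aj + b[j + 1 :]
                    out.append(RNASequence(f"{s.id}|m{i}{ai}_{j}{aj}", mut))
    return out


def _mutant_pool(
    s: RNASequence, config: FitnessConfig, rng: np.random.Generator
) -> list[RNASequence]:
    pool = enumerate_point_mutants(s, config.mutation_orders)
    if not pool:
        raise ValueError(f"empty mutant pool for {s.id!r}")
    if config.exhaustive or len(pool) <= config.ell:
        return pool
    idx = rng.choice(len(pool), size=config.ell, replace=False)
    return [pool[i] for i in sorted(idx)]


def rna_fitness(
    s: RNASequence,
    protein: ProteinSequence,
    scorer: PropensityScorer,
    config: FitnessConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of sampled point mutants scoring strictly below ``s``."""
    value, _ = rna_fitness_detail(s, protein, scorer, config, rng)
    return value


def rna_fitness_detail(
    s: RNASequence,
    protein: ProteinSequence,
    scorer: PropensityScorer,
    config: FitnessConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """As :func:`rna_fitness`, also returning the pool size actually used."""
    if rng is None:
        rng = substream(config.seed, "rna", s.bases)
    pool = _mutant_pool(s, config, rng)
    pi_s = scorer.score(protein, s)
    hits = sum(heaviside(pi_s - scorer.score(protein, m)) for m in pool)
    return hits / len(pool), len(pool)


def shuffle_protein(protein: ProteinSequence, rng: np.random.Generator) -> ProteinSequence:
    """Uniformly random permutation of the residues (composition preserved)."""
    perm = rng.permutation(list(protein.residues))
    return ProteinSequence(id=f"{protein.id}|shuf", residues="".join(perm))


def _distinct_permutations(protein: ProteinSequence, limit: int = 50000) -> list[ProteinSequence]:
    seen = set()
    out = []
    for p in permutations(protein.residues):
        if p not in seen:
            seen.add(p)
            out.append(ProteinSequence(id=f"{protein.id}|perm{len(out)}", residues="".join(p)))
            if len(out) > limit:
                raise ValueError(
                    f"exhaustive shuffle pool for {protein.id!r} exceeds {limit} permutations"
                )
    return out


def protein_fitness(
    s: RNASequence,
    protein: ProteinSequence,
    scorer: PropensityScorer,
    config: FitnessConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of composition-preserving shuffles scoring strictly below the
    true protein. Chance re-draws of the original order are kept as
    competitors (they tie and contribute 0)."""
    value, _ = protein_fitness_detail(s, protein, scorer, config, rng)
    return value


def protein_fitness_detail(
    s: RNASequence,
    protein: ProteinSequence,
    scorer: PropensityScorer,
    config: FitnessConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    if rng is None:
        rng = substream(config.seed, "protein", s.bases)
    if config.exhaustive:
        pool = _distinct_permutations(protein)
    else:
        pool = [shuffle_protein(protein, rng) for _ in range(config.ell)]
    pi_true = scorer.score(protein, s)
    hits = sum(heaviside(pi_true - scorer.score(p, s)) for p in pool)
    return hits / len(pool), len(pool)


def reverse_complement(s: RNASequence) -> RNASequence:
    """RNA reverse complement (A<->U, C<->G, order reversed); the standard
    negative-control construction for a designed aptamer."""
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    return RNASequence(id=f"{s.id}|revcomp", bases="".join(comp[b] for b in reversed(s.bases)))


def select_candidates(
    results: Sequence[FitnessResult],
    scorer: PropensityScorer,
    min_protein_fitness: float = 0.75,
    require_rna_fitness: float = 1.0,
    strict_protein_fitness: bool = False,
) -> list[CandidateAptamer]:
    """Filter fitness results to named candidate aptamers.

    Selection keeps fragments with positive interaction propensity (strictly
    above the scorer's positivity threshold), RNA fitness equal to
    ``require_rna_fitness`` and protein fitness at or above
    ``min_protein_fitness`` (strictly above with ``strict_protein_fitness``).
    Identical sequences are deduplicated first, keeping the best
    (protein fitness, propensity) representative. Survivors are named Apt-1,
    Apt-2, ... by descending protein fitness, ties broken by descending
    propensity then lexicographic sequence.
    """
    best: dict[str, FitnessResult] = {}
    for r in results:
        cur = best.get(r.fragment.sequence)
        if cur is None or (r.protein_fitness, r.propensity) > (cur.protein_fitness, cur.propensity):
            best[r.fragment.sequence] = r
    dedup = list(best.values())

    n_in = len(results)
    survivors = []
    n_pi = n_rf = n_pf = 0
    for r in dedup:
        if not r.propensity > scorer.positivity_threshold:
            n_pi += 1
            continue
        if abs(r.rna_fitness - require_rna_fitness) > 1e-12:
            n_rf += 1
            continue
        pf_ok = (
            r.protein_fitness > min_protein_fitness
            if strict_protein_fitness
            else r.protein_fitness >= min_protein_fitness
        )
        if not pf_ok:
            n_pf += 1
            continue
        survivors.append(r)
    log.info(
        "candidate selection: %d results, %d unique sequences; dropped %d "
        "non-positive propensity, %d RNA-fitness, %d protein-fitness; kept %d",
        n_in, len(dedup), n_pi, n_rf, n_pf, len(survivors),
    )
    survivors.sort(key=lambda r: (-r.protein_fitness, -r.propensity, r.fragment.sequence))
    return [
        CandidateAptamer(
            name=f"Apt-{k + 1}",
            sequence=r.fragment.sequence,
            propensity=r.propensity,
            rna_fitness=r.rna_fitness,
            protein_fitness=r.protein_fitness,
            parent_region_id=r.fragment.parent_region_id,
            offset=r.fragment.offset,
        )
        for k, r in enumerate(survivors)
    ]


def _resize_within_parent(
    bases: str, offset: int, parent_seq: str, target: int
) -> str | None:
    """Build the length-``target`` variant of a subsequence by symmetric
    trimming or by extension alternating 3' then 5' within the parent;
    None when the parent cannot supply the requested length."""
    w = len(bases)
    if target == w:
        return bases
    if target < w:
        trim = w - target
        t3 = (trim + 1) // 2  # 3' trimmed first when odd
        t5 = trim - t3
        return bases[t5 : w - t3]
    if target > len(parent_seq):
        return None
    left, right = offset, offset + w
    grow_right = True  # 3' first
    while right - left < target:
        if grow_right and right < len(parent_seq):
            right += 1
        elif left > 0:
            left -= 1
        elif right < len(parent_seq):
            right += 1
        grow_right = not grow_right
    return parent_seq[left:right]


def length_scan(
    s: RNASequence,
    parent: CLIPRegion,
    protein: ProteinSequence,
    scorer: PropensityScorer,
    config: FitnessConfig,
    lengths: Sequence[int] = range(6, 16),
) -> pd.DataFrame:
    """Recompute both fitness scores for resized variants of a candidate.

    Used to check that the chosen window length is (near-)optimal: the
    variant of each length is built from the candidate's parent-region
    context, and rows whose length the parent cannot supply are flagged
    unavailable rather than silently shortened.
    """
    offset = parent.sequence.find(s.bases)
    if offset < 0:
        raise ValueError(f"parent region {parent.region_id} does not contain {s.bases!r}")
    rows = []
    for L in lengths:
        var = _resize_within_parent(s.bases, offset, parent.sequence, L)
        if var is None:
            rows.append({"length": L, "sequence": None, "propensity": np.nan,
                         "rna_fitness": np.nan, "protein_fitness": np.nan,
                         "available": False})
            continue
        v = RNASequence(id=f"{s.id}|len{L}", bases=var)
        rf = rna_fitness(v, protein, scorer, config)
        pf = protein_fitness(v, protein, scorer, config)
        rows.append({"length": L, "sequence": var,
                     "propensity": scorer.score(protein, v), "rna_fitness": rf,
                     "protein_fitness": pf, "available": True})
    return pd.DataFrame(rows)


@dataclass
class DesignReport:
    """End-to-end pipeline output with full provenance."""

    regions: list[CLIPRegion]
    fragments: list[Fragment]
    results: list[FitnessResult]
    candidates: list[CandidateAptamer]
    provenance: dict = field(default_factory=dict)

    def fitness_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fragment_id": r.fragment.fragment_id,
                    "parent_region_id": r.fragment.parent_region_id,
                    "offset": r.fragment.offset,
                    "sequence": r.fragment.sequence,
                    "propensity": r.propensity,
                    "rna_fitness": r.rna_fitness,
                    "protein_fitness": r.protein_fitness,
                    "mutant_pool": r.pool_sizes[0],
                    "shuffle_pool": r.pool_sizes[1],
                }
                for r in self.results
            ]
        )

    def candidate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": c.name,
                    "sequence": c.sequence,
                    "propensity": c.propensity,
                    "rna_fitness": c.rna_fitness,
                    "protein_fitness": c.protein_fitness,
                    "parent_region_id": c.parent_region_id,
                    "offset": c.offset,
                }
                for c in self.candidates
            ],
            columns=["name", "sequence", "propensity", "rna_fitness",
                     "protein_fitness", "parent_region_id", "offset"],
        )

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        regions_to_frame(self.regions).to_csv(outdir / "regions.tsv", sep="\t", index=False)
        write_fasta([f.to_rna() for f in self.fragments], outdir / "fragments.fasta")
        self.fitness_frame().to_csv(outdir / "fitness.tsv", sep="\t", index=False)
        self.candidate_frame().to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        write_fasta(
            [RNASequence(id=c.name, bases=c.sequence) for c in self.candidates],
            outdir / "candidates.fasta",
        )
        with open(outdir / "run.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")


def design_aptamers(
    peaks: Sequence[PeakRecord],
    transcripts: Mapping[str, RNASequence],
    protein: ProteinSequence,
    scorer: PropensityScorer,
    config: FitnessConfig,
    n_top_regions: int = 30,
    window: int = 10,
    step: int = 1,
    max_gap: int = 3,
    min_size: int = 50,
    min_protein_fitness: float = 0.75,
) -> DesignReport:
    """End-to-end pipeline: merge peaks -> rank regions -> fragment the top
    regions -> score -> fitness -> select and name candidates.

    Per-fragment RNG substreams are derived from (seed, fragment sequence),
    so results do not depend on evaluation order and identical seeds
    reproduce the report byte-for-byte.
    """
    regions = rank_regions(merge_peaks_to_regions(peaks, transcripts, max_gap, min_size))
    if n_top_regions > len(regions):
        warnings.warn(
            f"requested top {n_top_regions} regions but only {len(regions)} available; using all"
        )
    top = regions[:n_top_regions]
    fragments: list[Fragment] = []
    for r in top:
        fragments.extend(fragment_region(r, window=window, step=step))
    log.info("pipeline: %d regions (%d kept), %d fragments", len(regions), len(top), len(fragments))

    results: list[FitnessResult] = []
    for f in fragments:
        s = f.to_rna()
        pi = scorer.score(protein, s)
        rf, n_mut = rna_fitness_detail(s, protein, scorer, config)
        pf, n_shuf = protein_fitness_detail(s, protein, scorer, config)
        results.append(FitnessResult(f, pi, rf, pf, (n_mut, n_shuf)))

    candidates = select_candidates(
        results, scorer, min_protein_fitness=min_protein_fitness
    )
    from aptadesign import __version__

    provenance = {
        "tool": "aptadesign",
        "version": __version__,
        "seed": config.seed,
        "ell": config.ell,
        "exhaustive": config.exhaustive,
        "mutation_orders": list(config.mutation_orders),
        "scorer": scorer.name,
        "protein_id": protein.id,
        "window": window,
        "step": step,
        "max_gap": max_gap,
        "min_size": min_size,
        "n_top_regions": n_top_regions,
        "n_regions_found": len(regions),
        "n_fragments": len(fragments),
        "n_candidates": len(candidates),
    }
    return DesignReport(list(top), fragments, results, candidates, provenance)
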