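"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the most naive route
available (all-pairs scans, exhaustive enumeration) so they stay independent
of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from aptadesign import (
    FitnessConfig,
    FixtureSpec,
    PeakRecord,
    RNASequence,
    generate_fixture,
    gu_motif_scorer,
)

RNA_ALPHABET = "ACGU"


@pytest.fixture
def gu_scorer():
    return gu_motif_scorer()


@pytest.fixture
def exhaustive_config():
    return FitnessConfig(ell=100, seed=7, exhaustive=True)


@pytest.fixture
def small_fixture():
    return generate_fixture(FixtureSpec(seed=11))


def random_rna(rng: np.random.Generator, length: int, id: str = "s") -> RNASequence:
    return RNASequence(id=id, bases="".join(rng.choice(list(RNA_ALPHABET), size=length)))


# ---------------------------------------------------------------- oracles


def oracle_merge(peaks: list[PeakRecord], max_gap: int, min_size: int):
    """Brute-force region merge: connected components over all peak pairs."""
    out = []
    by_tx: dict[str, list[int]] = {}
    for p in peaks:
        by_tx.setdefault(p.transcript_id, []).append(p.position)
    reads = {(p.transcript_id, p.position): 0 for p in peaks}
    for p in peaks:
        reads[(p.transcript_id, p.position)] += p.reads
    for tx, positions in sorted(by_tx.items()):
        positions = sorted(set(positions))
        n = len(positions)
        # transitive closure of the "within max_gap+1" relation
        adj = np.zeros((n, n), dtype=bool)
        for i, j in itertools.product(range(n), range(n)):
            adj[i, j] = abs(positions[i] - positions[j]) <= max_gap + 1
        reach = adj.copy()
        for _ in range(n):
            reach = reach | (reach @ reach)
        seen = set()
        for i in range(n):
            if i in seen:
                continue
            comp = {j for j in range(n) if reach[i, j]}
            seen |= comp
            members = sorted(positions[j] for j in comp)
            start, end = members[0], members[-1] + 1
            if end - start < min_size:
                continue
            total = sum(reads[(tx, m)] for m in members)
            out.append((tx, start, end, total / (end - start)))
    return sorted(out)


def oracle_auc(pos_scores, neg_scores) -> float:
    """Pair-counting AUC: concordant pairs count 1, ties 0.5."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos_scores) * len(neg_scores))


def oracle_rank_fitness(pi_s: float, pool_scores) -> float:
    """|{i : pi(i) < pi(s)}| / |pool|."""
    return sum(1 for x in pool_scores if x < pi_s) / len(pool_scores)


def oracle_signed_rank_p(diffs: np.ndarray) -> float:
    """Exhaustive sign-flip two-sided signed-rank p with hand-rolled midranks."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(absd))
    i = 0
    sorted_abs = absd[order]
    pos = 1
    while i < len(absd):
        j = i
        while j < len(absd) and sorted_abs[j] == sorted_abs[i]:
            j += 1
        midrank = (pos + (pos + (j - i) - 1)) / 2
        for k in range(i, j):
            ranks[order[k]] = midrank
        pos += j - i
        i = j
    w_obs = ranks[diffs > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2 * min(p_low, p_high)))


def oracle_contacts(complex, cutoff: float, heavy_only: bool = False):
    """All-pairs atom distance scan for residue contacts."""
    atoms = complex.atoms
    if heavy_only:
        atoms = atoms[atoms["element"].str.upper() != "H"]
    prot = atoms[atoms["chain"].map(complex.chain_types) == "protein"]
    rna = atoms[atoms["chain"].map(complex.chain_types) == "rna"]
    pairs = set()
    for pa in prot.itertuples():
        for ra in rna.itertuples():
            d = ((pa.x - ra.x) ** 2 + (pa.y - ra.y) ** 2 + (pa.z - ra.z) ** 2) ** 0.5
            if d < cutoff:
                pairs.add(((pa.chain, pa.resid, pa.resname), (ra.chain, ra.resid, ra.resname)))
    return pairs


def candidate_transcript_interval(candidate, window: int = 10):
    """Map a candidate back to transcript coordinates via its provenance."""
    tx, span = candidate.parent_region_id.split(":")
    start = int(span.split("-")[0])
    lo = start + candidate.offset
    return tx, lo, lo + window
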