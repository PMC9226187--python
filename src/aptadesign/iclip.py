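"""Peak-to-region processing, labeled-set construction, AUC and GU-enrichment.

A *region* is a maximal run of peaks on one transcript in which consecutive
peaks are separated by at most ``max_gap`` intervening nucleotides (default 3);
runs shorter than ``min_size`` nucleotides (default 50) are discarded. The
region's iCLIP score is the sum of its member reads divided by its length, a
per-nucleotide binding-evidence density used to rank regions as design
templates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from aptadesign.seqio import PeakRecord, ProteinSequence, RNASequence
from aptadesign.scorer import PropensityScorer

log = logging.getLogger(__name__)


class UnknownTranscriptError(KeyError):
    pass


class CapacityError(ValueError):
    """Requested more labeled pairs than the data can supply."""


@dataclass(frozen=True)
class CLIPRegion:
    """A contiguous transcript interval with per-nucleotide binding evidence.

    ``start``/``end`` are 0-based half-open transcript coordinates;
    ``iclip_score`` is total member reads divided by region length.
    """

    transcript_id: str
    start: int
    end: int
    sequence: str
    iclip_score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("region sequence length must equal end - start")
        if self.iclip_score < 0:
            raise ValueError("iclip_score must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"

    def to_rna(self) -> RNASequence:
        return RNASequence(id=self.region_id, bases=self.sequence)


@dataclass
class LabeledSet:
    """Paired positive (top-scoring) and negative (peak-free) regions.

    Negative k has the same length as positive k and contains no peak
    nucleotide, so paired analyses are length-matched by construction.
    """

    positives: list[CLIPRegion]
    negatives: list[CLIPRegion]

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positives and negatives must be paired (equal lengths)")


def merge_peaks_to_regions(
    peaks: Sequence[PeakRecord],
    transcripts: Mapping[str, RNASequence],
    max_gap: int = 3,
    min_size: int = 50,
) -> list[CLIPRegion]:
    """Merge peaks into contiguous scored regions.

    Peaks on the same transcript with at most ``max_gap`` intervening
    nucleotides (position difference <= max_gap + 1) join one region spanning
    first to last member peak. Regions shorter than ``min_size`` are dropped.
    """
    by_tx: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        if p.transcript_id not in transcripts:
            raise UnknownTranscriptError(
                f"peak references unknown transcript {p.transcript_id!r}"
            )
        if p.position >= len(transcripts[p.transcript_id]):
            raise ValueError(
                f"peak position {p.position} outside transcript {p.transcript_id!r}"
            )
        by_tx.setdefault(p.transcript_id, []).append(p)

    regions: list[CLIPRegion] = []
    for tx_id in sorted(by_tx):
        tx_peaks = sorted(by_tx[tx_id], key=lambda p: p.position)
        runs: list[list[PeakRecord]] = [[tx_peaks[0]]]
        for p in tx_peaks[1:]:
            if p.position - runs[-1][-1].position <= max_gap + 1:
                runs[-1].append(p)
            else:
                runs.append([p])
        for run in runs:
            start, end = run[0].position, run[-1].position + 1
            if end - start < min_size:
                continue
            total = sum(p.reads for p in run)
            seq = transcripts[tx_id].bases[start:end]
            regions.append(
                CLIPRegion(tx_id, start, end, seq, total / (end - start))
            )
    return regions


def rank_regions(regions: Sequence[CLIPRegion]) -> list[CLIPRegion]:
    """Sort by iclip_score descending; ties broken by (transcript_id, start)."""
    return sorted(regions, key=lambda r: (-r.iclip_score, r.transcript_id, r.start))


def _peak_free_intervals(
    transcripts: Mapping[str, RNASequence], peaks: Sequence[PeakRecord]
) -> list[tuple[str, int, int]]:
    """Maximal peak-free intervals per transcript, in (tx, start) order."""
    occupied: dict[str, set[int]] = {t: set() for t in transcripts}
    for p in peaks:
        occupied[p.transcript_id].add(p.position)
    out = []
    for tx_id in sorted(transcripts):
        L = len(transcripts[tx_id])
        occ = occupied[tx_id]
        start = None
        for i in range(L + 1):
            free = i < L and i not in occ
            if free and start is None:
                start = i
            elif not free and start is not None:
                out.append((tx_id, start, i))
                start = None
    return out


def build_labeled_set(
    regions: Sequence[CLIPRegion],
    transcripts: Mapping[str, RNASequence],
    peaks: Sequence[PeakRecord],
    n: int = 100,
) -> LabeledSet:
    """Top-``n`` regions by iCLIP score paired with length-matched peak-free
    stretches of the same transcriptome.

    Negative stretches are allocated deterministically, leftmost-first in
    transcript-id order, and never overlap any peak nucleotide or each other.
    """
    ranked = rank_regions(regions)
    if len(ranked) < n:
        raise CapacityError(
            f"requested {n} positives but only {len(ranked)} regions available"
        )
    positives = ranked[:n]

    free = _peak_free_intervals(transcripts, peaks)  # consumed left to right
    negatives: list[CLIPRegion] = []
    cursors = [[tx, s, e] for tx, s, e in free]
    for k, pos in enumerate(positives):
        need = pos.length
        placed = False
        for iv in cursors:
            tx, s, e = iv
            if e - s >= need:
                seq = transcripts[tx].bases[s : s + need]
                negatives.append(CLIPRegion(tx, s, s + need, seq, 0.0))
                iv[1] = s + need
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place negative stretch {k} of length {need}; "
                f"achievable n = {len(negatives)}"
            )
    return LabeledSet(positives=positives, negatives=negatives)


def mannwhitney_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """ROC AUC via the Mann-Whitney rank formulation, ties credited 0.5."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def auc_discrimination(
    labeled: LabeledSet,
    scorer: PropensityScorer,
    protein: ProteinSequence,
    n_values: Sequence[int],
) -> pd.DataFrame:
    """AUC of propensity scores discriminating binding from peak-free regions.

    For each n, the n highest-iCLIP positives are compared with the n
    lowest-iCLIP negatives; smaller n isolates the strongest-signal regions,
    so AUC as a function of n traces how discrimination improves with signal
    strength.
    """
    pos_sorted = sorted(labeled.positives, key=lambda r: (-r.iclip_score, r.transcript_id, r.start))
    neg_sorted = sorted(labeled.negatives, key=lambda r: (r.iclip_score, r.transcript_id, r.start))
    rows = []
    for n in n_values:
        if n < 1 or n > len(pos_sorted):
            raise ValueError(f"n = {n} exceeds available positives ({len(pos_sorted)})")
        p_scores = [scorer.score(protein, r.to_rna()) for r in pos_sorted[:n]]
        n_scores = [scorer.score(protein, r.to_rna()) for r in neg_sorted[:n]]
        rows.append({"n": n, "auc": mannwhitney_auc(p_scores, n_scores)})
    return pd.DataFrame(rows)


def count_gu_repeats(seq: RNASequence, runs: bool = False) -> int:
    """Number of GU dinucleotide occurrences in ``seq``.

    With ``runs=True``, counts maximal (GU)n runs with n >= 2 instead of
    individual dinucleotides.
    """
    b = seq.bases
    if not runs:
        return sum(1 for i in range(len(b) - 1) if b[i] == "G" and b[i + 1] == "U")
    count = 0
    i = 0
    while i < len(b) - 1:
        n = 0
        while i + 2 * (n + 1) <= len(b) and b[i + 2 * n : i + 2 * n + 2] == "GU":
            n += 1
        if n >= 2:
            count += 1
        i += max(2 * n, 1)
    return count


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by exhaustive sign-flip enumeration (midranks)."""
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(ranks)
    # all 2^n sign assignments; W+ = sum of ranks given positive sign
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    w_all = signs @ ranks
    p_low = np.mean(w_all <= w_obs + 1e-12)
    p_high = np.mean(w_all >= w_obs - 1e-12)
    return float(min(1.0, 2 * min(p_low, p_high)))


def gu_enrichment_test(
    top_counts: Sequence[int],
    bottom_counts: Sequence[int],
    paired: bool = True,
) -> float:
    """Two-sided Wilcoxon test for GU-count enrichment in top vs bottom regions.

    Paired by rank position (k-th top vs k-th bottom) by default; zero
    differences are dropped per standard signed-rank practice. For n <= 16
    pairs after zero removal the p-value is computed by exhaustive sign-flip
    enumeration over midranks (exact under ties); larger samples use
    :func:`scipy.stats.wilcoxon`. ``paired=False`` gives the unpaired
    Mann-Whitney rank-sum variant.
    """
    top = np.asarray(top_counts, dtype=float)
    bottom = np.asarray(bottom_counts, dtype=float)
    if not paired:
        return float(stats.mannwhitneyu(top, bottom, alternative="two-sided").pvalue)
    if len(top) != len(bottom):
        raise ValueError("paired test requires equal-length count lists")
    diffs = top - bottom
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        warnings.warn("all paired differences are zero; returning p = 1.0")
        return 1.0
    if len(diffs) == 1:
        warnings.warn("only one nonzero paired difference; p from the 2-point null")
        return _exact_signed_rank_p(diffs)
    if len(diffs) <= 16:
        return _exact_signed_rank_p(diffs)
    return float(stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided").pvalue)


REGION_COLUMNS = ["transcript_id", "start", "end", "length", "iclip_score", "sequence"]


def regions_to_frame(regions: Sequence[CLIPRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "iclip_score": r.iclip_score,
                "sequence": r.sequence,
            }
            for r in regions
        ],
        columns=REGION_COLUMNS,
    )


def frame_to_regions(df: pd.DataFrame) -> list[CLIPRegion]:
    return [
        CLIPRegion(str(row.transcript_id), int(row.start), int(row.end),
                   str(row.sequence), float(row.iclip_score))
        for row in df.itertuples()
    ]
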