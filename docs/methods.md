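# Methods

## Pipeline overview

The package designs short single-stranded RNA aptamers against an
RNA-binding protein from iCLIP-style binding evidence. The stages are:

1. **Region construction.** Crosslink peaks (transcript, 0-based position,
   read count) on the same transcript are merged whenever at most `max_gap`
   nucleotides (default 3) lie between consecutive peaks; merged runs
   shorter than `min_size` (default 50 nt) are discarded. Each region gets
   an iCLIP score: sum of member reads divided by region length. All
   coordinates are 0-based half-open.
2. **Discrimination check.** The top-n regions by iCLIP score are paired
   with length-matched, peak-free stretches of the same transcriptome, and
   the propensity scorer's ability to separate them is summarised as the
   ROC AUC, computed by the Mann–Whitney rank formulation with ties
   credited 0.5. Sweeping n from large to small isolates progressively
   stronger-signal regions.
3. **Fragmentation.** The top `n_top_regions` (default 30) regions are cut
   with a sliding window (default 10 nt, step 1) from 5′ to 3′.
4. **Fitness scoring.** Every fragment receives the two rank scores
   described in the README: RNA Fitness over a pool of single- and
   double-point mutants, Protein Fitness over composition-preserving
   shuffles of the target protein.
5. **Selection and naming.** Candidates need strictly positive propensity,
   RNA Fitness exactly 1 and Protein Fitness ≥ 0.75; the threshold is
   inclusive because a candidate sitting exactly at 0.75 is still the
   weakest admissible specificity, and a strict variant is available via a
   flag. Winners are named Apt-k by descending Protein Fitness, with ties
   broken by descending propensity and then lexicographic sequence so the
   ordering is total and reproducible.

## Interaction-propensity scorers

The propensity π(s, P) is a contract: any deterministic map from a
(protein, RNA) pair to a real number. Trained protein–RNA interaction
predictors are intentionally out of scope; their output enters through the
score-table bridge, which refuses to invent values for missing pairs. Two
reference scorers ship with the package:

* `gu` — π = w₁·(#GU dinucleotides) + w₂·(#U) − 0.5 with w₁ = 1, w₂ = 0.25.
  Protein-blind by construction; under it every protein shuffle ties, so
  Protein Fitness is identically 0. Useful for exact oracles.
* `gu_aromatic` — the same RNA term multiplied by (1 + α·f), where f is the
  fraction of the protein's aromatic residues (F/Y/W) falling in its
  N-terminal half. RRM domains stack conserved aromatics against
  single-stranded bases, and in a tandem-RRM architecture the RNA-facing
  aromatics cluster toward the N-terminal domain; shuffling the chain
  disperses them, so the true sequence usually outranks its shuffles. This
  makes Protein Fitness non-degenerate while remaining a transparent test
  instrument, not a binding predictor.

"Positive interaction propensity" means π strictly above the scorer's
`positivity_threshold` (default 0); the sign convention of an external
scorer is its own, so the threshold travels with the scorer.

## Fitness pools and sampling

* The full mutant pool of an n-mer holds 3n singles and 9·C(n,2) doubles
  (435 for n = 10). With ℓ = 100 (default) mutants are drawn uniformly
  without replacement; `exhaustive` uses the whole pool and the pool size
  actually used is recorded in every output row. Sampling without
  replacement makes the sampled score an unbiased estimate of the
  exhaustive rank fraction with sub-binomial variance.
* Protein shuffles are independent uniform permutations; a draw that
  happens to reproduce the original order is kept (it ties and contributes
  0), keeping the null exactly uniform over permutations. Exhaustive mode
  enumerates distinct permutations and is guarded against combinatorial
  blow-up, so it is only for short test proteins.
* Randomness: one seeded generator per (seed, purpose, fragment sequence),
  derived via CRC32-hashed spawn keys. Results are therefore independent
  of evaluation order, and identical seeds reproduce all outputs byte for
  byte.

## Length scan

To check that the design window is well chosen, a candidate is rebuilt at
every length in 6–15 nt from its parent-region context: shrinking trims
symmetrically (3′ first on odd trims), growing extends alternately 3′ then
5′ while the region has context, and lengths the region cannot supply are
flagged unavailable rather than silently shortened. Because short perfect
GU repeats are also unimprovable (RNA Fitness 1), fitness alone ties across
several lengths; the scan therefore ranks lengths by (RNA Fitness,
propensity), preferring the strongest binder among unimprovable variants —
the same tie-break used in candidate naming.

## Structural contact analysis

A residue-level contact is an (amino acid, nucleotide) pair with any
interatomic distance strictly below 4 Å. All atoms are used by default,
hydrogens included when the deposition provides them, with a `heavy_only`
flag because deposition practice varies; for NMR ensembles the default is
model 1, with an ensemble-consensus option counting a nucleotide when it is
contacted in at least a fraction f (default 0.5) of models. The count of
distinct contacted nucleotides in a deposited complex of the target protein
bound to a GU-rich oligonucleotide is the empirical anchor for the 10-nt
window default. A companion heuristic flags sequences capable of forming a
hairpin (two non-overlapping reverse-complementary stretches of ≥ 4 nt
separated by ≥ 3 nt); it is a pairing screen for single-strandedness, not a
thermodynamic folding prediction.

## Statistical tests

GU-dinucleotide enrichment between top- and bottom-ranked regions uses a
two-sided Wilcoxon signed-rank test paired by rank position (the k-th top
region against the k-th bottom region), dropping zero differences. Counts
tie heavily, so for up to 16 informative pairs the p-value is computed by
exhaustive sign-flip enumeration over midranks (exact under ties); larger
samples fall back to the scipy implementation. An unpaired rank-sum variant
is available behind a flag. "GU repetitions" are counted as GU-dinucleotide
occurrences (which cannot overlap); a variant counting maximal (GU)ₙ runs
with n ≥ 2 sits behind a flag.

## Synthetic data generator

The fixture generator emulates the shape of the real input at toy scale:
uniform-random transcripts carrying non-overlapping GU-enriched islands
(default: 8 transcripts × 1500 nt, 8 islands of 60 nt, GU enrichment 0.9).
Island nucleotides are fully covered by peaks whose read counts are Poisson
with mean 5 per covered nucleotide; the background is sparsely covered
(2 % of nucleotides) at mean 0.5 reads — a 10× read-rate contrast. GU
enrichment plants GU dinucleotides at random even offsets until the target
fraction of island nucleotides is covered, so enrichment 1.0 yields exact
(GU)ₙ islands and island length is always preserved. Everything is
determined by the spec plus its seed, and the ground-truth island table is
emitted alongside the data.

What the generator does **not** model: crosslink truncation biology, PCR
duplicates, transcript-abundance confounding, and any realistic propensity
landscape — the reference scorers are motif counters. Passing tests
therefore demonstrate that the machinery (merging, ranking, fitness,
selection, contacts) is correct and reproducible, not that the reference
scorers would discover binders in real data; for real use, plug in an
external propensity model via the score table.

## Problem sizes and numerical choices

The default test and acceptance runs use the fixture scale above with
ℓ = 100 pools, 10–20 generator seeds per property, exhaustive pools
(435 mutants, 12 permutations) wherever an exact oracle exists, and 10-nt
windows over 8 regions (≈ 400 fragments per run) — sizes chosen so the
whole suite completes in a couple of minutes on one core while keeping
every statistical check at full pool size. Fitness comparisons use strict
inequality as defined (θ[0] = 0); no floating-point tolerance is applied to
the rank indicators because propensities enter as exact arithmetic on
counts. Selection compares RNA Fitness to its target within 1e-12 to absorb
division artifacts only.

## Known limitations

* Protein Fitness under a protein-blind scorer is identically 0; candidate
  selection then rejects everything, by design. Use a protein-aware scorer.
* The exhaustive shuffle pool is limited to short proteins; long proteins
  always use sampling.
* The hairpin flag ignores G·U wobble pairing and loop energetics.
* PDB parsing resolves altlocs to the highest-occupancy conformer and
  recognises the standard amino acids plus common RNA residue synonyms;
  exotic residues require renaming upstream.
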