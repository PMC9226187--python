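import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptadesign import (
    CLIPRegion,
    FitnessConfig,
    FixtureSpec,
    Fragment,
    ProteinSequence,
    PropensityScorer,
    RNASequence,
    design_aptamers,
    enumerate_point_mutants,
    fragment_region,
    generate_fixture,
    gu_aromatic_scorer,
    gu_motif_scorer,
    heaviside,
    length_scan,
    protein_fitness,
    reverse_complement,
    rna_fitness,
    select_candidates,
    shuffle_protein,
)
from aptadesign.design import FitnessResult, protein_fitness_detail, rna_fitness_detail, substream

from conftest import candidate_transcript_interval, oracle_rank_fitness, random_rna

PROT = ProteinSequence(id="P", residues="MRRK")
rna_strategy = st.text(alphabet="ACGU", min_size=1, max_size=25).map(
    lambda b: RNASequence(id="h", bases=b)
)


@pytest.mark.parametrize("x, expected", [(0.5, 1), (0.0, 0), (-1e-12, 0), (1e-12, 1)])
def test_heaviside_is_strict(x, expected):
    assert heaviside(x) == expected


class TestFragmentation:
    def _region(self, length, seed=0):
        rng = np.random.default_rng(seed)
        return CLIPRegion("tx", 100, 100 + length, random_rna(rng, length).bases, 2.0)

    def test_window_count(self):
        frags = fragment_region(self._region(50), window=10, step=1)
        assert len(frags) == 41
        assert [f.offset for f in frags] == list(range(41))
        region = self._region(50)
        for f in fragment_region(region, 10):
            assert f.sequence == region.sequence[f.offset : f.offset + 10]

    def test_window_equal_length_single_fragment(self):
        region = self._region(10)
        (frag,) = fragment_region(region, window=10)
        assert frag.sequence == region.sequence and frag.offset == 0

    def test_too_short_region_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert fragment_region(self._region(9), window=10) == []

    def test_step_thins_offsets(self):
        frags = fragment_region(self._region(50), window=10, step=5)
        assert [f.offset for f in frags] == [0, 5, 10, 15, 20, 25, 30, 35, 40]


class TestMutants:
    def test_ten_mer_pool_size(self):
        s = RNASequence(id="s", bases="GUGUGAAUGA")
        pool = enumerate_point_mutants(s)
        assert len(pool) == 10 * 3 + math.comb(10, 2) * 9 == 435
        assert len({m.bases for m in pool}) == 435
        assert s.bases not in {m.bases for m in pool}

    def test_single_base_orders_one(self):
        pool = enumerate_point_mutants(RNASequence(id="s", bases="A"), orders=(1,))
        assert sorted(m.bases for m in pool) == ["C", "G", "U"]

    @settings(max_examples=25, deadline=None)
    @given(rna_strategy)
    def test_hamming_distance_bounded(self, s):
        if len(s) < 2:
            return
        for m in enumerate_point_mutants(s):
            d = sum(a != b for a, b in zip(s.bases, m.bases))
            assert d in (1, 2)


class TestRNAFitness:
    def test_constant_scorer_gives_zero(self, exhaustive_config):
        const = PropensityScorer(name="const", fn=lambda p, r: 1.0)
        s = RNASequence(id="s", bases="GUGUGAAUGA")
        assert rna_fitness(s, PROT, const, exhaustive_config) == 0.0

    def test_gu_repeat_ten_mer_is_unimprovable(self, gu_scorer, exhaustive_config):
        s = RNASequence(id="s", bases="GUGUGUGUGU")
        assert rna_fitness(s, PROT, gu_scorer, exhaustive_config) == 1.0

    def test_poly_a_ten_mer_is_minimal(self, gu_scorer, exhaustive_config):
        s = RNASequence(id="s", bases="AAAAAAAAAA")
        assert rna_fitness(s, PROT, gu_scorer, exhaustive_config) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_matches_rank_oracle(self, seed, gu_scorer, exhaustive_config):
        rng = np.random.default_rng(seed)
        s = random_rna(rng, int(rng.integers(6, 13)))
        got = rna_fitness(s, PROT, gu_scorer, exhaustive_config)
        pool = enumerate_point_mutants(s)
        expected = oracle_rank_fitness(
            gu_scorer.score(PROT, s), [gu_scorer.score(PROT, m) for m in pool]
        )
        assert got == expected

    def test_invariant_under_strictly_increasing_transform(self, gu_scorer, exhaustive_config):
        """Rank statistic: any strictly increasing rescaling of the scorer
        leaves the fitness unchanged."""
        warped = PropensityScorer(
            name="warped", fn=lambda p, r: math.exp(0.7 * gu_scorer.score(p, r)) + 3
        )
        for seed in range(5):
            s = random_rna(np.random.default_rng(seed), 8)
            assert rna_fitness(s, PROT, gu_scorer, exhaustive_config) == rna_fitness(
                s, PROT, warped, exhaustive_config
            )

    def test_sampled_pool_size_recorded_and_reproducible(self, gu_scorer):
        cfg = FitnessConfig(ell=100, seed=5)
        s = RNASequence(id="s", bases="GUGAAUGUAC")
        v1, n1 = rna_fitness_detail(s, PROT, gu_scorer, cfg)
        v2, n2 = rna_fitness_detail(s, PROT, gu_scorer, cfg)
        assert (v1, n1) == (v2, n2)
        assert n1 == 100
        exhaustive = rna_fitness(s, PROT, gu_scorer, FitnessConfig(ell=100, seed=5, exhaustive=True))
        sigma = math.sqrt(exhaustive * (1 - exhaustive) / 100)
        assert abs(v1 - exhaustive) <= 4 * sigma

    def test_small_pool_falls_back_to_exhaustive(self, gu_scorer):
        cfg = FitnessConfig(ell=100, seed=1)
        s = RNASequence(id="s", bases="GUA")  # 9 singles + 27 doubles = 36 < 100
        _, n = rna_fitness_detail(s, PROT, gu_scorer, cfg)
        assert n == 36


class TestProteinFitness:
    def test_shuffle_preserves_composition_and_length(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            shuf = shuffle_protein(PROT, rng)
            assert sorted(shuf.residues) == sorted(PROT.residues)

    def test_all_distinct_permutations_reachable(self):
        rng = np.random.default_rng(1)
        seen = {shuffle_protein(PROT, rng).residues for _ in range(500)}
        assert len(seen) == 12  # 4!/2! distinct orderings of MRRK

    def test_protein_blind_scorer_gives_zero(self, gu_scorer):
        s = RNASequence(id="s", bases="GUGUGU")
        cfg = FitnessConfig(ell=50, seed=2)
        assert protein_fitness(s, PROT, gu_scorer, cfg) == 0.0

    def test_first_residue_scorer_exhaustive_is_three_quarters(self):
        """3 of the 12 distinct MRRK permutations start with M and tie; the
        other 9 score strictly lower, so the exhaustive fitness is 9/12."""
        scorer = PropensityScorer(
            name="first-res",
            fn=lambda p, r: (r.bases.count("GU")) if p.residues.startswith("M") else 0.0,
        )
        s = RNASequence(id="s", bases="GUGU")
        cfg = FitnessConfig(ell=100, seed=0, exhaustive=True)
        value, n = protein_fitness_detail(s, PROT, scorer, cfg)
        assert n == 12
        assert value == 9 / 12

    def test_bounded_for_arbitrary_scorer(self):
        rng = np.random.default_rng(3)
        wild = PropensityScorer(name="wild", fn=lambda p, r: hash(p.residues) % 17 - 8)
        cfg = FitnessConfig(ell=30, seed=4)
        for _ in range(5):
            s = random_rna(rng, 8)
            assert 0.0 <= protein_fitness(s, PROT, wild, cfg) <= 1.0


class TestReverseComplement:
    def test_known_sequence(self):
        s = RNASequence(id="s", bases="GUGUGAAUGAAU")
        assert reverse_complement(s).bases == "AUUCAUUCACAC"

    def test_single_base(self):
        assert reverse_complement(RNASequence(id="s", bases="A")).bases == "U"

    @settings(max_examples=50, deadline=None)
    @given(rna_strategy)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)).bases == s.bases


class TestSelection:
    def _result(self, seq, pf, rf, pi, offset=0):
        return FitnessResult(Fragment("r:0-50", offset, seq), pi, rf, pf, (435, 100))

    def test_stated_criteria_and_naming(self, gu_scorer):
        results = [
            self._result("GUGUGUGUGU", 0.99, 1.0, 5.0),
            self._result("GUGUGUGUAA", 0.80, 0.9, 4.0),
            self._result("GUGUGUGAAA", 0.76, 1.0, 3.0),
        ]
        cands = select_candidates(results, gu_scorer)
        assert [c.name for c in cands] == ["Apt-1", "Apt-2"]
        assert cands[0].sequence == "GUGUGUGUGU" and cands[1].sequence == "GUGUGUGAAA"

    def test_nonpositive_propensity_never_selected(self, gu_scorer):
        results = [self._result("AUAUAUAUAU", 1.0, 1.0, 0.0),
                   self._result("ACACACACAC", 1.0, 1.0, -2.0)]
        assert select_candidates(results, gu_scorer) == []

    def test_boundary_protein_fitness_inclusive_by_default(self, gu_scorer):
        results = [self._result("GUGUGUGUGU", 0.75, 1.0, 5.0)]
        assert len(select_candidates(results, gu_scorer)) == 1
        assert select_candidates(results, gu_scorer, strict_protein_fitness=True) == []

    def test_duplicate_sequences_deduplicated_keeping_best(self, gu_scorer):
        results = [
            self._result("GUGUGUGUGU", 0.80, 1.0, 5.0, offset=3),
            self._result("GUGUGUGUGU", 0.95, 1.0, 5.0, offset=9),
        ]
        (cand,) = select_candidates(results, gu_scorer)
        assert cand.protein_fitness == 0.95 and cand.offset == 9

    def test_output_invariant_to_input_order(self, gu_scorer):
        rng = np.random.default_rng(6)
        results = [
            self._result(random_rna(rng, 10, f"s{i}").bases,
                         float(rng.choice([0.7, 0.8, 1.0])),
                         float(rng.choice([0.9, 1.0])),
                         float(rng.normal()), offset=i)
            for i in range(20)
        ]
        a = select_candidates(results, gu_scorer)
        b = select_candidates(list(reversed(results)), gu_scorer)
        assert a == b


class TestLengthScan:
    def _parent_and_core(self):
        parent = CLIPRegion("tx", 0, 58, "AAAACCCCAAAAACCCAAAAAAAA"
                            + "GUGUGUGUGU" + "AAAACCAAAAACCCAAAAACCCAA", 2.0)
        core = RNASequence(id="core", bases="GUGUGUGUGU")
        return parent, core

    def test_native_length_row_reproduces_fitness(self, gu_scorer, exhaustive_config):
        parent, core = self._parent_and_core()
        table = length_scan(core, parent, PROT, gu_scorer, exhaustive_config)
        row = table[table["length"] == 10].iloc[0]
        assert row["sequence"] == core.bases
        assert row["rna_fitness"] == rna_fitness(core, PROT, gu_scorer, exhaustive_config)

    def test_design_window_is_scan_optimum_on_gu_maximal_core(self, gu_scorer, exhaustive_config):
        """When the 10-mer is the unique GU-maximal window of its region, no
        scanned length beats it: extensions add mutable non-GU context."""
        parent, core = self._parent_and_core()
        table = length_scan(core, parent, PROT, gu_scorer, exhaustive_config)
        avail = table[table["available"]]
        best = avail["rna_fitness"].max()
        assert avail[avail["length"] == 10]["rna_fitness"].iloc[0] == best == 1.0
        longer = avail[avail["length"] > 10]["rna_fitness"]
        assert (longer < 1.0).all()
        # among fitness-tied shorter GU repeats, the 10-mer is the strongest binder
        ranked = avail.sort_values(["rna_fitness", "propensity", "length"],
                                   ascending=False)
        assert ranked.iloc[0]["length"] == 10

    def test_unavailable_lengths_flagged_not_shortened(self, gu_scorer, exhaustive_config):
        parent = CLIPRegion("tx", 0, 12, "AAGUGUGUGUGU", 2.0)
        core = RNASequence(id="core", bases="GUGUGUGUGU")
        table = length_scan(core, parent, PROT, gu_scorer, exhaustive_config,
                            lengths=range(6, 16))
        unavailable = table[~table["available"]]
        assert list(unavailable["length"]) == [13, 14, 15]
        assert unavailable["sequence"].isna().all()

    def test_variants_stay_within_parent(self, gu_scorer, exhaustive_config):
        parent, core = self._parent_and_core()
        table = length_scan(core, parent, PROT, gu_scorer, exhaustive_config)
        for row in table[table["available"]].itertuples():
            assert row.sequence in parent.sequence
            assert len(row.sequence) == row.length


class TestPipeline:
    def test_top_candidate_overlaps_truth_island(self):
        fx = generate_fixture(FixtureSpec(seed=3))
        cfg = FitnessConfig(ell=100, seed=3)
        report = design_aptamers(fx.peaks, fx.transcripts, fx.protein,
                                 gu_aromatic_scorer(), cfg, n_top_regions=8)
        assert report.candidates, "pipeline selected no candidates"
        tx, lo, hi = candidate_transcript_interval(report.candidates[0])
        assert any(
            isl.transcript_id == tx and lo < isl.end and hi > isl.start
            for isl in fx.islands.itertuples()
        )

    def test_rerun_identical_seed_is_byte_identical(self, tmp_path):
        fx = generate_fixture(FixtureSpec(seed=4))
        cfg = FitnessConfig(ell=50, seed=9)
        outs = []
        for name in ("a", "b"):
            report = design_aptamers(fx.peaks, fx.transcripts, fx.protein,
                                     gu_aromatic_scorer(), cfg, n_top_regions=4)
            d = tmp_path / name
            report.write(d)
            outs.append(d)
        for f in sorted(p.name for p in outs[0].iterdir()):
            assert (outs[0] / f).read_bytes() == (outs[1] / f).read_bytes()

    def test_requesting_more_regions_than_available_warns_and_uses_all(self):
        fx = generate_fixture(FixtureSpec(seed=5))
        cfg = FitnessConfig(ell=20, seed=1)
        with pytest.warns(UserWarning, match="using all"):
            report = design_aptamers(fx.peaks, fx.transcripts, fx.protein,
                                     gu_aromatic_scorer(), cfg, n_top_regions=999)
        assert report.provenance["n_regions_found"] == len(report.regions)

    def test_provenance_carries_seed_and_scorer(self):
        fx = generate_fixture(FixtureSpec(seed=6))
        cfg = FitnessConfig(ell=20, seed=42)
        report = design_aptamers(fx.peaks, fx.transcripts, fx.protein,
                                 gu_aromatic_scorer(), cfg, n_top_regions=2)
        assert report.provenance["seed"] == 42
        assert report.provenance["scorer"] == "gu_aromatic"
        df = report.fitness_frame()
        assert set(df["mutant_pool"]) == {20} and set(df["shuffle_pool"]) == {20}


def test_substreams_independent_of_evaluation_order(gu_scorer):
    cfg = FitnessConfig(ell=30, seed=8)
    a = RNASequence(id="a", bases="GUGAAUGUAC")
    b = RNASequence(id="b", bases="ACGUACGUAC")
    fa1 = rna_fitness(a, PROT, gu_scorer, cfg)
    fb1 = rna_fitness(b, PROT, gu_scorer, cfg)
    fb2 = rna_fitness(b, PROT, gu_scorer, cfg)
    fa2 = rna_fitness(a, PROT, gu_scorer, cfg)
    assert (fa1, fb1) == (fa2, fb2)
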