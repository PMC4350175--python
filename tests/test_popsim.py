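"""Unit and property tests for the chemostat Wright-Fisher simulator."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from chemosweep.popsim import (
    ANCESTOR,
    GeneModel,
    Genotype,
    PlantedLineage,
    PopulationState,
    SimConfig,
    Simulation,
    annotate_effect,
    fitness_of,
    freq_dep_equilibrium,
    generations_per_day,
    planted_lineage_truth,
    run_simulation,
)

DAYS = (5, 7, 14, 20, 28, 35, 40, 45, 50, 56, 60)


class TestGenerationsPerDay:
    @pytest.mark.parametrize(
        "rate,expected",
        [(0.0, 0.0), (0.1, 3.46247), (0.2, 6.92494)],
    )
    def test_values(self, rate, expected):
        assert generations_per_day(rate) == pytest.approx(expected, abs=1e-4)

    def test_sixty_day_total(self):
        assert 60 * generations_per_day(0.1) == pytest.approx(207.748, abs=1e-2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generations_per_day(-0.1)


def one_gene_config(**kw):
    genes = (GeneModel("rpoS", 101, 1100, "+", "driver_strong", 0.1, 20),)
    defaults = dict(N=10_000, genome_length=2_000, mu=0.0, genes=genes, seed=7)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestFitness:
    def test_ancestor_is_neutral(self):
        cfg = one_gene_config()
        state = PopulationState(0, {ANCESTOR: cfg.N})
        assert fitness_of(ANCESTOR, state, cfg) == 1.0

    def test_driver_benefit_counted_once_per_gene(self):
        """Two distinct alleles of one driver gene give 1+s, not (1+s)^2."""
        cfg = one_gene_config()
        sim = Simulation(cfg)
        targets = sorted(cfg.genes[0].target_sites())
        parent = ANCESTOR
        spawned = 0
        for pos in targets:
            child = sim._spawn(parent, pos, "S-indel", sim.rng)  # indels always activate
            assert sim.registry[child.mutation_ids[-1]].role == "driver_strong"
            parent = child
            spawned += 1
            if spawned == 2:
                break
        state = PopulationState(0, {parent: cfg.N})
        assert len(parent.mutation_ids) == 2
        assert fitness_of(parent, state, cfg) == pytest.approx(1.1)

    def test_freq_dep_term_tracks_carrier_frequency(self):
        cfg = one_gene_config(freq_dep_s=0.2, freq_dep_c=1.0)
        carrier = Genotype(1, ("x",), frozenset(), True, False)
        state = PopulationState(0, {carrier: 2_000, ANCESTOR: 8_000})
        # x_h = 0.2 -> 1 + 0.2 - 1.0*0.2 = 1.0
        assert fitness_of(carrier, state, cfg) == pytest.approx(1.0)

    def test_epistasis_blocks_freq_dep_benefit(self):
        """A freq-dep mutation on an rpoS-driver background is inert."""
        cfg = one_gene_config(epistasis_genes=("rpoS",))
        blocked = Genotype(1, ("a", "b"), frozenset({"rpoS"}), True, False)
        state = PopulationState(0, {blocked: 1_000, ANCESTOR: 9_000})
        assert fitness_of(blocked, state, cfg) == pytest.approx(1.1)

    def test_fitness_clipped_at_zero(self):
        cfg = one_gene_config(freq_dep_s=0.1, freq_dep_c=100.0)
        carrier = Genotype(1, ("x",), frozenset(), True, False)
        state = PopulationState(0, {carrier: 5_000, ANCESTOR: 5_000})
        assert fitness_of(carrier, state, cfg) == 0.0


class TestFreqDepEquilibrium:
    def test_fixed_point_is_s_over_c(self):
        assert freq_dep_equilibrium(0.2, 1.0) == pytest.approx(0.2, abs=1e-6)
        assert freq_dep_equilibrium(0.1, 0.5) == pytest.approx(0.2, abs=1e-6)

    def test_converges_from_above(self):
        assert freq_dep_equilibrium(0.2, 1.0, x0=0.9) == pytest.approx(0.2, abs=1e-6)


class TestStepGeneration:
    def test_population_size_conserved(self, rng):
        cfg = one_gene_config(mu=1e-5)
        sim = Simulation(cfg, rng=rng)
        state = sim.initial_state()
        for _ in range(5):
            state = sim.step(state)
            assert state.size == cfg.N

    def test_no_mutation_single_genotype_unchanged(self, rng):
        cfg = one_gene_config(mu=0.0)
        sim = Simulation(cfg, rng=rng)
        state = sim.step(sim.initial_state())
        assert state.counts == {ANCESTOR: cfg.N}
        assert state.generation == 1

    def test_empty_population_rejected(self, rng):
        sim = Simulation(one_gene_config(), rng=rng)
        with pytest.raises(ValueError):
            sim.step(PopulationState(0, {}))

    def test_selection_matches_deterministic_formula(self, rng):
        """Mean one-step frequency change equals x(1+s)/(1+sx) - x."""
        s, x, n_rep = 0.05, 0.3, 10_000
        cfg = one_gene_config(N=10_000, mu=0.0)
        sim = Simulation(cfg, rng=rng)
        driver = Genotype(1, ("d",), frozenset({"rpoS"}), False, False)
        cfg2 = one_gene_config(
            N=10_000, mu=0.0,
            genes=(GeneModel("rpoS", 101, 1100, "+", "driver_strong", s, 20),),
        )
        sim = Simulation(cfg2, rng=rng)
        k = int(x * cfg2.N)
        start = PopulationState(0, {driver: k, ANCESTOR: cfg2.N - k})
        deltas = np.empty(n_rep)
        for i in range(n_rep):
            new = sim.step(start)
            deltas[i] = new.counts.get(driver, 0) / cfg2.N - x
        expected = x * (1 + s) / (1 + s * x) - x
        se = deltas.std(ddof=1) / math.sqrt(n_rep)
        assert abs(deltas.mean() - expected) < 3 * se


class TestAnnotateEffect:
    # genome: 9 bp intergenic, then a + strand gene ATG GGT TAT TAA
    GENOME = "AAACCCGGG" + "ATGGGTTATTAA" + "TTTTTT"
    GENES = (GeneModel("g1", 10, 21, "+", "neutral", 0.0, 0),)

    def test_intergenic_is_noncoding(self):
        assert annotate_effect(3, "A", "G", self.GENES, self.GENOME) == "noncoding"

    def test_wobble_change_is_synonymous(self):
        # GGT -> GGC, third codon position (genome position 15), Gly -> Gly
        assert annotate_effect(15, "T", "C", self.GENES, self.GENOME) == "synonymous"

    def test_stop_gain_is_nonsynonymous(self):
        # TAT -> TAA at position 18 (codon 3, third base): Tyr -> stop
        assert annotate_effect(18, "T", "A", self.GENES, self.GENOME) == "nonsynonymous"

    def test_minus_strand_codon(self):
        # same gene sequence encoded on the - strand: reverse complement of
        # ATGGGTTATTAA is TTAATAACCCAT; gene read 5'->3' from the right end
        genome = "AAACCCGGG" + "TTAATAACCCAT" + "TTTTTT"
        genes = (GeneModel("g1", 10, 21, "-", "neutral", 0.0, 0),)
        # genomic position 16 is the wobble base of codon GGT on the - strand
        assert annotate_effect(16, "A", "G", genes, genome) == "synonymous"

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError):
            annotate_effect(3, "G", "T", self.GENES, self.GENOME)

    def test_non_snp_rejected(self):
        with pytest.raises(ValueError):
            annotate_effect(3, "A", "A", self.GENES, self.GENOME)


class TestRunSimulation:
    def test_zero_duration_gives_ancestral_truth(self):
        cfg = one_gene_config(duration_days=0.0, sample_days=(0,), mu=1e-6)
        truth = run_simulation(cfg)
        assert list(truth.freqs.columns) == [0.0]
        assert len(truth.freqs) == 0

    def test_reproducible_under_seed(self):
        cfg = one_gene_config(mu=1e-5, duration_days=5.0, sample_days=(2, 5), seed=42)
        t1 = run_simulation(cfg)
        t2 = run_simulation(cfg)
        pd.testing.assert_frame_equal(t1.freqs, t2.freqs)
        pd.testing.assert_frame_equal(t1.mutations, t2.mutations)

    def test_truth_frequencies_in_unit_interval(self):
        cfg = one_gene_config(mu=1e-4, N=1_000, duration_days=5.0, sample_days=(2, 5))
        truth = run_simulation(cfg)
        assert ((truth.freqs >= 0) & (truth.freqs <= 1)).all().all()

    def test_stronger_selection_sweeps_earlier(self, rng):
        """First passage above 50% carrier frequency is faster at s=0.15
        than s=0.05 (one-sided rank test over replicates)."""

        def first_passage(s, seed):
            genes = (GeneModel("drv", 101, 1100, "+", "driver_strong", s, 50),)
            cfg = SimConfig(N=10_000, genome_length=20_000, mu=2e-7, genes=genes, seed=seed)
            sim = Simulation(cfg)
            state = sim.initial_state()
            for gen in range(1, 401):
                state = sim.step(state)
                carriers = sum(c for g, c in state.counts.items() if g.driver_genes)
                if carriers >= 0.5 * cfg.N:
                    return gen
            return 401

        fast = [first_passage(0.15, 100 + i) for i in range(20)]
        slow = [first_passage(0.05, 200 + i) for i in range(20)]
        assert mannwhitneyu(fast, slow, alternative="less").pvalue < 0.01


class TestPlantedLineages:
    def test_private_mutations_share_their_lineage_trajectory(self, rng):
        lineages = [
            PlantedLineage(1.1, 0.01, (("gA", "driver_strong"), ("gB", "passenger"))),
            PlantedLineage(1.0, 0.2, (("gC", "neutral"),)),
        ]
        truth = planted_lineage_truth(lineages, N=10_000, sample_days=DAYS, rng=rng)
        pd.testing.assert_series_equal(
            truth.freqs.loc["p0_0"], truth.freqs.loc["p0_1"], check_names=False
        )
        assert set(truth.mutations["lineage_id"]) == {0, 1}

    def test_neutral_lineage_mean_matches_initial_frequency(self, rng):
        """Drift is a martingale: E[final frequency] = initial frequency."""
        finals = np.array(
            [
                planted_lineage_truth(
                    [PlantedLineage(1.0, 0.10, (("m", "neutral"),))],
                    N=10_000, sample_days=(60,), rng=rng,
                ).freqs.iloc[0, 0]
                for _ in range(60)
            ]
        )
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - 0.10) < 3 * se

    def test_freq_dep_lineage_persists_without_fixation(self):
        """Stochastic freq-dep balancing: the carrier lineage hovers near
        s_h/c and neither fixes nor dies in the vast majority of runs."""
        cfg = SimConfig(N=100_000, genome_length=2_000, mu=0.0,
                        genes=(GeneModel("hfq", 101, 400, "+", "freq_dep", 0.0, 4),),
                        freq_dep_s=0.2, freq_dep_c=1.0, seed=3)
        sim = Simulation(cfg)
        carrier = Genotype(1, ("h",), frozenset(), True, False)
        n_gen = math.ceil(60 * generations_per_day(0.1))
        ok = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            k = cfg.N // 100
            state = PopulationState(0, {carrier: k, ANCESTOR: cfg.N - k})
            for _ in range(n_gen):
                state = sim.step(state, rng)
            final = state.counts.get(carrier, 0)
            if 0 < final < cfg.N:
                ok += 1
        assert ok >= 0.9 * n_rep


class TestConfigValidation:
    def test_default_config_is_valid(self):
        assert SimConfig().validate() == []

    def test_all_violations_reported(self):
        cfg = SimConfig(N=10, mu=-1.0, sample_days=(5, 3), duration_days=60)
        errors = cfg.validate()
        assert any("N" in e for e in errors)
        assert any("mu" in e for e in errors)
        assert any("sample_days" in e for e in errors)

    def test_overlapping_genes_rejected(self):
        genes = (
            GeneModel("a", 10, 100, "+", "neutral", 0.0, 0),
            GeneModel("b", 50, 150, "+", "neutral", 0.0, 0),
        )
        cfg = SimConfig(genes=genes, genome_length=1_000)
        assert any("overlap" in e for e in cfg.validate())
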