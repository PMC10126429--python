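"""Generative model of the pooled selection screen."""

import numpy as np
import pytest

from y2hseq import (
    BAIT,
    EMPTY,
    GeneModel,
    InvalidConfigError,
    ScreenTruth,
    SimConfig,
    SimulationExhaustedError,
    generate_library,
    simulate_screen,
)


def small_config(**kw) -> SimConfig:
    base = dict(
        n_genes=30, n_colonies_picked=60, total_reads=2000, read_length=60,
        mean_protein_length=120, min_protein_length=60, seed=11,
        multi_plasmid_prob=0.0, leak_prob=0.0, seq_error_rate=0.0,
        interactor_fraction=0.2, self_activator_fraction=0.15,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateLibrary:
    def test_contract(self):
        cfg = SimConfig(n_genes=100, seed=1, total_reads=0)
        library, truth = generate_library(cfg)
        assert len(library) == 100
        ids = [g.gene_id for g in library]
        assert len(set(ids)) == 100
        assert truth.gene_ids == ids
        assert abs(truth.abundance.sum() - 1.0) < 1e-9
        for g in library:
            assert len(g.cds_seq) == g.length_bp == 3 * len(g.protein_seq)
            assert g.length_bp >= cfg.read_length

    def test_no_shared_read_length_kmer_between_genes(self):
        cfg = small_config(n_genes=15)
        library, _ = generate_library(cfg)
        k = cfg.read_length
        seen = {}
        for g in library:
            for i in range(g.length_bp - k + 1):
                kmer = g.cds_seq[i:i + k]
                assert seen.setdefault(kmer, g.gene_id) == g.gene_id
                seen[kmer] = g.gene_id

    def test_deterministic(self):
        cfg = SimConfig(n_genes=40, seed=5)
        lib1, truth1 = generate_library(cfg)
        lib2, truth2 = generate_library(cfg)
        assert [g.cds_seq for g in lib1] == [g.cds_seq for g in lib2]
        assert [g.protein_seq for g in lib1] == [g.protein_seq for g in lib2]
        assert np.array_equal(truth1.abundance, truth2.abundance)
        assert np.array_equal(truth1.is_interactor, truth2.is_interactor)

    def test_degenerate_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_library(SimConfig(n_genes=0))
        with pytest.raises(InvalidConfigError):
            generate_library(SimConfig(read_length=500, min_protein_length=100))
        with pytest.raises(InvalidConfigError):
            SimConfig(multi_plasmid_prob=1.5).validate()

    def test_tm_abundance_multiplier_shifts_mass(self):
        lo = generate_library(small_config(tm_fraction=0.5, tm_abundance_multiplier=1.0))
        hi = generate_library(small_config(tm_fraction=0.5, tm_abundance_multiplier=50.0))
        # same genes drawn, so the boosted library concentrates mass on fewer genes
        assert (hi[1].abundance.max()) > (lo[1].abundance.max())


class TestScreenTruth:
    def test_abundance_sum_enforced(self):
        with pytest.raises(Exception):
            ScreenTruth(gene_ids=["a", "b"], is_interactor=[True, False],
                        is_self_activator=[False, False], abundance=[0.6, 0.6])

    def test_roundtrip_tsv(self, tmp_path):
        _, truth = generate_library(small_config())
        p = tmp_path / "truth.tsv"
        truth.to_tsv(p)
        back = ScreenTruth.from_tsv(p)
        assert back.gene_ids == truth.gene_ids
        assert np.array_equal(back.is_interactor, truth.is_interactor)
        np.testing.assert_allclose(back.abundance, truth.abundance)


class TestSimulateScreen:
    def test_read_conservation_and_length(self):
        cfg = small_config()
        library, truth = generate_library(cfg)
        rs = simulate_screen(library, truth, cfg, BAIT)
        assert len(rs) == cfg.total_reads
        assert all(len(s) == cfg.read_length for s in rs.sequences)

    def test_empty_screen_support_is_self_activators(self):
        cfg = small_config()
        library, truth = generate_library(cfg)
        rs = simulate_screen(library, truth, cfg, EMPTY)
        assert set(rs.origins) <= truth.self_activators

    def test_bait_screen_support_is_interactors_or_self_activators(self):
        cfg = small_config()
        library, truth = generate_library(cfg)
        rs = simulate_screen(library, truth, cfg, BAIT)
        assert set(rs.origins) <= (truth.interactors | truth.self_activators)

    def test_seed_determinism(self):
        cfg = small_config(seq_error_rate=0.01, multi_plasmid_prob=0.1, leak_prob=0.05)
        library, truth = generate_library(cfg)
        r1 = simulate_screen(library, truth, cfg, BAIT)
        r2 = simulate_screen(library, truth, cfg, BAIT)
        assert r1.sequences == r2.sequences
        assert r1.origins == r2.origins
        assert r1.read_ids == r2.read_ids

    def test_single_interactor_takes_all_reads(self):
        cfg = small_config(interactor_fraction=0.0, self_activator_fraction=0.0)
        library, truth = generate_library(cfg)
        truth.is_interactor[3] = True  # exactly one interactor, no self-activators
        rs = simulate_screen(library, truth, cfg, BAIT)
        assert set(rs.origins) == {truth.gene_ids[3]}

    def test_exhaustion_when_nothing_survives(self):
        cfg = small_config(interactor_fraction=0.0, self_activator_fraction=0.0,
                           n_colonies_picked=5)
        library, truth = generate_library(cfg)
        with pytest.raises(SimulationExhaustedError):
            simulate_screen(library, truth, cfg, EMPTY)

    def test_read_share_proportional_to_length(self):
        # two equal-abundance interactor genes, lengths 1000 and 2000; with many
        # colonies their amplified copies agree to ~1%, so the read share ratio
        # approaches the 1:2 length ratio
        rng = np.random.default_rng(0)
        genes = [
            GeneModel("gA", 1000, "".join(rng.choice(list("ACGT"), size=1000))),
            GeneModel("gB", 2000, "".join(rng.choice(list("ACGT"), size=2000))),
        ]
        truth = ScreenTruth(gene_ids=["gA", "gB"], is_interactor=[True, True],
                            is_self_activator=[False, False], abundance=[0.5, 0.5])
        cfg = SimConfig(n_genes=2, n_colonies_picked=20_000, total_reads=200_000,
                        multi_plasmid_prob=0.0, leak_prob=0.0, seq_error_rate=0.0,
                        pcr_amplification_cv=0.0, read_length=75, seed=3)
        rs = simulate_screen(genes, truth, cfg, BAIT)
        share_b = sum(1 for o in rs.origins if o == "gB") / len(rs)
        assert abs(share_b / (1 - share_b) - 2.0) < 0.1

    def test_read_fraction_matches_sampling_mass(self):
        # Monte-Carlo check of the sampling law: empirical per-gene read
        # fraction equals (amplified copies x length) / total mass within
        # 3 binomial standard errors at 1e6 reads
        cfg = small_config(n_genes=20, total_reads=1_000_000,
                           pcr_amplification_cv=0.4, interactor_fraction=0.5,
                           n_colonies_picked=100, seed=23)
        library, truth = generate_library(cfg)
        rs = simulate_screen(library, truth, cfg, BAIT)
        total_mass = sum(rs.gene_read_mass.values())
        obs = {}
        for o in rs.origins:
            obs[o] = obs.get(o, 0) + 1
        n = len(rs)
        for gid, mass in rs.gene_read_mass.items():
            p = mass / total_mass
            se = max((p * (1 - p) / n) ** 0.5, 1e-9)
            assert abs(obs.get(gid, 0) / n - p) <= 3 * se + 1e-9

    def test_fastq_roundtrip(self, tmp_path):
        cfg = small_config(total_reads=100)
        library, truth = generate_library(cfg)
        rs = simulate_screen(library, truth, cfg, BAIT)
        p = tmp_path / "r.fastq"
        rs.to_fastq(p)
        from y2hseq import ReadSet

        back = ReadSet.from_fastq(p, BAIT)
        assert back.sequences == rs.sequences
        assert back.read_ids == rs.read_ids
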