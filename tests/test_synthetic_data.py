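"""Generator contracts: determinism, dropout/contamination signatures, shapes."""

import numpy as np
import pytest

from phycofunc.module_catalog import ModuleCatalog
from phycofunc.phylo_metrics import leaf_labels, read_tree
from phycofunc.synthetic_data import (
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    sample_names,
    simulate_coverage,
    simulate_genomes,
    simulate_tree,
    write_outputs,
)
from phycofunc.util import parse_taxonomy


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_genomes=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(completeness_range=(90, 110))
    with pytest.raises(ConfigurationError):
        SimulationConfig(contamination_range=(5, 2))


def test_empty_catalog_is_configuration_error():
    with pytest.raises(ConfigurationError, match="catalog"):
        simulate_genomes(SimulationConfig(n_genomes=2), ModuleCatalog())


class TestGenomes:
    def test_no_dropout_no_gain_identity(self, catalog):
        cfg = SimulationConfig(
            n_genomes=20, seed=3,
            completeness_range=(100, 100), contamination_range=(0, 0),
        )
        genomes, truth = simulate_genomes(cfg, catalog)
        for g in genomes:
            assert g.ko_set == truth.true_ko_by_genome[g.genome_id]

    def test_full_dropout_leaves_trait_blocks_empty(self, catalog):
        cfg = SimulationConfig(
            n_genomes=20, seed=3,
            completeness_range=(0, 0), contamination_range=(0, 0),
        )
        genomes, truth = simulate_genomes(cfg, catalog)
        for g in genomes:
            assert g.ko_set & truth.true_ko_by_genome[g.genome_id] == frozenset()

    def test_deterministic_under_seed(self, catalog):
        cfg = SimulationConfig(n_genomes=30, seed=7)
        a = simulate_genomes(cfg, catalog)
        b = simulate_genomes(cfg, catalog)
        assert [g.ko_set for g in a[0]] == [g.ko_set for g in b[0]]
        assert [g.completeness for g in a[0]] == [g.completeness for g in b[0]]
        assert a[1] == b[1]

    def test_truth_modules_fully_complete_in_true_ko_set(self, catalog):
        cfg = SimulationConfig(n_genomes=30, seed=2)
        _, truth = simulate_genomes(cfg, catalog)
        for gid, modules in truth.modules_by_genome.items():
            kos = truth.true_ko_by_genome[gid]
            for mid in modules:
                assert catalog[mid].identifiers() <= kos

    def test_retention_rate_matches_completeness(self, catalog):
        # expected retained fraction = completeness/100 (Bernoulli), 3-SE band
        p = 0.7
        cfg = SimulationConfig(
            n_genomes=60, seed=13,
            completeness_range=(100 * p, 100 * p), contamination_range=(0, 0),
        )
        genomes, truth = simulate_genomes(cfg, catalog)
        retained = total = 0
        for g in genomes:
            true = truth.true_ko_by_genome[g.genome_id]
            retained += len(g.ko_set & true)
            total += len(true)
        se = np.sqrt(p * (1 - p) / total)
        assert abs(retained / total - p) <= 3 * se

    def test_zero_contamination_means_no_background_kos(self, catalog):
        cfg = SimulationConfig(n_genomes=40, seed=5, contamination_range=(0, 0))
        genomes, truth = simulate_genomes(cfg, catalog)
        for g in genomes:
            assert g.ko_set <= truth.true_ko_by_genome[g.genome_id]

    def test_contamination_adds_expected_background_count(self, catalog):
        cfg = SimulationConfig(
            n_genomes=20, seed=5,
            completeness_range=(100, 100), contamination_range=(10, 10),
        )
        genomes, truth = simulate_genomes(cfg, catalog)
        for g in genomes:
            true = truth.true_ko_by_genome[g.genome_id]
            gained = g.ko_set - true
            assert len(gained) == round(0.10 * len(true))
            assert gained <= cfg.background_ko_pool

    def test_taxonomy_is_seven_rank_gtdb_style(self, catalog):
        genomes, _ = simulate_genomes(SimulationConfig(n_genomes=9, seed=1), catalog)
        for g in genomes:
            assert g.taxonomy.count(";") == 6
            ranks = parse_taxonomy(g.taxonomy)
            assert ranks["domain"] == "Bacteria"
            assert ranks["species"]

    def test_truth_json_roundtrip(self, catalog):
        _, truth = simulate_genomes(SimulationConfig(n_genomes=6, seed=8), catalog)
        assert GroundTruth.from_json(truth.to_json()) == truth


class TestTree:
    def test_two_leaves(self):
        tree = read_tree(simulate_tree(2, seed=0))
        assert len(tree.leaf_nodes()) == 2

    def test_too_few_leaves(self):
        with pytest.raises(ConfigurationError):
            simulate_tree(1, seed=0)

    def test_deterministic_newick(self):
        assert simulate_tree(8, seed=42) == simulate_tree(8, seed=42)

    def test_leaf_count_and_uniqueness_at_421(self):
        tree = read_tree(simulate_tree(421, seed=17))
        labels = [l.taxon.label for l in tree.leaf_nodes()]
        assert len(labels) == 421
        assert len(set(labels)) == 421

    def test_all_branch_lengths_positive(self):
        tree = read_tree(simulate_tree(30, seed=4))
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                assert edge.length > 0


class TestCoverage:
    def test_shape_and_sample_names(self, catalog):
        cfg = SimulationConfig(n_genomes=10, n_samples=6, seed=0)
        genomes, _ = simulate_genomes(cfg, catalog)
        cov = simulate_coverage(genomes, 6, cfg)
        assert list(cov.columns) == ["RZ-A", "RZ-B", "RZ-C", "ND-A", "ND-B", "ND-C"]
        assert cov.shape == (10, 6)
        assert (cov.to_numpy() >= 0).all()

    def test_sigma_zero_gives_equal_coverage(self, catalog):
        cfg = SimulationConfig(n_genomes=5, seed=0, lognormal_mu=1.0, lognormal_sigma=0.0)
        genomes, _ = simulate_genomes(cfg, catalog)
        cov = simulate_coverage(genomes, 3, cfg)
        assert cov.to_numpy() == pytest.approx(np.e)

    def test_deterministic_and_stream_split(self, catalog):
        cfg = SimulationConfig(n_genomes=8, seed=21)
        genomes, _ = simulate_genomes(cfg, catalog)
        a = simulate_coverage(genomes, 6, cfg)
        b = simulate_coverage(genomes, 6, cfg)
        assert a.equals(b)
        # adding samples never perturbs genome simulation or earlier columns
        wide = simulate_coverage(genomes, 4, cfg)
        assert wide.iloc[:, 0].to_numpy() == pytest.approx(a.iloc[:, 0].to_numpy())
        again, _ = simulate_genomes(cfg, catalog)
        assert [g.ko_set for g in again] == [g.ko_set for g in genomes]


def test_sample_names_split():
    assert sample_names(6) == ["RZ-A", "RZ-B", "RZ-C", "ND-A", "ND-B", "ND-C"]
    assert sample_names(3) == ["RZ-A", "RZ-B", "ND-A"]


def test_write_outputs_emits_all_files(tmp_path, catalog):
    cfg = SimulationConfig(n_genomes=6, n_samples=4, seed=2)
    paths = write_outputs(tmp_path, cfg, catalog)
    for name in ("genomes.tsv", "annotations.tsv", "tree.nwk", "coverage.tsv", "truth.json"):
        assert paths[name].exists() and paths[name].stat().st_size > 0
    tree = read_tree(paths["tree.nwk"].read_text())
    assert leaf_labels(tree) == {f"MAG-{i}" for i in range(1, 7)}
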