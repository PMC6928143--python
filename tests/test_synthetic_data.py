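"""Generator contracts: determinism, printed sizes, planted guarantees."""

import numpy as np
import pytest

from momnet.omics_io import ConfigurationError, Direction, load_dataset
from momnet.ptm_quant import quantify_table
from momnet.synthetic_data import (
    DEFAULT_DATASET_SIZES,
    SERIAL_GROUP,
    SERIAL_KIND,
    SyntheticConfig,
    generate_bundle,
    generate_kb,
    generate_ptm_table,
)
import pandas as pd


SMALL = dict(
    n_universe=400,
    n_pathways=40,
    dataset_sizes={1: (30, 30), 2: (10, 10), 3: 60, 4: 12, 5: (40, 20),
                   6: (12, 12), 7: 120, 8: 8, 9: 15},
    planted_hubs=(("HUB01", frozenset({1, 3, 5})),),
    planted_pathways=(("PW_PLANTED_A", frozenset({1, 5}), 0.4),),
)


class TestDeterminism:
    def test_bundle_files_byte_identical_across_runs(self, tmp_path):
        config = SyntheticConfig(seed=7, **SMALL)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        generate_bundle(config, dir_a)
        generate_bundle(config, dir_b)
        for name in ["kb.gmt", "kb.sif", "dataset_1.tsv", "dataset_7.tsv",
                     "ptm_quant.tsv", "function_map.tsv", "truth.json"]:
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes(), name

    def test_different_seeds_differ(self, tmp_path):
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        generate_bundle(SyntheticConfig(seed=1, **SMALL), dir_a)
        generate_bundle(SyntheticConfig(seed=2, **SMALL), dir_b)
        assert (dir_a / "kb.sif").read_bytes() != (dir_b / "kb.sif").read_bytes()


class TestDatasetSizes:
    def test_default_bundle_reproduces_printed_totals(self, default_bundle):
        outdir, _, _ = default_bundle
        expected_totals = {1: 280, 2: 50, 3: 218, 4: 12, 5: 346, 6: 57,
                           7: 1469, 8: 8, 9: 28}
        for serial, total in expected_totals.items():
            ds = load_dataset(
                outdir / f"dataset_{serial}.tsv",
                serial, SERIAL_KIND[serial], SERIAL_GROUP[serial],
            )
            assert len(ds) == total, f"dataset {serial}"

    @pytest.mark.parametrize(
        "serial,n_up,n_down", [(1, 114, 166), (2, 21, 29), (5, 233, 113), (6, 30, 27)]
    )
    def test_up_down_splits(self, default_bundle, serial, n_up, n_down):
        outdir, _, _ = default_bundle
        ds = load_dataset(
            outdir / f"dataset_{serial}.tsv",
            serial, SERIAL_KIND[serial], SERIAL_GROUP[serial],
        )
        assert ds.n_by_direction(Direction.UP) == n_up
        assert ds.n_by_direction(Direction.DOWN) == n_down

    def test_no_duplicate_identifiers_planted(self, default_bundle):
        outdir, _, _ = default_bundle
        for serial in DEFAULT_DATASET_SIZES:
            ds = load_dataset(
                outdir / f"dataset_{serial}.tsv",
                serial, SERIAL_KIND[serial], SERIAL_GROUP[serial],
            )
            assert len(set(ds.identifiers)) == len(ds)


class TestPlantedStructure:
    def test_planted_hub_degree_guarantee(self, default_bundle):
        _, kb, truth = default_bundle
        for name, info in truth.planted_hubs.items():
            group = set(info["companions"]) | {name}
            assert kb.graph.subgraph_degree(name, group) >= 5

    def test_hub_and_companions_present_in_target_datasets(self, default_bundle):
        outdir, _, truth = default_bundle
        for name, info in truth.planted_hubs.items():
            for serial in info["serials"]:
                ds = load_dataset(
                    outdir / f"dataset_{serial}.tsv",
                    serial, SERIAL_KIND[serial], SERIAL_GROUP[serial],
                )
                ids = set(ds.identifiers)
                assert name in ids
                assert sum(1 for c in info["companions"] if c in ids) >= 5

    def test_planted_pathway_overlap_fraction_met(self, default_bundle):
        outdir, _, truth = default_bundle
        for pw_name, info in truth.planted_enriched_pathways.items():
            members = set(info["members"])
            for serial in info["serials"]:
                ds = load_dataset(
                    outdir / f"dataset_{serial}.tsv",
                    serial, SERIAL_KIND[serial], SERIAL_GROUP[serial],
                )
                overlap = len(members & set(ds.identifiers))
                assert overlap >= info["overlap_fraction"] * len(members)

    def test_graph_edge_count_attachment_formula(self):
        # without planted hubs the edge count is exactly the
        # preferential-attachment formula (n - m) * m
        config = SyntheticConfig(
            seed=3, n_universe=300, n_pathways=20, planted_hubs=(), ptm_planted=()
        )
        kb, _ = generate_kb(config)
        m = config.graph_attachment
        assert kb.graph.n_edges == (config.n_universe - m) * m

    def test_planted_wiring_only_adds_edges(self):
        base = SyntheticConfig(seed=3, n_universe=300, n_pathways=20,
                               planted_hubs=(), ptm_planted=())
        kb_plain, _ = generate_kb(base)
        kb_hubs, _ = generate_kb(SyntheticConfig(seed=3, n_universe=300, n_pathways=20))
        assert kb_hubs.graph.n_edges > kb_plain.graph.n_edges


class TestPtmGeneration:
    def test_noiseless_recovery_is_exact(self):
        config = SyntheticConfig(seed=5, noise_sigma=0.0, **SMALL)
        rows, truth = generate_ptm_table(config)
        measurements, rejects = quantify_table(pd.DataFrame(rows).astype(str))
        assert not rejects
        planted = {k.split("|")[1]: v for k, v in truth.planted_ptm_ratios.items()}
        for m in measurements:
            assert m.signed_ratio == pytest.approx(planted[m.peptide], rel=1e-6)

    def test_noisy_recovery_within_oracle_bound(self):
        # 200 planted peptides at sigma = 0.1; the Monte-Carlo oracle for
        # median |log(recovered/planted)| never exceeded 0.087 over 2000
        # replicates, so 0.10 is a safe frozen bound
        planted = tuple(
            (f"GENE{i:04d}", "EAESSPFVER", "S4", ratio)
            for i, ratio in enumerate(
                np.linspace(2.0, 50.0, 100).tolist()
                + (-np.linspace(2.0, 50.0, 100)).tolist()
            )
        )
        config = SyntheticConfig(seed=11, noise_sigma=0.1, ptm_planted=planted, **SMALL)
        rows, truth = generate_ptm_table(config)
        measurements, _ = quantify_table(pd.DataFrame(rows).astype(str))
        truth_by_gene = {k.split("|")[0]: v for k, v in truth.planted_ptm_ratios.items()}
        errors = [
            abs(np.log(abs(m.signed_ratio)) - np.log(abs(truth_by_gene[m.gene_symbol])))
            for m in measurements
        ]
        assert len(errors) == 200
        assert np.median(errors) < 0.10


class TestConfigValidation:
    def test_pathway_size_exceeding_universe(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_universe=30, pathway_size_range=(10, 60))

    def test_dataset_quota_exceeding_universe(self):
        config = SyntheticConfig(
            n_universe=100, n_pathways=5, pathway_size_range=(5, 10),
            dataset_sizes={7: 1469}, planted_hubs=(), planted_pathways=(),
        )
        kb, truth = generate_kb(config)
        from momnet.synthetic_data import generate_datasets
        with pytest.raises(ConfigurationError, match="quota"):
            generate_datasets(config, kb, truth)

    def test_hub_serials_confined_to_tumor_group(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(planted_hubs=(("H", frozenset({7})),))

    def test_overlap_fraction_domain(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(planted_pathways=(("P", frozenset({1}), 1.5),))

    def test_planted_ratio_floor(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(ptm_planted=(("G", "PEPTIDER", "S1", 0.5),))
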