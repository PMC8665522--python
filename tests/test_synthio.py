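"""Synthetic-data generator: determinism, planted structure, ground truth."""

import numpy as np
import pandas as pd
import pytest

import cernapivot as cp
from cernapivot.synthio import (
    SimulationError,
    read_interaction_table,
    write_interaction_table,
)


class TestSimulateExpression:
    def test_deterministic_given_seed(self):
        config = cp.SimulationConfig(seed=11)
        m1, t1 = cp.simulate_expression(config)
        m2, t2 = cp.simulate_expression(cp.SimulationConfig(seed=11))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.de_gene_ids == t2.de_gene_ids
        assert t1.hub_lncrna_id == t2.hub_lncrna_id

    def test_shapes_and_truth_consistency(self, default_dataset):
        config, matrix, truth = default_dataset
        assert matrix.values.shape == (
            config.n_mrna + config.n_lncrna, 2 * config.n_pairs)
        assert matrix.biotypes[truth.hub_lncrna_id] == "lncRNA"
        assert all(matrix.biotypes[g] == "mRNA" for g in truth.module_mrna_ids)
        assert set(truth.module_mrna_ids) <= set(truth.de_gene_ids)
        assert truth.hub_lncrna_id in truth.de_gene_ids
        lengths = matrix.lengths.to_numpy()
        assert lengths.min() >= 200 and lengths.max() <= 10000

    def test_null_config_plants_nothing(self):
        config = cp.SimulationConfig(seed=3, de_fraction=0.0, de_log2fc=0.0,
                                     module_rho=1e-6)
        _, truth = cp.simulate_expression(config)
        assert truth.de_gene_ids == {}
        assert truth.true_log2fc == {}

    def test_correlation_planting_monotone_in_rho(self):
        # empirical hub-module correlation increases with the target rho
        means = []
        for rho in (0.2, 0.8):
            rs = []
            for seed in range(3):
                config = cp.SimulationConfig(seed=seed, module_rho=rho,
                                             de_fraction=0.0, n_pairs=20)
                matrix, truth = cp.simulate_expression(config)
                log_fpkm = np.log2(cp.compute_fpkm(matrix).values + 1)
                hub = log_fpkm.loc[truth.hub_lncrna_id].to_numpy()
                rs += [np.corrcoef(hub, log_fpkm.loc[g].to_numpy())[0, 1]
                       for g in truth.module_mrna_ids]
            means.append(np.mean(rs))
        assert means[0] < means[1]
        assert means[1] > 0.6  # approaches the 0.8 target

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(module_size=500), "module_size"),
            (dict(de_fraction=1.5), "de_fraction"),
            (dict(nb_dispersion=-0.1), "nb_dispersion"),
            (dict(de_fraction=0.0001), "single gene"),
            (dict(shared_mirna_count=999), "shared_mirna_count"),
        ],
    )
    def test_invalid_config(self, kwargs, match):
        with pytest.raises(SimulationError, match=match):
            cp.SimulationConfig(**kwargs)


class TestInteractionTable:
    def test_hub_module_share_mirnas_by_construction(self, default_dataset):
        config, _, truth = default_dataset
        table = cp.simulate_interaction_table(config, truth)
        targets = table.groupby("target_id")["mirna_id"].agg(set)
        hub_mirs = targets[truth.hub_lncrna_id]
        for m in truth.module_mrna_ids:
            assert len(hub_mirs & targets[m]) >= config.shared_mirna_count

    def test_no_duplicate_rows_and_consistent_biotype(self, default_dataset):
        config, _, truth = default_dataset
        table = cp.simulate_interaction_table(config, truth)
        assert not table.duplicated(["mirna_id", "target_id"]).any()
        per_target = table.groupby("target_id")["target_biotype"].nunique()
        assert (per_target == 1).all()

    def test_zero_shared_mirnas_drops_hub_edges_downstream(self):
        config = cp.SimulationConfig(seed=5, shared_mirna_count=0,
                                     background_targets_per_mirna=1)
        matrix, truth = cp.simulate_expression(config)
        table = cp.simulate_interaction_table(config, truth)
        edges = pd.DataFrame(
            {"lncrna_id": [truth.hub_lncrna_id] * len(truth.module_mrna_ids),
             "mrna_id": truth.module_mrna_ids,
             "r": 0.9, "p_value": 0.001, "n_samples": 12,
             "shared_mirnas": [None] * len(truth.module_mrna_ids)}
        )
        kept = cp.cross_reference(edges, table, min_shared=1)
        # no guaranteed sharing: at most chance background overlap survives
        assert len(kept) < len(edges)

    def test_tsv_round_trip(self, tmp_path, default_dataset):
        config, _, truth = default_dataset
        table = cp.simulate_interaction_table(config, truth)
        path = tmp_path / "interactions.tsv"
        write_interaction_table(table, path)
        pd.testing.assert_frame_equal(read_interaction_table(path), table)


class TestGeneSets:
    def test_enriched_term_is_mostly_planted_de(self, default_dataset):
        config, _, truth = default_dataset
        sets = cp.simulate_gene_sets(config, truth)
        assert truth.enriched_term_id in sets
        members = set(sets[truth.enriched_term_id])
        de_mrna = {g for g in truth.de_gene_ids if g.startswith("MRNA")}
        assert len(members & de_mrna) >= 0.8 * len(members)
        assert all(len(s) == config.geneset_size for s in sets.values())

    def test_empty_de_truth_gives_background_only(self):
        config = cp.SimulationConfig(seed=2, de_fraction=0.0, de_log2fc=0.0,
                                     module_rho=1e-6)
        _, truth = cp.simulate_expression(config)
        sets = cp.simulate_gene_sets(config, truth)
        assert truth.enriched_term_id is None
        assert len(sets) == config.geneset_count

    def test_gmt_round_trip(self, tmp_path, default_dataset):
        config, _, truth = default_dataset
        sets = cp.simulate_gene_sets(config, truth)
        path = tmp_path / "sets.gmt"
        cp.write_gmt(sets, path)
        back = cp.read_gmt(path)
        assert back.terms == {k: sorted(v) for k, v in sets.items()}


class TestSimulateQpcr:
    def test_noise_free_fold_is_exact(self):
        config = cp.SimulationConfig(seed=4, qpcr_noise_sd=0.0)
        _, truth = cp.simulate_expression(config)
        target = truth.module_mrna_ids[0]
        truth.true_log2fc[target] = -1.0
        wells = cp.simulate_qpcr(truth, config, targets=[target], noise_sd=0.0)
        rel = cp.relative_expression(wells, "REF", "control")
        tumor = rel[rel["group"] == "tumor"]
        np.testing.assert_allclose(tumor["fold"], 0.5)

    def test_same_seed_identical_plate(self, default_dataset):
        config, _, truth = default_dataset
        w1 = cp.simulate_qpcr(truth, config)
        w2 = cp.simulate_qpcr(truth, config)
        pd.testing.assert_frame_equal(w1, w2)

    def test_triplicate_structure(self, default_dataset):
        config, _, truth = default_dataset
        wells = cp.simulate_qpcr(truth, config, n_replicates=3)
        counts = wells.groupby(["sample_id", "target"]).size()
        assert (counts == 3).all()
        assert "REF" in set(wells["target"])

    def test_group_test_power_at_strong_effect(self):
        # |true log2FC| = 2, sd 0.2, 10 samples/group: detected in every seed
        hits = 0
        for seed in range(10):
            config = cp.SimulationConfig(seed=seed)
            _, truth = cp.simulate_expression(config)
            target = truth.module_mrna_ids[0]
            truth.true_log2fc[target] = 2.0
            wells = cp.simulate_qpcr(truth, config, targets=[target],
                                     n_per_group=10, noise_sd=0.2)
            rel = cp.relative_expression(wells, "REF", "control")
            hits += cp.compare_groups(rel, target)["p_value"] < 0.05
        assert hits >= 10 * 0.95

    def test_zero_replicates_rejected(self, default_dataset):
        config, _, truth = default_dataset
        with pytest.raises(SimulationError, match="replicates"):
            cp.simulate_qpcr(truth, config, n_replicates=0)
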