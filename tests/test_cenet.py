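"""Correlation edges, thresholds, miRNA cross-reference, network assembly."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cernapivot as cp
from cernapivot.cenet import write_edges_table
from cernapivot.expr import ExpressionError

from conftest import make_matrix


def vector_with_correlation(x, rho, rng):
    """Construct y with exact sample Pearson correlation rho to x."""
    x = np.asarray(x, dtype=float)
    e = rng.normal(size=len(x))
    xc = (x - x.mean()) / x.std()
    ec = e - e.mean() - np.dot(e - e.mean(), xc) / len(x) * xc
    ec /= ec.std()
    return rho * xc + np.sqrt(1 - rho**2) * ec


def lnc_mrna_matrix(x, y):
    m = make_matrix(np.vstack([x, y]), unit="log2fpkm",
                    biotypes=["lncRNA", "mRNA"])
    return m


class TestCorrelationEdges:
    def test_perfect_affine_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        m = lnc_mrna_matrix(x, 3 * x + 2)
        edges = cp.correlation_edges(m, ["G1"], ["G2"])
        assert edges["r"].iloc[0] == pytest.approx(1.0)
        assert edges["p_value"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n,expected_p", [(6, 0.2080), (12, 0.0392)])
    def test_boundary_r06_pvalues(self, n, expected_p):
        # r = 0.6 fails P<0.05 at n=6 but passes at n=12
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        y = vector_with_correlation(x, 0.6, rng)
        m = lnc_mrna_matrix(x, y)
        edges = cp.correlation_edges(m, ["G1"], ["G2"])
        assert edges["r"].iloc[0] == pytest.approx(0.6, abs=1e-10)
        # oracle: scipy's exact Pearson test on the same vectors
        r_ref, p_ref = stats.pearsonr(x, y)
        assert edges["p_value"].iloc[0] == pytest.approx(p_ref, abs=1e-10)
        assert edges["p_value"].iloc[0] == pytest.approx(expected_p, abs=5e-4)

    def test_constant_gene_gives_nan_and_is_filtered(self):
        m = lnc_mrna_matrix(np.full(6, 2.0), np.arange(6, dtype=float))
        edges = cp.correlation_edges(m, ["G1"], ["G2"])
        assert np.isnan(edges["r"].iloc[0])
        assert len(cp.filter_correlation(edges)) == 0

    def test_sample_order_invariance(self, default_fpkm, default_de):
        sig = default_de[default_de["status"] != "ns"]
        lnc = sig.loc[sig["biotype"] == "lncRNA", "gene_id"].tolist()[:5]
        mrna = sig.loc[sig["biotype"] == "mRNA", "gene_id"].tolist()[:10]
        e1 = cp.correlation_edges(default_fpkm, lnc, mrna)
        from dataclasses import replace
        perm = list(default_fpkm.sample_ids)[::-1]
        shuffled = replace(default_fpkm, values=default_fpkm.values[perm],
                           samples=default_fpkm.samples.loc[perm])
        e2 = cp.correlation_edges(shuffled, lnc, mrna)
        np.testing.assert_allclose(e1["r"], e2["r"], atol=1e-12)

    def test_too_few_samples(self):
        m = lnc_mrna_matrix(np.array([1.0, 2]), np.array([2.0, 1]))
        with pytest.raises(ExpressionError, match=">= 3 samples"):
            cp.correlation_edges(m, ["G1"], ["G2"])

    def test_bruteforce_all_pairs_oracle(self, default_fpkm):
        # 50 genes x 12 samples: exact agreement with per-pair pearsonr
        lnc = list(default_fpkm.genes_of_biotype("lncRNA")[:10])
        mrna = list(default_fpkm.genes_of_biotype("mRNA")[:40])
        edges = cp.correlation_edges(default_fpkm, lnc, mrna)
        logv = np.log2(default_fpkm.values + 1)
        for row in edges.sample(60, random_state=0).itertuples():
            r_ref, p_ref = stats.pearsonr(logv.loc[row.lncrna_id],
                                          logv.loc[row.mrna_id])
            assert row.r == pytest.approx(r_ref, abs=1e-10)
            assert row.p_value == pytest.approx(p_ref, abs=1e-10)


class TestFilterCorrelation:
    def _edges(self, rows):
        return pd.DataFrame(
            [{"lncrna_id": "L", "mrna_id": f"M{i}", "r": r, "p_value": p,
              "n_samples": 12, "shared_mirnas": None}
             for i, (r, p) in enumerate(rows)]
        )

    def test_threshold_semantics(self):
        edges = self._edges([(0.95, 0.001), (0.60, 0.039), (0.59, 0.01),
                             (0.8, 0.06), (-0.95, 0.001)])
        kept = cp.filter_correlation(edges)
        assert list(kept["r"]) == [0.95, 0.60]  # r >= 0.6 inclusive, p < 0.05
        kept_abs = cp.filter_correlation(edges, sign_mode="absolute")
        assert list(kept_abs["r"]) == [0.95, 0.60, -0.95]

    def test_monotone_in_rmin(self):
        rng = np.random.default_rng(1)
        edges = self._edges([(r, p) for r, p in
                             zip(rng.uniform(-1, 1, 50), rng.uniform(0, 1, 50))])
        loose = set(cp.filter_correlation(edges, r_min=0.5)["mrna_id"])
        tight = set(cp.filter_correlation(edges, r_min=0.8)["mrna_id"])
        assert tight <= loose

    def test_invalid_rmin(self):
        with pytest.raises(ExpressionError, match="r_min"):
            cp.filter_correlation(self._edges([(0.9, 0.01)]), r_min=1.5)


class TestCrossReference:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["mirna_id", "target_id"]).assign(
            target_biotype="mRNA")

    def test_shared_mirnas_recorded(self):
        edges = pd.DataFrame([{"lncrna_id": "L", "mrna_id": "M", "r": 0.9,
                               "p_value": 0.01, "n_samples": 12,
                               "shared_mirnas": None}])
        table = self._table([("mir1", "L"), ("mir1", "M"), ("mir2", "L"),
                             ("mir2", "M"), ("mir3", "L"), ("mir3", "M"),
                             ("mir4", "L")])
        kept = cp.cross_reference(edges, table, min_shared=1)
        assert kept["shared_mirnas"].iloc[0] == ["mir1", "mir2", "mir3"]
        assert len(cp.cross_reference(edges, table, min_shared=4)) == 0

    def test_no_shared_mirna_drops_edge(self):
        edges = pd.DataFrame([{"lncrna_id": "L", "mrna_id": "M", "r": 0.9,
                               "p_value": 0.01, "n_samples": 12,
                               "shared_mirnas": None}])
        table = self._table([("mir1", "L"), ("mir2", "M")])
        assert len(cp.cross_reference(edges, table)) == 0

    def test_empty_table_empty_output(self):
        edges = pd.DataFrame([{"lncrna_id": "L", "mrna_id": "M", "r": 0.9,
                               "p_value": 0.01, "n_samples": 12,
                               "shared_mirnas": None}])
        out = cp.cross_reference(edges, self._table([]))
        assert len(out) == 0

    def test_planted_edges_survive(self, default_dataset, default_fpkm,
                                   default_de):
        config, _, truth = default_dataset
        table = cp.simulate_interaction_table(config, truth)
        sig = default_de[default_de["status"] != "ns"]
        edges = cp.correlation_edges(
            default_fpkm,
            sig.loc[sig["biotype"] == "lncRNA", "gene_id"].tolist(),
            sig.loc[sig["biotype"] == "mRNA", "gene_id"].tolist())
        supported = cp.cross_reference(cp.filter_correlation(edges), table)
        hub_edges = supported[supported["lncrna_id"] == truth.hub_lncrna_id]
        assert len(hub_edges) > 0
        assert set(hub_edges["mrna_id"]) <= set(truth.module_mrna_ids) | set(
            table["target_id"])


class TestBuildCerna:
    def test_single_edge_expansion_counts(self):
        edges = pd.DataFrame([{"lncrna_id": "L", "mrna_id": "M", "r": 0.9,
                               "p_value": 0.01, "n_samples": 12,
                               "shared_mirnas": ["mir1", "mir2"]}])
        g = cp.build_cerna(edges)
        assert g.number_of_nodes() == 4
        kinds = [d["kind"] for _, _, d in g.edges(data=True)]
        assert kinds.count("correlation") == 1
        assert kinds.count("targeting") == 4
        assert g.nodes["L"]["type"] == "lncRNA"
        assert g.nodes["mir1"]["type"] == "miRNA"

    def test_empty_edges_empty_network(self):
        g = cp.build_cerna(pd.DataFrame(columns=cp.cenet.EDGE_COLUMNS)
                           if hasattr(cp, "cenet") else pd.DataFrame(
                               columns=["lncrna_id", "mrna_id", "r", "p_value",
                                        "n_samples", "shared_mirnas"]))
        assert g.number_of_nodes() == 0

    def test_export_import_round_trip(self, tmp_path):
        edges = pd.DataFrame([
            {"lncrna_id": "L1", "mrna_id": "M1", "r": 0.9, "p_value": 0.01,
             "n_samples": 12, "shared_mirnas": ["mir1"]},
            {"lncrna_id": "L1", "mrna_id": "M2", "r": 0.7, "p_value": 0.02,
             "n_samples": 12, "shared_mirnas": ["mir1", "mir2"]},
        ])
        g = cp.build_cerna(edges)
        cp.write_network(g, tmp_path / "e.tsv", tmp_path / "n.tsv")
        back = cp.read_network(tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert nx.utils.graphs_equal(
            nx.Graph(((a, b, {"kind": d["kind"]})
                      for a, b, d in g.edges(data=True))),
            nx.Graph(((a, b, {"kind": d["kind"]})
                      for a, b, d in back.edges(data=True))))
        assert dict(g.nodes(data="type")) == dict(back.nodes(data="type"))
        write_edges_table(edges, tmp_path / "edges.tsv")
        sif = tmp_path / "net.sif"
        cp.write_sif(g, sif)
        assert len(sif.read_text().splitlines()) == g.number_of_edges()
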