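import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from compnoise.clustering import (
    ClusterAssignment,
    build_snn_graph,
    louvain_cluster,
    per_cluster_compare,
    snn_graph_from_neighbors,
)
from compnoise.differential import compare_pair
from compnoise.model import ModelSpec, estimate_size_factors
from compnoise.simulate import preset_scenarios, simulate_dataset


class TestSNNGraph:
    def test_identical_neighbor_sets_give_weight_one(self):
        # cells 0 and 1 both have neighbours {2, 3, 4}
        neighbors = np.array([[2, 3, 4], [2, 3, 4], [0, 1, 3], [0, 1, 2], [0, 1, 2]])
        g = snn_graph_from_neighbors(neighbors)
        assert g[0][1]["weight"] == pytest.approx(1.0)

    def test_disjoint_neighbor_sets_give_no_edge(self):
        neighbors = np.array([[1, 2], [0, 2], [0, 1], [4, 5], [3, 5], [3, 4]])
        g = snn_graph_from_neighbors(neighbors)
        assert not g.has_edge(0, 3)

    def test_weights_match_hand_computed_jaccard_on_ten_cells(self):
        rng = np.random.default_rng(2)
        neighbors = np.array([rng.choice([j for j in range(10) if j != i], 4, replace=False) for i in range(10)])
        g = snn_graph_from_neighbors(neighbors)
        sets = [set(row) for row in neighbors]
        for a, b in itertools.combinations(range(10), 2):
            shared = len(sets[a] & sets[b])
            expected = shared / len(sets[a] | sets[b]) if shared else None
            if expected is None:
                assert not g.has_edge(a, b)
            else:
                assert g[a][b]["weight"] == pytest.approx(expected)

    def test_k_not_smaller_than_cells_rejected(self, redundant_dataset):
        ds = redundant_dataset
        sub = ds.counts.subset_cells(ds.counts.cell_ids[:10])
        sf = estimate_size_factors(sub)
        with pytest.raises(ValueError, match="k="):
            build_snn_graph(sub, sf, k=10)

    def test_graph_weights_in_unit_interval(self, redundant_dataset):
        ds = redundant_dataset
        sub = ds.counts.subset_cells(ds.counts.cell_ids[:150])
        sf = estimate_size_factors(sub)
        g = build_snn_graph(sub, sf, k=10, n_pcs=10)
        weights = np.array([d["weight"] for _, _, d in g.edges(data=True)])
        assert weights.size > 0
        assert np.all((weights > 0) & (weights <= 1))


class TestLouvain:
    def test_two_cliques_recovered_exactly(self):
        g = nx.Graph()
        for block, offset in ((range(3), 0), (range(3), 3)):
            for a, b in itertools.combinations([i + offset for i in block], 2):
                g.add_edge(a, b, weight=1.0)
        g.add_edge(0, 3, weight=0.01)
        ca = louvain_cluster(g, seed=1)
        assert ca.n_clusters == 2
        assert len({ca.labels[i] for i in (0, 1, 2)}) == 1
        assert len({ca.labels[i] for i in (3, 4, 5)}) == 1
        # brute-force modularity over all partitions of 6 nodes confirms optimality
        best = max(
            (nx.community.modularity(g, parts, weight="weight"), parts)
            for parts in _partitions(list(g.nodes()))
        )
        found = [set(ca.labels.index[ca.labels == k]) for k in range(ca.n_clusters)]
        assert nx.community.modularity(g, found, weight="weight") == pytest.approx(best[0])

    def test_uniform_complete_graph_is_one_cluster(self):
        g = nx.complete_graph(8)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert louvain_cluster(g, seed=0).n_clusters == 1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(40, 0.2, seed=4)
        nx.set_edge_attributes(g, 1.0, "weight")
        a = louvain_cluster(g, seed=7)
        b = louvain_cluster(g, seed=7)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_cluster(nx.Graph())


def _partitions(nodes):
    if not nodes:
        yield []
        return
    head, *rest = nodes
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {head}] + part[i + 1 :]
        yield part + [{head}]


class TestPhaseRecovery:
    def test_planted_phases_recovered_and_strains_mixed(self):
        """Joint clustering of two strains separates the planted cell-cycle
        phases (high ARI) and mixes the strains within clusters when the
        strains differ only by modest downstream effects."""
        from sklearn.metrics import adjusted_rand_score

        design = preset_scenarios(
            "redundant_pair", seed=7, n_genes=300, cells_per_replicate=50,
            n_shared=10, n_private=0,
        )
        ds = simulate_dataset(design)
        strain_of = dict(zip(ds.meta["cell_id"], ds.meta["strain"]))
        cells = [c for c in ds.counts.cell_ids if strain_of[c] in ("WT", "dTF1")]
        sub = ds.counts.subset_cells(cells)
        sf = estimate_size_factors(sub)
        ca = louvain_cluster(build_snn_graph(sub, sf, seed=0), seed=0)
        phase = ds.meta.set_index("cell_id").loc[cells, "phase"].to_numpy()
        labels = ca.labels.loc[cells].to_numpy()
        assert adjusted_rand_score(phase, labels) > 0.8
        strains = np.array([strain_of[c] for c in cells])
        for k in range(ca.n_clusters):
            frac_wt = (strains[labels == k] == "WT").mean()
            assert 0.1 <= frac_wt <= 0.9

    def test_marker_genes_biased_across_clusters(self):
        """Phase-marker genes show a far more uneven distribution of their
        counts across recovered clusters than non-marker genes."""
        design = preset_scenarios("null", seed=9, n_genes=300, cells_per_replicate=50)
        ds = simulate_dataset(design)
        strain_of = dict(zip(ds.meta["cell_id"], ds.meta["strain"]))
        cells = [c for c in ds.counts.cell_ids if strain_of[c] in ("WT", "dTF1")]
        sub = ds.counts.subset_cells(cells)
        sf = estimate_size_factors(sub)
        ca = louvain_cluster(build_snn_graph(sub, sf, seed=0), seed=0)
        labels = ca.labels.loc[sub.cell_ids].to_numpy()
        sizes = np.array([(labels == k).sum() for k in range(ca.n_clusters)])
        expected_frac = sizes / sizes.sum()
        chi2 = []
        for row in sub.counts:
            tot = row.sum()
            obs = np.array([row[labels == k].sum() for k in range(ca.n_clusters)])
            exp = expected_frac * tot
            chi2.append(((obs - exp) ** 2 / np.maximum(exp, 1e-9)).sum())
        chi2 = np.array(chi2)
        marker = (
            ds.truth.query("strain == 'WT'").set_index("gene")["phase_marker"]
            .loc[sub.gene_ids].to_numpy()
        )
        cutoff = np.quantile(chi2[~marker], 0.95)
        assert np.median(chi2[marker]) > cutoff


class TestPerClusterCompare:
    SPEC = ModelSpec(n_iter=300, burn_in=150, thin=3, seed=3)

    def test_single_cluster_reduces_to_unclustered_pipeline(self, redundant_dataset):
        ds = redundant_dataset
        strain_of = dict(zip(ds.meta["cell_id"], ds.meta["strain"]))
        cells = [c for c in ds.counts.cell_ids if strain_of[c] in ("WT", "dTF1")]
        sub = ds.counts.subset_cells(cells)
        ca = ClusterAssignment(pd.Series(0, index=cells))
        pcc = per_cluster_compare(sub, ds.meta, ca, ("WT", "dTF1"), self.SPEC, min_cells=10)
        direct = compare_pair(sub, ds.meta, ("WT", "dTF1"), self.SPEC, 0.01)
        got = pcc.tables[0]
        pd.testing.assert_frame_equal(got, direct.table)
        assert pcc.candidates.members == (
            set(direct.table.index[direct.table["call"].isin(["MeanChange", "NoiseOnly"])])
        )

    def test_all_clusters_too_small_raise_with_diagnostics(self, redundant_dataset):
        ds = redundant_dataset
        strain_of = dict(zip(ds.meta["cell_id"], ds.meta["strain"]))
        cells = [c for c in ds.counts.cell_ids if strain_of[c] in ("WT", "dTF1")]
        sub = ds.counts.subset_cells(cells)
        ca = ClusterAssignment(pd.Series(0, index=cells))
        with pytest.raises(ValueError, match="skip reasons"):
            per_cluster_compare(
                sub, ds.meta, ca, ("WT", "dTF1"), self.SPEC, min_cells=10**6
            )

    def test_candidate_if_significant_in_any_cluster(self):
        calls = pd.DataFrame(
            {
                "cluster0": ["NoChange", "NoChange"],
                "cluster1": ["NoiseOnly", "NoChange"],
            },
            index=pd.Index(["hit", "miss"], name="gene"),
        )
        from compnoise.clustering import PerClusterCalls

        pcc = PerClusterCalls(calls=calls, skipped={})
        assert pcc.candidates.members == {"hit"}
        assert pcc.aggregated_call()["hit"] == "NoiseOnly"
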