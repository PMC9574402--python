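import numpy as np
import pandas as pd
import pytest

from apmsquant.enrich import enrich_proteins, filter_all_replicates
from apmsquant.errors import ApmsError
from apmsquant.netpca import (
    build_network,
    filter_network_nodes,
    pca_replicates,
)
from apmsquant.quantify import build_quant_matrix
from apmsquant.simulate import SimulationConfig, default_interactors, simulate_experiment


def records(rows):
    return pd.DataFrame(
        rows, columns=["protein", "mean_si_gi", "significant", "detected_in_all"]
    )


class TestNodeFilter:
    def test_threshold_boundary_is_strict(self):
        recs = records(
            [
                ("at_threshold", 0.0005, True, True),
                ("just_above", 0.00051, True, True),
                ("partial", 0.01, True, False),
                ("not_significant", 0.01, False, True),
            ]
        )
        kept = filter_network_nodes(recs)
        assert list(kept["protein"]) == ["just_above"]

    def test_matches_brute_force_refilter(self):
        rng = np.random.default_rng(17)
        recs = records(
            [
                (f"P{i}", float(rng.lognormal(-7, 2)), bool(rng.random() < 0.6), bool(rng.random() < 0.8))
                for i in range(200)
            ]
        )
        kept = set(filter_network_nodes(recs, 0.0005)["protein"])
        brute = {
            r.protein
            for r in recs.itertuples(index=False)
            if r.significant and r.detected_in_all and r.mean_si_gi > 0.0005
        }
        assert kept == brute

    def test_negative_threshold_rejected(self):
        with pytest.raises(ApmsError):
            filter_network_nodes(records([]), -1.0)


class TestBuildNetwork:
    NODES = records([("A", 0.01, True, True), ("B", 0.002, True, True), ("C", 0.001, True, True)])

    def edges(self, rows):
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])

    def test_empty_interaction_table_gives_isolated_nodes(self):
        g = build_network(self.NODES, self.edges([]))
        assert set(g.nodes) == {"A", "B", "C"} and g.number_of_edges() == 0

    def test_edges_restricted_to_node_pairs(self):
        g = build_network(self.NODES, self.edges([("A", "B", 0.9), ("B", "D", 0.8)]))
        assert set(g.edges) == {("A", "B")}

    def test_reversed_duplicate_rows_collapse(self):
        g = build_network(
            self.NODES, self.edges([("A", "B", 0.5), ("B", "A", 0.9), ("C", "C", 1.0)])
        )
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["score"] == 0.9  # best score kept

    def test_go_annotation_attaches_top_term(self):
        ann = pd.DataFrame(
            {
                "protein": ["A", "A", "B"],
                "go_term": ["cytoskeleton organization", "ion transport", "signal transduction"],
                "score": [0.4, 0.9, 0.7],
            }
        )
        g = build_network(self.NODES, None, ann)
        assert g.nodes["A"]["go_term"] == "ion transport"
        assert g.nodes["C"]["go_term"] == ""
        assert g.nodes["A"]["mean_si_gi"] == 0.01


class TestPcaReplicates:
    def make_matrix(self, values, conditions=None):
        proteins = [f"P{i}" for i in range(values.shape[0])]
        runs = [f"r{j}" for j in range(values.shape[1])]
        vals = pd.DataFrame(values, index=proteins, columns=runs)
        meta = pd.DataFrame(
            {
                "condition": conditions or ["bait"] * len(runs),
                "bait_label": "IP",
                "genotype": "WT",
                "band": "250kDa",
            },
            index=pd.Index(runs, name="run_id"),
        )
        from apmsquant.quantify import QuantMatrix

        return QuantMatrix(values=vals, detected=vals > 0, runs=meta)

    def test_rank_one_case(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        matrix = self.make_matrix(np.vstack([x, 10 * x]))
        result = pca_replicates(matrix)
        assert result.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert result.variance_fractions[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_fixture(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2, 6))  # 2 features x 6 runs
        matrix = self.make_matrix(X)
        result = pca_replicates(matrix)
        assert result.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert result.variance_fractions[0] >= result.variance_fractions[1]
        Z = (X.T - X.T.mean(0)) / X.T.std(0, ddof=1)
        ref = sklearn_pca(n_components=2).fit(Z)
        assert np.allclose(
            result.variance_fractions, ref.explained_variance_ratio_, atol=1e-10
        )
        assert np.allclose(
            np.abs(result.scores.to_numpy()), np.abs(ref.transform(Z)), atol=1e-10
        )

    def test_scores_invariant_to_feature_order_up_to_sign(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 7))
        m = self.make_matrix(X)
        a = pca_replicates(m)
        order = ["P3", "P0", "P4", "P1", "P2"]
        b = pca_replicates(m, features=order)
        assert np.allclose(a.variance_fractions, b.variance_fractions, atol=1e-10)
        assert np.allclose(np.abs(a.scores.to_numpy()), np.abs(b.scores.to_numpy()), atol=1e-10)

    def test_variance_fractions_non_increasing_and_normalized(self):
        rng = np.random.default_rng(15)
        m = self.make_matrix(rng.lognormal(0, 1, size=(20, 8)))
        result = pca_replicates(m)
        f = result.variance_fractions
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(f) <= min(8, 20)

    def test_zero_variance_feature_dropped_with_warning(self):
        X = np.vstack([np.ones(4), [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 2.0, 3.0]])
        m = self.make_matrix(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            result = pca_replicates(m)
        assert result.dropped_features == ["P0"]
        assert result.features == ["P1", "P2"]

    def test_degenerate_inputs_rejected(self):
        m = self.make_matrix(np.ones((3, 4)))
        with pytest.raises(ApmsError, match="non-zero variance"):
            pca_replicates(m)
        tiny = self.make_matrix(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ApmsError, match=">= 3 runs"):
            pca_replicates(tiny)


def test_two_bait_experiment_separates_along_pc1():
    """Disjoint planted interactomes put the two purifications on opposite
    sides of the first principal component."""
    a = simulate_experiment(
        SimulationConfig(
            seed=31,
            bait_label="alpha1-IP",
            interactors=default_interactors(12),
            n_background=40,
            dropout=0.0,
        )
    )
    b_int = {f"X{i:03d}": f for i, f in enumerate(default_interactors(12).values())}
    b = simulate_experiment(
        SimulationConfig(
            seed=32,
            bait_label="alpha4-IP",
            bait_proteins={"GABRA4": 4.6, "GABRB3": 1.0},
            interactors=b_int,
            n_background=40,
            dropout=0.0,
            n_control_runs=0,
        )
    )
    psms = pd.concat([a.psms, b.psms], ignore_index=True)
    matrix = build_quant_matrix(psms)
    features = set()
    for label in ("alpha1-IP", "alpha4-IP"):
        recs = filter_all_replicates(enrich_proteins(matrix, bait_label=label))
        features |= set(recs.loc[recs["significant"], "protein"])
    result = pca_replicates(matrix, features=sorted(features))
    scores = result.scores["PC1"]
    mean_a = scores[[r for r in scores.index if r.startswith("alpha1")]].mean()
    mean_b = scores[[r for r in scores.index if r.startswith("alpha4")]].mean()
    assert mean_a * mean_b < 0
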