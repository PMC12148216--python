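import numpy as np
import pandas as pd
import pytest

from kgsynergy.embedding.training import TrainConfig, train_embeddings
from kgsynergy.features import (
    KGTopology,
    build_pair_features,
    tanimoto,
    topology_features,
)
from kgsynergy.kg import KnowledgeGraph
from kgsynergy.ml import MODEL_GRIDS, nested_cv
from kgsynergy.synthetic import (
    generate_drug_properties,
    generate_labeled_pair_features,
)


class TestTopology:
    def test_triangle_clustering_coefficient(self):
        kg = KnowledgeGraph.from_triples([("a", "r", "b"), ("b", "r", "c"), ("c", "r", "a")])
        topo = KGTopology(kg)
        assert topo.node_features("a")["clustering"] == 1.0

    def test_two_node_symmetric_pagerank(self):
        kg = KnowledgeGraph.from_triples([("a", "r", "b")])
        topo = KGTopology(kg)
        assert topo.pagerank["a"] == pytest.approx(0.5)
        assert topo.pagerank["b"] == pytest.approx(0.5)

    def test_adjacent_nodes_distance_one(self):
        kg = KnowledgeGraph.from_triples([("a", "r", "b"), ("b", "r", "c")])
        feats = topology_features(kg, "a", "b")
        assert feats["shortest_path"] == 1.0

    def test_adjacency_cosine(self):
        # a and b share exactly one neighbour (c); deg(a)=deg(b)=2
        kg = KnowledgeGraph.from_triples(
            [("a", "r", "c"), ("b", "r", "c"), ("a", "r", "x"), ("b", "r", "y")]
        )
        topo = KGTopology(kg)
        assert topo.adjacency_cosine("a", "b") == pytest.approx(1 / 2)

    def test_missing_drug_errors(self):
        kg = KnowledgeGraph.from_triples([("a", "r", "b")])
        with pytest.raises(KeyError, match="zz"):
            topology_features(kg, "zz", "a")


class TestTanimoto:
    def test_identity(self):
        assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_set_arithmetic(self):
        assert tanimoto({1, 2}, {2, 3}) == pytest.approx(1 / 3)

    def test_disjoint_and_empty(self):
        assert tanimoto({1}, {2}) == 0.0
        with pytest.warns(UserWarning):
            assert tanimoto(set(), set()) == 0.0

    def test_array_input(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = np.array([0, 1, 1, 0], dtype=bool)
        assert tanimoto(a, b) == pytest.approx(1 / 3)


def _handcrafted_inputs(n_drugs=10, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [f"D{i}" for i in range(n_drugs)]
    triples = []
    for i in range(n_drugs):
        for j in rng.choice(n_drugs, size=3, replace=False):
            if i != j:
                triples.append((drugs[i], "targets", f"P{j}"))
        triples.append((drugs[i], "targets", f"P{(i + 1) % n_drugs}"))
    kg = KnowledgeGraph.from_triples(triples, entity_type={d: "Drug" for d in drugs})
    table, fps = generate_drug_properties(drugs, seed=seed, n_bits=64)
    return kg, drugs, table, fps


class TestBuildPairFeatures:
    def test_order_invariance(self):
        kg, drugs, table, fps = _handcrafted_inputs()
        topo = KGTopology(kg)
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(30):
            a, b = rng.choice(len(drugs), size=2, replace=False)
            pairs.append((drugs[a], drugs[b]))
        fwd = build_pair_features(pairs, "handcrafted", topo, table, fps)
        rev = build_pair_features([(b, a) for a, b in pairs], "handcrafted", topo, table, fps)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_embedding_mode_dimension(self):
        kg = KnowledgeGraph.from_triples([("A", "r", "B"), ("B", "r", "C")])
        state = train_embeddings(kg, TrainConfig(model="TransE", dim=64, epochs=1, seed=0))
        X = build_pair_features([("A", "B")], mode="embedding", embeddings=state)
        assert X.shape == (1, 128)

    def test_missing_value_imputed_with_mask(self):
        kg, drugs, table, fps = _handcrafted_inputs()
        table.loc[drugs[0], "logp"] = np.nan
        X = build_pair_features([(drugs[0], drugs[1])], "handcrafted", KGTopology(kg), table, fps)
        assert X["a_logp_imputed"].iloc[0] == 1.0
        assert np.isfinite(X["a_logp"].iloc[0])
        assert not X.isna().any().any()

    def test_missing_drug_errors(self):
        kg, drugs, table, fps = _handcrafted_inputs()
        with pytest.raises(KeyError):
            build_pair_features([("D0", "nope")], "handcrafted", KGTopology(kg), table, fps)

    def test_disconnected_pair_gets_finite_sentinel(self):
        kg = KnowledgeGraph.from_triples([("a", "r", "b"), ("x", "r", "y")])
        table, fps = generate_drug_properties(["a", "b", "x", "y"], seed=0, n_bits=16)
        X = build_pair_features(
            [("a", "b"), ("a", "x")], "handcrafted", KGTopology(kg), table, fps
        )
        finite_max = 1.0  # a-b are adjacent
        assert X["shortest_path"].iloc[1] == finite_max + 1.0


class TestNestedCV:
    def test_separable_features_random_forest(self):
        X, y = generate_labeled_pair_features(n_pairs=120, seed=0)
        reports = nested_cv(X, y, models=["random_forest"], n_loops=2, seed=0)
        assert reports["random_forest"].mean_holdout_auc >= 0.95

    def test_reproducible_under_fixed_seed(self):
        X, y = generate_labeled_pair_features(n_pairs=80, seed=1)
        grids = {"logistic_regression": {"clf__C": [1.0]}}
        r1 = nested_cv(X, y, models=["logistic_regression"], grids=grids, n_loops=2, seed=3)
        r2 = nested_cv(X, y, models=["logistic_regression"], grids=grids, n_loops=3, seed=3)
        assert (
            r1["logistic_regression"].holdout_auc
            == r2["logistic_regression"].holdout_auc[:2]
        )

    def test_stratification_and_split_sizes(self):
        X, y = generate_labeled_pair_features(n_pairs=100, seed=2)
        reports = nested_cv(
            X, y, models=["logistic_regression"],
            grids={"logistic_regression": {"clf__C": [1.0]}}, n_loops=1, seed=0,
        )
        rep = reports["logistic_regression"]
        assert rep.n_train == 90 and rep.n_holdout == 10

    def test_single_class_errors(self):
        X = np.zeros((30, 2))
        with pytest.raises(ValueError):
            nested_cv(X, ["synergism"] * 30, models=["svm"], seed=0)

    def test_empty_grid_errors(self):
        X, y = generate_labeled_pair_features(n_pairs=40, seed=0)
        with pytest.raises(ValueError):
            nested_cv(X, y, models=["svm"], grids={"svm": {}}, seed=0)

    def test_all_five_models_share_report_schema(self):
        X, y = generate_labeled_pair_features(n_pairs=60, seed=4)
        grids = {name: {k: v[:1] for k, v in grid.items()} for name, grid in MODEL_GRIDS.items()}
        reports = nested_cv(X, y, grids=grids, n_loops=1, seed=0)
        assert set(reports) == set(MODEL_GRIDS)
        for rep in reports.values():
            assert len(rep.holdout_auc) == 1
            assert 0.0 <= rep.holdout_auc[0] <= 1.0
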