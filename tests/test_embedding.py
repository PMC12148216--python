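import numpy as np
import pytest

from kgsynergy.embedding.models import (
    MODEL_REGISTRY,
    circular_correlation,
    circular_correlation_naive,
    get_model,
)
from kgsynergy.embedding.training import (
    ModelState,
    TrainConfig,
    sample_negatives,
    train_embeddings,
)
from kgsynergy.kg import KnowledgeGraph
from kgsynergy.splitting import split_triples

MODELS = sorted(MODEL_REGISTRY)


class TestScoreAlgebra:
    def test_hole_worked_example(self):
        # (h * t) for h=(1,2), t=(3,4) is (11, 10); r=(1,0) dots to 11
        model = get_model("HolE")
        params = {"ent": np.array([[1.0, 2.0], [3.0, 4.0]]), "rel": np.array([[1.0, 0.0]])}
        corr = circular_correlation_naive(params["ent"][0], params["ent"][1])
        assert np.allclose(corr, [11.0, 10.0])
        score = model.score(params, np.array([0]), np.array([0]), np.array([1]))
        assert score[0] == pytest.approx(11.0)

    def test_hole_fft_matches_double_loop_oracle(self, rng):
        for d in (2, 3, 5, 8, 16):
            a = rng.normal(size=d)
            b = rng.normal(size=d)
            assert np.allclose(
                circular_correlation(a, b), circular_correlation_naive(a, b), atol=1e-10
            )

    def test_complex_hand_example_zero(self):
        # h=1+1i, r=2+0i, t=1-1i (d=1): Re(h r conj(t)) = Re(4i) = 0
        model = get_model("ComplEx")
        params = {
            "ent_re": np.array([[1.0], [1.0]]),
            "ent_im": np.array([[1.0], [-1.0]]),
            "rel_re": np.array([[2.0]]),
            "rel_im": np.array([[0.0]]),
        }
        score = model.score(params, np.array([0]), np.array([0]), np.array([1]))
        assert score[0] == pytest.approx(0.0)

    def test_transe_exact_translation_is_maximal(self):
        model = MODEL_REGISTRY["TransE"](normalize_entities=False)
        params = {"ent": np.array([[0.0, 0.0], [1.0, 1.0]]), "rel": np.array([[1.0, 1.0]])}
        score = model.score(params, np.array([0]), np.array([0]), np.array([1]))
        assert score[0] == pytest.approx(0.0, abs=1e-5)

    def test_complex_real_relation_symmetry(self, rng):
        model = get_model("ComplEx")
        d, n = 6, 4
        params = {
            "ent_re": rng.normal(size=(n, d)),
            "ent_im": rng.normal(size=(n, d)),
            "rel_re": rng.normal(size=(1, d)),
            "rel_im": np.zeros((1, d)),
        }
        h, r, t = np.array([0]), np.array([0]), np.array([1])
        assert model.score(params, h, r, t)[0] == pytest.approx(
            model.score(params, t, r, h)[0]
        )

    def test_complex_imaginary_relation_antisymmetry(self, rng):
        model = get_model("ComplEx")
        d, n = 6, 4
        params = {
            "ent_re": rng.normal(size=(n, d)),
            "ent_im": rng.normal(size=(n, d)),
            "rel_re": np.zeros((1, d)),
            "rel_im": rng.normal(size=(1, d)),
        }
        h, r, t = np.array([0]), np.array([0]), np.array([1])
        assert model.score(params, h, r, t)[0] == pytest.approx(
            -model.score(params, t, r, h)[0]
        )

    def test_rotate_phase_pi_symmetry(self, rng):
        model = get_model("RotatE")
        d, n = 5, 6
        params = {
            "ent_re": rng.normal(size=(n, d)),
            "ent_im": rng.normal(size=(n, d)),
            "phase": np.full((1, d), np.pi),
        }
        for h, t in [(0, 1), (2, 3), (4, 5)]:
            s_ht = model.score(params, np.array([h]), np.array([0]), np.array([t]))[0]
            s_th = model.score(params, np.array([t]), np.array([0]), np.array([h]))[0]
            assert s_ht == pytest.approx(s_th, rel=1e-10)

    def test_transe_translation_invariance(self, rng):
        model = MODEL_REGISTRY["TransE"](normalize_entities=False)
        d, n = 8, 5
        params = {"ent": rng.normal(size=(n, d)), "rel": rng.normal(size=(3, d))}
        h, r, t = np.array([0, 1]), np.array([0, 2]), np.array([2, 3])
        before = model.score(params, h, r, t)
        shifted = {"ent": params["ent"] + rng.normal(size=d), "rel": params["rel"]}
        assert np.allclose(model.score(shifted, h, r, t), before)


class TestGradients:
    @pytest.mark.parametrize("name", MODELS)
    def test_backward_matches_finite_differences(self, name, rng):
        model = get_model(name)
        n_ent, n_rel, d = 5, 3, 4
        params = model.init_params(n_ent, n_rel, d, rng)
        h = np.array([0, 1, 2])
        r = np.array([0, 1, 2])
        t = np.array([3, 4, 0])
        upstream = rng.normal(size=3)

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        model.backward(params, h, r, t, upstream, grads)

        def objective(p):
            return float(np.dot(upstream, model.score(p, h, r, t)))

        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            for idx in rng.choice(flat.size, size=min(20, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = objective(params)
                flat[idx] = orig - eps
                down = objective(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), (
                    f"{name}.{key}[{idx}]"
                )


class TestNegativeSampling:
    def test_counts_and_single_slot_difference(self, rng):
        pos = np.array([[0, 0, 1], [2, 1, 3]] * 5)
        neg = sample_negatives(pos, n_entities=10, k=5, rng=rng)
        assert len(neg) == 50
        rep = np.repeat(pos, 5, axis=0)
        diffs = (neg != rep).sum(axis=1)
        assert np.all(diffs == 1)
        assert np.all(neg[:, 1] == rep[:, 1])  # relation never corrupted

    def test_determinism(self):
        pos = np.array([[0, 0, 1], [2, 1, 3]])
        a = sample_negatives(pos, 10, 3, np.random.default_rng(7))
        b = sample_negatives(pos, 10, 3, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_too_few_entities(self, rng):
        with pytest.raises(ValueError):
            sample_negatives(np.array([[0, 0, 0]]), 1, 1, rng)


class TestTraining:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(negatives_per_positive=0)
        with pytest.raises(ValueError):
            TrainConfig(model="NotAModel")

    def test_determinism_identical_final_parameters(self, small_planted):
        _, kg, _ = small_planted
        cfg = TrainConfig(model="TransE", dim=8, epochs=3, seed=5)
        s1 = train_embeddings(kg, cfg)
        s2 = train_embeddings(kg, cfg)
        for key in s1.params:
            assert np.array_equal(s1.params[key], s2.params[key])

    @pytest.mark.parametrize("name", MODELS)
    def test_loss_decreases_on_moving_average(self, name, small_planted):
        _, kg, _ = small_planted
        cfg = TrainConfig(model=name, dim=16, epochs=15, seed=0)
        state = train_embeddings(kg, cfg)
        traj = np.array(state.loss_trajectory)
        ma = np.convolve(traj, np.ones(5) / 5, mode="valid")
        assert ma[-1] < ma[0]

    def test_rotate_phases_stay_unit_modulus(self, small_planted):
        _, kg, _ = small_planted
        state = train_embeddings(kg, TrainConfig(model="RotatE", dim=8, epochs=2, seed=0))
        mod = np.cos(state.params["phase"]) ** 2 + np.sin(state.params["phase"]) ** 2
        assert np.allclose(mod, 1.0)


class TestRanking:
    def _tiny_state(self, n_rel=1):
        kg = KnowledgeGraph.from_triples(
            [("a", f"r{i}", "b") for i in range(n_rel)] + [("b", "r0", "c")]
        )
        return train_embeddings(kg, TrainConfig(model="TransE", dim=4, epochs=2, seed=0))

    def test_singleton_vocabulary(self):
        state = self._tiny_state(n_rel=1)
        ranking = state.rank_relations("a", "b")
        assert ranking.relation_at(1) == "r0"
        assert len(ranking.ranked) == 1

    def test_full_vocabulary_and_tie_break_stability(self):
        state = self._tiny_state(n_rel=4)
        r1 = state.rank_relations("a", "c")
        r2 = state.rank_relations("a", "c")
        assert [rel for rel, _ in r1.ranked] == [rel for rel, _ in r2.ranked]
        assert sorted(rel for rel, _ in r1.ranked) == sorted(state.relation_index)
        scores = [s for _, s in r1.ranked]
        assert scores == sorted(scores, reverse=True)

    def test_equal_scores_fall_back_to_vocabulary_order(self):
        state = self._tiny_state(n_rel=3)
        # force exactly equal relation vectors -> equal scores
        state.params["rel"][:] = 0.0
        ranking = state.rank_relations("a", "b")
        assert [rel for rel, _ in ranking.ranked] == state.relations

    def test_nan_parameters_rejected(self):
        state = self._tiny_state()
        state.params["ent"][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            state.rank_relations("a", "b")

    def test_unknown_entity_lookup(self):
        state = self._tiny_state()
        with pytest.raises(KeyError):
            state.score_triple("nope", "r0", "b")


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, small_planted):
        _, kg, _ = small_planted
        cfg = TrainConfig(model="HolE", dim=8, epochs=2, seed=1)
        state = train_embeddings(kg, cfg)
        path = tmp_path / "model.npz"
        state.save(path)
        back = ModelState.load(path)
        assert back.model_name == "HolE"
        assert back.entity_index == state.entity_index
        assert back.relation_index == state.relation_index
        for key in state.params:
            assert np.array_equal(back.params[key], state.params[key])
        h, t = state.relations[0], None
        ents = sorted(state.entity_index)
        assert back.rank_relations(ents[0], ents[1]).ranked == state.rank_relations(
            ents[0], ents[1]
        ).ranked
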