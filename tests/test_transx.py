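import numpy as np
import pytest

from kgcascade import (
    KnowledgeGraph,
    PlantedKGSpec,
    Side,
    TransXConfig,
    TransXModel,
    Triplet,
    init_transx,
    make_translation_kg,
    margin_loss,
    project_entity,
    score_batch,
    score_triplet,
    train_transx,
)
from kgcascade.tasks import roc_curve
from kgcascade.transx import pair_gradients, sparse_degrees


def small_graph():
    g, _ = make_translation_kg(
        PlantedKGSpec(n_entities=12, n_relations=2, triplets_per_relation=20, seed=3)
    )
    return g


class TestConfig:
    def test_transe_requires_equal_dims(self):
        with pytest.raises(ValueError):
            TransXConfig(model="transe", dim_entity=4, dim_relation=8)

    def test_margin_must_be_positive(self):
        with pytest.raises(ValueError):
            TransXConfig(margin=0.0)

    def test_defaults_follow_reference_protocol(self):
        cfg = TransXConfig()
        assert (cfg.margin, cfg.learn_rate, cfg.dim_entity, cfg.epochs) == (
            1.5, 0.001, 100, 1000,
        )


class TestSparseDegrees:
    def test_formula_on_hand_counts(self):
        # relation 0 links 2 distinct heads, relation 1 links 4 -> theta (0.5, 0)
        g = KnowledgeGraph(
            [f"e{i}" for i in range(8)],
            ["r0", "r1"],
            [Triplet(0, 0, 4), Triplet(1, 0, 4)]
            + [Triplet(i, 1, 7) for i in range(4)],
        )
        theta_h, _ = sparse_degrees(g, theta_min=0.0)
        assert theta_h == pytest.approx([0.5, 0.0])

    def test_busiest_relation_gets_theta_min(self):
        g = small_graph()
        theta_h, theta_t = sparse_degrees(g, theta_min=0.3)
        assert min(theta_h) == pytest.approx(0.3)
        assert min(theta_t) == pytest.approx(0.3)

    def test_full_sparsity_projects_to_zero(self):
        g = small_graph()
        cfg = TransXConfig(
            model="transparse", dim_entity=4, dim_relation=4, theta_min=1.0, seed=0
        )
        m = init_transx(g, cfg)
        v = project_entity(m, 0, 0, Side.HEAD)
        assert np.allclose(v, 0.0)

    def test_declared_sparsity_matches_stored_pattern(self):
        g = small_graph()
        cfg = TransXConfig(
            model="transparse", dim_entity=6, dim_relation=6, theta_min=0.2, seed=1
        )
        m = init_transx(g, cfg)
        size = 36
        for r in range(g.n_relations):
            nnz = m.mask_head[r].sum()
            expected = round((1 - m.theta_head[r]) * size)
            assert abs(nnz - expected) <= 1


class TestScoring:
    def _manual_model(self):
        cfg = TransXConfig(model="transe", dim_entity=2, dim_relation=2, margin=1.0)
        ev = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0]])
        rv = np.array([[1.0, 0.0], [0.0, 1.0]])
        return TransXModel(cfg, ev, rv)

    def test_exact_translation_scores_zero(self):
        m = self._manual_model()
        assert score_triplet(m, Triplet(0, 0, 1)) == 0.0

    def test_l1_score_hand_example(self):
        cfg = TransXConfig(model="transe", dim_entity=2, dim_relation=2, norm="L1")
        ev = np.array([[1.0, 2.0], [0.0, 0.0]])
        rv = np.array([[0.0, 1.0]])
        m = TransXModel(cfg, ev, rv)
        assert score_triplet(m, Triplet(0, 0, 1)) == pytest.approx(4.0)  # |1| + |3|

    def test_l2_never_exceeds_l1(self, rng):
        g = small_graph()
        m1 = init_transx(g, TransXConfig(model="transe", dim_entity=8, dim_relation=8, norm="L1", seed=2))
        m2 = TransXModel(m1.config.__class__(**{**m1.config.__dict__, "norm": "L2"}),
                         m1.entity_vecs, m1.relation_vecs)
        for _ in range(20):
            t = Triplet(int(rng.integers(12)), int(rng.integers(2)), int(rng.integers(12)))
            assert score_triplet(m2, t) <= score_triplet(m1, t) + 1e-12

    def test_projection_hand_matrix_vector_product(self):
        g = KnowledgeGraph(["a", "b"], ["r"], [Triplet(0, 0, 1)])
        cfg = TransXConfig(model="transparse", dim_entity=2, dim_relation=2, seed=0)
        m = init_transx(g, cfg)
        m.proj_head[0] = np.array([[1.0, 0.0], [1.0, 1.0]])
        m.mask_head[0] = np.ones((2, 2), dtype=bool)
        m.entity_vecs[0] = [2.0, 3.0]
        assert np.allclose(project_entity(m, 0, 0, Side.HEAD), [2.0, 5.0])

    def test_batch_scores_match_single(self, rng):
        g = small_graph()
        for model in ("transe", "transparse"):
            m = init_transx(
                g, TransXConfig(model=model, dim_entity=5, dim_relation=5, seed=4)
            )
            ts = [
                Triplet(int(rng.integers(12)), int(rng.integers(2)), int(rng.integers(12)))
                for _ in range(10)
            ]
            batch = score_batch(m, np.array([tuple(t) for t in ts]))
            singles = [score_triplet(m, t) for t in ts]
            assert np.allclose(batch, singles)

    def test_scores_invariant_under_entity_permutation(self, rng):
        g = small_graph()
        m = init_transx(g, TransXConfig(model="transe", dim_entity=6, dim_relation=6, seed=5))
        perm = rng.permutation(g.n_entities)
        m2 = m.copy()
        m2.entity_vecs = m.entity_vecs[perm]
        inv = np.argsort(perm)
        for t in list(sorted(g.triplets))[:10]:
            assert score_triplet(m, t) == pytest.approx(
                score_triplet(m2, Triplet(inv[t.head], t.relation, inv[t.tail]))
            )


class TestMarginLoss:
    @pytest.mark.parametrize(
        "d_pos,d_neg,margin,expected",
        [(0.2, 2.0, 1.5, 0.0), (1.0, 1.2, 1.5, 1.3), (0.7, 0.7, 1.5, 1.5)],
    )
    def test_hinge_values(self, d_pos, d_neg, margin, expected):
        assert margin_loss(d_pos, d_neg, margin) == pytest.approx(expected)


@pytest.mark.parametrize("model_name", ["transe", "transparse"])
@pytest.mark.parametrize("norm", ["L1", "L2"])
def test_gradients_match_central_finite_differences(model_name, norm, rng):
    """Analytic hinge-loss gradients agree with finite differences to 1e-4."""
    g = small_graph()
    cfg = TransXConfig(
        model=model_name, dim_entity=5, dim_relation=5, margin=1.0, norm=norm,
        theta_min=0.3 if model_name == "transparse" else 0.0, seed=1,
    )
    m = init_transx(g, cfg)
    m.entity_vecs += 0.1 * rng.standard_normal(m.entity_vecs.shape)
    if m.is_sparse:
        m.proj_head += 0.05 * rng.standard_normal(m.proj_head.shape) * m.mask_head
        m.proj_tail += 0.05 * rng.standard_normal(m.proj_tail.shape) * m.mask_tail
    pos, neg = Triplet(0, 0, 1), Triplet(2, 0, 1)
    loss, grads = pair_gradients(m, pos, neg, 1.0)
    assert loss > 0
    arrays = {
        "entity": m.entity_vecs, "relation": m.relation_vecs,
        "proj_head": m.proj_head, "proj_tail": m.proj_tail,
    }
    eps = 1e-6
    for (kind, idx), grad in grads.items():
        arr = arrays[kind]
        mask = None
        if kind == "proj_head":
            mask = m.mask_head[idx]
        elif kind == "proj_tail":
            mask = m.mask_tail[idx]
        it = np.nditer(grad, flags=["multi_index"])
        while not it.finished:
            mi = it.multi_index
            if mask is not None and not mask[mi]:
                it.iternext()
                continue
            orig = arr[idx][mi]
            arr[idx][mi] = orig + eps
            lp = margin_loss(score_triplet(m, pos), score_triplet(m, neg), 1.0)
            arr[idx][mi] = orig - eps
            lm = margin_loss(score_triplet(m, pos), score_triplet(m, neg), 1.0)
            arr[idx][mi] = orig
            fd = (lp - lm) / (2 * eps)
            if abs(fd) > 1e-7 or abs(grad[mi]) > 1e-7:
                rel = abs(fd - grad[mi]) / max(abs(fd), abs(grad[mi]))
                assert rel < 1e-4, f"{kind}[{idx}]{mi}: fd={fd} vs {grad[mi]}"
            it.iternext()


class TestTraining:
    def test_zero_epochs_returns_initialization(self):
        g = small_graph()
        cfg = TransXConfig(model="transe", dim_entity=4, dim_relation=4, epochs=0, seed=8)
        assert np.array_equal(
            train_transx(g, cfg).entity_vecs, init_transx(g, cfg).entity_vecs
        )

    def test_fixed_seed_reproduces_trajectory(self):
        g = small_graph()
        cfg = TransXConfig(
            model="transe", dim_entity=4, dim_relation=4, epochs=5,
            learn_rate=0.05, margin=0.5, batch_size=8, seed=8,
        )
        assert np.array_equal(
            train_transx(g, cfg).entity_vecs, train_transx(g, cfg).entity_vecs
        )

    def test_entity_norms_bounded_after_training(self):
        g = small_graph()
        cfg = TransXConfig(
            model="transe", dim_entity=4, dim_relation=4, epochs=10,
            learn_rate=0.1, margin=0.5, batch_size=4, seed=2,
        )
        m = train_transx(g, cfg)
        assert np.all(np.linalg.norm(m.entity_vecs, axis=1) <= 1.0 + 1e-9)

    def test_sparse_zero_pattern_conserved_through_training(self):
        g = small_graph()
        cfg = TransXConfig(
            model="transparse", dim_entity=5, dim_relation=5, theta_min=0.3,
            epochs=10, learn_rate=0.05, margin=0.5, batch_size=4, seed=3,
        )
        m = train_transx(g, cfg)
        assert np.all(m.proj_head[~m.mask_head] == 0.0)
        assert np.all(m.proj_tail[~m.mask_tail] == 0.0)

    def test_planted_positives_score_below_corruptions(self, planted, rng):
        """After training, held-out true facts are closer to h + r = t than
        random corruptions (AUC > 0.9 on the noise-free planted graph)."""
        from kgcascade import corrupt_triplet, split_train_test

        g, _ = planted
        train, test = split_train_test(g, 20, seed=5)
        cfg = TransXConfig(
            model="transe", dim_entity=16, dim_relation=16, margin=0.25,
            learn_rate=0.05, epochs=200, norm="L2", batch_size=1, seed=6,
        )
        m = train_transx(train, cfg)
        negs = [corrupt_triplet(t, g, rng).triplet for t in test]
        d_pos = score_batch(m, np.array([tuple(t) for t in test]))
        d_neg = score_batch(m, np.array([tuple(t) for t in negs]))
        assert d_pos.mean() < d_neg.mean()
        scores = np.concatenate([-d_pos, -d_neg])
        labels = np.array([1] * len(test) + [0] * len(negs))
        _, _, auc = roc_curve(scores, labels)
        assert auc > 0.9

    def test_checkpoint_roundtrip(self, tmp_path):
        g = small_graph()
        cfg = TransXConfig(
            model="transparse", dim_entity=4, dim_relation=4, epochs=2,
            learn_rate=0.05, margin=0.5, batch_size=8, seed=9,
        )
        m = train_transx(g, cfg)
        m.save(tmp_path / "ckpt")
        m2 = TransXModel.load(tmp_path / "ckpt")
        assert np.array_equal(m.entity_vecs, m2.entity_vecs)
        assert np.array_equal(m.proj_head, m2.proj_head)
        assert m2.config == cfg
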