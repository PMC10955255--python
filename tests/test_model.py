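"""Contrastive loss, embedding properties, pair construction, training."""

import numpy as np
import pytest

from svembed.model import (
    EmbeddingModel,
    LossConfig,
    ModelConfig,
    TrainConfig,
    contrastive_loss,
    ensemble_distance,
    load_model,
    make_training_pairs,
    pair_distance,
    save_model,
    train,
)
from svembed.pileup import ImageTensor, Window
from svembed.variants import GenotypeHypothesis, SVRecord

GEOM = ModelConfig(height=16, width=32, embedding_dim=16)


def _img(rng, h=16, w=32, provenance="actual"):
    data = rng.random((h, w, 9)).astype(np.float32)
    return ImageTensor(data, Window("chr1", 0, w), provenance)


class TestContrastiveLoss:
    @pytest.mark.parametrize(
        "y,d,m,expected",
        [
            (1, 0.0, 1.0, 0.0),      # matched identical pair
            (0, 1.0, 1.0, 0.0),      # mismatched pair at the margin
            (0, 0.5, 1.0, 0.25),     # (m - D)^2
            (1, 0.5, 1.0, 0.25),     # Y * D^2
            (1, 2.0, 1.0, 4.0),
            (0, 2.0, 1.0, 0.0),      # beyond the margin: no penalty
            (0, 0.25, 0.5, 0.0625),
        ],
    )
    def test_matches_formula(self, y, d, m, expected):
        assert contrastive_loss(y, d, m) == pytest.approx(expected)

    def test_vectorized_and_zero_set(self):
        y = np.array([1, 1, 0, 0, 0])
        d = np.array([0.0, 0.3, 1.0, 1.5, 0.2])
        loss = contrastive_loss(y, d, m=1.0)
        assert np.all(loss >= 0)
        # zero exactly on {Y=1, D=0} and {Y=0, D>=m}
        assert (loss == 0).tolist() == [True, False, True, True, False]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(1, -0.1, 1.0)

    def test_margin_must_be_positive(self):
        with pytest.raises(ValueError):
            LossConfig(margin=0.0)


class TestEmbedding:
    def test_embedding_is_deterministic(self):
        rng = np.random.default_rng(0)
        model = EmbeddingModel(GEOM, seed=1)
        img = _img(rng)
        e1, e2 = model.embed(img), model.embed(img)
        assert np.array_equal(e1, e2)
        assert e1.shape == (16,)

    def test_identical_pair_distance_zero(self):
        rng = np.random.default_rng(1)
        model = EmbeddingModel(GEOM, seed=1)
        img = _img(rng)
        assert pair_distance(model.embed(img), model.embed(img)) == 0.0

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(2)
        model = EmbeddingModel(GEOM, seed=3)
        for _ in range(10):
            a, b, c = (model.embed(_img(rng)) for _ in range(3))
            dab, dba = pair_distance(a, b), pair_distance(b, a)
            assert dab >= 0 and np.isfinite(dab)
            assert dab == pytest.approx(dba)
            assert pair_distance(a, c) <= dab + pair_distance(b, c) + 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pair_distance(np.zeros(4), np.zeros(5))

    def test_geometry_mismatch_rejected(self):
        model = EmbeddingModel(GEOM, seed=0)
        with pytest.raises(ValueError, match="geometry"):
            model.embed(np.zeros((10, 10, 9), dtype=np.float32))


class TestTrainingPairs:
    def _sv(self):
        return SVRecord("sv1", "chr1", 100, "A" * 60, ["A"], truth_genotype=(0, 1))

    def test_one_pair_per_hypothesis_replicate(self):
        rng = np.random.default_rng(4)
        sv = self._sv()
        actual = _img(rng)
        sims = {
            GenotypeHypothesis((0, 0)): [_img(rng)],
            GenotypeHypothesis((0, 1)): [_img(rng)],
            GenotypeHypothesis((1, 1)): [_img(rng)],
        }
        pairs = make_training_pairs(sv, actual, sims)
        assert len(pairs) == 3
        assert sum(p.label for p in pairs) == 1
        assert all(p.actual_image is actual for p in pairs)

    def test_two_replicates_each(self):
        rng = np.random.default_rng(5)
        sv = self._sv()
        sims = {
            GenotypeHypothesis(g): [_img(rng), _img(rng)]
            for g in [(0, 0), (0, 1), (1, 1)]
        }
        pairs = make_training_pairs(sv, _img(rng), sims)
        assert len(pairs) == 6
        assert sum(p.label for p in pairs) == 2

    def test_homref_truth_labels_homref_replicates(self):
        rng = np.random.default_rng(6)
        sv = SVRecord("sv2", "chr1", 100, "A" * 60, ["A"], truth_genotype=(0, 0))
        sims = {
            GenotypeHypothesis(g): [_img(rng)] for g in [(0, 0), (0, 1), (1, 1)]
        }
        pairs = make_training_pairs(sv, _img(rng), sims)
        labelled = {p.hypothesis.label: p.label for p in pairs}
        assert labelled == {"0/0": 1, "0/1": 0, "1/1": 0}

    def test_truth_required(self):
        rng = np.random.default_rng(7)
        sv = SVRecord("sv3", "chr1", 100, "A" * 60, ["A"])
        with pytest.raises(ValueError, match="truth"):
            make_training_pairs(sv, _img(rng), {GenotypeHypothesis((0, 0)): [_img(rng)]})


class TestTrain:
    def _toy_pairs(self, rng, n_svs=8):
        """Y=1 pairs are identical tensors; Y=0 pairs are independent."""
        from svembed.model import TrainingPair

        pairs = []
        for i in range(n_svs):
            a = _img(rng)
            pairs.append(
                TrainingPair(a, ImageTensor(a.data.copy(), a.region, "sim"), 1,
                             f"sv{i}", GenotypeHypothesis((0, 1)))
            )
            pairs.append(
                TrainingPair(a, _img(rng, provenance="sim"), 0,
                             f"sv{i}", GenotypeHypothesis((0, 0)))
            )
        return pairs

    def test_learnable_toy_task_reaches_near_zero_loss(self):
        rng = np.random.default_rng(8)
        pairs = self._toy_pairs(rng)
        model = train(
            pairs, LossConfig(), TrainConfig(epochs=30, seed=0, learning_rate=3e-3), GEOM
        )
        assert model.training_curve[-1] < 0.02
        # loss non-increasing over a moving window
        curve = np.array(model.training_curve)
        smoothed = np.convolve(curve, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] <= smoothed[0]

    def test_shuffled_labels_do_worse(self):
        rng = np.random.default_rng(9)
        pairs = self._toy_pairs(rng)
        good = train(pairs, LossConfig(), TrainConfig(epochs=15, seed=0), GEOM)
        import copy

        shuffled = [copy.copy(p) for p in pairs]
        labels = [p.label for p in shuffled]
        perm = np.random.default_rng(1).permutation(len(labels))
        while all(labels[int(i)] == labels[j] for j, i in enumerate(perm)):
            perm = np.random.default_rng(2).permutation(len(labels))
        for p, i in zip(shuffled, perm):
            p.label = labels[int(i)]
        bad = train(shuffled, LossConfig(), TrainConfig(epochs=15, seed=0), GEOM)
        assert bad.training_curve[-1] >= good.training_curve[-1]

    def test_single_pair_overfits(self):
        rng = np.random.default_rng(10)
        pairs = self._toy_pairs(rng, n_svs=1)[:1]
        model = train(pairs, LossConfig(), TrainConfig(epochs=25, seed=0, learning_rate=3e-3), GEOM)
        assert model.training_curve[-1] < 1e-3

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train([], LossConfig(), TrainConfig())


class TestEnsemble:
    def test_single_model_is_its_own_distance(self):
        rng = np.random.default_rng(11)
        model = EmbeddingModel(GEOM, seed=0)
        a, b = _img(rng), _img(rng)
        d = pair_distance(model.embed(a), model.embed(b))
        assert ensemble_distance([model], (a, b)) == pytest.approx(d)

    def test_mean_and_permutation_invariance(self):
        rng = np.random.default_rng(12)
        m1, m2 = EmbeddingModel(GEOM, seed=1), EmbeddingModel(GEOM, seed=2)
        a, b = _img(rng), _img(rng)
        d1 = pair_distance(m1.embed(a), m1.embed(b))
        d2 = pair_distance(m2.embed(a), m2.embed(b))
        d12 = ensemble_distance([m1, m2], (a, b))
        assert d12 == pytest.approx((d1 + d2) / 2)
        assert d12 == pytest.approx(ensemble_distance([m2, m1], (a, b)))

    def test_empty_ensemble_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            ensemble_distance([], (_img(rng), _img(rng)))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        model = EmbeddingModel(GEOM, seed=5)
        model.training_curve = [0.5, 0.2]
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        loaded = load_model(path)
        img = _img(rng)
        assert np.allclose(model.embed(img), loaded.embed(img))
        assert loaded.training_curve == [0.5, 0.2]

    def test_geometry_mismatch_refused(self, tmp_path):
        model = EmbeddingModel(GEOM, seed=5)
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        with pytest.raises(ValueError, match="geometry"):
            load_model(path, expect_geometry=(100, 300, 9))
        loaded = load_model(path, expect_geometry=(16, 32, 9))
        assert loaded.config.geometry() == (16, 32, 9)
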