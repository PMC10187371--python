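"""Losses, the two-phase training loop, serialization and grid search."""

import hashlib
from dataclasses import replace

import numpy as np
import pytest

from clclsa import synthetic
from clclsa.data_model import split_dataset
from clclsa.training import (
    CLCLSAModel,
    LossWeights,
    TrainConfig,
    auxiliary_loss,
    classification_loss,
    grid_search,
    predict,
    total_loss,
    train,
)


class TestClassificationLoss:
    def test_one_hot_correct_is_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert classification_loss(probs, [0, 1]).data == pytest.approx(0.0, abs=1e-9)

    def test_uniform_binary_is_log2(self):
        assert classification_loss(np.array([[0.5, 0.5]]), [0]).data == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_sums_over_subjects(self, rng):
        p = rng.dirichlet(np.ones(3), size=2)
        y = [0, 2]
        total = classification_loss(p, y).data
        assert total == pytest.approx(-np.log(p[0, 0]) - np.log(p[1, 2]), abs=1e-10)

    def test_label_out_of_range(self):
        with pytest.raises(IndexError):
            classification_loss(np.array([[0.5, 0.5]]), [2])


class TestAuxiliaryLoss:
    def test_perfect_confidence_and_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0]])
        matt = np.array([[1.0]])
        assert auxiliary_loss([matt], [probs], [0]).data == pytest.approx(0.0, abs=1e-9)

    def test_squared_confidence_gap(self):
        probs = np.array([[1.0, 0.0]])  # CE term 0, conf = 1
        matt = np.array([[0.5]])
        assert auxiliary_loss([matt], [probs], [0]).data == pytest.approx(0.25, abs=1e-9)

    def test_sums_over_omics_brute_force(self, rng):
        y = np.array([0, 1])
        matts = [rng.uniform(0.2, 0.8, size=(2, 1)) for _ in range(2)]
        probs = [rng.dirichlet(np.ones(2), size=2) for _ in range(2)]
        total = auxiliary_loss(matts, probs, y).data
        manual = 0.0
        for m, p in zip(matts, probs):
            conf = p[np.arange(2), y][:, None]
            manual += ((m - conf) ** 2).sum()
            manual += -(np.log(p[np.arange(2), y])).sum()
        assert total == pytest.approx(manual, abs=1e-10)

    def test_max_confidence_variant(self):
        probs = np.array([[0.3, 0.7]])
        matt = np.array([[0.7]])
        loss = auxiliary_loss([matt], [probs], [1], confidence="max").data
        assert loss == pytest.approx(-np.log(0.7), abs=1e-10)


class TestTotalLoss:
    def test_zero_weights_reduce_to_classification(self):
        total, bundle = total_loss(1.5, 2.0, 3.0, 4.0, LossWeights(0, 0, 0))
        assert total.data == pytest.approx(1.5)
        assert bundle.l_al == 2.0

    def test_weighted_sum_hand_value(self):
        total, bundle = total_loss(1.0, 2.0, 3.0, 4.0, LossWeights(0.1, 0.05, 0.01))
        assert total.data == pytest.approx(1.39, abs=1e-12)
        assert bundle.total == pytest.approx(
            bundle.l_clf + 0.1 * bundle.l_al + 0.05 * bundle.l_co + 0.01 * bundle.l_cl,
            abs=1e-10,
        )

    def test_nan_component_raises_named_error(self):
        with pytest.raises(RuntimeError, match="l_co"):
            total_loss(1.0, 1.0, float("nan"), 1.0, LossWeights())

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_al=-0.1)


def _param_hash(modules):
    h = hashlib.sha256()
    for p in modules.parameters():
        h.update(p.data.tobytes())
    return h.hexdigest()


class TestTrain:
    def test_same_seed_identical_trajectory(self, tiny_ds, tiny_cfg):
        a = train(tiny_ds, tiny_cfg, seed=5)
        b = train(tiny_ds, tiny_cfg, seed=5)
        assert [x.total for x in a.history] == [x.total for x in b.history]
        np.testing.assert_array_equal(predict(a, tiny_ds), predict(b, tiny_ds))

    def test_complete_data_never_touches_bridges(self, tiny_ds, tiny_cfg):
        model = train(tiny_ds, tiny_cfg, seed=0)  # eta = 0 -> lambda_co forced 0
        fresh = CLCLSAModel(model.arch, model.cfg, seed=0)
        assert _param_hash(model.bank) == _param_hash(fresh.bank)

    def test_loss_decreases_early(self):
        ds = synthetic.generate(
            synthetic.SimConfig(n_subjects=90, view_dims=(15, 12, 10), seed=1)
        )
        for seed in range(3):
            model = train(ds, TrainConfig.desk_scale(50, latent_dim=8), seed=seed)
            assert model.history[-1].total < model.history[0].total

    def test_bundle_invariant_every_epoch(self, tiny_ds):
        cfg = TrainConfig.desk_scale(10, latent_dim=8)
        ds = tiny_ds.with_mask(
            __import__("clclsa").make_missing_mask(tiny_ds.n_subjects, 3, 0.3, seed=2)
        )
        model = train(ds, cfg, seed=0)
        w = cfg.weights
        for b in model.history:
            assert b.total == pytest.approx(
                b.l_clf + w.lambda_al * b.l_al + w.lambda_co * b.l_co + w.lambda_cl * b.l_cl,
                abs=1e-10,
            )

    def test_empty_training_set_rejected(self, tiny_ds, tiny_cfg):
        with pytest.raises(ValueError):
            train(tiny_ds.subset(np.array([], dtype=int)), tiny_cfg, seed=0)

    def test_missing_class_rejected(self, tiny_ds, tiny_cfg):
        only0 = tiny_ds.subset(np.flatnonzero(tiny_ds.labels == 0))
        with pytest.raises(ValueError, match="classes"):
            train(only0, tiny_cfg, seed=0)


class TestPredict:
    def test_rows_sum_to_one(self, tiny_ds, tiny_cfg):
        model = train(tiny_ds, tiny_cfg, seed=0)
        probs = predict(model, tiny_ds)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_complete_subjects_unaffected_by_imputation_mode(self, tiny_ds, tiny_cfg):
        model = train(tiny_ds, tiny_cfg, seed=0)
        a = predict(model, tiny_ds)
        model.cfg = replace(model.cfg, imputation="zero")
        np.testing.assert_array_equal(a, predict(model, tiny_ds))

    def test_dimension_mismatch_raises(self, tiny_ds, tiny_cfg, default_ds):
        model = train(tiny_ds, tiny_cfg, seed=0)
        with pytest.raises(ValueError):
            predict(model, default_ds)


def test_save_load_bit_identical(tmp_path, tiny_ds, tiny_cfg):
    model = train(tiny_ds, tiny_cfg, seed=3)
    model.save(tmp_path / "ckpt")
    back = CLCLSAModel.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(predict(model, tiny_ds), predict(back, tiny_ds))
    assert [b.total for b in back.history] == [b.total for b in model.history]


class TestGridSearch:
    def test_bookkeeping_and_tie_breaking(self, tiny_ds):
        cfg = TrainConfig.desk_scale(8, latent_dim=8)
        best, table = grid_search(
            tiny_ds, lambda_grid=(0.0, 0.1), seeds=(0,), cfg=cfg
        )
        # complete data: lambda_co collapses to {0} -> 2 * 1 * 2 combos
        assert len(table) == 4
        assert best.lambda_co == 0.0
        assert set(table.columns) >= {"lambda_al", "lambda_co", "lambda_cl", "seed", "acc"}

    def test_rows_scale_with_seeds(self, tiny_ds):
        cfg = TrainConfig.desk_scale(5, latent_dim=8)
        _, table = grid_search(tiny_ds, lambda_grid=(0.0,), seeds=(0, 1), cfg=cfg)
        assert len(table) == 2

    def test_empty_grid_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            grid_search(tiny_ds, lambda_grid=())
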