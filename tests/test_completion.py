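"""Cross-omics bridges: reconstruction-loss identities and imputation rules."""

import numpy as np
import pytest

from clclsa.attention import LatentBlock
from clclsa.completion import (
    BridgeBank,
    impute_missing,
    pair_reconstruction_loss,
    predict_latent,
    total_reconstruction_loss,
)
from clclsa.nn import Linear, Module, Sequential, Tensor


class ConstantBridge(Module):
    """Test double returning a fixed matrix regardless of input."""

    def __init__(self, value):
        super().__init__()
        self.value = np.atleast_2d(np.array(value, dtype=float))

    def forward(self, x):
        return Tensor(np.tile(self.value, (x.data.shape[0], 1)))


def constant_bank(n_views, d, mapping):
    bank = BridgeBank.__new__(BridgeBank)
    Module.__init__(bank)
    bank.n_views = n_views
    bank.layer_spec = "test"
    bank.bridges = {k: ConstantBridge(v) for k, v in mapping.items()}
    return bank


class TestPairLoss:
    def test_zero_when_equal(self, rng):
        z = rng.normal(size=(4, 3))
        assert pair_reconstruction_loss(z, z).data == 0.0

    def test_hand_value(self):
        loss = pair_reconstruction_loss(np.array([[1.0, 2.0]]), np.zeros((1, 2)))
        assert loss.data == pytest.approx(5.0)

    def test_nonnegative(self, rng):
        a, b = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        assert pair_reconstruction_loss(a, b).data >= 0.0


class TestTotalReconstruction:
    def test_equals_biview_form_at_m2(self, rng):
        zs = [rng.normal(size=(5, 3)) for _ in range(2)]
        bank = BridgeBank(2, "3-3", np.random.default_rng(0))
        bank.set_training(False)
        mask = np.ones((5, 2), dtype=bool)
        total = total_reconstruction_loss(zs, bank, mask).data
        manual = (
            pair_reconstruction_loss(bank[(0, 1)](Tensor(zs[1])), Tensor(zs[0])).data
            + pair_reconstruction_loss(bank[(1, 0)](Tensor(zs[0])), Tensor(zs[1])).data
        )
        assert total == pytest.approx(manual, abs=1e-10)

    def test_ordered_pair_count_m3(self):
        # every directed pair loss is 1: prediction differs from target by a
        # unit vector -> total must be M(M-1) = 6
        zs = [np.zeros((1, 2)) for _ in range(3)]
        bank = constant_bank(3, 2, {
            (i, k): [[1.0, 0.0]] for i in range(3) for k in range(3) if i != k
        })
        total = total_reconstruction_loss(zs, bank, np.ones((1, 3), dtype=bool))
        assert total.data == pytest.approx(6.0)

    def test_perfect_bridges_give_zero(self, rng):
        z = rng.normal(size=(4, 2))
        bank = constant_bank(2, 2, {(0, 1): z[:1], (1, 0): z[:1]})
        zs = [np.tile(z[:1], (4, 1)), np.tile(z[:1], (4, 1))]
        assert total_reconstruction_loss(zs, bank, np.ones((4, 2), bool)).data == 0.0

    def test_single_view_rejected(self, rng):
        with pytest.raises(ValueError):
            total_reconstruction_loss(
                [rng.normal(size=(3, 2))], None, np.ones((3, 1), bool)
            )

    def test_restricted_to_jointly_observed(self, rng):
        zs = [rng.normal(size=(4, 2)) for _ in range(2)]
        bank = BridgeBank(2, "2-2", np.random.default_rng(0))
        bank.set_training(False)
        mask = np.array([[1, 1], [1, 0], [0, 1], [1, 1]], dtype=bool)
        rows = np.array([0, 3])
        total = total_reconstruction_loss(zs, bank, mask).data
        manual = total_reconstruction_loss(
            [z[rows] for z in zs], bank, np.ones((2, 2), bool)
        ).data
        assert total == pytest.approx(manual, abs=1e-10)

    def test_subject_permutation_invariance(self, rng):
        zs = [rng.normal(size=(6, 3)) for _ in range(3)]
        bank = BridgeBank(3, "3-3", np.random.default_rng(1))
        bank.set_training(False)
        mask = np.ones((6, 3), bool)
        perm = rng.permutation(6)
        a = total_reconstruction_loss(zs, bank, mask).data
        b = total_reconstruction_loss([z[perm] for z in zs], bank, mask[perm]).data
        assert a == pytest.approx(b, rel=1e-10)


class TestPredictLatent:
    def test_shape_preserved_and_deterministic(self, rng):
        bank = BridgeBank(2, "4-3-BN-ReLU-4", np.random.default_rng(0))
        z = rng.normal(size=(5, 4))
        a = predict_latent(z, bank[(0, 1)]).data
        b = predict_latent(z, bank[(0, 1)]).data
        assert a.shape == (5, 4)
        np.testing.assert_array_equal(a, b)

    def test_unknown_pair_lookup(self):
        bank = BridgeBank(2, "2-2", np.random.default_rng(0))
        with pytest.raises(LookupError):
            bank[(0, 0)]

    def test_hand_composed_forward(self, rng):
        bank = BridgeBank(2, "2-2", np.random.default_rng(0))
        lin = bank[(0, 1)].layers[0]
        z = rng.normal(size=(3, 2))
        np.testing.assert_allclose(
            predict_latent(z, bank[(0, 1)]).data, z @ lin.W.data + lin.b.data
        )


class TestImputeMissing:
    def test_full_mask_is_identity(self, rng):
        zs = [rng.normal(size=(3, 2)) for _ in range(2)]
        bank = BridgeBank(2, "2-2", np.random.default_rng(0))
        out = impute_missing(LatentBlock([Tensor(z) for z in zs]), bank, np.ones((3, 2), bool))
        for a, b in zip(out.latents, zs):
            np.testing.assert_array_equal(a.data, b)

    def test_mean_over_observed_sources(self):
        # view 0 missing; bridges from views 1 and 2 return [1,1] and [3,3]
        zs = [np.zeros((1, 2)), np.ones((1, 2)), np.ones((1, 2))]
        bank = constant_bank(3, 2, {
            (0, 1): [[1.0, 1.0]], (0, 2): [[3.0, 3.0]],
            (1, 0): [[9.0, 9.0]], (1, 2): [[9.0, 9.0]],
            (2, 0): [[9.0, 9.0]], (2, 1): [[9.0, 9.0]],
        })
        mask = np.array([[0, 1, 1]], dtype=bool)
        out = impute_missing(LatentBlock([Tensor(z) for z in zs]), bank, mask)
        np.testing.assert_allclose(out.latents[0].data, [[2.0, 2.0]])
        np.testing.assert_array_equal(out.latents[1].data, zs[1])

    def test_single_source_degenerate_mean(self, rng):
        zs = [rng.normal(size=(1, 2)), np.zeros((1, 2))]
        bank = BridgeBank(2, "2-2", np.random.default_rng(0))
        bank.set_training(False)
        mask = np.array([[1, 0]], dtype=bool)
        out = impute_missing(LatentBlock([Tensor(z) for z in zs]), bank, mask)
        expected = predict_latent(zs[0], bank[(1, 0)]).data
        np.testing.assert_allclose(out.latents[1].data, expected)

    def test_no_observed_view_is_contract_violation(self, rng):
        zs = [rng.normal(size=(1, 2)) for _ in range(2)]
        bank = BridgeBank(2, "2-2", np.random.default_rng(0))
        with pytest.raises(ValueError):
            impute_missing(
                LatentBlock([Tensor(z) for z in zs]), bank, np.zeros((1, 2), bool)
            )
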