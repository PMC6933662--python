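import logging

import numpy as np
import pytest

from deepmf import (
    DeepMFModel,
    OmicsMatrix,
    TrainingConfig,
    apply_dropout,
    fit,
    generate_pattern,
    impute,
    masked_global_loss,
    select_architecture,
    total_loss,
)
from deepmf.core import _init_model, loss_and_gradients
from deepmf.proximity import feature_sample_graphs
from deepmf.synthetic import PatternSpec

from conftest import make_matrix


def chain_oracle(model):
    """Explicit matrix-chain forward pass for every one-hot input."""
    rows = []
    for i in range(model.M):
        h = np.maximum(model.U[i], 0.0)
        for w in model.W_hidden:
            h = np.maximum(h @ w, 0.0)
        rows.append(h @ model.V)
    return np.vstack(rows)


def random_model(rng, m=7, n=5, k=3, layers=3):
    return DeepMFModel(
        U=rng.normal(size=(m, k)),
        W_hidden=[rng.normal(size=(k, k)) for _ in range(layers - 1)],
        V=rng.normal(size=(k, n)),
    )


class TestForward:
    def test_identity_construction(self):
        u = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        model = DeepMFModel(U=u, W_hidden=[], V=np.eye(3))
        for i in range(4):
            np.testing.assert_allclose(model.forward(i), u[i])

    def test_zero_row_gives_zero_output(self, rng):
        model = random_model(rng, layers=1)
        model.U[2] = 0.0
        np.testing.assert_array_equal(model.forward(2), np.zeros(model.N))

    def test_matches_chain_oracle(self, rng):
        model = random_model(rng, layers=3)
        stacked = np.vstack([model.forward(i) for i in range(model.M)])
        np.testing.assert_allclose(stacked, chain_oracle(model), atol=1e-12)
        np.testing.assert_allclose(model.forward_all(), chain_oracle(model), atol=1e-12)

    def test_index_out_of_range(self, rng):
        model = random_model(rng)
        with pytest.raises(IndexError):
            model.forward(model.M)


class TestMaskedGlobalLoss:
    def test_no_missing(self):
        assert masked_global_loss(
            np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]]), np.ones((1, 2), bool)
        ) == pytest.approx(5.0)

    def test_masked_entry_dropped(self):
        y = np.array([[1.0, 123.0]])
        yhat = np.array([[0.0, 7.0]])
        mask = np.array([[True, False]])
        assert masked_global_loss(y, yhat, mask) == pytest.approx(1.0)

    def test_all_missing_zero(self):
        assert masked_global_loss(
            np.ones((3, 4)), np.zeros((3, 4)), np.zeros((3, 4), bool)
        ) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            masked_global_loss(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2), bool))


def frobenius_reg(model):
    return float((model.U ** 2).sum() + (model.V ** 2).sum()
                 + sum((w ** 2).sum() for w in model.W_hidden))


class TestTotalLoss:
    def test_alpha_beta_zero_mix_is_global(self, rng, small_sparse):
        model = random_model(rng, m=6, n=4, layers=2)
        graphs = feature_sample_graphs(small_sparse)
        cfg = TrainingConfig(alpha=0.0, beta=0.0)
        lb = total_loss(model, small_sparse, graphs, cfg)
        assert lb.mix == lb.global_

    def test_zero_model_on_zero_matrix(self):
        m = make_matrix(np.zeros((4, 3)))
        model = DeepMFModel(U=np.zeros((4, 2)), W_hidden=[], V=np.zeros((2, 3)))
        graphs = feature_sample_graphs(m)
        lb = total_loss(model, m, graphs, TrainingConfig())
        assert lb.global_ == 0.0 and lb.reg == 0.0
        assert lb.local == pytest.approx(0.0, abs=1e-12)

    def test_components_match_independent_oracles(self, rng, small_sparse):
        from test_proximity import pairwise_penalty

        model = random_model(rng, m=6, n=4, layers=2)
        graphs = feature_sample_graphs(small_sparse)
        cfg = TrainingConfig(alpha=0.3, beta=0.01)
        lb = total_loss(model, small_sparse, graphs, cfg)

        # masked sum-of-squares loop
        yhat = chain_oracle(model)
        expect_global = 0.0
        for i in range(6):
            for j in range(4):
                if small_sparse.mask[i, j]:
                    expect_global += (small_sparse.values[i, j] - yhat[i, j]) ** 2
        expect_global /= 6
        assert lb.global_ == pytest.approx(expect_global, rel=1e-10)

        # pairwise Laplacian sums
        expect_local = pairwise_penalty(model.U, graphs[0].similarity) \
            + pairwise_penalty(model.V.T, graphs[1].similarity)
        assert lb.local == pytest.approx(expect_local, rel=1e-8)

        # explicit squared Frobenius norms
        assert lb.reg == pytest.approx(frobenius_reg(model), rel=1e-12)
        assert lb.mix == lb.global_ + cfg.alpha * lb.local + cfg.beta * lb.reg

    def test_misaligned_graphs_rejected(self, rng, small_sparse):
        model = random_model(rng, m=6, n=4)
        other = make_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="do not match"):
            total_loss(model, small_sparse, feature_sample_graphs(other),
                       TrainingConfig())


class TestGradients:
    def test_matches_finite_differences(self, rng, small_sparse):
        model = random_model(rng, m=6, n=4, k=2, layers=2)
        graphs = feature_sample_graphs(small_sparse)
        cfg = TrainingConfig(alpha=0.2, beta=0.05)
        _, grads = loss_and_gradients(model, small_sparse, graphs, cfg)
        eps = 1e-6

        def mix_at(u=None, v=None, w0=None):
            m2 = DeepMFModel(
                U=u if u is not None else model.U,
                W_hidden=[w0 if w0 is not None else model.W_hidden[0]],
                V=v if v is not None else model.V,
            )
            return total_loss(m2, small_sparse, graphs, cfg).mix

        for name, param, grad in [
            ("U", model.U, grads["U"]),
            ("V", model.V, grads["V"]),
            ("W", model.W_hidden[0], grads["W_hidden"][0]),
        ]:
            idx = (1, 1)
            p = param.copy()
            p[idx] += eps
            plus = mix_at(**{{"U": "u", "V": "v", "W": "w0"}[name]: p})
            p[idx] -= 2 * eps
            minus = mix_at(**{{"U": "u", "V": "v", "W": "w0"}[name]: p})
            fd = (plus - minus) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name

    def test_masked_cells_are_invisible(self, rng, small_sparse):
        graphs = feature_sample_graphs(small_sparse)
        cfg = TrainingConfig()
        model = random_model(rng, m=6, n=4, layers=2)
        lb1, g1 = loss_and_gradients(model, small_sparse, graphs, cfg)

        perturbed = small_sparse.copy()
        vals = perturbed.values.copy()
        vals[~perturbed.mask] = rng.normal(size=(~perturbed.mask).sum()) * 1e6
        perturbed.values = vals
        lb2, g2 = loss_and_gradients(model, perturbed, graphs, cfg)

        assert lb1.mix == lb2.mix
        np.testing.assert_array_equal(g1["U"], g2["U"])
        np.testing.assert_array_equal(g1["V"], g2["V"])
        for a, b in zip(g1["W_hidden"], g2["W_hidden"]):
            np.testing.assert_array_equal(a, b)


def quick_cfg(**kw):
    base = dict(epochs=400, restarts=2, seed=0)
    base.update(kw)
    return TrainingConfig(**base)


class TestFit:
    def test_self_reconstruction_rank2_block(self):
        m, _, _ = generate_pattern(PatternSpec(2, 2, (30, 12), noise_sd=0.0, seed=1))
        res = fit(m, 2, 1, quick_cfg(epochs=2000, restarts=3))
        rel = np.linalg.norm(res.refined.values - m.values) / np.linalg.norm(m.values)
        assert rel < 0.05

    def test_imputation_with_dropout(self):
        m, _, _ = generate_pattern(PatternSpec(2, 2, (30, 12), noise_sd=0.0, seed=1))
        sparse = apply_dropout(m, 0.5, seed=2)
        res = fit(sparse, 2, 1, quick_cfg(epochs=2000, restarts=3))
        miss = ~sparse.mask
        rel = np.linalg.norm(res.refined.values[miss] - m.values[miss]) \
            / np.linalg.norm(m.values[miss])
        assert rel < 0.1

    def test_refined_fully_observed_same_ids(self, small_sparse):
        res = fit(small_sparse, 2, 1, quick_cfg(epochs=50))
        assert res.refined.is_fully_observed()
        assert res.refined.feature_ids == small_sparse.feature_ids
        assert res.refined.sample_ids == small_sparse.sample_ids

    def test_determinism(self, small_sparse):
        r1 = fit(small_sparse, 2, 1, quick_cfg(epochs=50))
        r2 = fit(small_sparse, 2, 1, quick_cfg(epochs=50))
        assert r1.selected_restart == r2.selected_restart
        np.testing.assert_array_equal(r1.model.U, r2.model.U)
        np.testing.assert_array_equal(r1.model.V, r2.model.V)

    def test_history_mix_consistent(self, small_sparse):
        cfg = quick_cfg(epochs=50, alpha=0.2, beta=0.01)
        res = fit(small_sparse, 2, 1, cfg)
        for lb in res.history[::10]:
            assert lb.mix == pytest.approx(
                lb.global_ + cfg.alpha * lb.local + cfg.beta * lb.reg, rel=1e-12
            )

    def test_more_epochs_lower_median_loss(self, small_sparse):
        finals = {}
        for epochs in (100, 200):
            mixes = []
            for r in range(5):
                res = fit(small_sparse, 2, 1,
                          TrainingConfig(epochs=epochs, restarts=1, seed=100 + r))
                mixes.append(res.final_mix)
            finals[epochs] = np.median(mixes)
        assert finals[200] < finals[100]

    def test_invalid_k_l(self, small_sparse):
        with pytest.raises(ValueError):
            fit(small_sparse, 1, 1, quick_cfg())
        with pytest.raises(ValueError):
            fit(small_sparse, 2, 0, quick_cfg())

    def test_deeper_network_trains(self, small_sparse):
        res = fit(small_sparse, 2, 3, quick_cfg(epochs=100))
        assert res.model.L == 3 and len(res.model.W_hidden) == 2
        assert np.isfinite(res.final_mix)


class TestImpute:
    def test_consistent_with_refined(self, small_sparse):
        res = fit(small_sparse, 2, 1, quick_cfg(epochs=50))
        for i, j in np.argwhere(~small_sparse.mask):
            assert impute(res, i, j) == pytest.approx(res.refined.values[i, j])

    def test_rank1_recovery(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(1, 2, 20)
        b = rng.uniform(1, 2, 10)
        truth = np.outer(a, b)
        mask = np.ones_like(truth, bool)
        mask[3, 4] = False
        m = OmicsMatrix(np.where(mask, truth, np.nan), mask,
                        [f"f{i}" for i in range(20)], [f"s{j}" for j in range(10)])
        res = fit(m, 2, 1, quick_cfg(epochs=2000, restarts=3))
        assert impute(res, 3, 4) == pytest.approx(truth[3, 4], rel=0.05)

    def test_out_of_range(self, small_sparse):
        res = fit(small_sparse, 2, 1, quick_cfg(epochs=20))
        with pytest.raises(IndexError):
            impute(res, 0, 99)


class TestSelectArchitecture:
    def test_single_cell_grid(self, small_sparse, caplog):
        cfg = quick_cfg(epochs=60, validation_fraction=0.15)
        with caplog.at_level(logging.INFO, logger="deepmf.core"):
            k, l, res = select_architecture(small_sparse, 2, [1], cfg)
        assert (k, l) == (2, 1)
        assert sum("validation L_mix" in r.message for r in caplog.records) == 1

    def test_scores_logged_per_combination(self, small_sparse, caplog):
        cfg = quick_cfg(epochs=40, validation_fraction=0.15)
        with caplog.at_level(logging.INFO, logger="deepmf.core"):
            select_architecture(small_sparse, 3, [1, 2], cfg)
        assert sum("validation L_mix" in r.message for r in caplog.records) == 4

    def test_rank_recovery(self):
        hits = []
        for rep in range(5):
            m, _, _ = generate_pattern(
                PatternSpec(3, 3, (30, 15), noise_sd=0.1, seed=rep)
            )
            cfg = TrainingConfig(epochs=800, restarts=2, seed=rep,
                                 validation_fraction=0.1)
            k, _, _ = select_architecture(m, 4, [1], cfg)
            hits.append(k)
        assert all(abs(k - 3) <= 1 for k in hits)

    def test_invalid_c(self, small_sparse):
        with pytest.raises(ValueError):
            select_architecture(small_sparse, 1, [1], quick_cfg())


class TestInit:
    def test_first_layer_nonnegative(self, rng):
        model = _init_model(10, 6, 3, 2, rng)
        assert (model.U >= 0).all()
        assert model.L == 2 and len(model.W_hidden) == 1

    def test_l1_has_no_hidden_weights(self, rng):
        model = _init_model(10, 6, 3, 1, rng)
        assert model.W_hidden == []
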