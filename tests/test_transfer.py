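"""Labeling, splits, target representative, loss assembly and training."""

import math

import numpy as np
import pytest

from molhnn.autodiff import Tensor
from molhnn.hmpnn import HnnConfig, HnnModel
from molhnn.synthetic import (
    SyntheticConfig, empirical_free_energy, generate_chain, sample_ensemble,
)
from molhnn.transfer import (
    HypergraphDataset, TrainingConfig, ZeroShotViolationError, bce_loss,
    compute_target_representative, featurize, label_conformations,
    predict, predict_source, split_dataset, target_regularizer, total_loss,
    train, unflatten_target,
)


class TestLabels:
    def test_global_minimum_is_low(self):
        labels = label_conformations([0.0, 5.0, 20.0], 8.0)
        np.testing.assert_array_equal(labels, [1, 1, 0])

    def test_boundary_inclusive(self):
        assert label_conformations([0.0, 8.0], 8.0)[1] == 1

    def test_above_threshold_high(self):
        assert label_conformations([0.0, 12.0], 8.0)[1] == 0

    def test_minimum_shifted_before_threshold(self):
        # energies 100..108 span exactly the low interval after shifting
        labels = label_conformations([100.0, 108.0, 109.0], 8.0)
        np.testing.assert_array_equal(labels, [1, 1, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            label_conformations([], 8.0)


class TestSplits:
    def test_consecutive_scheme_proportions(self):
        tr, va, te = split_dataset(10, "consecutive_5")
        assert (tr.size, va.size, te.size) == (2, 4, 4)
        np.testing.assert_array_equal(tr, [0, 5])

    def test_random_scheme_proportions(self):
        tr, va, te = split_dataset(100, "random_20_20_60", seed=4)
        assert (tr.size, va.size, te.size) == (20, 20, 60)
        assert len(np.intersect1d(tr, va)) == 0
        assert len(np.union1d(np.union1d(tr, va), te)) == 100

    def test_seed_reproducible(self):
        a = split_dataset(50, "random_20_20_60", seed=9)
        b = split_dataset(50, "random_20_20_60", seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(4, "consecutive_5")


class TestTargetRepresentative:
    def test_identity_matrix(self):
        rep = compute_target_representative(np.eye(2))
        np.testing.assert_allclose(rep.r_D, [1.0, 1.0], atol=1e-12)

    def test_rank_one_rows(self):
        D = np.tile([[1.0, 0.0]], (3, 1))
        rep = compute_target_representative(D)
        assert rep.n_retained == 1
        np.testing.assert_allclose(rep.r_D, [1.0, 0.0], atol=1e-12)

    def test_scale_invariant(self, rng):
        D = rng.standard_normal((6, 4))
        a = compute_target_representative(D).r_D
        b = compute_target_representative(5.0 * D).r_D
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        """Right singular vectors are the eigenvectors of D^T D."""
        D = rng.standard_normal((8, 4))
        rep = compute_target_representative(D)
        evals, evecs = np.linalg.eigh(D.T @ D)
        keep = evals > 1e-20 * evals.max()
        vecs = evecs[:, keep].T
        flip = np.sign(vecs[np.arange(vecs.shape[0]),
                            np.argmax(np.abs(vecs), axis=1)])
        oracle = (vecs * flip[:, None]).sum(axis=0)
        np.testing.assert_allclose(np.sort(rep.r_D), np.sort(oracle),
                                   atol=1e-8)
        np.testing.assert_allclose(rep.r_D, oracle, atol=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_target_representative(np.zeros((3, 2)))


class TestBce:
    def test_confident_correct_is_zero(self):
        assert bce_loss([1], [1 - 1e-12]) == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_is_log2(self):
        assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_quarter_is_log4(self):
        assert bce_loss([1], [0.25]) == pytest.approx(math.log(4))

    def test_tensor_and_numpy_agree(self, rng):
        y = rng.integers(0, 2, 10)
        p = rng.uniform(0.01, 0.99, 10)
        t = bce_loss(y, Tensor(p, requires_grad=True))
        assert float(t.data) == pytest.approx(bce_loss(y, p), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([1, 0], [0.5])


def tiny_datasets():
    cfg = SyntheticConfig(n_residues=3, n_samples=60, seed=3)
    topo = generate_chain(cfg)
    ens = sample_ensemble(topo, cfg)
    _, conf_F = empirical_free_energy(ens.coords, topo, cfg.beta)
    src = featurize(topo, ens.coords,
                    labels=label_conformations(conf_F, cfg.energy_threshold))
    tcfg = SyntheticConfig(n_residues=5, n_samples=20, seed=4)
    ttopo = generate_chain(tcfg)
    tens = sample_ensemble(ttopo, tcfg)
    tgt = featurize(ttopo, tens.coords)
    return src, tgt


class TestTargetRegularizer:
    def test_nonnegative(self, rng):
        src, tgt = tiny_datasets()
        model = HnnModel(HnnConfig(seed=0, d_h=4))
        rep = compute_target_representative(tgt.raw_flat())
        val = target_regularizer(rep.r_D, model.detached_layers(), tgt)
        assert val >= 0

    def test_zero_parameter_layers_hand_value(self):
        """With all-zero maps the output is pure sigmoid message sums.

        On a 2-atom target (1 bond hyperedge): M_v = 0.5 everywhere,
        agg = |e| * 0.5 = 1, W' = agg, M_e = sigmoid(0) = 0.5,
        X' = 0.5 per component.  Unrolling a second layer the same way
        gives closed-form outputs whose norm the test recomputes.
        """
        from molhnn.hypergraph import build_chain_topology
        from molhnn.synthetic import chain_coordinates
        topo = build_chain_topology(2)
        coords = chain_coordinates(np.array([[1.5]]), np.zeros((1, 0)),
                                   np.zeros((1, 0)))
        tgt = featurize(topo, coords)
        d_h = 3
        model = HnnModel(HnnConfig(seed=0, d_h=d_h))
        for layer in model.layers:
            for lin in layer.maps().values():
                lin.W.data = np.zeros_like(lin.W.data)
                lin.b.data = np.zeros_like(lin.b.data)
        r_D = np.ones(tgt.X0.size + tgt.W.size)
        val = target_regularizer(r_D, model.detached_layers(), tgt)
        sig = lambda z: 1 / (1 + math.exp(-z))
        # layer 1: X1_v = sum over the one edge of sigmoid(0) = 0.5;
        # W1_e = 2 * sigmoid(0) = 1.0 per component
        # layer 2: M_v = sigmoid(0) = 0.5; agg = 1.0; W2 = 1.0;
        # M_e = sigmoid(0) = 0.5; X2_v = 0.5
        expected = math.sqrt(2 * d_h * 0.5**2 + 1 * d_h * 1.0**2)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_incompatible_length_rejected(self):
        _, tgt = tiny_datasets()
        with pytest.raises(ValueError):
            unflatten_target(np.ones(7), tgt)


class TestTotalLoss:
    def test_decomposition_exact(self):
        src, tgt = tiny_datasets()
        config = TrainingConfig(l2_coeff=0.3, target_reg_coeff=0.7, epochs=1)
        model = HnnModel(HnnConfig(seed=1, d_h=4, k_points=2))
        from molhnn.pooling import select_points_of_interest
        from molhnn.transfer import _source_reps
        model.points = select_points_of_interest(
            _source_reps(model, src, np.arange(src.n)), 2, 0).P
        rep = compute_target_representative(tgt.raw_flat())
        batch = np.arange(10)
        loss, parts = total_loss(model, src, batch, config, rep, tgt)
        recomposed = parts["bce"] + 0.3 * parts["l2"] + 0.7 * parts["target_reg"]
        assert float(loss.data) == pytest.approx(recomposed, abs=1e-12)
        # and each part matches an independent computation
        probs = predict_source(model, src, batch)
        assert parts["bce"] == pytest.approx(bce_loss(src.labels[batch], probs),
                                             rel=1e-9)
        l2 = sum(float(np.sum(p.data**2)) for p in model.parameters())
        assert parts["l2"] == pytest.approx(l2, rel=1e-12)
        reg = target_regularizer(rep.r_D, model.detached_layers(), tgt)
        assert parts["target_reg"] == pytest.approx(reg, rel=1e-9)

    def test_zero_coefficients_leave_bce(self):
        src, tgt = tiny_datasets()
        config = TrainingConfig(l2_coeff=0.0, target_reg_coeff=0.0, epochs=1)
        model = HnnModel(HnnConfig(seed=1, d_h=4, k_points=2))
        from molhnn.pooling import select_points_of_interest
        from molhnn.transfer import _source_reps
        model.points = select_points_of_interest(
            _source_reps(model, src, np.arange(src.n)), 2, 0).P
        loss, parts = total_loss(model, src, np.arange(8), config, None, None)
        assert float(loss.data) == pytest.approx(parts["bce"], abs=1e-12)


class TestGradientCheck:
    def test_backprop_matches_finite_differences(self):
        """Numerical gradient of the full objective vs backpropagation."""
        src, tgt = tiny_datasets()
        config = TrainingConfig(l2_coeff=0.01, target_reg_coeff=0.05, epochs=1)
        model = HnnModel(HnnConfig(seed=2, d_h=3, k_points=2))
        from molhnn.pooling import select_points_of_interest
        from molhnn.transfer import _source_reps
        model.points = select_points_of_interest(
            _source_reps(model, src, np.arange(src.n)), 2, 0).P
        rep = compute_target_representative(tgt.raw_flat())
        batch = np.arange(6)

        def objective():
            loss, _ = total_loss(model, src, batch, config, rep, tgt)
            return float(loss.data)

        loss, _ = total_loss(model, src, batch, config, rep, tgt)
        model.zero_grad()
        loss.backward()
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, p in model.named_parameters().items():
            flat = p.data.ravel()
            idxs = rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                fp = objective()
                flat[i] = orig - eps
                fm = objective()
                flat[i] = orig
                num = (fp - fm) / (2 * eps)
                ana = p.grad.ravel()[i]
                assert ana == pytest.approx(num, rel=1e-5, abs=1e-8), \
                    f"{name}[{i}]"


class TestTraining:
    def test_zero_shot_audit(self):
        src, tgt = tiny_datasets()
        tgt.free_energy = np.zeros(tgt.n)
        with pytest.raises(ZeroShotViolationError):
            train(src, tgt, TrainingConfig(epochs=1))

    def test_zero_learning_rate_keeps_parameters(self):
        src, tgt = tiny_datasets()
        cfg = TrainingConfig(epochs=1, learning_rate=0.0, seed=0)
        res = train(src, tgt, cfg, HnnConfig(seed=7, d_h=4, k_points=2))
        fresh = HnnModel(HnnConfig(seed=7, d_h=4, k_points=2))
        for a, b in zip(res.model.parameters(), fresh.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_fixed_seed_reproducible(self):
        src, tgt = tiny_datasets()
        cfg = TrainingConfig(epochs=3, seed=5)
        mc = HnnConfig(seed=5, d_h=4, k_points=2)
        h1 = train(src, tgt, cfg, mc).history
        h2 = train(src, tgt, cfg, mc).history
        np.testing.assert_array_equal(h1["total"].to_numpy(),
                                      h2["total"].to_numpy())

    def test_loss_decreases_on_separable_labels(self):
        src, tgt = tiny_datasets()
        cfg = TrainingConfig(epochs=10, seed=0, learning_rate=3e-3)
        res = train(src, tgt, cfg, HnnConfig(seed=0, d_h=4, k_points=2))
        bce = res.history["bce"].to_numpy()
        assert bce[-1] < bce[0]

    def test_target_regularizer_changes_parameters(self):
        src, tgt = tiny_datasets()
        mc = HnnConfig(seed=1, d_h=4, k_points=2)
        with_reg = train(src, tgt, TrainingConfig(
            epochs=2, seed=1, target_reg_coeff=0.5), mc)
        without = train(src, tgt, TrainingConfig(
            epochs=2, seed=1, target_reg_coeff=0.0), mc)
        diffs = [np.abs(a.data - b.data).max()
                 for a, b in zip(with_reg.model.parameters(),
                                 without.model.parameters())]
        assert max(diffs) > 0

    def test_predict_is_deterministic_and_bounded(self):
        src, tgt = tiny_datasets()
        res = train(src, tgt, TrainingConfig(epochs=2, seed=0),
                    HnnConfig(seed=0, d_h=4, k_points=2))
        t1 = predict(res.model, tgt)
        t2 = predict(res.model, tgt)
        np.testing.assert_array_equal(t1["probability"], t2["probability"])
        p = t1["probability"].to_numpy()
        assert np.all((p >= 0) & (p <= 1))

    def test_predict_ignores_labels(self):
        src, tgt = tiny_datasets()
        res = train(src, tgt, TrainingConfig(epochs=2, seed=0),
                    HnnConfig(seed=0, d_h=4, k_points=2))
        tgt_labeled = HypergraphDataset(
            topology=tgt.topology, X0=tgt.X0, W=tgt.W, B=tgt.B,
            labels=np.ones(tgt.n, dtype=int))
        np.testing.assert_array_equal(
            predict(res.model, tgt)["probability"],
            predict(res.model, tgt_labeled)["probability"])
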