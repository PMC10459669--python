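"""Network operations: closed-form oracles, symmetry properties, variants."""

import copy

import numpy as np
import pytest

from equivs.autodiff import Tensor
from equivs.errors import AttentionUnavailableError, ShapeError
from equivs.model import (
    EquiVS,
    EquiVSConfig,
    attend,
    egnn_coord_update,
    egnn_layer,
    egnn_message,
    forward_single,
    gcn_encode,
    init_params,
    make_batch,
    predict_conformer,
    predict_molecule,
    skip_concat,
)

from conftest import random_rigid_motion


def tiny_params(node_dim=3, edge_dim=2, hidden=4, n_layers=2, seed=0):
    cfg = EquiVSConfig(
        hidden_dim=hidden, n_layers=n_layers, node_dim=node_dim,
        edge_dim=edge_dim, seed=seed,
    )
    return init_params(cfg), cfg


def rigid(coords, R, t):
    return coords @ R.T + t


class TestGcnEncode:
    def test_permutation_invariance_of_graph_readout(self):
        params, _ = tiny_params()
        rng = np.random.default_rng(1)
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        HV = rng.normal(size=(3, 3))
        _, H1 = gcn_encode(A, HV, params)
        perm = np.array([2, 0, 1])
        _, H1p = gcn_encode(A[np.ix_(perm, perm)], HV[perm], params)
        np.testing.assert_allclose(H1, H1p, atol=1e-10)

    def test_single_node_readout_closed_form(self):
        params, _ = tiny_params()
        HV = np.array([[0.3, -0.2, 0.5]])
        h1, H1 = gcn_encode(np.zeros((1, 1)), HV, params)
        # isolated node: zero message sum, then gate * h
        expected_h = HV @ params["gcn_phi_h_W"][:3] + params["gcn_phi_h_b"]
        np.testing.assert_allclose(h1, expected_h, atol=1e-12)
        gate = 1 / (1 + np.exp(-(h1 @ params["readout0_W"] + params["readout0_b"])))
        np.testing.assert_allclose(H1, (gate * h1)[0], atol=1e-12)

    def test_zero_update_map_gives_zero_readout(self):
        params, _ = tiny_params()
        params = {k: np.zeros_like(v) for k, v in params.items()}
        _, H1 = gcn_encode(np.array([[0, 1], [1, 0]]), np.ones((2, 3)), params)
        np.testing.assert_array_equal(H1, np.zeros(4))


class TestEgnnMessage:
    def setup_method(self):
        self.params, _ = tiny_params()
        self.rng = np.random.default_rng(2)

    def test_rigid_motion_leaves_message_unchanged(self):
        h_i, h_j = self.rng.normal(size=(2, 3))
        e = self.rng.normal(size=2)
        x_i, x_j = self.rng.normal(size=(2, 3))
        m0 = egnn_message(h_i, h_j, x_i, x_j, e, self.params, 0)
        R, t = random_rigid_motion(self.rng)
        m1 = egnn_message(
            h_i, h_j, rigid(x_i, R, t), rigid(x_j, R, t), e, self.params, 0
        )
        np.testing.assert_allclose(m0, m1, atol=1e-5)

    def test_coincident_atoms_zero_distance_term(self):
        h = self.rng.normal(size=3)
        x = np.array([1.0, 2.0, 3.0])
        e = self.rng.normal(size=2)
        m = egnn_message(h, h, x, x, e, self.params, 0)
        # matches the explicit product with d2 = 0
        inp = np.concatenate([h, h, [0.0], e])
        expected = inp @ self.params["egnn0_phi_e_W"] + self.params["egnn0_phi_e_b"]
        np.testing.assert_allclose(m, expected, atol=1e-10)

    def test_two_node_linear_oracle(self):
        """Hand-set weights: the message equals an independently computed
        matrix product on the concatenated inputs."""
        params, _ = tiny_params(node_dim=2, edge_dim=1, hidden=2)
        W = np.arange(12, dtype=np.float64).reshape(6, 2) * 0.1
        b = np.array([0.5, -0.5])
        params["egnn0_phi_e_W"], params["egnn0_phi_e_b"] = W, b
        h_i, h_j = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        x_i, x_j = np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 2.0])
        e = np.array([1.0])
        m = egnn_message(h_i, h_j, x_i, x_j, e, params, 0)
        oracle = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 1.0]) @ W + b
        np.testing.assert_allclose(m, oracle, atol=1e-12)


class TestEgnnCoordUpdate:
    def test_zero_phi_x_leaves_coordinates(self):
        params, _ = tiny_params()
        params["egnn0_phi_x_W"] = np.zeros_like(params["egnn0_phi_x_W"])
        x = np.random.default_rng(0).normal(size=(3, 3))
        src = np.array([0, 1, 1, 2])
        dst = np.array([1, 0, 2, 1])
        msgs = np.random.default_rng(1).normal(size=(4, 4))
        out = egnn_coord_update(x, src, dst, msgs, params, 0)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_two_node_constant_phi_x_closed_form(self):
        params, _ = tiny_params()
        params["egnn0_phi_x_W"] = np.zeros_like(params["egnn0_phi_x_W"])
        c = 0.7
        params["egnn0_phi_x_b"] = np.array([c])
        x = np.array([[0.0, 0.0, 0.0], [1.0, -1.0, 2.0]])
        src, dst = np.array([0, 1]), np.array([1, 0])
        msgs = np.zeros((2, 4))
        out = egnn_coord_update(x, src, dst, msgs, params, 0)
        # n=2 so C = 1/(n-1) = 1: x_i' = x_i + c * (x_i - x_j)
        expected = x + c * (x - x[::-1])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_equivariance_under_rigid_motion(self):
        params, _ = tiny_params()
        rng = np.random.default_rng(5)
        n = 5
        x = rng.normal(size=(n, 3))
        src = np.array([0, 1, 1, 2, 3, 4, 2, 0])
        dst = np.array([1, 0, 2, 1, 4, 3, 0, 2])
        h = rng.normal(size=(n, 3))
        e = rng.normal(size=(len(src), 2))
        R, t = random_rigid_motion(rng)

        def messages(xx):
            return np.stack(
                [
                    egnn_message(h[i], h[j], xx[i], xx[j], e[k], params, 0)
                    for k, (i, j) in enumerate(zip(src, dst))
                ]
            )

        out0 = egnn_coord_update(x, src, dst, messages(x), params, 0)
        xr = rigid(x, R, t)
        out1 = egnn_coord_update(xr, src, dst, messages(xr), params, 0)
        np.testing.assert_allclose(out1, rigid(out0, R, t), atol=1e-5)


class TestEgnnLayer:
    def test_invariance_of_features_and_readout(self):
        params, cfg = tiny_params()
        rng = np.random.default_rng(7)
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        h = rng.normal(size=(3, 3))
        x = rng.normal(size=(3, 3))
        src, dst = np.nonzero(A)
        HE = rng.normal(size=(len(src), 2))
        h1, x1, r1 = egnn_layer(A, h, HE, x, params, 0)
        R, t = random_rigid_motion(rng)
        h2, x2, r2 = egnn_layer(A, h, HE, rigid(x, R, t), params, 0)
        np.testing.assert_allclose(h1, h2, atol=1e-5)
        np.testing.assert_allclose(r1, r2, atol=1e-5)
        np.testing.assert_allclose(x2, rigid(x1, R, t), atol=1e-5)

    def test_identical_coordinates_identical_readouts(self):
        params, _ = tiny_params()
        rng = np.random.default_rng(8)
        A = np.array([[0, 1], [1, 0]])
        h = rng.normal(size=(2, 3))
        x = rng.normal(size=(2, 3))
        HE = rng.normal(size=(2, 2))
        _, _, ra = egnn_layer(A, h, HE, x, params, 0)
        _, _, rb = egnn_layer(A, h, HE, x.copy(), params, 0)
        np.testing.assert_array_equal(ra, rb)


class TestSkipConcat:
    def test_default_width_is_256(self):
        out = skip_concat([np.zeros(128), np.zeros(128)])
        assert out.shape == (256,)

    def test_single_layer_identity(self):
        r = np.arange(4.0)
        np.testing.assert_array_equal(skip_concat([r]), r)

    def test_slicing_recovers_layers(self):
        a, b = np.arange(4.0), np.arange(4.0, 8.0)
        out = skip_concat([a, b])
        np.testing.assert_array_equal(out[:4], a)
        np.testing.assert_array_equal(out[4:], b)

    def test_mismatched_widths_raise(self):
        with pytest.raises(ShapeError):
            skip_concat([np.zeros(4), np.zeros(5)])


class TestAttend:
    def test_identical_reps_give_uniform_tenth(self):
        params, cfg = tiny_params()
        rng = np.random.default_rng(10)
        reps = np.tile(rng.normal(size=cfg.rep_dim), (10, 1))
        alpha, HG = attend(reps, params)
        np.testing.assert_allclose(alpha, np.full(10, 0.1), atol=1e-7)
        assert alpha.mean() == pytest.approx(0.10)
        np.testing.assert_allclose(HG, reps[0], atol=1e-6)

    def test_single_conformer(self):
        params, cfg = tiny_params()
        rep = np.arange(float(cfg.rep_dim))
        alpha, HG = attend(rep[None, :], params)
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(HG, rep)

    def test_softmax_closed_form_two_thirds(self):
        """Engineered scores (log 2, log 1) must give alpha = (2/3, 1/3)."""
        params = {
            "attn_W": np.array([[1.0]]),
            "attn_b": np.array([0.0]),
            "attn_q": np.array([[1.0]]),
        }
        reps = np.array([[np.arctanh(np.log(2.0))], [0.0]])
        alpha, _ = attend(reps, params)
        np.testing.assert_allclose(alpha, [2 / 3, 1 / 3], atol=1e-12)

    def test_normalization_for_random_inputs(self):
        params, _ = tiny_params()
        rng = np.random.default_rng(11)
        for _ in range(20):
            alpha, _ = attend(rng.normal(size=(rng.integers(1, 12), 3 * 2 + 2)), params)
            assert alpha.min() > 0
            assert alpha.sum() == pytest.approx(1.0)


class TestPredictors:
    def test_zero_weights_return_bias(self):
        params, cfg = tiny_params()
        params = {k: np.zeros_like(v) for k, v in params.items()}
        params["ins_b2"] = np.array([2.5])
        params["bag_b2"] = np.array([-1.5])
        rep = np.ones(cfg.rep_dim)
        assert predict_conformer(rep, params) == pytest.approx(2.5)
        assert predict_molecule(np.ones(cfg.hidden_dim), rep, params) == pytest.approx(-1.5)

    def test_hand_set_weights_match_matrix_oracle(self):
        params = {
            "ins_W1": np.array([[1.0, -1.0], [0.5, 2.0]]),
            "ins_b1": np.array([0.1, -0.2]),
            "ins_W2": np.array([[2.0], [1.0]]),
            "ins_b2": np.array([0.3]),
        }
        rep = np.array([1.0, 2.0])
        hid = np.maximum(rep @ params["ins_W1"] + params["ins_b1"], 0)
        oracle = (hid @ params["ins_W2"] + params["ins_b2"]).item()
        assert predict_conformer(rep, params) == pytest.approx(oracle)

    def test_relu_clamps_negative_preactivations(self):
        params, cfg = tiny_params()
        params["ins_W1"] = np.zeros_like(params["ins_W1"])
        params["ins_b1"] = np.full_like(params["ins_b1"], -5.0)  # all negative
        params["ins_b2"] = np.array([0.7])
        assert predict_conformer(np.ones(cfg.rep_dim), params) == pytest.approx(0.7)

    def test_width_mismatch_raises(self):
        params, cfg = tiny_params()
        with pytest.raises(ShapeError):
            predict_conformer(np.ones(cfg.rep_dim + 1), params)
        with pytest.raises(ShapeError):
            predict_molecule(np.ones(3), np.ones(3), params)


class TestForwardFull:
    def test_contract_alpha_normalized_and_finite(self, small_graphs, tiny_model):
        for res in tiny_model.predict(small_graphs):
            assert np.isfinite(res.yG)
            assert res.alpha.sum() == pytest.approx(1.0, abs=1e-5)
            assert np.all(res.alpha > 0)
            assert res.yGm.shape == (10,)

    def test_batched_matches_single_graph_reference(self, small_graphs, tiny_model):
        batch = make_batch(small_graphs, 10)
        out = tiny_model.forward(batch)
        for i, g in enumerate(small_graphs):
            ref = forward_single(g, tiny_model.params, tiny_model.config)
            assert out.yG.value[i] == pytest.approx(ref.yG, abs=1e-4)
            np.testing.assert_allclose(out.yGm.value[i], ref.yGm, atol=1e-4)
            np.testing.assert_allclose(out.alpha.value[i], ref.alpha, atol=1e-5)

    def test_rigid_motion_invariance_of_predictions(self, small_graphs, tiny_model):
        rng = np.random.default_rng(13)
        for g in small_graphs:
            ref = forward_single(g, tiny_model.params, tiny_model.config)
            g2 = copy.deepcopy(g)
            for m in range(g.M):
                R, t = random_rigid_motion(rng)
                g2.HC[:, 3 * m : 3 * m + 3] = (
                    g.conformer_coords(m).astype(np.float64) @ R.T + t
                ).astype(np.float32)
            moved = forward_single(g2, tiny_model.params, tiny_model.config)
            assert abs(moved.yG - ref.yG) < 1e-5 * max(1.0, abs(ref.yG))
            np.testing.assert_allclose(moved.yGm, ref.yGm, atol=1e-4)
            np.testing.assert_allclose(moved.alpha, ref.alpha, atol=1e-5)

    def test_atom_permutation_invariance_of_prediction(
        self, toluene_ensemble, tiny_model
    ):
        from rdkit import Chem

        from equivs.molgraph import assemble_graph

        g = assemble_graph(toluene_ensemble)
        ens2 = toluene_ensemble.copy()
        perm = np.random.default_rng(3).permutation(g.n_atoms)
        ens2.mol = Chem.RenumberAtoms(ens2.mol, [int(p) for p in perm])
        g2 = assemble_graph(ens2)
        a = forward_single(g, tiny_model.params, tiny_model.config)
        b = forward_single(g2, tiny_model.params, tiny_model.config)
        assert a.yG == pytest.approx(b.yG, abs=1e-4)

    def test_gradient_reaches_first_egnn_layer(self, small_graphs, tiny_model):
        """Skip connections keep the shallow equivariant layer trainable."""
        from equivs.training import batch_loss

        batch = make_batch(small_graphs, 10)
        out = tiny_model.forward(batch)
        batch_loss(out, batch.y, 0.5).backward()
        g = out.param_tensors["egnn0_phi_e_W"].grad
        assert g is not None and np.abs(g).max() > 0


class TestVariants:
    def test_no_attention_aggregates_by_plain_sum(self, small_graphs):
        cfg = EquiVSConfig.for_variant("no_aa", hidden_dim=8, seed=3)
        model = EquiVS(cfg)
        batch = make_batch(small_graphs, 10)
        out = model.forward(batch)
        assert out.alpha is None
        # oracle: run the per-layer readouts via the reference path and sum
        ref = forward_single(small_graphs[0], model.params, cfg)
        assert out.yG.value[0] == pytest.approx(ref.yG, abs=1e-4)
        with pytest.raises(AttentionUnavailableError):
            model.attention_coefficients(small_graphs)

    def test_single_conformer_alpha_is_one(self, small_graphs):
        cfg = EquiVSConfig.for_variant("single", hidden_dim=8, seed=3)
        model = EquiVS(cfg)
        res = model.predict(small_graphs)[0]
        np.testing.assert_allclose(res.alpha, [1.0])
        assert res.yGm.shape == (1,)

    def test_no_skip_uses_last_readout_width(self):
        cfg = EquiVSConfig.for_variant("no_skip", hidden_dim=8)
        assert cfg.rep_dim == 8
        params = init_params(cfg)
        assert params["attn_W"].shape == (8, 8)

    def test_no_gcn_has_linear_encoder(self):
        cfg = EquiVSConfig.for_variant("no_gcn", hidden_dim=8)
        params = init_params(cfg)
        assert "lin_W" in params and "gcn_phi_e_W" not in params

    def test_checkpoint_round_trip(self, tmp_path, small_graphs, tiny_model):
        path = tmp_path / "ckpt.npz"
        tiny_model.save(path)
        back = EquiVS.load(path)
        assert back.config == tiny_model.config
        a = tiny_model.predict(small_graphs)
        b = back.predict(small_graphs)
        for ra, rb in zip(a, b):
            assert ra.yG == pytest.approx(rb.yG)
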