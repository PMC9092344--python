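"""Directed message passing: shapes, oracle equivalence, gradients, counts."""

import numpy as np
import pytest

from cgrnet import (EncoderConfig, aggregate, atom_hidden_states,
                    batch_graphs, build_cgr, count_parameters, encode,
                    featurize_cgr, featurize_molecule, init_edge_states,
                    message_passing_step, parse_reaction)
from cgrnet.encoder import init_encoder_weights
from cgrnet.nn import DMPNNetwork, mse_loss, n_parameters

from _reference import (brute_force_atom_states, brute_force_edge_states,
                        brute_force_embedding, random_graph)


def _weights(cfg, atom_dim, bond_dim, seed=0, randomize_bias=True):
    rng = np.random.default_rng(seed)
    w = init_encoder_weights(cfg, atom_dim, bond_dim, rng)
    if randomize_bias:
        w["b_h"] = 0.1 * rng.standard_normal(cfg.hidden_size)
        w["b_o"] = 0.1 * rng.standard_normal(cfg.hidden_size)
    return w


class TestEdgeInitialization:
    def test_reaction_input_dimension_193(self, water_records):
        g = featurize_cgr(build_cgr(water_records[0]))
        cfg = EncoderConfig(hidden_size=300)
        w = _weights(cfg, 165, 28)
        assert w["W_i"].shape == (300, 193)
        h0 = init_edge_states(g, cfg, w)
        assert h0.shape == (g.n_directed_edges, 300)

    def test_molecular_input_dimension_147(self):
        g = featurize_molecule(parse_reaction("[CH4:1]>>[CH4:1]").reactant)
        cfg = EncoderConfig(hidden_size=8)
        w = _weights(cfg, 133, 14)
        assert w["W_i"].shape[1] == 147
        assert init_edge_states(g, cfg, w).shape[1] == 8

    def test_zero_weights_give_zero_states(self, water_records):
        g = featurize_cgr(build_cgr(water_records[0]))
        cfg = EncoderConfig(hidden_size=4)
        w = _weights(cfg, 165, 28)
        w["W_i"] = np.zeros_like(w["W_i"])
        assert np.all(init_edge_states(g, cfg, w) == 0)

    def test_dimension_mismatch_raises(self, water_records):
        g = featurize_cgr(build_cgr(water_records[0]))
        cfg = EncoderConfig(hidden_size=4)
        w = _weights(cfg, 133, 14)  # molecular weights, reaction graph
        with pytest.raises(ValueError, match="dim"):
            init_edge_states(g, cfg, w)


class TestMessagePassing:
    def test_path_graph_excludes_reverse_edge(self):
        """On a path a-b-c, the message into (b->c) must use only h_(a->b),
        never h_(c->b): checked by hand against the neighbor enumeration."""
        rng = np.random.default_rng(1)
        g = random_graph(rng, max_atoms=3, atom_dim=4, bond_dim=2)
        while g.n_atoms != 3 or g.n_directed_edges != 4:
            g = random_graph(rng, max_atoms=3, atom_dim=4, bond_dim=2)
        cfg = EncoderConfig(hidden_size=5, depth=1)
        w = _weights(cfg, 4, 2, seed=2)
        h0 = init_edge_states(g, cfg, w)
        h1 = message_passing_step(h0, h0, g, cfg, w)
        for e in range(g.n_directed_edges):
            v, wv = g.edge_src[e], g.edge_tgt[e]
            s = np.zeros(5)
            for e2 in range(g.n_directed_edges):
                if g.edge_tgt[e2] == v and g.edge_src[e2] != wv:
                    s += h0[e2]
            expect = np.maximum(h0[e] + w["W_h"] @ s + w["b_h"], 0)
            np.testing.assert_allclose(h1[e], expect, atol=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        """Vectorized update vs the dense loop reference, 20 graphs <=8 atoms."""
        rng = np.random.default_rng(42)
        cfg = EncoderConfig(hidden_size=6, depth=3)
        for trial in range(20):
            g = random_graph(rng, max_atoms=8, atom_dim=9, bond_dim=4)
            w = _weights(cfg, 9, 4, seed=trial)
            h0 = init_edge_states(g, cfg, w)
            ht = h0
            for _ in range(cfg.depth):
                ht = message_passing_step(ht, h0, g, cfg, w)
            ref = brute_force_edge_states(g, w, cfg.depth)
            for e in range(g.n_directed_edges):
                key = (int(g.edge_src[e]), int(g.edge_tgt[e]))
                np.testing.assert_allclose(ht[e], ref[key], atol=1e-6)
            atoms = atom_hidden_states(ht, g, cfg, w)
            np.testing.assert_allclose(
                atoms, brute_force_atom_states(g, w, cfg.depth), atol=1e-6)


class TestAtomReadout:
    def test_isolated_atom_uses_empty_neighbor_sum(self):
        from cgrnet.featurizer import FeaturizedGraph
        g = FeaturizedGraph(atom_matrix=np.ones((1, 4)),
                            edge_matrix=np.zeros((0, 2)),
                            edge_src=np.zeros(0, int),
                            edge_tgt=np.zeros(0, int),
                            rev_index=np.zeros(0, int))
        cfg = EncoderConfig(hidden_size=3)
        w = _weights(cfg, 4, 2, seed=3)
        states = np.zeros((0, 3))
        atoms = atom_hidden_states(states, g, cfg, w)
        expect = np.maximum(
            w["W_o"] @ np.concatenate([g.atom_matrix[0], np.zeros(3)])
            + w["b_o"], 0)
        np.testing.assert_allclose(atoms[0], expect)

    def test_output_weight_input_dim_default_reaction_mode(self):
        cfg = EncoderConfig(hidden_size=300)
        w = _weights(cfg, 165, 28)
        assert w["W_o"].shape == (300, 465)


class TestAggregate:
    def test_mean_of_identical_rows_is_that_row(self):
        cfg = EncoderConfig(hidden_size=4)
        row = np.array([1.0, -2.0, 3.0, 0.5])
        emb = aggregate(np.tile(row, (5, 1)), None, cfg)
        np.testing.assert_allclose(emb, row)

    def test_extra_features_extend_embedding(self):
        cfg = EncoderConfig(hidden_size=300)
        emb = aggregate(np.ones((2, 300)), np.arange(6.0), cfg)
        assert emb.shape == (306,)
        emb = aggregate(np.ones((2, 300)), None, cfg)
        assert emb.shape == (300,)

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate(np.zeros((0, 4)), None, EncoderConfig(hidden_size=4))


class TestParameterCount:
    @pytest.mark.parametrize("n_extra,expected",
                             [(0, 378_601), (6, 380_401), (218, 444_001)])
    def test_default_reaction_model_counts(self, n_extra, expected):
        cfg = EncoderConfig(hidden_size=300, depth=3)
        assert count_parameters(cfg, 165, 28, ffn_layers=2,
                                n_extra=n_extra, out_dim=1) == expected

    def test_closed_form_matches_instantiated_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            h = int(rng.integers(2, 40))
            ffn = int(rng.integers(1, 4))
            ne = int(rng.integers(0, 8))
            out = int(rng.integers(1, 5))
            da, db = int(rng.integers(4, 30)), int(rng.integers(2, 10))
            cfg = EncoderConfig(hidden_size=h, depth=int(rng.integers(0, 4)))
            net = DMPNNetwork(enc_cfg=cfg, atom_dim=da, bond_dim=db,
                              ffn_layers=ffn, n_extra=ne, out_dim=out)
            assert n_parameters(net.init_params(rng)) \
                == count_parameters(cfg, da, db, ffn, ne, out)


class TestEncoderInvariants:
    def test_atom_permutation_leaves_embedding_unchanged(self):
        rng = np.random.default_rng(5)
        cfg = EncoderConfig(hidden_size=7, depth=2)
        for trial in range(5):
            g = random_graph(rng, max_atoms=7, atom_dim=6, bond_dim=3)
            w = _weights(cfg, 6, 3, seed=trial)
            emb = encode(g, cfg, w)
            perm = rng.permutation(g.n_atoms)
            inv = np.argsort(perm)
            from cgrnet.featurizer import FeaturizedGraph
            g2 = FeaturizedGraph(atom_matrix=g.atom_matrix[perm],
                                 edge_matrix=g.edge_matrix,
                                 edge_src=inv[g.edge_src],
                                 edge_tgt=inv[g.edge_tgt],
                                 rev_index=g.rev_index)
            np.testing.assert_allclose(encode(g2, cfg, w), emb, atol=1e-6)

    def test_depth_zero_still_defines_an_embedding(self, water_records):
        g = featurize_cgr(build_cgr(water_records[0]))
        cfg = EncoderConfig(hidden_size=5, depth=0)
        w = _weights(cfg, 165, 28)
        emb = encode(g, cfg, w)
        assert emb.shape == (5,) and np.all(np.isfinite(emb))

    def test_full_encoder_matches_brute_force(self):
        rng = np.random.default_rng(9)
        cfg = EncoderConfig(hidden_size=5, depth=2)
        for trial in range(5):
            g = random_graph(rng, max_atoms=6, atom_dim=5, bond_dim=3,
                             with_extra=True)
            w = _weights(cfg, 5, 3, seed=trial + 10)
            np.testing.assert_allclose(
                encode(g, cfg, w), brute_force_embedding(g, w, cfg.depth),
                atol=1e-8)


class TestBatching:
    def test_batched_forward_equals_per_graph(self):
        rng = np.random.default_rng(3)
        cfg = EncoderConfig(hidden_size=6, depth=2)
        graphs = [random_graph(rng, max_atoms=6, atom_dim=5, bond_dim=3)
                  for _ in range(4)]
        net = DMPNNetwork(enc_cfg=cfg, atom_dim=5, bond_dim=3, out_dim=2)
        params = net.init_params(rng)
        batched, _ = net.forward(params, batch_graphs(graphs))
        singles = np.concatenate(
            [net.forward(params, batch_graphs([g]))[0] for g in graphs])
        np.testing.assert_allclose(batched, singles, atol=1e-12)


class TestGradients:
    def test_backprop_matches_finite_differences(self, toy_records):
        """Analytic gradients of the full model vs central differences.

        Biases are shifted off zero first so no ReLU pre-activation sits
        exactly on the kink where the subgradient is ambiguous.
        """
        batch = batch_graphs([featurize_cgr(build_cgr(r))
                              for r in toy_records[:3]])
        net = DMPNNetwork(enc_cfg=EncoderConfig(hidden_size=6, depth=2),
                          atom_dim=165, bond_dim=28, ffn_layers=2, out_dim=1)
        rng = np.random.default_rng(0)
        params = net.init_params(rng)
        for k in params:
            params[k] = params[k] + 0.05 * rng.standard_normal(params[k].shape)
        y = rng.standard_normal((3, 1))

        out, cache = net.forward(params, batch)
        _, dout = mse_loss(out, y)
        grads = net.backward(params, cache, dout)

        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for k, p in params.items():
            flat = check_rng.choice(p.size, size=min(12, p.size),
                                    replace=False)
            for i in flat:
                ix = np.unravel_index(i, p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = mse_loss(net.forward(params, batch)[0], y)[0]
                p[ix] = orig - eps
                lm = mse_loss(net.forward(params, batch)[0], y)[0]
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[k][ix]) \
                    <= 1e-6 * max(1.0, abs(num)), f"grad mismatch in {k}"
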