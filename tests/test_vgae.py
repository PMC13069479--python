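import math

import numpy as np
import pytest

from grnwalker.nn import Tensor
from grnwalker.vgae import (
    GraphDecoder,
    GraphEncoder,
    GraphTransformerLayer,
    GraphVAE,
    LatentDistribution,
    TransConvConfig,
    directed_edge_arrays,
    pairwise_attention,
    reparameterize,
)
from grnwalker.walker import TFAnchoredSubgraph

SMALL = TransConvConfig(hidden=8, heads=2, encoder_blocks=2, decoder_blocks=2, embed_dim=8)


def _scalar_cfg():
    return TransConvConfig(
        hidden=1, heads=1, encoder_blocks=1, decoder_blocks=1, latent_dim=2, embed_dim=1
    )


def _random_graph(rng, n=10, m=20, dim=8):
    src = rng.integers(0, n, m)
    dst = rng.integers(0, n, m)
    keep = src != dst
    src, dst = src[keep], dst[keep]
    x = rng.standard_normal((n, dim)).astype(np.float32)
    e = rng.standard_normal((len(src), dim)).astype(np.float32)
    return Tensor(x), Tensor(e), src, dst


class TestPairwiseAttention:
    def test_uniform_when_logits_equal(self):
        """Equal q, k and zero edge features: 4 neighbours get 0.25 each."""
        layer = GraphTransformerLayer(_scalar_cfg(), np.random.default_rng(0))
        x = Tensor(np.ones((5, 1), dtype=np.float32))
        src = np.array([1, 2, 3, 4])
        dst = np.array([0, 0, 0, 0])
        e = Tensor(np.zeros((4, 1), dtype=np.float32))
        alpha = pairwise_attention(layer, x, e, src, dst)
        np.testing.assert_allclose(alpha.ravel(), 0.25, atol=1e-6)

    def test_single_neighbour_gets_weight_one(self):
        layer = GraphTransformerLayer(_scalar_cfg(), np.random.default_rng(0))
        alpha = pairwise_attention(
            layer,
            np.ones((2, 1), dtype=np.float32),
            np.zeros((1, 1), dtype=np.float32),
            np.array([1]),
            np.array([0]),
        )
        assert alpha.ravel()[0] == pytest.approx(1.0, abs=1e-7)

    def test_hand_computed_two_neighbour_logits(self):
        """1-dim q, k, e with d = 1: softmax of the two hand-computed logits."""
        layer = GraphTransformerLayer(_scalar_cfg(), np.random.default_rng(0))
        wq, wk, we = 1.5, -0.7, 0.4
        layer.wq.weight.data = np.array([[wq]])
        layer.wk.weight.data = np.array([[wk]])
        layer.we.weight.data = np.array([[we]])
        x = np.array([[0.3], [1.2], [-0.8]])
        e = np.array([[0.5], [-1.0]])
        src = np.array([1, 2])
        dst = np.array([0, 0])
        alpha = pairwise_attention(layer, x, e, src, dst)
        logits = [
            (wq * 0.3) * (wk * 1.2 + we * 0.5),
            (wq * 0.3) * (wk * -0.8 + we * -1.0),
        ]
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(alpha.ravel(), expected, atol=1e-8)

    def test_rows_sum_to_one_on_random_graphs(self, rng):
        layer = GraphTransformerLayer(SMALL, np.random.default_rng(1))
        for trial in range(10):
            x, e, src, dst = _random_graph(np.random.default_rng(trial))
            alpha = pairwise_attention(layer, x, e, src, dst)
            sums = np.zeros((10, SMALL.heads))
            np.add.at(sums, dst, alpha)
            present = np.unique(dst)
            np.testing.assert_allclose(sums[present], 1.0, atol=1e-6)


class TestTransformerBlock:
    def test_shapes_preserved(self, rng):
        layer = GraphTransformerLayer(SMALL, np.random.default_rng(2))
        x, e, src, dst = _random_graph(rng)
        x2, e2 = layer(x, e, src, dst)
        assert x2.shape == x.shape
        assert e2.shape == e.shape

    def test_residual_path_preserves_signal_under_masked_attention(self, rng):
        """Zeroing attention messages does not zero the output."""
        layer = GraphTransformerLayer(SMALL, np.random.default_rng(3))
        x, e, src, dst = _random_graph(rng)
        layer.wv.weight.data *= 0.0  # kill values
        layer.we.weight.data *= 0.0  # kill edge messages
        x2, _ = layer(x, e, src, dst)
        assert float(np.abs(x2.data).sum()) > 0.1

    def test_leaky_relu_keeps_scaled_negative_signal(self):
        x = Tensor(np.array([[-2.0, 1.0]], dtype=np.float32))
        out = x.leaky_relu(0.01)
        np.testing.assert_allclose(out.data, [[-0.02, 1.0]], atol=1e-7)

    def test_one_block_matches_scalar_arithmetic_oracle(self):
        """3-node, 2-edge toy with hand-set 1-dim weights, replayed in pure
        python float arithmetic, agrees to 1e-8 (float64 parameters)."""
        cfg = _scalar_cfg()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        wq, wk, wv, we, wo, bo = 1.1, -0.6, 0.9, 0.5, 1.3, 0.1
        w1, b1, w2, b2 = 0.7, -0.2, 1.2, 0.05
        wu = [0.3, -0.4, 0.8]
        bu = 0.2
        gn, bn_, ge, be = 1.4, 0.3, 0.8, -0.1
        layer.wq.weight.data = np.array([[wq]])
        layer.wk.weight.data = np.array([[wk]])
        layer.wv.weight.data = np.array([[wv]])
        layer.we.weight.data = np.array([[we]])
        layer.wo.weight.data = np.array([[wo]])
        layer.wo.bias.data = np.array([bo])
        layer.ffn.fc1.weight.data = np.array([[w1]])
        layer.ffn.fc1.bias.data = np.array([b1])
        layer.ffn.fc2.weight.data = np.array([[w2]])
        layer.ffn.fc2.bias.data = np.array([b2])
        layer.edge_update.weight.data = np.array([[wu[0]], [wu[1]], [wu[2]]])
        layer.edge_update.bias.data = np.array([bu])
        layer.bn_node.gamma.data = np.array([gn])
        layer.bn_node.beta.data = np.array([bn_])
        layer.bn_edge.gamma.data = np.array([ge])
        layer.bn_edge.beta.data = np.array([be])
        layer.eval()

        sg = TFAnchoredSubgraph(
            anchor="a",
            node_ids=["a", "b", "c"],
            edges=[("a", "b", 0.6), ("b", "c", -0.4)],
            hop_reached=1,
        )
        src, dst, w = directed_edge_arrays(sg)
        xv = [0.25, -0.5, 1.0]
        ev = [0.6, -0.4, 0.6, -0.4]  # forward then reverse copies
        x2, e2 = layer(
            Tensor(np.array(xv)[:, None]), Tensor(np.array(ev)[:, None]), src, dst
        )

        # --- independent scalar replay -----------------------------------
        def leaky(v, s=0.01):
            return v if v >= 0 else s * v

        q = [wq * v for v in xv]
        k = [wk * v for v in xv]
        v_ = [wv * v for v in xv]
        eh = [we * v for v in ev]
        logits = [q[d] * (k[s] + eh[m]) for m, (s, d) in enumerate(zip(src, dst))]
        agg = [0.0, 0.0, 0.0]
        for node in range(3):
            ms = [m for m in range(4) if dst[m] == node]
            if not ms:
                continue
            mx = max(logits[m] for m in ms)
            exps = {m: math.exp(logits[m] - mx) for m in ms}
            z = sum(exps.values())
            for m in ms:
                agg[node] += exps[m] / z * (v_[src[m]] + eh[m])
        h = [xv[i] + (wo * agg[i] + bo) for i in range(3)]
        h = [h[i] + (w2 * leaky(w1 * h[i] + b1) + b2) for i in range(3)]
        h3 = [leaky(v) for v in h]
        mu = sum(h3) / 3
        var = sum((v - mu) ** 2 for v in h3) / 3
        xo = [gn * (v - mu) / math.sqrt(var + 1e-5) + bn_ for v in h3]
        em = [
            wu[0] * xo[src[m]] + wu[1] * xo[dst[m]] + wu[2] * ev[m] + bu
            for m in range(4)
        ]
        er = [leaky(ev[m] + em[m]) for m in range(4)]
        emu = sum(er) / 4
        evar = sum((v - emu) ** 2 for v in er) / 4
        eo = [ge * (v - emu) / math.sqrt(evar + 1e-5) + be for v in er]

        np.testing.assert_allclose(x2.data.ravel(), xo, atol=1e-8)
        np.testing.assert_allclose(e2.data.ravel(), eo, atol=1e-8)


class TestEncoderLatent:
    def test_latent_width_is_sixteen_by_default(self, rng):
        cfg = TransConvConfig(hidden=8, heads=2, embed_dim=8)
        enc = GraphEncoder(cfg, np.random.default_rng(4))
        x, _, src, dst = _random_graph(rng)
        ld = enc(x, rng.standard_normal((len(src), 1)).astype(np.float32), src, dst)
        assert ld.node_mu.shape == (10, 16)
        assert ld.edge_mu.shape == (len(src), 16)

    def test_finite_outputs_across_random_trials(self):
        enc = GraphEncoder(SMALL, np.random.default_rng(5))
        for trial in range(100):
            rng = np.random.default_rng(trial)
            x, _, src, dst = _random_graph(rng, n=6, m=10)
            w = rng.standard_normal((len(src), 1)).astype(np.float32)
            ld = enc(x, w, src, dst)
            for t in (ld.node_mu, ld.node_log_var, ld.edge_mu, ld.edge_log_var):
                assert np.all(np.isfinite(t.data))

    def test_eval_mode_deterministic(self, rng):
        enc = GraphEncoder(SMALL, np.random.default_rng(6)).eval()
        x, _, src, dst = _random_graph(rng)
        w = np.ones((len(src), 1), dtype=np.float32)
        a = enc(x, w, src, dst).node_mu.data
        b = enc(x, w, src, dst).node_mu.data
        np.testing.assert_array_equal(a, b)


class TestReparameterize:
    def _ld(self, mu, log_var):
        t = lambda v: Tensor(np.asarray(v, dtype=np.float32))
        return LatentDistribution(
            node_mu=t(mu), node_log_var=t(log_var), edge_mu=t(mu), edge_log_var=t(log_var)
        )

    def test_zero_sigma_returns_mu(self):
        ld = self._ld(np.full((4, 2), 2.0), np.full((4, 2), -80.0))
        z, _ = reparameterize(ld, seed=0)
        np.testing.assert_allclose(z.data, 2.0, atol=1e-6)

    def test_eval_mode_returns_mean_exactly(self):
        ld = self._ld(np.full((4, 2), 1.5), np.zeros((4, 2)))
        z, _ = reparameterize(ld, training=False)
        np.testing.assert_array_equal(z.data, ld.node_mu.data)

    def test_fixed_seed_reproducible(self):
        ld = self._ld(np.zeros((5, 3)), np.zeros((5, 3)))
        a, _ = reparameterize(ld, seed=42)
        b, _ = reparameterize(ld, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sample_moments_match_mu_sigma(self):
        n = 10_000
        ld = self._ld(np.full((n, 1), 2.0), np.full((n, 1), np.log(9.0)))
        z, _ = reparameterize(ld, seed=123)
        assert abs(z.data.mean() - 2.0) < 3 * (3.0 / np.sqrt(n))
        assert abs(z.data.std() - 3.0) / 3.0 < 0.05


class TestDecoderAndReconstruction:
    def test_decoder_output_counts_and_finiteness(self, rng):
        dec = GraphDecoder(SMALL, np.random.default_rng(7))
        zn = Tensor(rng.standard_normal((10, 16)).astype(np.float32))
        src = np.array([0, 1, 2, 3])
        dst = np.array([1, 2, 3, 0])
        ze = Tensor(rng.standard_normal((4, 16)).astype(np.float32))
        zp, ea = dec(zn, ze, src, dst)
        assert zp.shape[0] == 10
        assert ea.shape == (4,)
        assert np.all(np.isfinite(zp.data))

    def test_latent_perturbation_moves_that_nodes_embedding(self, rng):
        dec = GraphDecoder(SMALL, np.random.default_rng(8)).eval()
        zn = rng.standard_normal((6, 16)).astype(np.float32)
        src, dst = np.array([0, 1]), np.array([1, 0])
        ze = rng.standard_normal((2, 16)).astype(np.float32)
        base, _ = dec(Tensor(zn.copy()), Tensor(ze), src, dst)
        zn[3] += 1.0
        moved, _ = dec(Tensor(zn), Tensor(ze), src, dst)
        assert np.abs(moved.data[3] - base.data[3]).max() > 1e-4

    def test_zero_embeddings_give_half_probability(self):
        vae = GraphVAE(SMALL, np.random.default_rng(9))
        zp = Tensor(np.zeros((4, SMALL.out_dim), dtype=np.float32))
        ea = Tensor(np.zeros(4, dtype=np.float32))
        src, dst = np.array([0, 1]), np.array([1, 2])
        epm = vae.reconstruct_adjacency(zp, ea, src, dst, list("abcd"))
        np.testing.assert_allclose(epm.probabilities, 0.5, atol=1e-7)

    def test_probability_increases_with_inner_product(self):
        vae = GraphVAE(SMALL, np.random.default_rng(10))
        src, dst = np.array([0]), np.array([1])
        ea = Tensor(np.zeros(2, dtype=np.float32))
        probs = []
        for scale in (0.0, 0.5, 1.0, 2.0):
            zp = np.zeros((2, SMALL.out_dim), dtype=np.float32)
            zp[0, 0] = zp[1, 0] = scale
            epm = vae.reconstruct_adjacency(
                Tensor(zp), ea, np.array([0]), np.array([1]), ["a", "b"]
            )
            probs.append(epm.probabilities[0, 1])
        assert probs == sorted(probs)
        assert probs[0] < probs[-1]

    def test_symmetric_construction(self, rng):
        vae = GraphVAE(SMALL, np.random.default_rng(11))
        zp = np.tile(rng.standard_normal(SMALL.out_dim).astype(np.float32), (3, 1))
        ea = Tensor(rng.standard_normal(4).astype(np.float32))
        src, dst = np.array([0, 1]), np.array([1, 2])
        epm = vae.reconstruct_adjacency(Tensor(zp), ea, src, dst, list("abc"))
        np.testing.assert_allclose(
            epm.probabilities, epm.probabilities.T, atol=1e-6
        )

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        vae = GraphVAE(SMALL, np.random.default_rng(12))
        zp = Tensor(100.0 * rng.standard_normal((5, SMALL.out_dim)).astype(np.float32))
        ea = Tensor(np.zeros(2, dtype=np.float32))
        epm = vae.reconstruct_adjacency(zp, ea, np.array([0]), np.array([1]), list("abcde"))
        assert ((epm.probabilities > 0) & (epm.probabilities < 1)).all()
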