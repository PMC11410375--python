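import numpy as np
import pytest
import scipy.sparse as sp

from duogate import model as md
from duogate.graph import NeighborhoodGraph


def random_graph(rng, m, avg_deg=3):
    rows = rng.integers(0, m, size=m * avg_deg)
    cols = rng.integers(0, m, size=m * avg_deg)
    keep = rows != cols
    B = sp.csr_matrix((np.ones(keep.sum()), (rows[keep], cols[keep])), shape=(m, m))
    B.data[:] = 1.0
    B.sum_duplicates()
    B.data[:] = 1.0
    return NeighborhoodGraph(W=B.copy(), B=B)


def dense_reference_layer(H, B, params, use_attention, activation, slope=0.2):
    """Per-cell loop implementation of score/softmax/aggregate."""
    m = H.shape[0]
    G = H @ params.W + params.b
    out = np.zeros((m, params.W.shape[1]))
    for i in range(m):
        neigh = sorted(set(np.flatnonzero(B[i]).tolist()) | {i})
        if use_attention:
            scores = []
            for j in neigh:
                s = params.a_src @ G[i] + params.a_dst @ G[j]
                scores.append(s if s > 0 else slope * s)
            scores = np.array(scores)
            w = np.exp(scores - scores.max())
            w = w / w.sum()
        else:
            w = np.full(len(neigh), 1.0 / len(neigh))
        agg = sum(wj * G[j] for wj, j in zip(w, neigh))
        if activation == "relu":
            out[i] = np.maximum(agg, 0)
        elif activation == "tanh":
            out[i] = np.tanh(agg)
        else:
            out[i] = agg
    return out


class TestAttentionLayer:
    @pytest.mark.parametrize("use_attention,activation", [
        (True, "relu"), (True, "tanh"), (True, "linear"), (False, "tanh"), (False, "relu"),
    ])
    def test_matches_dense_loop_reference(self, use_attention, activation):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 8)
        ei = md.EdgeIndex(g)
        H = rng.standard_normal((8, 5))
        params = md.init_layer(rng, 5, 4, use_attention)
        out, _ = md.attention_layer(H, ei, params, use_attention, activation)
        ref = dense_reference_layer(H, g.B.toarray(), params, use_attention, activation)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_isolated_cell_reduces_to_linear_map(self):
        rng = np.random.default_rng(1)
        m = 5
        B = sp.csr_matrix((m, m))  # no edges at all: self-loops only
        ei = md.EdgeIndex(NeighborhoodGraph(W=B, B=B))
        H = rng.standard_normal((m, 3))
        params = md.init_layer(rng, 3, 2, True)
        out, _ = md.attention_layer(H, ei, params, True, "tanh")
        np.testing.assert_allclose(out, np.tanh(H @ params.W + params.b), atol=1e-12)

    def test_uniform_weights_without_attention(self):
        # cell 0 with neighbors 1 and 2 carrying identical features: each of
        # the three (incl. self-loop) contributes exactly 1/3
        B = sp.csr_matrix((np.ones(2), ([0, 0], [1, 2])), shape=(3, 3))
        ei = md.EdgeIndex(NeighborhoodGraph(W=B, B=B))
        H = np.array([[3.0], [1.0], [1.0]])
        params = md.LayerParams(W=np.array([[1.0]]), b=np.zeros(1))
        out, _ = md.attention_layer(H, ei, params, False, "linear")
        assert out[0, 0] == pytest.approx((3 + 1 + 1) / 3)

    def test_attention_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 10)
        ei = md.EdgeIndex(g)
        H = rng.standard_normal((10, 4))
        params = md.init_layer(rng, 4, 3, True)
        _, cache = md.attention_layer(H, ei, params, True, "relu")
        sums = np.add.reduceat(cache["alpha"], ei.indptr[:-1])
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)

    @pytest.mark.parametrize("use_attention,activation", [
        (True, "relu"), (True, "tanh"), (False, "tanh"), (True, "linear"),
    ])
    def test_gradients_match_finite_differences(self, use_attention, activation):
        rng = np.random.default_rng(3)
        g = random_graph(rng, 7)
        ei = md.EdgeIndex(g)
        H = rng.standard_normal((7, 4))
        params = md.init_layer(rng, 4, 3, use_attention)
        C = rng.standard_normal((7, 3))  # loss = sum(out * C)
        out, cache = md.attention_layer(H, ei, params, use_attention, activation)
        grads, dH = md.attention_layer_backward(C, cache)

        def loss():
            o, _ = md.attention_layer(H, ei, params, use_attention, activation)
            return float((o * C).sum())

        eps = 1e-6
        to_check = [("W", params.W, grads["W"]), ("b", params.b, grads["b"])]
        if use_attention:
            to_check += [("a_src", params.a_src, grads["a_src"]),
                         ("a_dst", params.a_dst, grads["a_dst"])]
        for _, arr, g_arr in to_check:
            flat = arr.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 6)):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                assert (lp - lm) / (2 * eps) == pytest.approx(g_arr.ravel()[idx], abs=1e-6)
        old = H[2, 1]
        H[2, 1] = old + eps
        lp = loss()
        H[2, 1] = old - eps
        lm = loss()
        H[2, 1] = old
        assert (lp - lm) / (2 * eps) == pytest.approx(dH[2, 1], abs=1e-6)


class TestEncodeDecode:
    def _setup(self, m=12, din=6, hidden=8, emb=3, seed=4):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, m)
        ei = md.EdgeIndex(g)
        cfg = md.GateConfig(input_dim=din, hidden_dim=hidden, embedding_dim=emb)
        path = md.init_path(cfg, rng)
        X = rng.standard_normal((m, din))
        return rng, ei, path, X, g

    def test_embedding_bounded_by_tanh(self):
        _, ei, path, X, _ = self._setup()
        emb, _ = md.encode(X, ei, path)
        assert np.all(np.abs(emb) <= 1.0)

    def test_zero_input_zero_biases_gives_zero_embedding(self):
        _, ei, path, X, _ = self._setup()
        emb, _ = md.encode(np.zeros_like(X), ei, path)
        np.testing.assert_allclose(emb, 0.0, atol=1e-15)

    def test_permutation_equivariance(self):
        rng, ei, path, X, g = self._setup()
        perm = rng.permutation(X.shape[0])
        P = sp.csr_matrix((np.ones(len(perm)), (np.arange(len(perm)), perm)))
        B_perm = (P @ g.B @ P.T).tocsr()
        ei_perm = md.EdgeIndex(NeighborhoodGraph(W=B_perm, B=B_perm))
        emb, _ = md.encode(X, ei, path)
        emb_perm, _ = md.encode(X[perm], ei_perm, path)
        np.testing.assert_allclose(emb_perm, emb[perm], atol=1e-10)

    def test_decoder_mirrors_input_shape(self):
        _, ei, path, X, _ = self._setup()
        emb, _ = md.encode(X, ei, path)
        recon, _ = md.decode(emb, ei, path)
        assert recon.shape == X.shape

    def test_zero_embedding_zero_biases_gives_zero_reconstruction(self):
        _, ei, path, X, _ = self._setup()
        recon, _ = md.decode(np.zeros((X.shape[0], 3)), ei, path)
        np.testing.assert_allclose(recon, 0.0, atol=1e-15)

    def test_forward_deterministic(self):
        _, ei, path, X, _ = self._setup()
        a, _ = md.encode(X, ei, path)
        b, _ = md.encode(X, ei, path)
        np.testing.assert_array_equal(a, b)


class TestJointEmbedding:
    def test_concatenation_and_slicing(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(-1, 1, (10, 30))
        P = rng.uniform(-1, 1, (10, 30))
        je = md.concat_embeddings(T, P)
        assert je.Z.shape == (10, 60)
        np.testing.assert_array_equal(je.Z[:, :30], T)
        np.testing.assert_array_equal(je.Z[:, 30:], P)

    def test_zero_block_propagates(self):
        T = np.ones((4, 3))
        je = md.concat_embeddings(T, np.zeros((4, 3)))
        assert np.all(je.Z[:, 3:] == 0)

    def test_cell_mismatch_rejected(self):
        with pytest.raises(ValueError):
            md.concat_embeddings(np.ones((4, 3)), np.ones((5, 3)))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        cfg = md.GateConfig(input_dim=5, hidden_dim=6, embedding_dim=2)
        model = md.DualGateModel(rna=md.init_path(cfg, rng), protein=md.init_path(cfg, rng))
        f = str(tmp_path / "ckpt.npz")
        sidecar = str(tmp_path / "ckpt.json")
        model.save(f, sidecar)
        back = md.DualGateModel.load(f, sidecar)
        np.testing.assert_array_equal(back.rna.enc1.W, model.rna.enc1.W)
        np.testing.assert_array_equal(back.protein.dec2.a_src, model.protein.dec2.a_src)
        assert back.rna.config.embedding_dim == 2
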