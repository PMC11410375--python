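"""Dual-path graph-attention auto-encoder (NumPy, analytic gradients).

Each modality passes through its own auto-encoder. The encoder has two graph
layers: the first applies single-head additive attention over the pruned
neighborhood (plus a self-loop) with a ReLU nonlinearity; the second
aggregates neighbors uniformly and maps to the embedding through Tanh. The
decoder mirrors this: uniform aggregation back to the hidden width (ReLU),
then an attention layer with a linear output for reconstruction. The two
embeddings are concatenated column-wise into the joint representation Z.

All forward and backward passes are written directly in NumPy over a fixed
edge structure, which keeps the model dependency-light and bitwise
deterministic on a single CPU; gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import NeighborhoodGraph

LEAKY_SLOPE = 0.2
EMBEDDING_DIM_DEFAULT = 30
HIDDEN_DIM_DEFAULT = 256


@dataclass
class GateConfig:
    """Architecture of one path's auto-encoder."""

    input_dim: int
    hidden_dim: int = HIDDEN_DIM_DEFAULT
    embedding_dim: int = EMBEDDING_DIM_DEFAULT
    attention: tuple = (True, False)  # per encoder layer; decoder mirrors
    leaky_slope: float = LEAKY_SLOPE
    tied_weights: bool = False

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.hidden_dim < self.embedding_dim:
            raise ValueError("hidden_dim must be >= embedding_dim")


class EdgeIndex:
    """Fixed message-passing structure: pruned edges plus one self-loop per cell.

    Edges are stored sorted by (receiver, sender) so per-receiver segments are
    contiguous; a reusable CSR pattern makes aggregation and its transpose
    cheap sparse matmuls.
    """

    def __init__(self, graph_or_B, n_cells: int | None = None):
        B = graph_or_B.B if isinstance(graph_or_B, NeighborhoodGraph) else graph_or_B
        B = sp.csr_matrix(B)
        m = B.shape[0] if n_cells is None else n_cells
        coo = B.tocoo()
        row = np.concatenate([coo.row, np.arange(m)])
        col = np.concatenate([coo.col, np.arange(m)])
        order = np.lexsort((col, row))
        self.row = np.ascontiguousarray(row[order])
        self.col = np.ascontiguousarray(col[order])
        self.m = m
        self.indptr = np.searchsorted(self.row, np.arange(m + 1)).astype(np.int64)
        self.deg = np.diff(self.indptr).astype(np.float64)  # includes self-loop
        # receiver-sorted edges re-sorted by sender, for transpose scatters
        self._perm_by_col = np.lexsort((self.row, self.col))
        col_sorted = self.col[self._perm_by_col]
        self._indptr_col = np.searchsorted(col_sorted, np.arange(m + 1)).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return len(self.row)

    def _csr(self, data: np.ndarray) -> sp.csr_matrix:
        return sp.csr_matrix((data, self.col, self.indptr), shape=(self.m, self.m))

    def aggregate(self, weights: np.ndarray, G: np.ndarray) -> np.ndarray:
        """out_i = sum over edges (i <- j) of weights * G_j."""
        return self._csr(weights) @ G

    def aggregate_T(self, weights: np.ndarray, dZ: np.ndarray) -> np.ndarray:
        """dG_j = sum over edges (i <- j) of weights * dZ_i."""
        return self._csr(weights).T @ dZ

    def segment_sum_rows(self, x: np.ndarray) -> np.ndarray:
        out = np.add.reduceat(x, self.indptr[:-1], axis=0)
        out[self.deg == 0] = 0
        return out

    def segment_sum_cols(self, x: np.ndarray) -> np.ndarray:
        xs = x[self._perm_by_col]
        counts = np.diff(self._indptr_col)
        out = np.zeros((self.m,) + x.shape[1:], dtype=x.dtype)
        nz = counts > 0
        out[nz] = np.add.reduceat(xs, self._indptr_col[:-1][nz], axis=0)
        return out

    def segment_softmax(self, e: np.ndarray) -> np.ndarray:
        # every row segment is non-empty (self-loops), so reduceat is safe
        emax = np.maximum.reduceat(e, self.indptr[:-1])
        ex = np.exp(e - emax[self.row])
        denom = np.add.reduceat(ex, self.indptr[:-1])
        return ex / denom[self.row]


@dataclass
class LayerParams:
    """One graph layer: linear transform plus optional attention vectors."""

    W: np.ndarray
    b: np.ndarray
    a_src: np.ndarray | None = None  # receiver-role vector
    a_dst: np.ndarray | None = None  # sender-role vector

    def flat(self) -> list:
        out = [self.W, self.b]
        if self.a_src is not None:
            out += [self.a_src, self.a_dst]
        return out


def init_layer(rng: np.random.Generator, din: int, dout: int, attention: bool) -> LayerParams:
    """Xavier-uniform initialization, seeded through ``rng``."""
    lim = np.sqrt(6.0 / (din + dout))
    W = rng.uniform(-lim, lim, size=(din, dout))
    b = np.zeros(dout)
    if not attention:
        return LayerParams(W=W, b=b)
    lim_a = np.sqrt(6.0 / (dout + 1))
    a_src = rng.uniform(-lim_a, lim_a, size=dout)
    a_dst = rng.uniform(-lim_a, lim_a, size=dout)
    return LayerParams(W=W, b=b, a_src=a_src, a_dst=a_dst)


def _act(pre: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(pre, 0.0)
    if activation == "tanh":
        return np.tanh(pre)
    if activation == "linear":
        return pre
    raise ValueError(f"unknown activation {activation!r}")


def _act_grad(dout: np.ndarray, pre: np.ndarray, out: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return dout * (pre > 0)
    if activation == "tanh":
        return dout * (1.0 - out * out)
    return dout


def attention_layer(
    H: np.ndarray,
    ei: EdgeIndex,
    params: LayerParams,
    use_attention: bool,
    activation: str,
    slope: float = LEAKY_SLOPE,
):
    """Forward pass of one graph layer; returns (output, cache).

    With attention on, edge scores are LeakyReLU(a_src . G_i + a_dst . G_j)
    softmax-normalized over each receiver's neighborhood (self-loop included);
    with attention off every neighbor (and the self-loop) gets weight 1/deg.
    """
    if H.shape[0] != ei.m:
        raise ValueError("feature matrix and graph disagree on the number of cells")
    G = H @ params.W + params.b
    Grow = Gcol = None
    if use_attention:
        Grow, Gcol = G[ei.row], G[ei.col]
        s = Grow @ params.a_src + Gcol @ params.a_dst
        e = np.where(s > 0, s, slope * s)
        alpha = ei.segment_softmax(e)
        cache_att = (s, alpha)
    else:
        alpha = 1.0 / ei.deg[ei.row]
        cache_att = (None, alpha)
    pre = ei.aggregate(alpha, G)
    out = _act(pre, activation)
    cache = dict(
        H=H, G=G, Grow=Grow, Gcol=Gcol, pre=pre, out=out, s=cache_att[0], alpha=cache_att[1],
        use_attention=use_attention, activation=activation, slope=slope, params=params, ei=ei,
    )
    return out, cache


def attention_layer_backward(dout: np.ndarray, cache: dict):
    """Analytic gradients of one graph layer; returns (grads, dH)."""
    ei: EdgeIndex = cache["ei"]
    params: LayerParams = cache["params"]
    alpha = cache["alpha"]
    G = cache["G"]
    dZ = _act_grad(dout, cache["pre"], cache["out"], cache["activation"])
    dG = ei.aggregate_T(alpha, dZ)
    grads = {}
    if cache["use_attention"]:
        s = cache["s"]
        Grow, Gcol = cache["Grow"], cache["Gcol"]
        dalpha = np.einsum("ed,ed->e", dZ[ei.row], Gcol)
        inner = np.add.reduceat(alpha * dalpha, ei.indptr[:-1])
        de = alpha * (dalpha - inner[ei.row])
        ds = de * np.where(s > 0, 1.0, cache["slope"])
        grads["a_src"] = ds @ Grow
        grads["a_dst"] = ds @ Gcol
        dG += ei.segment_sum_rows(ds[:, None]) * params.a_src  # receiver role
        dG += ei.segment_sum_cols(ds[:, None]) * params.a_dst  # sender role
    grads["W"] = cache["H"].T @ dG
    grads["b"] = dG.sum(axis=0)
    dH = dG @ params.W.T
    return grads, dH


@dataclass
class PathParams:
    """Encoder/decoder parameter stack for one modality."""

    enc1: LayerParams
    enc2: LayerParams
    dec1: LayerParams
    dec2: LayerParams
    config: GateConfig = None

    def layers(self):
        return {"enc1": self.enc1, "enc2": self.enc2, "dec1": self.dec1, "dec2": self.dec2}


def init_path(config: GateConfig, rng: np.random.Generator) -> PathParams:
    att1, att2 = config.attention
    return PathParams(
        enc1=init_layer(rng, config.input_dim, config.hidden_dim, att1),
        enc2=init_layer(rng, config.hidden_dim, config.embedding_dim, att2),
        dec1=init_layer(rng, config.embedding_dim, config.hidden_dim, att2),
        dec2=init_layer(rng, config.hidden_dim, config.input_dim, att1),
        config=config,
    )


def encode(X: np.ndarray, ei: EdgeIndex, path: PathParams, return_attention: bool = False):
    """Two-layer encoder: attention + ReLU, then uniform aggregation + Tanh."""
    att1, att2 = path.config.attention
    h1, c1 = attention_layer(X, ei, path.enc1, att1, "relu", path.config.leaky_slope)
    emb, c2 = attention_layer(h1, ei, path.enc2, att2, "tanh", path.config.leaky_slope)
    if not np.all(np.isfinite(emb)):
        raise FloatingPointError("non-finite values in encoder layer 2 output")
    if return_attention:
        return emb, (c1, c2), c1["alpha"]
    return emb, (c1, c2)


def decode(emb: np.ndarray, ei: EdgeIndex, path: PathParams):
    """Mirrored decoder: uniform aggregation + ReLU, then attention + linear."""
    att1, att2 = path.config.attention
    h1, c1 = attention_layer(emb, ei, path.dec1, att2, "relu", path.config.leaky_slope)
    recon, c2 = attention_layer(h1, ei, path.dec2, att1, "linear", path.config.leaky_slope)
    return recon, (c1, c2)


def path_forward(X: np.ndarray, ei: EdgeIndex, path: PathParams):
    emb, enc_caches = encode(X, ei, path)
    recon, dec_caches = decode(emb, ei, path)
    return emb, recon, (enc_caches, dec_caches)


def path_backward(d_recon: np.ndarray, d_emb_extra: np.ndarray, caches):
    """Backprop one path given d(loss)/d(recon) and extra gradient on the embedding."""
    (ec1, ec2), (dc1, dc2) = caches
    grads = {}
    g, dh = attention_layer_backward(d_recon, dc2)
    grads["dec2"] = g
    g, d_emb = attention_layer_backward(dh, dc1)
    grads["dec1"] = g
    d_emb = d_emb + d_emb_extra
    g, dh = attention_layer_backward(d_emb, ec2)
    grads["enc2"] = g
    g, _ = attention_layer_backward(dh, ec1)
    grads["enc1"] = g
    return grads


@dataclass
class JointEmbedding:
    """Per-path embeddings and their column-wise concatenation Z."""

    T_emb: np.ndarray
    P_emb: np.ndarray
    Z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.T_emb.shape[0] != self.P_emb.shape[0]:
            raise ValueError("embeddings must cover the same cells in the same order")
        self.Z = np.concatenate([self.T_emb, self.P_emb], axis=1)


def concat_embeddings(T_emb: np.ndarray, P_emb: np.ndarray) -> JointEmbedding:
    """Joint representation Z = [T_emb | P_emb], transcriptome block first."""
    return JointEmbedding(T_emb=T_emb, P_emb=P_emb)


@dataclass
class DualGateModel:
    """Both paths' parameters plus the graphs' fixed edge structures."""

    rna: PathParams
    protein: PathParams

    def save(self, path: str, sidecar: str | None = None) -> None:
        arrays = {}
        for tag, p in (("rna", self.rna), ("protein", self.protein)):
            for name, layer in p.layers().items():
                arrays[f"{tag}.{name}.W"] = layer.W
                arrays[f"{tag}.{name}.b"] = layer.b
                if layer.a_src is not None:
                    arrays[f"{tag}.{name}.a_src"] = layer.a_src
                    arrays[f"{tag}.{name}.a_dst"] = layer.a_dst
        np.savez(path, **arrays)
        if sidecar:
            import json

            cfg = {
                tag: {
                    "input_dim": p.config.input_dim,
                    "hidden_dim": p.config.hidden_dim,
                    "embedding_dim": p.config.embedding_dim,
                    "attention": list(p.config.attention),
                    "leaky_slope": p.config.leaky_slope,
                }
                for tag, p in (("rna", self.rna), ("protein", self.protein))
            }
            with open(sidecar, "w") as fh:
                json.dump(cfg, fh, indent=2)

    @classmethod
    def load(cls, path: str, sidecar: str) -> "DualGateModel":
        import json

        with open(sidecar) as fh:
            cfg = json.load(fh)
        data = np.load(path)
        paths = {}
        for tag in ("rna", "protein"):
            c = GateConfig(
                input_dim=cfg[tag]["input_dim"],
                hidden_dim=cfg[tag]["hidden_dim"],
                embedding_dim=cfg[tag]["embedding_dim"],
                attention=tuple(cfg[tag]["attention"]),
                leaky_slope=cfg[tag]["leaky_slope"],
            )
            layers = {}
            for name in ("enc1", "enc2", "dec1", "dec2"):
                key = f"{tag}.{name}"
                layers[name] = LayerParams(
                    W=data[f"{key}.W"],
                    b=data[f"{key}.b"],
                    a_src=data.get(f"{key}.a_src"),
                    a_dst=data.get(f"{key}.a_dst"),
                )
            paths[tag] = PathParams(config=c, **layers)
        return cls(rna=paths["rna"], protein=paths["protein"])
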