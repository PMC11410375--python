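"""Self-supervised training of the dual-path auto-encoder.

The objective combines per-modality mean-squared reconstruction error with
per-modality triplet self-supervision evaluated on the joint representation:

    L = (L_recon^t + L_recon^p) + lambda * (L_super^t + L_super^p)

Triplets are resampled every epoch from each modality's pruned graph: the
positive is a retained neighbor of the anchor, the negative a cell from a
different pruning community. Optimization is full-batch Adam; everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import ClusterLabels, NeighborhoodGraph
from .model import (
    DualGateModel,
    EdgeIndex,
    GateConfig,
    PathParams,
    concat_embeddings,
    encode,
    init_path,
    path_backward,
    path_forward,
)

logger = logging.getLogger("duogate")

EPOCHS_DEFAULT = 300
LR_DEFAULT = 0.001
LAMBDA_DEFAULT = 0.1
MARGIN_DEFAULT = 1.0
PER_ANCHOR_DEFAULT = 1


@dataclass
class LossBreakdown:
    """Components of the combined weighted loss at one epoch."""

    recon_t: float
    recon_p: float
    super_t: float
    super_p: float
    lam: float

    @property
    def total(self) -> float:
        return (self.recon_t + self.recon_p) + self.lam * (self.super_t + self.super_p)


@dataclass
class TripletSet:
    """(anchor, positive, negative) index triples from one modality's graph."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    margin: float = MARGIN_DEFAULT
    modality: str = ""

    def __len__(self) -> int:
        return len(self.anchors)


def mse_reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    if X.shape != X_hat.shape:
        raise ValueError("reconstruction shape does not match input shape")
    return float(np.mean((X - X_hat) ** 2))


def sample_triplets(
    graph: NeighborhoodGraph,
    labels: ClusterLabels,
    per_anchor: int = PER_ANCHOR_DEFAULT,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    margin: float = MARGIN_DEFAULT,
) -> TripletSet:
    """Draw positives from pruned neighbors, negatives from other communities.

    Anchors without a retained neighbor or without any differently labelled
    cell are skipped. Deterministic given the seed (or supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lab = labels.labels
    m = graph.n_cells
    if len(lab) != m:
        raise ValueError("labels do not cover the graph's cells")
    if labels.n_clusters < 2:
        logger.warning("sample_triplets: single community, no negatives available")
        empty = np.empty(0, dtype=np.int64)
        return TripletSet(empty, empty, empty, margin, labels.modality)
    indptr, indices = graph.B.indptr, graph.B.indices
    counts = np.diff(indptr)
    valid = counts > 0  # anchors need at least one retained neighbor
    skipped = int((~valid).sum())
    if skipped:
        logger.debug("sample_triplets: skipped %d anchor(s) without neighbors", skipped)
    base = np.flatnonzero(valid)
    if len(base) == 0:
        empty = np.empty(0, dtype=np.int64)
        return TripletSet(empty, empty, empty, margin, labels.modality)
    anchors = np.repeat(base, per_anchor)
    offs = rng.integers(0, counts[anchors])
    positives = indices[indptr[anchors] + offs].astype(np.int64)
    # rejection-sample negatives until every one has a different community
    negatives = rng.integers(0, m, size=len(anchors))
    bad = lab[negatives] == lab[anchors]
    while bad.any():
        negatives[bad] = rng.integers(0, m, size=int(bad.sum()))
        bad = lab[negatives] == lab[anchors]
    return TripletSet(anchors, positives, negatives.astype(np.int64), margin, labels.modality)


def triplet_loss(Z: np.ndarray, triplets: TripletSet) -> float:
    loss, _ = triplet_loss_grad(Z, triplets, with_grad=False)
    return loss


def triplet_loss_grad(Z: np.ndarray, triplets: TripletSet, with_grad: bool = True):
    """Mean hinge max(0, ||z_a - z_p|| - ||z_a - z_n|| + margin) and dL/dZ."""
    n = len(triplets)
    if n == 0:
        logger.warning("triplet_loss: empty triplet set, returning 0")
        return 0.0, (np.zeros_like(Z) if with_grad else None)
    a, p, ng = triplets.anchors, triplets.positives, triplets.negatives
    if max(a.max(), p.max(), ng.max()) >= Z.shape[0]:
        raise IndexError("triplet index out of range")
    dap = Z[a] - Z[p]
    dan = Z[a] - Z[ng]
    eps = 1e-12
    nap = np.sqrt((dap**2).sum(axis=1) + eps)
    nan_ = np.sqrt((dan**2).sum(axis=1) + eps)
    h = nap - nan_ + triplets.margin
    active = h > 0
    loss = float(np.maximum(h, 0.0).mean())
    if not with_grad:
        return loss, None
    dZ = np.zeros_like(Z)
    if active.any():
        w = active / (n * 1.0)
        gp = (w / nap)[:, None] * dap  # d||z_a-z_p||/dz_a
        gn = (w / nan_)[:, None] * dan
        np.add.at(dZ, a, gp - gn)
        np.add.at(dZ, p, -gp)
        np.add.at(dZ, ng, gn)
    return loss, dZ


def combined_loss(components: LossBreakdown) -> float:
    if components.lam < 0:
        raise ValueError("lambda must be non-negative")
    return components.total


class Adam:
    """Full-batch Adam on a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _collect(path: PathParams, grads: dict | None = None):
    arrays, garrays = [], []
    for name, layer in path.layers().items():
        keys = ["W", "b"] + (["a_src", "a_dst"] if layer.a_src is not None else [])
        for k in keys:
            arrays.append(getattr(layer, k))
            if grads is not None:
                garrays.append(grads[name][k])
    return (arrays, garrays) if grads is not None else arrays


def fit(
    rna_X: np.ndarray,
    protein_X: np.ndarray,
    tg: NeighborhoodGraph,
    pg: NeighborhoodGraph,
    t_labels: ClusterLabels,
    p_labels: ClusterLabels,
    embedding_dim: int = 30,
    hidden_dim: int = 256,
    epochs: int = EPOCHS_DEFAULT,
    lr: float = LR_DEFAULT,
    lam: float = LAMBDA_DEFAULT,
    margin: float = MARGIN_DEFAULT,
    per_anchor: int = PER_ANCHOR_DEFAULT,
    seed: int = 0,
    objective: str = "combined",  # or "reconstruction"
    tied_weights: bool = False,
):
    """Train both paths under the combined weighted loss.

    Returns ``(model, embedding, history)`` where ``history`` is the per-epoch
    list of LossBreakdown records. With ``objective="reconstruction"`` the
    supervision terms are never computed (their history entries are 0).
    """
    m = rna_X.shape[0]
    if protein_X.shape[0] != m or tg.n_cells != m or pg.n_cells != m:
        raise ValueError("inputs must cover the same cells")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    ss = np.random.SeedSequence(seed)
    rng_t, rng_p, rng_trip = (np.random.default_rng(s) for s in ss.spawn(3))

    cfg_t = GateConfig(rna_X.shape[1], hidden_dim, embedding_dim, tied_weights=tied_weights)
    cfg_p = GateConfig(protein_X.shape[1], hidden_dim, embedding_dim, tied_weights=tied_weights)
    path_t = init_path(cfg_t, rng_t)
    path_p = init_path(cfg_p, rng_p)
    ei_t, ei_p = EdgeIndex(tg), EdgeIndex(pg)

    params_t = _collect(path_t)
    params_p = _collect(path_p)
    opt = Adam(params_t + params_p, lr=lr)
    use_super = objective == "combined"
    d_t = embedding_dim

    history: list[LossBreakdown] = []
    for epoch in range(epochs):
        T_emb, recon_t, caches_t = path_forward(rna_X, ei_t, path_t)
        P_emb, recon_p, caches_p = path_forward(protein_X, ei_p, path_p)
        je = concat_embeddings(T_emb, P_emb)

        l_rt = mse_reconstruction_loss(rna_X, recon_t)
        l_rp = mse_reconstruction_loss(protein_X, recon_p)
        d_recon_t = 2.0 * (recon_t - rna_X) / rna_X.size
        d_recon_p = 2.0 * (recon_p - protein_X) / protein_X.size

        l_st = l_sp = 0.0
        dZ = np.zeros_like(je.Z)
        if use_super:
            trip_t = sample_triplets(tg, t_labels, per_anchor, rng=rng_trip, margin=margin)
            trip_p = sample_triplets(pg, p_labels, per_anchor, rng=rng_trip, margin=margin)
            l_st, dZ_t = triplet_loss_grad(je.Z, trip_t)
            l_sp, dZ_p = triplet_loss_grad(je.Z, trip_p)
            if lam != 0.0:
                dZ = lam * (dZ_t + dZ_p)

        comp = LossBreakdown(l_rt, l_rp, l_st, l_sp, lam)
        total = comp.total
        if not np.isfinite(total):
            raise FloatingPointError(f"training diverged at epoch {epoch}: loss={total}")
        history.append(comp)
        logger.debug(
            "epoch %d: L=%.6f recon=(%.6f, %.6f) super=(%.6f, %.6f)",
            epoch, total, l_rt, l_rp, l_st, l_sp,
        )

        grads_t = path_backward(d_recon_t, dZ[:, :d_t], caches_t)
        grads_p = path_backward(d_recon_p, dZ[:, d_t:], caches_p)
        _, gt = _collect(path_t, grads_t)
        _, gp = _collect(path_p, grads_p)
        opt.step(gt + gp)

    T_emb, _ = encode(rna_X, ei_t, path_t)
    P_emb, _ = encode(protein_X, ei_p, path_p)
    model = DualGateModel(rna=path_t, protein=path_p)
    return model, concat_embeddings(T_emb, P_emb), history
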