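"""End-to-end orchestration: read -> preprocess -> graphs -> fit -> evaluate.

Single-cell and spatial inputs share one pipeline; the mode is detected from
the presence of a finite coordinate table unless set explicitly. Every run
writes a manifest recording all resolved hyperparameters so it can be
reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import graph as gr
from . import preprocess as pp
from . import train as tr
from .preprocess import OmicsMatrix

logger = logging.getLogger("duogate")


@dataclass
class RunConfig:
    """All resolved settings of one integration run."""

    rna_path: str | None = None
    protein_path: str | None = None
    coords_path: str | None = None
    truth_path: str | None = None
    mode: str = "auto"  # single_cell | spatial | auto
    target_sum: float = pp.TARGET_SUM_DEFAULT
    n_hvg: int = pp.N_HVG_DEFAULT
    pca_components: int = pp.PCA_COMPONENTS_DEFAULT
    n_neighbors: int = gr.N_NEIGHBORS_DEFAULT
    prune_resolution: float = gr.PRUNE_RESOLUTION_DEFAULT
    spatial_prune: str = "expression"
    symmetrize: bool = False
    embedding_dim: int = 30
    hidden_dim: int = 256
    epochs: int = tr.EPOCHS_DEFAULT
    lr: float = tr.LR_DEFAULT
    lam: float = tr.LAMBDA_DEFAULT
    margin: float = tr.MARGIN_DEFAULT
    per_anchor: int = tr.PER_ANCHOR_DEFAULT
    noise_level: float = 0.0  # percent Gaussian noise on the normalized inputs
    resolutions: tuple = ev.RESOLUTIONS_DEFAULT
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "resolutions" in data:
            data["resolutions"] = tuple(data["resolutions"])
        return cls(**data)

    def manifest(self) -> dict:
        d = asdict(self)
        d["resolutions"] = [float(r) for r in self.resolutions]
        d["noise_definition"] = "additive N(0, (level/100 * feature_sd)^2) on normalized matrices"
        return d


def detect_mode(coords: np.ndarray | None) -> str:
    """spatial iff a finite cells x 2 coordinate table is present."""
    if coords is None:
        return "single_cell"
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2 or not np.all(np.isfinite(coords)):
        raise ValueError(
            "coordinate table is present but malformed (needs finite cells x 2); "
            "pass mode explicitly to override"
        )
    return "spatial"


def run_arrays(
    rna: OmicsMatrix,
    protein: OmicsMatrix,
    coords: np.ndarray | None = None,
    truth=None,
    config: RunConfig | None = None,
) -> dict:
    """Run the full integration on in-memory raw count matrices.

    Returns a dict with the joint embedding, the trained model, loss history,
    resolved mode, and (when ``truth`` is given) the metrics report.
    """
    cfg = config or RunConfig()
    mode = cfg.mode if cfg.mode != "auto" else detect_mode(coords)
    if mode == "spatial" and coords is None:
        raise ValueError("spatial mode requires coordinates")
    logger.info("mode resolved to %s", mode)

    rna, protein, kept = pp.filter_paired_cells(rna, protein)
    if coords is not None:
        coords = np.asarray(coords, dtype=np.float64)[kept]
    if truth is not None:
        truth = np.asarray(truth)[kept]

    rna_norm = pp.normalize_rna(rna, target_sum=cfg.target_sum)
    rna_hvg = pp.select_hvg(rna_norm, n_top=cfg.n_hvg)
    prot_norm = pp.clr_protein(protein)
    if cfg.noise_level > 0:
        rna_hvg = ev.add_gaussian_noise(rna_hvg, cfg.noise_level, seed=cfg.seed + 101)
        prot_norm = ev.add_gaussian_noise(prot_norm, cfg.noise_level, seed=cfg.seed + 202)
    rna_red = pp.pca_reduce(rna_hvg, n_components=cfg.pca_components)

    if mode == "single_cell":
        tg, pg, tl, pl = gr.build_graphs_single_cell(
            rna_red.values, prot_norm.values,
            n=cfg.n_neighbors, resolution=cfg.prune_resolution, seed=cfg.seed,
        )
    else:
        tg, pg, tl, pl = gr.build_graphs_spatial(
            coords, rna_red.values, prot_norm.values,
            n=cfg.n_neighbors, resolution=cfg.prune_resolution, seed=cfg.seed,
            prune=cfg.spatial_prune,
        )
    if cfg.symmetrize:
        tg, pg = gr.symmetrize(tg), gr.symmetrize(pg)

    model, embedding, history = tr.fit(
        rna_hvg.values, prot_norm.values, tg, pg, tl, pl,
        embedding_dim=cfg.embedding_dim, hidden_dim=cfg.hidden_dim,
        epochs=cfg.epochs, lr=cfg.lr, lam=cfg.lam, margin=cfg.margin,
        per_anchor=cfg.per_anchor, seed=cfg.seed,
    )

    result = dict(
        mode=mode,
        embedding=embedding,
        model=model,
        history=history,
        graphs=(tg, pg),
        labels=(tl, pl),
        cell_ids=rna_hvg.cell_ids,
        truth=truth,
        coords=coords,
        config=cfg,
    )
    if truth is not None:
        result["report"] = ev.sweep_and_report(
            embedding.Z, truth, resolutions=cfg.resolutions, seed=cfg.seed,
            n_neighbors=cfg.n_neighbors,
        )
    return result


def _load_coords(path: str) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64)


def run(config: RunConfig) -> str:
    """File-based entry point; writes all artifacts to ``config.outdir``."""
    if config.rna_path is None or config.protein_path is None:
        raise ValueError("rna_path and protein_path are required")
    outdir = config.outdir or "duogate_run"
    os.makedirs(outdir, exist_ok=True)
    rna = pp.read_matrix(config.rna_path, "rna")
    protein = pp.read_matrix(config.protein_path, "protein")
    coords = _load_coords(config.coords_path) if config.coords_path else None
    truth = None
    if config.truth_path:
        tdf = pd.read_csv(config.truth_path)
        truth = tdf["label"].to_numpy() if "label" in tdf.columns else tdf.iloc[:, -1].to_numpy()

    res = run_arrays(rna, protein, coords=coords, truth=truth, config=config)

    emb = res["embedding"]
    ids = res["cell_ids"]
    zcols = [f"T{i}" for i in range(emb.T_emb.shape[1])] + [f"P{i}" for i in range(emb.P_emb.shape[1])]
    pd.DataFrame(emb.Z, index=ids, columns=zcols).to_csv(os.path.join(outdir, "Z.csv"))
    try:
        import anndata as ad

        adata = ad.AnnData(X=emb.Z, obs=pd.DataFrame(index=pd.Index(ids.astype(str))))
        adata.obsm["T_emb"] = emb.T_emb
        adata.obsm["P_emb"] = emb.P_emb
        adata.write_h5ad(os.path.join(outdir, "embedding.h5ad"))
    except Exception as exc:  # pragma: no cover - io convenience only
        logger.warning("could not write embedding.h5ad: %s", exc)
    hist = pd.DataFrame(
        [
            dict(epoch=i, total=h.total, recon_t=h.recon_t, recon_p=h.recon_p,
                 super_t=h.super_t, super_p=h.super_p)
            for i, h in enumerate(res["history"])
        ]
    )
    hist.to_csv(os.path.join(outdir, "loss_history.csv"), index=False)
    res["model"].save(os.path.join(outdir, "checkpoint.npz"), os.path.join(outdir, "checkpoint.json"))

    labels_df = pd.DataFrame(index=pd.Index(ids, name="cell"))
    for r in config.resolutions:
        pred = ev.cluster_embedding(emb.Z, resolution=float(r), seed=config.seed,
                                    n_neighbors=config.n_neighbors)
        labels_df[f"leiden_{r}"] = pred.labels
    labels_df.to_csv(os.path.join(outdir, "cluster_labels.csv"))
    if "report" in res:
        res["report"].to_csv(os.path.join(outdir, "metrics.csv"))

    manifest = config.manifest()
    manifest["mode_resolved"] = res["mode"]
    manifest["n_cells"] = int(len(ids))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run complete: %s", outdir)
    return outdir
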