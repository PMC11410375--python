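"""Per-modality normalization and dimensionality reduction.

RNA counts are depth-scaled to a common total and log1p-transformed, then
restricted to highly variable genes. Protein (ADT) counts get the Seurat-style
centered log-ratio transform across features within each cell. A PCA projection
of the normalized RNA matrix is used downstream only for neighbor search, never
as the auto-encoder input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("duogate")

TARGET_SUM_DEFAULT = 10_000.0
N_HVG_DEFAULT = 2_000
PCA_COMPONENTS_DEFAULT = 200


@dataclass
class OmicsMatrix:
    """Cells x features matrix for one modality with its processing state.

    ``values`` is always a dense float64 array; ``modality`` is ``"rna"`` or
    ``"protein"``; ``state`` tracks the pipeline stage (``raw`` counts,
    ``normalized`` expression, or a ``reduced`` projection).
    """

    values: np.ndarray
    modality: str
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x features matrix")
        self.cell_ids = np.asarray(self.cell_ids)
        self.feature_ids = np.asarray(self.feature_ids)
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match number of rows")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length does not match number of columns")
        if len(set(self.cell_ids.tolist())) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if len(set(self.feature_ids.tolist())) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.modality not in ("rna", "protein"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.state == "raw":
            if not np.all(np.isfinite(self.values)):
                raise ValueError("raw values must be finite")
            if np.any(self.values < 0):
                raise ValueError("raw values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_idx) -> "OmicsMatrix":
        return replace(
            self,
            values=self.values[mask_or_idx],
            cell_ids=self.cell_ids[mask_or_idx],
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell")),
            var=pd.DataFrame(index=pd.Index(self.feature_ids.astype(str), name="feature")),
        )
        adata.uns["modality"] = self.modality
        adata.uns["state"] = self.state
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, modality: str, state: str = "raw") -> "OmicsMatrix":
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        return cls(
            values=np.asarray(X, dtype=np.float64),
            modality=modality,
            cell_ids=adata.obs_names.to_numpy(),
            feature_ids=adata.var_names.to_numpy(),
            state=state,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str, modality: str, state: str = "raw") -> OmicsMatrix:
    """Read a cells x features matrix from h5ad, MTX(+TSV sidecars) or CSV/TSV.

    CSV/TSV files carry cells in rows with an index column of cell ids and a
    header of feature ids. For MTX, ``<stem>_barcodes.tsv`` and
    ``<stem>_features.tsv`` sidecars next to the matrix supply the ids.
    """
    path = str(path)
    if path.endswith(".h5ad"):
        return OmicsMatrix.from_anndata(ad.read_h5ad(path), modality=modality, state=state)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        X = np.asarray(sp.csr_matrix(mmread(path)).todense())
        stem = path[: -len(".mtx")]
        cells = pd.read_csv(stem + "_barcodes.tsv", sep="\t", header=None)[0].to_numpy()
        feats = pd.read_csv(stem + "_features.tsv", sep="\t", header=None)[0].to_numpy()
        return OmicsMatrix(X, modality, cells, feats, state=state)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return OmicsMatrix(
        df.to_numpy(dtype=np.float64),
        modality,
        df.index.to_numpy(),
        df.columns.to_numpy(),
        state=state,
    )


def write_matrix(mat: OmicsMatrix, path: str) -> None:
    """Write to h5ad or CSV depending on the file extension."""
    path = str(path)
    if path.endswith(".h5ad"):
        mat.to_anndata().write_h5ad(path)
    else:
        pd.DataFrame(mat.values, index=mat.cell_ids, columns=mat.feature_ids).to_csv(path)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def filter_paired_cells(rna: OmicsMatrix, protein: OmicsMatrix):
    """Drop cells with zero total counts in either modality from both.

    Keeps the two matrices paired cell-for-cell; returns the filtered pair and
    the integer indices of the kept cells.
    """
    if not np.array_equal(rna.cell_ids, protein.cell_ids):
        raise ValueError("modalities must share identical cell_ids in identical order")
    keep = (rna.values.sum(axis=1) > 0) & (protein.values.sum(axis=1) > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d cell(s) with zero total counts in a modality", dropped)
    idx = np.flatnonzero(keep)
    return rna.subset_cells(idx), protein.subset_cells(idx), idx


def normalize_rna(counts: OmicsMatrix, target_sum: float = TARGET_SUM_DEFAULT) -> OmicsMatrix:
    """Depth-scale each cell to ``target_sum`` total counts, then log1p.

    Cells with zero total counts are dropped (logged), never divided by zero.
    """
    if counts.modality != "rna" or counts.state != "raw":
        raise ValueError("normalize_rna expects raw RNA counts")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = counts.values.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("all cells have zero total counts")
    if not keep.all():
        logger.warning("normalize_rna: dropping %d zero-count cell(s)", int((~keep).sum()))
        counts = counts.subset_cells(np.flatnonzero(keep))
        totals = totals[keep]
    scaled = counts.values * (target_sum / totals[:, None])
    return replace(counts, values=np.log1p(scaled), state="normalized")


def normalized_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-flavor dispersion of log-normalized data, z-scored in mean bins.

    Mean and dispersion (variance/mean) are computed on the linear (expm1)
    scale; features are grouped into quantile bins of mean expression and the
    dispersion is standardized within each bin. Bins collapse gracefully when
    features are few or means tie; zero-variance features score -inf so they
    can never outrank a variable feature.
    """
    Y = np.expm1(values)
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1) if Y.shape[0] > 1 else np.zeros(Y.shape[1])
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    # aim for >= 10 features per bin so the within-bin z-score is meaningful
    n_bins = max(1, min(n_bins, len(mean) // 10))
    edges = np.unique(np.quantile(mean, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(mean, edges)
    z = np.empty_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu = disp[sel].mean()
        sd = disp[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else disp[sel] - mu
    z[np.ptp(values, axis=0) == 0] = -np.inf  # constant features never selected
    return z


def select_hvg(norm: OmicsMatrix, n_top: int = N_HVG_DEFAULT) -> OmicsMatrix:
    """Keep the ``n_top`` genes with highest bin-standardized dispersion.

    Output preserves the original feature order restricted to the selection.
    """
    if n_top <= 0:
        raise ValueError("n_top must be a positive integer")
    if norm.state != "normalized":
        raise ValueError("select_hvg expects a normalized matrix")
    if n_top >= norm.n_features:
        return norm
    z = normalized_dispersion(norm.values)
    order = np.lexsort((np.arange(len(z)), -z))  # score desc, index asc on ties
    idx = np.sort(order[:n_top])
    return replace(norm, values=norm.values[:, idx], feature_ids=norm.feature_ids[idx])


def clr_protein(counts: OmicsMatrix) -> OmicsMatrix:
    """Seurat-style centered log-ratio across features within each cell.

    y_ij = log1p( x_ij / exp(mean_j log1p(x_ij)) ).
    """
    if counts.modality != "protein" or counts.state != "raw":
        raise ValueError("clr_protein expects raw protein counts")
    if np.any(counts.values < 0):
        raise ValueError("protein counts must be non-negative")
    logx = np.log1p(counts.values)
    geo = np.exp(logx.mean(axis=1, keepdims=True))
    return replace(counts, values=np.log1p(counts.values / geo), state="normalized")


def pca_reduce(norm: OmicsMatrix, n_components: int = PCA_COMPONENTS_DEFAULT) -> OmicsMatrix:
    """Project the column-centered matrix onto its top principal components.

    Components are ordered by non-increasing explained variance and sign-fixed
    so each component's largest-magnitude loading is positive, making the
    projection deterministic.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    X = norm.values
    if not np.all(np.isfinite(X)):
        raise ValueError("pca_reduce requires finite input")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        logger.warning("pca_reduce: clipping n_components from %d to %d", n_components, max_rank)
        n_components = max_rank
    Xc = X - X.mean(axis=0, keepdims=True)
    # full SVD keeps the projection exact and deterministic at desk scale
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_components].T  # features x k loadings
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    proj = Xc @ (V * signs)
    comp_ids = np.array([f"PC{i + 1}" for i in range(n_components)])
    return replace(norm, values=proj, feature_ids=comp_ids, state="reduced")
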