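"""Seeded generator of paired RNA + protein counts with known cluster structure.

Cells get a latent position: a cluster center plus unit Gaussian scatter in a
shared low-dimensional space. Modality-specific linear maps turn the latent
position into log-scale expected expression; RNA counts are drawn from a
negative binomial with a per-cell library size and Bernoulli dropout (sparse,
high-dimensional), protein counts from a Poisson with a high baseline (dense,
low-dimensional) — mimicking the CITE-seq RNA/ADT asymmetry. A spatial variant
places cells on a jittered grid with contiguous Voronoi label regions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .preprocess import OmicsMatrix


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults are the desk-scale study conditions."""

    m: int = 600            # cells
    k: int = 3              # clusters
    t: int = 200            # genes
    p: int = 30             # proteins
    separation: float = 3.0  # cluster-center scale relative to unit within-cluster sd
    latent_dim: int = 10
    dispersion: float = 0.5  # NB: var = mu + dispersion * mu^2
    dropout: float = 0.3     # RNA Bernoulli zeroing rate
    lib_range: tuple = (1000, 5000)
    protein_mean: float = 30.0
    grid: tuple | None = None  # (nx, ny) for spatial mode
    jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.m >= self.k >= 1):
            raise ValueError("need m >= k >= 1")
        if not (self.t >= self.p >= 1):
            raise ValueError("need t >= p >= 1")
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be a probability")
        if self.dispersion < 0 or self.separation < 0:
            raise ValueError("dispersion and separation must be non-negative")
        if self.grid is not None and self.grid[0] * self.grid[1] < self.m:
            raise ValueError("grid does not cover all cells")


@dataclass
class SyntheticDataset:
    """Paired counts, ground-truth labels and (in spatial mode) coordinates."""

    rna: OmicsMatrix
    protein: OmicsMatrix
    labels: np.ndarray
    latent_means: np.ndarray  # noiseless per-cell latent cluster means
    coords: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)

    def save(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.rna.to_anndata().write_h5ad(os.path.join(outdir, "rna.h5ad"))
        self.protein.to_anndata().write_h5ad(os.path.join(outdir, "protein.h5ad"))
        import pandas as pd

        pd.DataFrame({"cell": self.rna.cell_ids, "label": self.labels}).to_csv(
            os.path.join(outdir, "truth_labels.csv"), index=False
        )
        if self.coords is not None:
            pd.DataFrame(self.coords, columns=["x", "y"], index=self.rna.cell_ids).to_csv(
                os.path.join(outdir, "coords.csv")
            )
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _expression_given_labels(rng: np.random.Generator, labels: np.ndarray, spec: SyntheticSpec):
    """Draw paired counts conditioned on an existing label vector."""
    m, k, L = len(labels), spec.k, spec.latent_dim
    centers = rng.normal(0.0, spec.separation, size=(k, L))
    z = centers[labels] + rng.normal(0.0, 1.0, size=(m, L))
    scale = 1.0 / np.sqrt(spec.separation**2 + 1.0)  # unit log-sd across cells

    # RNA: multinomial-style rates via softmax, NB sampling, then dropout
    A = rng.normal(0.0, 1.0, size=(L, spec.t)) / np.sqrt(L)
    base_g = rng.normal(0.0, 0.5, size=spec.t)
    logit = base_g + (z @ A) * scale
    logit -= logit.max(axis=1, keepdims=True)
    probs = np.exp(logit)
    probs /= probs.sum(axis=1, keepdims=True)
    libs = rng.integers(spec.lib_range[0], spec.lib_range[1] + 1, size=m)
    mu = libs[:, None] * probs
    if spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        rna = rng.negative_binomial(r, r / (r + mu)).astype(np.float64)
    else:
        rna = rng.poisson(mu).astype(np.float64)
    if spec.dropout > 0:
        rna[rng.random(size=rna.shape) < spec.dropout] = 0.0

    # protein: dense Poisson ADT-like counts with a high baseline
    Bm = rng.normal(0.0, 1.0, size=(L, spec.p)) / np.sqrt(L)
    base_p = rng.normal(np.log(spec.protein_mean), 0.3, size=spec.p)
    mu_p = np.exp(base_p + 0.8 * (z @ Bm) * scale)
    protein = rng.poisson(mu_p).astype(np.float64)

    cell_ids = np.array([f"cell_{i:05d}" for i in range(m)])
    gene_ids = np.array([f"gene_{j:04d}" for j in range(spec.t)])
    prot_ids = np.array([f"adt_{j:03d}" for j in range(spec.p)])
    rna_m = OmicsMatrix(rna, "rna", cell_ids, gene_ids, state="raw")
    prot_m = OmicsMatrix(protein, "protein", cell_ids, prot_ids, state="raw")
    return rna_m, prot_m, centers[labels]


def generate_paired(spec: SyntheticSpec) -> SyntheticDataset:
    """Paired single-cell dataset with balanced clusters; bitwise-deterministic."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.permutation(np.arange(spec.m) % spec.k)
    rna, protein, latent = _expression_given_labels(rng, labels, spec)
    manifest = {"generator": "generate_paired", **_manifest_fields(spec)}
    return SyntheticDataset(rna, protein, labels, latent, manifest=manifest)


def generate_spatial(spec: SyntheticSpec) -> SyntheticDataset:
    """Spatial dataset: jittered grid, contiguous Voronoi label regions.

    Cells occupy the first m grid positions in row-major order; labels are the
    nearest of k region seeds (on the unjittered lattice), re-drawn until all
    regions are populated.
    """
    if spec.grid is None:
        raise ValueError("spatial mode requires grid dimensions")
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.grid
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel()]).astype(np.float64)[: spec.m]
    for _ in range(100):
        seeds = rng.uniform([0, 0], [nx - 1, ny - 1], size=(spec.k, 2))
        d2 = ((lattice[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        if len(np.unique(labels)) == spec.k:
            break
    else:
        raise RuntimeError("could not draw k non-empty Voronoi regions")
    coords = lattice + rng.uniform(-spec.jitter, spec.jitter, size=lattice.shape)
    rna, protein, latent = _expression_given_labels(rng, labels, spec)
    manifest = {"generator": "generate_spatial", **_manifest_fields(spec)}
    return SyntheticDataset(rna, protein, labels, latent, coords=coords, manifest=manifest)


def _manifest_fields(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["lib_range"] = list(d["lib_range"])
    if d["grid"] is not None:
        d["grid"] = list(d["grid"])
    return d
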