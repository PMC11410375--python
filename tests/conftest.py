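import numpy as np
import pytest

from duogate import (
    RunConfig,
    SyntheticSpec,
    generate_paired,
    generate_spatial,
)
from duogate import graph as gr
from duogate import preprocess as pp

SMALL_SPEC = SyntheticSpec(m=200, k=3, t=150, p=20, seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_paired(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_spatial_dataset():
    return generate_spatial(SyntheticSpec(m=200, k=3, t=150, p=20, seed=43, grid=(20, 10)))


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    """Preprocessed matrices and graphs for the small paired fixture."""
    ds = small_dataset
    rna_norm = pp.normalize_rna(ds.rna)
    rna_hvg = pp.select_hvg(rna_norm, 2000)
    prot_norm = pp.clr_protein(ds.protein)
    rna_red = pp.pca_reduce(rna_hvg, 200)
    tg, pg, tl, pl = gr.build_graphs_single_cell(
        rna_red.values, prot_norm.values, n=10, resolution=1.0, seed=42
    )
    return dict(
        ds=ds, rna=rna_hvg, protein=prot_norm, reduced=rna_red,
        tg=tg, pg=pg, tl=tl, pl=pl,
    )
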