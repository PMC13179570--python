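"""Shared fixtures: small synthetic datasets and a trained classifier.

Expensive objects are session-scoped; every dataset is generated
programmatically with fixed seeds so the suite needs no files on disk.
"""

import numpy as np
import pandas as pd
import pytest

import probcell as pc


@pytest.fixture(scope="session")
def small_ref():
    """Annotated five-type reference, one shallow neutrophil-like type."""
    cfg = pc.default_reference_config(seed=11, n_cells_per_type=150, n_genes=2000)
    m, ann = pc.simulate_reference(cfg)
    return cfg, m, ann


@pytest.fixture(scope="session")
def small_model(small_ref):
    """Classifier trained on the small reference with a 200-gene panel."""
    _, m, ann = small_ref
    ts = pc.make_debris_training(m, ann, pc.DebrisFactor(20.0, seed=0), panel_size=200)
    return pc.train_classifier(ts, lambda_reg=1.0)


@pytest.fixture(scope="session")
def trajectory_data():
    """Differentiation continuum: 500 cells, 300 genes, 30 up / 30 down."""
    cfg = pc.TrajectoryConfig(
        n_cells=500, n_genes=300,
        monotone_up_genes=list(range(30)),
        monotone_down_genes=list(range(30, 60)),
        effect_size=2.0, seed=3,
    )
    m, t = pc.simulate_trajectory(cfg)
    nm = pc.normalize_mean_scaling(m)
    return cfg, m, t, nm


@pytest.fixture(scope="session")
def fitted_curve(trajectory_data):
    """Principal curve on the SVD embedding of the trajectory continuum,
    oriented by a monotone-down gene as the "young" anchor."""
    cfg, m, t, nm = trajectory_data
    rs = pc.reduce_svd(nm, d=10)
    emb = pc.embed_2d(rs, "svd2")
    curve = pc.fit_principal_curve(emb, cell_ids=m.barcode_ids)
    anchor_gene = f"gene{cfg.monotone_down_genes[0]:04d}"
    anchor = nm.values[nm.gene_ids.index(anchor_gene)]
    return pc.orient_curve(curve, anchor, anchor_gene)


def tiny_matrix(values, genes=None, barcodes=None, **kw):
    """Dense array -> CountMatrix helper for hand-computed examples."""
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    barcodes = barcodes or [f"b{j}" for j in range(values.shape[1])]
    return pc.CountMatrix(gene_ids=genes, barcode_ids=barcodes, counts=values, **kw)


@pytest.fixture
def tiny():
    return tiny_matrix
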