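"""Shared fixtures: toy layouts and a session-scoped synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spatialtme import coloc, spatial_io, synthgen


def make_cells(xs, types, ys=None, fov="F1", region="T"):
    """One-FOV cell table from coordinate/type lists."""
    xs = np.asarray(xs, dtype=float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, dtype=float)
    fovs = [fov] * len(xs) if isinstance(fov, str) else list(fov)
    regions = [region] * len(xs) if isinstance(region, str) else list(region)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(xs))],
            "x_um": xs,
            "y_um": ys,
            "fov_id": fovs,
            "core_id": [f"core_{f}" for f in fovs],
            "patient_id": "P1",
            "region": regions,
            "cell_type": list(types),
        }
    )


def make_matrix(cells, counts, genes=None):
    counts = np.asarray(counts)
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    return spatial_io.ExpressionMatrix(
        genes=np.array(genes, dtype=object),
        cells=cells["cell_id"].to_numpy(dtype=object),
        counts=sp.csr_matrix(counts),
    )


def csr_fov(n=2000, p_a=0.3, fov="F1", seed=0, size=510.0):
    """Complete-spatial-randomness FOV with i.i.d. binary type labels."""
    rng = np.random.default_rng(seed)
    types = np.where(rng.uniform(size=n) < p_a, "A", "B")
    return make_cells(
        rng.uniform(0, size, n), types, ys=rng.uniform(0, size, n), fov=fov
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seed 1), generated once per session."""
    return synthgen.generate_cohort(synthgen.default_config(seed=1))


@pytest.fixture(scope="session")
def cohort_graph50(default_cohort):
    return coloc.build_knn(default_cohort.cells, k=50)


def de_calibration_inputs(n_recv=1000, n_program=30, log2_effect=1.0, seed=0):
    """Grid of receiver cells, half with a sender 10 um away, plus a
    1000-gene panel carrying a planted low-baseline response program."""
    rows = []
    for i in range(n_recv):
        x, y = (i % 40) * 120.0, (i // 40) * 120.0
        rows.append((f"r{i}", x, y, "F1", "C1", "P1", "T", "mCAF"))
        if i % 2 == 0:
            rows.append((f"s{i}", x + 10.0, y, "F1", "C1", "P1", "T", "Capillary"))
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "x_um", "y_um", "fov_id", "core_id", "patient_id",
                 "region", "cell_type"],
    )
    program = tuple(f"PRG{i:03d}" for i in range(n_program))
    gene_model = synthgen.GeneModel(
        n_genes=1000,
        signatures={"mCAF": [], "Capillary": []},
        base_mean=0.8,
        total_target=800.0,
        extra_genes=("DLL4",) + program,
        gene_means={g: 0.4 for g in program},
    )
    coupling = synthgen.CouplingSpec(
        ligand="DLL4", sender="Capillary", receptor_program=program,
        receiver="mCAF", radius_um=30.0, log2_effect=log2_effect,
    )
    matrix, planted, proximal = synthgen.sample_expression(
        cells, gene_model, coupling, np.random.default_rng(seed)
    )
    return cells, matrix, planted, proximal
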