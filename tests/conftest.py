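import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ecaxis

#: Small but fully structured world shared by the unit tests.
SMALL = dict(
    n_genes=700,
    cells_per_sample=250,
    n_global_de=60,
    n_popspecific_de=20,
    n_sectional_de=6,
    n_zonation_arterial=30,
    n_zonation_venous=30,
    n_zonation_junction=10,
    n_program_genes=15,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    params = ecaxis.SimulationParams(**SMALL)
    matrix, ann, truth = ecaxis.simulate_experiment(params)
    return matrix, ann, truth


@pytest.fixture(scope="session")
def small_pre(small_sim):
    matrix, ann, _ = small_sim
    return ecaxis.preprocess(matrix, ann)


@pytest.fixture(scope="session")
def small_truth_ann(small_sim, small_pre):
    """Annotation carrying the TRUE populations (generator contract)."""
    _, _, truth = small_sim
    ann = small_pre.ann.copy()
    pops = truth.cell_truth.set_index("cell_id")["true_population"]
    ann["population"] = pops.loc[ann["cell_id"]].to_numpy()
    return ann


@pytest.fixture(scope="session")
def null_run():
    """Default-scale world with no condition effects and no batch variation,
    QC-filtered and normalized, with true populations in the annotation."""
    params = ecaxis.SimulationParams.null(seed=101)
    matrix, ann, truth = ecaxis.simulate_experiment(params)
    qc = ecaxis.compute_qc(matrix, "mt-",
                           sample_ids=ann["sample_id"].to_numpy())
    keep = ecaxis.filter_cells(qc)
    ann = ann.copy()
    ann["qc_pass"] = ann["cell_id"].isin(keep)
    pops = truth.cell_truth.set_index("cell_id")["true_population"]
    ann["population"] = pops.loc[ann["cell_id"]].to_numpy()
    norm = ecaxis.normalize(matrix.subset_cells(keep))
    return matrix, ann, truth, norm


def make_matrix(dense, genes=None, cells=None) -> ecaxis.ExpressionMatrix:
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{i}" for i in range(dense.shape[1])]
    return ecaxis.ExpressionMatrix(sp.csr_matrix(dense), np.array(genes,
                                   dtype=object), np.array(cells, dtype=object))


def make_norm(dense, genes=None, cells=None,
              scale=1e4) -> ecaxis.NormalizedMatrix:
    """Wrap an already-normalized dense array."""
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{i}" for i in range(dense.shape[1])]
    return ecaxis.NormalizedMatrix(
        sp.csr_matrix(dense), np.array(genes, dtype=object),
        np.array(cells, dtype=object), np.ones(dense.shape[1]), scale)


def make_ann(cell_ids, sample_ids, conditions, populations=None,
             reporter=None) -> pd.DataFrame:
    ann = ecaxis.new_annotation(cell_ids, sample_ids, conditions, reporter)
    if populations is not None:
        ann["population"] = populations
    return ann
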