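import numpy as np
import pytest
import scipy.sparse as sp

from bigsur.counts import CountMatrix, GeneFilterConfig, filter_genes
from bigsur.residuals import expected_values
from bigsur.simulate import SimDesign, simulate_null


def make_counts(array, gene_ids=None, cell_ids=None) -> CountMatrix:
    array = np.asarray(array)
    n_genes, n_cells = array.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(n_cells)]
    return CountMatrix(sp.csr_matrix(array), np.array(gene_ids, dtype=object),
                       np.array(cell_ids, dtype=object))


@pytest.fixture
def toy_counts():
    """2 genes x 3 cells with distinct margins."""
    return make_counts([[3, 1, 0], [2, 2, 1]])


@pytest.fixture(scope="session")
def reference_null_runs():
    """Filtered reference null simulations (1000 x 999, c=0.5, depth CV
    0.75) with their expected-value matrices, for seeds 1-3.  Shared by the
    calibration-heavy tests to avoid recomputation."""
    runs = {}
    for seed in (1, 2, 3):
        m = filter_genes(
            simulate_null(SimDesign(seed=seed)),
            GeneFilterConfig(min_cells_expressed=1),
        )
        runs[seed] = (m, expected_values(m))
    return runs
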