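"""Scikit-learn style estimators over the analytic machinery.

These classes follow sklearn conventions — ``fit``/``transform``,
``get_params``/``set_params``, fitted attributes with trailing
underscores, input as a cells x features (genes) matrix — so they compose
with sklearn pipelines and model selection.  They are thin stateful
shells; the statistics live in :mod:`bigsur.residuals`,
:mod:`bigsur.correlations` and :mod:`bigsur.communities`.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import communities as comm
from . import correlations as corr
from . import residuals as res
from .counts import CountMatrix
from .exceptions import ValidationError

__all__ = [
    "BigSurResiduals",
    "FanoFeatureSelector",
    "CorrelationNetwork",
    "WalktrapCommunities",
]


def _as_count_matrix(X) -> CountMatrix:
    """Cells x genes input (sklearn orientation) -> internal CountMatrix."""
    X = check_array(X, accept_sparse="csr", dtype=None)
    if sp.issparse(X):
        counts = X.T.tocsr()
    else:
        counts = sp.csr_matrix(np.asarray(X).T)
    n_genes, n_cells = counts.shape
    gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    return CountMatrix(counts, gene_ids, cell_ids)


class BigSurResiduals(TransformerMixin, BaseEstimator):
    """Transform raw UMI counts to modified corrected Pearson residuals.

    Parameters
    ----------
    c : float or "auto"
        Gene-noise coefficient of variation.  "auto" estimates a global c
        from the phi'-versus-mean trend on the fitted data.
    c_grid : array-like, optional
        Candidate grid for the "auto" estimate.
    """

    def __init__(self, c="auto", c_grid=None):
        self.c = c
        self.c_grid = c_grid

    def fit(self, X, y=None):
        m = _as_count_matrix(X)
        mu = res.expected_values(m)
        if self.c == "auto":
            grid = res.DEFAULT_C_GRID if self.c_grid is None else self.c_grid
            self.c_ = res.estimate_c(m, mu, grid)
        else:
            self.c_ = float(self.c)
        self.n_features_in_ = m.n_genes
        return self

    def transform(self, X):
        check_is_fitted(self, "c_")
        m = _as_count_matrix(X)
        if m.n_genes != self.n_features_in_:
            raise ValidationError("gene dimension changed between fit and transform")
        mu = res.expected_values(m)
        return res.modified_residuals(m, mu, self.c_).residuals.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class FanoFeatureSelector(BaseEstimator):
    """Select significantly variable genes by the phi' test.

    After ``fit``, exposes per-gene ``phi_prime_``, ``pvalues_`` and
    ``qvalues_``; ``get_support()`` masks genes significant at the
    configured BH FDR (the principled replacement for ad hoc
    highly-variable-gene cutoffs).
    """

    def __init__(self, c="auto", alpha=0.05, moments_order=5):
        self.c = c
        self.alpha = alpha
        self.moments_order = moments_order

    def fit(self, X, y=None):
        m = _as_count_matrix(X)
        mu = res.expected_values(m)
        c = res.estimate_c(m, mu) if self.c == "auto" else float(self.c)
        result = res.fano_pvalues(m, mu, c, moments_order=self.moments_order)
        self.c_ = c
        self.phi_prime_ = result.phi_prime
        self.pvalues_ = result.p_value
        self.qvalues_ = result.q_value
        self.n_features_in_ = m.n_genes
        return self

    def get_support(self):
        check_is_fitted(self, "qvalues_")
        return self.qvalues_ < self.alpha

    def transform(self, X):
        check_is_fitted(self, "qvalues_")
        X = check_array(X, accept_sparse="csr", dtype=None)
        return X[:, self.get_support()]


class CorrelationNetwork(BaseEstimator):
    """Score all gene pairs for significant correlation (PCC').

    Fitted attributes: ``results_`` (DataFrame over all pairs),
    ``edges_`` (significant signed equivalent-PCC edge list) and ``c_``.
    """

    def __init__(self, c="auto", fdr=corr.DEFAULT_FDR, moments_order=5, fast_fisher=False):
        self.c = c
        self.fdr = fdr
        self.moments_order = moments_order
        self.fast_fisher = fast_fisher

    def fit(self, X, y=None):
        m = _as_count_matrix(X)
        mu = res.expected_values(m)
        c = res.estimate_c(m, mu) if self.c == "auto" else float(self.c)
        self.c_ = c
        self.results_ = corr.correlation_pvalues(
            m, mu, c,
            fdr=self.fdr,
            moments_order=self.moments_order,
            fast_fisher=self.fast_fisher,
        )
        self.edges_ = corr.significant_edges(self.results_, self.fdr)
        self.n_features_in_ = m.n_genes
        return self


class WalktrapCommunities(ClusterMixin, BaseEstimator):
    """Cluster genes into communities from a signed adjacency matrix.

    ``fit(X)`` expects a square signed adjacency (genes x genes; zero =
    no edge), runs walktrap on the sign-stripped view, separates
    anti-correlated blocks on positive edges, optionally refines, and
    stores ``labels_`` (-1 marks genes absent from the graph).
    """

    def __init__(
        self,
        steps=comm.DEFAULT_WALK_STEPS,
        split_negative=True,
        refine=True,
        merge_ratio_threshold=comm.DEFAULT_MERGE_RATIO,
        max_size=comm.DEFAULT_MAX_COMMUNITY_SIZE,
    ):
        self.steps = steps
        self.split_negative = split_negative
        self.refine = refine
        self.merge_ratio_threshold = merge_ratio_threshold
        self.max_size = max_size

    def fit(self, X, y=None):
        A = check_array(X, accept_sparse="csr")
        if A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        A = sp.coo_matrix(A)
        edges = [
            (int(i), int(j), float(w))
            for i, j, w in zip(A.row, A.col, A.data)
            if i < j and w != 0
        ]
        g = comm.build_graph(edges)
        cs = comm.walktrap_communities(g.unweighted_view(), steps=self.steps)
        if self.split_negative:
            cs = comm.split_by_sign(g, cs, steps=self.steps)
        if self.refine:
            cs = comm.refine_communities(
                g, cs,
                merge_ratio_threshold=self.merge_ratio_threshold,
                max_size=self.max_size,
                steps=self.steps,
            )
        self.communities_ = cs
        labels = np.full(A.shape[0], -1, dtype=int)
        for node, lab in cs.assignment.items():
            labels[node] = lab
        self.labels_ = labels
        return self
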