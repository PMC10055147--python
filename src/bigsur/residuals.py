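"""Corrected Pearson residuals, modified corrected Fano factors, and the
gene-noise coefficient of variation.

The depth-aware expected value for gene j in cell i is

    mu_ij = (cell i total UMI) * (gene j total UMI) / (grand total UMI)

and the modified corrected Pearson residual is

    P'_ij = (x_ij - mu_ij) / sqrt(mu_ij (1 + c_j^2 mu_ij))

where c_j is the coefficient of variation of biological gene-expression
noise (a single global scalar by default).  The modified corrected Fano
factor phi'_j = sum_i (P'_ij)^2 / (n - 1) has expectation ~1 under the
Poisson-log-normal null when c matches the data, at every expression
level; its analytic null distribution gives per-gene variability p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import theilslopes

from . import null_moments as nm
from .counts import CountMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualMatrix",
    "FanoResult",
    "expected_values",
    "modified_residuals",
    "modified_fano",
    "fano_null_cumulants",
    "fano_pvalues",
    "estimate_c",
    "DEFAULT_C",
    "DEFAULT_C_GRID",
]

DEFAULT_C = 0.5
DEFAULT_C_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 3)


@dataclass
class ResidualMatrix:
    """Modified corrected Pearson residuals (genes x cells) and the c used."""

    residuals: np.ndarray
    c_used: np.ndarray  # scalar array or per-gene vector

    @property
    def n_cells(self) -> int:
        return self.residuals.shape[1]

    @property
    def n_genes(self) -> int:
        return self.residuals.shape[0]


@dataclass
class FanoResult:
    """Per-gene variability statistics and significance."""

    gene_ids: np.ndarray
    mean: np.ndarray          # observed mean UMI per cell
    phi: np.ndarray           # uncorrected (c = 0) Fano factor, diagnostic
    phi_prime: np.ndarray
    p_value: np.ndarray       # upper tail
    q_value: np.ndarray       # BH across genes
    method_flag: np.ndarray   # per-gene tail method (see null_moments)


def expected_values(m: CountMatrix) -> np.ndarray:
    """Depth-aware expected counts mu (genes x cells, dense float64).

    Row sums equal gene totals and column sums equal cell totals (up to
    float rounding).  Requires every gene and cell total to be positive,
    which gene/cell filtering guarantees.
    """
    gene_tot = m.gene_totals().astype(float)
    cell_tot = m.cell_totals().astype(float)
    grand = gene_tot.sum()
    if grand <= 0:
        raise ValidationError("zero grand total UMI")
    if np.any(gene_tot == 0):
        raise ValidationError("gene with zero total UMI; filter genes first")
    if np.any(cell_tot == 0):
        raise ValidationError("cell with zero total UMI; filter cells first")
    return np.outer(gene_tot, cell_tot) / grand


def _c_column(c, n_genes: int) -> np.ndarray:
    """Validate c and shape it as a (genes, 1) column for broadcasting."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValidationError("c must be non-negative")
    if c_arr.ndim == 0:
        return np.full((n_genes, 1), float(c_arr))
    if c_arr.shape != (n_genes,):
        raise ValidationError(
            f"per-gene c has length {c_arr.shape}, expected ({n_genes},)"
        )
    return c_arr[:, None]


def modified_residuals(m: CountMatrix, mu: np.ndarray, c) -> ResidualMatrix:
    """Modified corrected Pearson residuals P'_ij.

    ``c`` may be a global scalar or a per-gene vector.  With c = 0 this is
    the depth-aware corrected Pearson residual.
    """
    x = m.to_dense().astype(float)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != x.shape:
        raise ValidationError(f"mu shape {mu.shape} != counts shape {x.shape}")
    if np.any(mu <= 0):
        j, i = np.unravel_index(int(np.argmax(mu <= 0)), mu.shape)
        raise ValidationError(
            f"mu is not positive for gene {m.gene_ids[j]!r}, cell {m.cell_ids[i]!r}"
        )
    cc = _c_column(c, m.n_genes)
    denom = np.sqrt(mu * (1.0 + cc**2 * mu))
    resid = (x - mu) / denom
    if not np.all(np.isfinite(resid)):
        raise ValidationError("non-finite residuals")
    return ResidualMatrix(residuals=resid, c_used=np.asarray(c, dtype=float))


def modified_fano(r: ResidualMatrix) -> np.ndarray:
    """phi'_j = sum_i (P'_ij)^2 / (n - 1) for every gene."""
    n = r.n_cells
    if n < 2:
        raise ValidationError("modified_fano requires at least 2 cells")
    return np.sum(r.residuals**2, axis=1) / (n - 1)


def fano_null_cumulants(m: CountMatrix, mu: np.ndarray, c, moments_order: int = 5) -> np.ndarray:
    """Null cumulants of the per-gene sum of squared residuals.

    Per-cell terms are independent, so cumulants add; returns an array of
    shape (moments_order, n_genes).
    """
    cc = _c_column(c, m.n_genes)
    raw = nm.squared_residual_raw_moment_arrays(mu, cc, moments_order)
    return nm.raw_moments_to_cumulants(raw).sum(axis=2)


def fano_pvalues(
    m: CountMatrix,
    mu: np.ndarray,
    c,
    moments_order: int = 5,
) -> FanoResult:
    """Upper-tail p-values of phi' under the Poisson-log-normal null.

    For each gene the null cumulants of sum_i (P'_ij)^2 are assembled from
    the analytic per-cell moments of squared residuals (cumulants of
    independent terms add), and the observed statistic is mapped to a tail
    probability by Cornish-Fisher inversion; genes where the inversion is
    inadmissible fall back to the Gaussian tail and are flagged.
    q-values are Benjamini-Hochberg across genes.
    """
    if moments_order < 4:
        raise ValidationError("moments_order must be >= 4")
    resid = modified_residuals(m, mu, c)
    n = resid.n_cells
    phi_prime = modified_fano(resid)
    phi = modified_fano(modified_residuals(m, mu, 0.0))
    stat = phi_prime * (n - 1)  # sum of squared residuals

    kappa = fano_null_cumulants(m, mu, c, moments_order)

    order5 = np.zeros(m.n_genes) if moments_order < 5 else kappa[4]
    p_upper, _p_lower, flags = nm.cornish_fisher_pvalue_arrays(
        stat, kappa[0], kappa[1], kappa[2], kappa[3], order5
    )
    from .correlations import bh_fdr  # local import: avoid cycle

    q = bh_fdr(p_upper)
    flag_names = np.array(["cornish_fisher", "gaussian_fallback", "gaussian_bound"])
    return FanoResult(
        gene_ids=m.gene_ids,
        mean=m.gene_means(),
        phi=phi,
        phi_prime=phi_prime,
        p_value=p_upper,
        q_value=q,
        method_flag=flag_names[flags],
    )


def estimate_c(
    m: CountMatrix,
    mu: np.ndarray,
    candidate_grid=DEFAULT_C_GRID,
    min_mean: float = 1.0,
    min_genes: int = 20,
) -> float:
    """Estimate the global gene-noise CV c from the phi'-vs-mean trend.

    With c at its true value phi' is flat in mean expression; too-small c
    tilts the trend up at high expression and too-large c tilts it down.
    For each candidate the Theil-Sen (median-based) slope of log phi'
    against log mean over genes with mean > ``min_mean`` is computed, and
    the candidate with the smallest |slope| wins (first on ties, so the
    result is deterministic).  Falls back to the default 0.5 with a warning
    when fewer than ``min_genes`` genes are informative.
    """
    grid = np.asarray(candidate_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty candidate grid for c")
    if grid.size == 1:
        return float(grid[0])
    means = m.gene_means()
    informative = means > min_mean
    if informative.sum() < min_genes:
        logger.warning(
            "only %d genes with mean > %g; returning default c = %g",
            int(informative.sum()), min_mean, DEFAULT_C,
        )
        return DEFAULT_C
    log_mean = np.log(means[informative])
    sub = m.subset_genes(informative)
    mu_sub = np.asarray(mu)[informative]
    best_c, best_slope = None, np.inf
    for cand in grid:
        phi_prime = modified_fano(modified_residuals(sub, mu_sub, cand))
        ok = phi_prime > 0
        slope = abs(theilslopes(np.log(phi_prime[ok]), log_mean[ok])[0])
        if slope < best_slope - 1e-12:
            best_slope, best_c = slope, float(cand)
    return best_c
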