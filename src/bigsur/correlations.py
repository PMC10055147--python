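"""Gene-gene correlation significance: PCC', analytic p-values, FDR,
Fisher-formula utilities and the significant-edge list.

The modified corrected Pearson correlation coefficient for genes a, b is

    PCC'_ab = sum_i P'_ia P'_ib / ((n - 1) sqrt(phi'_a phi'_b)).

Its null distribution is obtained from the cumulants of the numerator
S_ab = sum_i P'_ia P'_ib (the phi' denominators aggregate information
across all cells and are treated as constants, a good first
approximation).  Per-cell terms are independent products of independent
mean-zero residuals, so their raw moments factorize,
E[T_i^r] = E[P'_ia^r] E[P'_ib^r], and the cumulants of S reduce to five
gene x gene matrix products over per-cell residual-moment arrays:

    kappa_2 = R2 R2^T                  kappa_3 = R3 R3^T
    kappa_4 = R4 R4^T - 3 (R2*R2)(R2*R2)^T
    kappa_5 = R5 R5^T - 10 (R3.R2)(R3.R2)^T

with R_r the (genes x cells) array of E[(P')^r].  Cornish-Fisher
inversion converts each pair's observed S into two-tailed p-values, and
Benjamini-Hochberg across all pairs controls the FDR.

The Fisher formula p = Erfc(sqrt((n-3)/2) arctanh|r|) is the classical
Gaussian-theory p-value of a correlation of n samples; its inverse maps a
p-value back to an "equivalent PCC", a length-comparable measure of
correlation strength.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import erfc, erfcinv
from statsmodels.stats.multitest import multipletests

from . import null_moments as nm
from .counts import CountMatrix
from .exceptions import ValidationError
from .residuals import modified_fano, modified_residuals

__all__ = [
    "fisher_pvalue",
    "fisher_inverse",
    "pcc_prime",
    "correlation_pvalues",
    "bh_fdr",
    "significant_edges",
    "DEFAULT_FDR",
]

DEFAULT_FDR = 0.02
EQ_PCC_CAP = 1.0 - 1e-12


def fisher_pvalue(r, n: int):
    """p = Erfc(sqrt((n-3)/2) * arctanh|r|); vectorized over r."""
    if n < 4:
        raise ValidationError("fisher_pvalue requires n >= 4")
    r = np.asarray(r, dtype=float)
    saturated = np.abs(r) >= 1.0
    rr = np.clip(r, -EQ_PCC_CAP, EQ_PCC_CAP)
    out = erfc(np.sqrt((n - 3) / 2.0) * np.arctanh(np.abs(rr)))
    out = np.maximum(out, nm.P_FLOOR)
    if np.any(saturated):
        warnings.warn("|r| >= 1 passed to fisher_pvalue; returning minimal p")
        out = np.where(saturated, nm.P_FLOOR, out)
    return out if out.ndim else float(out)


def fisher_inverse(p, n: int):
    """|r| with fisher_pvalue(|r|, n) = p; round-trips to high precision."""
    if n < 4:
        raise ValidationError("fisher_inverse requires n >= 4")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("p must lie strictly in (0, 1)")
    out = np.tanh(erfcinv(p) / np.sqrt((n - 3) / 2.0))
    out = np.minimum(out, EQ_PCC_CAP)
    return out if out.ndim else float(out)


def pcc_prime(r, phi: np.ndarray) -> np.ndarray:
    """Symmetric matrix of PCC' from residuals and per-gene phi'."""
    resid = r.residuals if hasattr(r, "residuals") else np.asarray(r, float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        bad = np.flatnonzero(phi <= 0)
        raise ValidationError(f"phi' must be positive; offending gene indices {bad.tolist()}")
    n = resid.shape[1]
    S = resid @ resid.T
    denom = (n - 1) * np.sqrt(np.outer(phi, phi))
    out = S / denom
    np.fill_diagonal(out, 1.0)
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_pvalues(
    m: CountMatrix,
    mu: np.ndarray,
    c,
    fdr: float = DEFAULT_FDR,
    moments_order: int = 5,
    fast_fisher: bool = False,
) -> pd.DataFrame:
    """Score all gene pairs: PCC', two-sided p, BH q, equivalent PCC.

    Returns a DataFrame over the m(m-1)/2 upper-triangle pairs with
    columns gene_a, gene_b, pcc_prime, p_two_sided, q_value,
    equivalent_pcc (signed), significant (q < fdr) and method.  With
    ``fast_fisher`` the (approximate) Fisher formula is applied directly
    to PCC' instead of the full moment machinery.
    """
    if m.n_genes < 2:
        raise ValidationError("need at least 2 genes")
    resid = modified_residuals(m, mu, c)
    n = resid.n_cells
    phi = modified_fano(resid)
    if np.any(phi <= 0):
        bad = m.gene_ids[phi <= 0]
        raise ValidationError(f"phi' is zero for genes {bad.tolist()}; filter them out")
    pcc = pcc_prime(resid, phi)
    iu, ju = np.triu_indices(m.n_genes, k=1)
    pcc_flat = pcc[iu, ju]

    if fast_fisher:
        p_two = fisher_pvalue(pcc_flat, n)
        method = np.full(p_two.shape, "fisher_on_pcc_prime", dtype=object)
    else:
        from .residuals import _c_column

        cc = _c_column(c, m.n_genes)
        R = nm.residual_raw_moment_arrays(mu, cc, 5)  # (5, genes, cells)
        R2, R3, R4, R5 = R[1], R[2], R[3], R[4]
        k2 = R2 @ R2.T
        k3 = R3 @ R3.T
        k4 = R4 @ R4.T - 3.0 * (R2 * R2) @ (R2 * R2).T
        k5 = R5 @ R5.T - 10.0 * (R3 * R2) @ (R3 * R2).T
        S = resid.residuals @ resid.residuals.T
        stat = S[iu, ju]
        zeros = np.zeros_like(stat)
        k5_flat = zeros if moments_order < 5 else k5[iu, ju]
        p_up, p_lo, flags = nm.cornish_fisher_pvalue_arrays(
            stat, zeros, k2[iu, ju], k3[iu, ju], k4[iu, ju], k5_flat
        )
        p_two = np.minimum(1.0, 2.0 * np.minimum(p_up, p_lo))
        p_two = np.maximum(p_two, nm.P_FLOOR)
        flag_names = np.array(
            ["cornish_fisher", "gaussian_fallback", "gaussian_bound"], dtype=object
        )
        method = flag_names[flags]

    q = bh_fdr(p_two)
    eq = np.sign(pcc_flat) * fisher_inverse(np.clip(p_two, nm.P_FLOOR, 1 - 1e-16), n)
    return pd.DataFrame(
        {
            "gene_a": m.gene_ids[iu],
            "gene_b": m.gene_ids[ju],
            "pcc_prime": pcc_flat,
            "p_two_sided": p_two,
            "q_value": q,
            "equivalent_pcc": eq,
            "significant": q < fdr,
            "method": method,
        }
    )


def significant_edges(results: pd.DataFrame, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Signed equivalent-PCC edge list for pairs with q below the FDR."""
    sig = results[results["q_value"] < fdr]
    return pd.DataFrame(
        {
            "gene_a": sig["gene_a"].to_numpy(),
            "gene_b": sig["gene_b"].to_numpy(),
            "weight": sig["equivalent_pcc"].to_numpy(),
        }
    )
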