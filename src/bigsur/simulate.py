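"""Synthetic UMI matrices under the Poisson-log-normal null.

The reference null design mirrors a typical droplet experiment: 1000
mutually independent genes across 999 cells, per-gene target means spaced
log-evenly from 0.035 to 3467 transcripts per cell, per-cell sequencing
depth factors from a log-normal of mean 1 and CV 0.75 (taken as a smooth
deterministic quantile grid so the depth range is covered evenly), and
counts x_ij ~ Poisson(lambda_ij) with lambda_ij log-normal of mean
(target_j * depth_i) and CV c = 0.5.

Planted-correlation designs make selected gene pairs share a per-cell
multiplicative log-normal latent factor (reciprocal-oriented for negative
pairs).  The shared factor is carved out of the gene's own biological
noise budget — its log-variance plus an independent per-gene remainder
add up to the log-variance implied by c — so planted genes keep exactly
the null marginal distribution while gaining a correlation of tunable
strength (latent_cv, which therefore cannot exceed c).

All randomness flows from a single seed through per-gene substreams, so
results are independent of how genes are blocked or parallelized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .counts import CountMatrix
from .exceptions import ValidationError

__all__ = [
    "SimDesign",
    "PlantedCorrelationDesign",
    "make_depth_factors",
    "make_target_means",
    "simulate_null",
    "simulate_planted",
    "fisher_calibration",
    "poisson_zero_fraction",
    "poisson_mean_for_zero_fraction",
]


@dataclass
class SimDesign:
    """Null-simulation design (defaults are the reference conditions)."""

    n_genes: int = 1000
    n_cells: int = 999
    mean_low: float = 0.035
    mean_high: float = 3467.0
    c: float = 0.5
    depth_cv: float = 0.75
    depth_mode: str = "quantile_grid"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValidationError("n_genes and n_cells must be >= 1")
        if not self.mean_low < self.mean_high:
            raise ValidationError("mean_low must be < mean_high")
        if self.c < 0 or self.depth_cv < 0:
            raise ValidationError("c and depth_cv must be non-negative")
        if self.depth_mode not in ("quantile_grid", "random"):
            raise ValidationError(f"unknown depth_mode {self.depth_mode!r}")


@dataclass
class PlantedCorrelationDesign:
    """Gene pairs that share a latent log-normal factor of CV latent_cv."""

    pair_list: list
    latent_cv: float = 0.5
    signs: list | None = None  # +1/-1 per pair, default all +1
    allow_overlap: bool = False

    def resolved_signs(self) -> list:
        if self.signs is None:
            return [1] * len(self.pair_list)
        if len(self.signs) != len(self.pair_list):
            raise ValidationError("signs must match pair_list length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValidationError("signs must be +1 or -1")
        return list(self.signs)

    def validate(self, n_genes: int) -> None:
        seen: set[int] = set()
        for a, b in self.pair_list:
            if not (0 <= a < n_genes and 0 <= b < n_genes) or a == b:
                raise ValidationError(f"invalid planted pair ({a}, {b})")
            if not self.allow_overlap and (a in seen or b in seen):
                raise ValidationError("overlapping planted pairs not allowed")
            seen.update((a, b))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu_log, sigma) of a log-normal with given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def make_depth_factors(d: SimDesign) -> np.ndarray:
    """Per-cell sequencing depth factors with mean ~1.

    ``quantile_grid`` mode returns the midpoint quantiles of the
    log-normal, sorted and deterministic, so the depth distribution is
    swept smoothly; ``random`` mode draws i.i.d. factors from the design
    seed.  With depth_cv = 0 all factors are exactly 1.
    """
    if d.depth_cv == 0:
        return np.ones(d.n_cells)
    mu_log, sigma = _lognormal_params(1.0, d.depth_cv)
    if d.depth_mode == "quantile_grid":
        from scipy.stats import norm

        probs = (np.arange(d.n_cells) + 0.5) / d.n_cells
        return np.exp(mu_log + sigma * norm.ppf(probs))
    rng = np.random.default_rng(np.random.SeedSequence([d.seed, 7]))
    return np.exp(rng.normal(mu_log, sigma, d.n_cells))


def make_target_means(d: SimDesign) -> np.ndarray:
    """Per-gene target means, log-evenly spaced (deterministic grid)."""
    if d.n_genes == 1:
        return np.array([d.mean_low])
    return np.geomspace(d.mean_low, d.mean_high, d.n_genes)


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"gene{i:05d}" for i in range(n)], dtype=object)


def _cell_ids(n: int) -> np.ndarray:
    return np.array([f"cell{i:05d}" for i in range(n)], dtype=object)


def _sample_counts(
    targets: np.ndarray,
    depths: np.ndarray,
    c: float,
    seed: int,
    extra_log_factors: dict | None = None,
    per_gene_sigma2: dict | None = None,
) -> np.ndarray:
    """Poisson-log-normal counts, one seeded substream per gene.

    ``per_gene_sigma2`` overrides the independent log-normal variance for
    selected genes (used when part of the noise budget is spent on a
    shared factor supplied through ``extra_log_factors``).
    """
    n_genes, n_cells = len(targets), len(depths)
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    streams = np.random.SeedSequence([seed, 11]).spawn(n_genes)
    default_sigma2 = np.log1p(c**2)
    for j in range(n_genes):
        rng = np.random.default_rng(streams[j])
        lam = targets[j] * depths
        sigma2 = default_sigma2
        if per_gene_sigma2 is not None and j in per_gene_sigma2:
            sigma2 = per_gene_sigma2[j]
        if sigma2 > 0:
            sigma = np.sqrt(sigma2)
            lam = lam * np.exp(rng.normal(-sigma2 / 2.0, sigma, n_cells))
        if extra_log_factors is not None and j in extra_log_factors:
            lam = lam * extra_log_factors[j]
        counts[j] = rng.poisson(lam)
    return counts


def simulate_null(d: SimDesign) -> CountMatrix:
    """Independent Poisson-log-normal genes with shared depth factors."""
    depths = make_depth_factors(d)
    targets = make_target_means(d)
    counts = _sample_counts(targets, depths, d.c, d.seed)
    return CountMatrix(sp.csr_matrix(counts), _gene_ids(d.n_genes), _cell_ids(d.n_cells))


def simulate_planted(d: SimDesign, p: PlantedCorrelationDesign) -> CountMatrix:
    """Null design plus correlated pairs sharing part of their gene noise.

    For a planted pair, the log-normal noise of both genes is decomposed
    into a shared component of CV ``latent_cv`` (the same per-cell draw
    for both genes; reciprocal orientation for sign -1) and an independent
    per-gene remainder, so the total log-variance still matches ``c``.
    Planted genes therefore keep the exact null marginal distribution;
    only the chosen pairs become correlated.  All other genes follow the
    null design.
    """
    p.validate(d.n_genes)
    sigma_tot2 = np.log1p(d.c**2)
    sigma_sh2 = np.log1p(p.latent_cv**2)
    if sigma_sh2 > sigma_tot2 + 1e-12:
        raise ValidationError(
            f"latent_cv={p.latent_cv} exceeds the gene noise budget c={d.c}"
        )
    depths = make_depth_factors(d)
    targets = make_target_means(d)
    extra: dict[int, np.ndarray] = {}
    shared_noise: dict[int, float] = {}
    if p.latent_cv > 0:
        sigma_sh = np.sqrt(sigma_sh2)
        streams = np.random.SeedSequence([d.seed, 13]).spawn(len(p.pair_list))
        for (a, b), sign, ss in zip(p.pair_list, p.resolved_signs(), streams):
            rng = np.random.default_rng(ss)
            z = rng.normal(size=d.n_cells)
            extra[a] = extra.get(a, 1.0) * np.exp(sigma_sh * z - sigma_sh2 / 2.0)
            extra[b] = extra.get(b, 1.0) * np.exp(sign * sigma_sh * z - sigma_sh2 / 2.0)
            # planted genes spend part of their noise budget on the shared factor
            shared_noise[a] = shared_noise.get(a, 0.0) + sigma_sh2
            shared_noise[b] = shared_noise.get(b, 0.0) + sigma_sh2
    residual_sigma2 = {
        j: max(sigma_tot2 - used, 0.0) for j, used in shared_noise.items()
    }
    counts = _sample_counts(
        targets, depths, d.c, d.seed, extra, per_gene_sigma2=residual_sigma2
    )
    return CountMatrix(sp.csr_matrix(counts), _gene_ids(d.n_genes), _cell_ids(d.n_cells))


def fisher_calibration(
    n_pairs: int,
    n_cells: int,
    mean: float,
    c: float = 0.0,
    depths: np.ndarray | None = None,
    normalize: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical |PCC| -> p curve for independent vector pairs.

    Simulates ``n_pairs`` pairs of independent Poisson(-log-normal)
    vectors, optionally depth-scaled and re-normalized, computes their
    Pearson correlations, and returns the empirical two-sided exceedance
    probability of each |PCC| for comparison against the Fisher formula.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    if depths is None:
        depths = np.ones(n_cells)
    sigma = np.sqrt(np.log1p(c**2)) if c > 0 else 0.0
    pccs = np.empty(n_pairs)
    chunk = max(1, int(2e6) // n_cells)
    done = 0
    while done < n_pairs:
        k = min(chunk, n_pairs - done)
        lam = mean * depths[None, :] * np.ones((2 * k, 1))
        if sigma > 0:
            lam = lam * np.exp(rng.normal(-sigma**2 / 2.0, sigma, lam.shape))
        x = rng.poisson(lam).astype(float)
        if normalize:
            x = x / depths[None, :]
        a, b = x[:k], x[k:]
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        denom[denom == 0] = np.inf
        pccs[done : done + k] = (a * b).sum(axis=1) / denom
        done += k
    order = np.argsort(-np.abs(pccs))
    ranked = np.abs(pccs)[order]
    emp_p = (np.arange(1, n_pairs + 1)) / n_pairs
    return pd.DataFrame({"abs_pcc": ranked, "empirical_p": emp_p})


def poisson_zero_fraction(mean: float) -> float:
    """Expected fraction of zeros in Poisson counts of the given mean."""
    return float(np.exp(-mean))


def poisson_mean_for_zero_fraction(frac: float) -> float:
    """The Poisson mean whose zero probability equals ``frac``."""
    if not 0 < frac <= 1:
        raise ValidationError("zero fraction must lie in (0, 1]")
    return float(-np.log(frac))
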