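# Methods

## The null model

Each UMI count `x_ij` (gene *j*, cell *i*) is modelled as a Poisson draw
whose rate is itself random:

    lambda_ij = mu_ij · L_ij,      L_ij ~ log-normal, E[L] = 1, CV = c
    x_ij | lambda_ij ~ Poisson(lambda_ij)

`mu_ij = (cell total · gene total) / grand total` is the depth-aware
expectation — the only use made of sequencing depth, so the data are
never normalized. The log-normal layer represents stochastic
transcription ("biological noise"); `c` is its coefficient of variation,
a single global scalar by default (a per-gene vector is accepted). This
compound distribution has no closed-form PMF, but every moment is exact:
with `w = 1 + c²` the mixing variable satisfies `E[L^r] = w^(r(r−1)/2)`,
the factorial moments of `x` are `mu^r · w^(r(r−1)/2)`, and raw/central
moments follow through Stirling numbers and binomial expansion. The
package carries out this algebra **once, exactly, in integer
arithmetic**, producing per-order polynomials in `(mu, w)` that are then
evaluated by Horner's rule (orders up to 12; order *k* cumulants of
squared residuals need count moments up to `2k`). Exactness is verified
in the tests against scipy's Poisson moments (at `c = 0`) and against
10⁷-draw Monte-Carlo sampling.

## Test statistics

The modified corrected Pearson residual

    P'_ij = (x_ij − mu_ij) / sqrt(mu_ij (1 + c² mu_ij))

has `E[P'] = 0` and `E[P'²] = 1` exactly under the null (the denominator
is the null variance: Poisson Fano factor 1 plus noise Fano factor
`c²·mu`). Two statistics are built from it:

- `φ'_j = Σ_i P'_ij² / (n−1)` — per-gene variability. Null cumulants of
  `Σ_i P'_ij²` are sums of independent per-cell cumulants, each obtained
  from the analytic moments of `(P')²` at that cell's `mu_ij`.
- `S_ab = Σ_i P'_ia P'_ib` — the numerator of PCC′. Per-cell terms are
  products of independent mean-zero residuals, so their raw moments
  factorize and the first five cumulants of `S` reduce to five
  gene × gene matrix products over per-cell residual-moment arrays
  (`kappa_2 = R2·R2ᵀ`, `kappa_3 = R3·R3ᵀ`,
  `kappa_4 = R4·R4ᵀ − 3(R2²)(R2²)ᵀ`,
  `kappa_5 = R5·R5ᵀ − 10(R3∘R2)(R3∘R2)ᵀ`), which is what makes scoring
  hundreds of thousands of pairs cheap. The `φ'` denominators of PCC′
  aggregate information across all cells and are treated as constants
  when computing null moments; standardization then makes the PCC′ test
  identical to testing `S`.

## Tail probabilities

Given cumulants `kappa_1..kappa_5`, the observed statistic is
standardized and mapped to an equivalent Gaussian deviate by inverting
the fourth-order Cornish–Fisher quantile polynomial (standardized
skewness, excess kurtosis and fifth-cumulant terms; with five cumulants
the polynomial is quartic). Inversion is a damped Newton iteration
started at the naive standardized value, which converges to the real
quartic root nearest that value and degrades gracefully when the
polynomial degenerates toward the identity; a direct companion-matrix
quartic solver is kept as a test-time cross-check. Where the iteration
fails to converge or the polynomial is locally decreasing (inadmissible
cumulant combinations far in the tails), the Gaussian tail of the
standardized statistic is returned instead and the result flagged
`gaussian_fallback`. Two-sided p-values are `min(1, 2·min(upper, lower))`,
floored at 1e-320. As a speed/accuracy trade, observations whose naive
Gaussian tail is already below 1e-12 skip the inversion and return that
bound (flagged `gaussian_bound`); such p-values are guaranteed to be at
or below the threshold, which is far past any FDR boundary of interest.
Accuracy checks: the chi-square(5) 0.999-quantile tail is reproduced
within a factor 1.04, and a 10⁶-replicate sampling oracle of φ' (200
Poisson-mean-5 cells) agrees with the analytic upper tail to within
Monte-Carlo error plus a small count-lattice allowance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `c` | 0.5 (or `auto`) | CV of log-normal expression noise; plausible range 0.2–0.6 |
| `moments_order` | 5 | cumulants used for tail inversion (4–5) |
| `fdr` | 0.02 | BH false-discovery-rate threshold for significant edges |
| `min_cells_expressed` | 8 | gene filter: minimum cells with ≥ 1 UMI |
| walktrap `steps` | 4 | random-walk length for community detection |
| `merge_ratio_threshold` | 0.25 | positive cross-edge density above which communities merge |
| `max_size` | 2000 | community size triggering one extra walktrap pass |

`estimate_c` exploits the fact that φ' is flat in expression when `c` is
right, tilted up (down) when `c` is too small (large): it scans a grid
(default 0–1 in steps of 0.05) and minimizes the absolute Theil–Sen
slope of `log φ'` versus `log mean` over genes with mean > 1. The
median-based slope makes the criterion robust to the handful of
genuinely variable genes expected in real data. Recovery tests: data
generated with `c = 0.5` give estimates of 0.5; pure Poisson data give
0. With fewer than 20 informative genes the estimator warns and returns
the default 0.5.

The merge threshold and `max_size` automate a curation step that is
inherently judgement-based (when is inter-community connectivity "too
large"?); 0.25 requires a quarter of all possible cross links to be
significant, far above what independent communities produce, and 2000
reflects that communities of thousands of genes are usually heterogeneity
artifacts worth re-splitting.

## The simulator

`simulate_null` reproduces a droplet-style null: 1000 independent genes ×
999 cells, target means log-evenly spaced over 0.035–3467 transcripts per
cell (five decades, matching the dynamic range of real data), per-cell
depth factors from a log-normal of mean 1 and CV 0.75 taken as a sorted
midpoint-quantile grid (deterministic, smoothly covering the depth
range), and Poisson-log-normal sampling with `c = 0.5`. Log-normals are
parameterized by arithmetic mean and CV (`sigma² = ln(1+CV²)`,
`mu_log = ln(mean) − sigma²/2`). All randomness derives from one seed
through per-gene substreams, so results do not depend on gene blocking.

`simulate_planted` adds correlated pairs by making both genes share a
log-normal factor of CV `latent_cv` drawn once per cell (reciprocal
orientation for negative pairs). The shared factor is carved out of the
gene's own noise budget — shared plus independent log-variances add to
`ln(1+c²)`, requiring `latent_cv ≤ c` — so planted genes keep exactly the
null marginal distribution and only the chosen pairs are correlated.
This matters for power studies: a latent factor added *on top* of `c`
would make planted genes marginally overdispersed and their pairings
with unrelated genes spuriously significant, contaminating false-positive
counts.

What the simulator does **not** emulate: cell-type mixtures, batch
effects, doublets, ambient RNA, gene-length or GC biases, and
non-log-normal noise. Tests passing on these simulations therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to real-data pathologies.

## Known limitations

- `mu_ij` is a plug-in estimate from finite margins. The per-cell depth
  estimate inherits biological noise from the most highly expressed
  genes, inducing a small shared component across all residuals of a
  cell. On the reference design this produces a mean PCC′ offset of
  ~+0.002 and a ~5% relative excess in two-sided type-I error at
  α = 10⁻²–10⁻³ (a control experiment with known `mu` is calibrated
  within Monte-Carlo error, isolating the cause). No correction is
  applied; the effect shrinks as the transcriptome diversifies and is
  negligible for FDR thresholds in practical use.
- BigSur's p tests the residual dot product with `φ'` treated as a
  constant; feeding PCC′ through the Fisher formula instead (the
  `fast_fisher` mode) additionally divides by the observed `φ'`, whose
  sampling noise (SD ≈ √(2/n)) produces occasional half-log10
  discrepancies between the two routes even at high expression. The two
  agree closely in the bulk (median |Δlog10 p| ≈ 0.01 on the reference
  design for pairs with means ≥ 1).
- The Cornish–Fisher expansion is asymptotic; for extremely sparse genes
  (expected counts ≪ 0.01 per cell) the discrete statistic's tail is
  approximated more coarsely. The gene filter (≥ 8 expressing cells)
  keeps such genes out by default.
- Community refinement automates what is ultimately a curation judgement;
  the defaults are sensible, not canonical.

## Problem sizes used in the test suite

Calibration tests run the full 1000 × 999 reference design (three
seeds); pair-level calibration uses the ~700 genes with observed mean
≥ 1 (~250k pairs per seed); moment oracles use 10⁷ draws; the φ'
sampling oracle uses 10⁶ replicates of a 200-cell gene; power tests use
100 genes × 999 cells with 10 planted pairs, three seeds. The exhaustive
community oracle enumerates all partitions with connected parts
(sufficient for maximum modularity, since splitting a disconnected part
never lowers it) on 10–12-node clique benchmarks.
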