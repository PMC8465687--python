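# Methods

## The model

We observe k time series of undirected graphs, each series G̃_i = {G_i^1,
…, G_i^T} on a fixed vertex set. The working assumption is that each graph
is drawn from a random-graph model whose parameter θ_i^t is itself a random
process; causality between the graph series is *defined* as Granger
causality between the latent parameter processes. Since θ is never
observed, we need an observable proxy that is a monotone function of the
parameter. The spectral radius λ₁ — the largest eigenvalue of the adjacency
matrix — plays that role: for an Erdős–Rényi graph E[λ₁] ≈ n·p, for a
deg-regular graph λ₁ = deg exactly, for a geometric graph λ₁ converges to a
function of the radius, and for Watts–Strogatz and Barabási–Albert graphs
λ₁ responds monotonically to the rewiring probability and attachment power
over the relevant ranges.

Writing y_{i,t} for the spectral radius of series i at time t, the k
series follow a VAR(p):

    y_{j,t} = v_j + Σ_{i=1..k} Σ_{l=1..p} a_{i,j}^l · y_{i,t−l} + ε_{j,t}

with errors that are serially independent but possibly contemporaneously
correlated (covariance Σ). Series i fails to Granger-cause series j exactly
when a_{i,j}^l = 0 for every lag l, so non-causality is a linear hypothesis
C β_j = 0 on the OLS coefficients.

## Estimation

The model is stacked as Y = Z β + u and solved by least squares (QR-based
`lstsq`, never an explicit inverse of Z′Z; the inverse is materialized only
inside the Wald quadratic form, via linear solves). Lag columns are ordered
series-major, lag-minor: column (i−1)p + l of Z holds y_{i,t−l}. An
intercept column is always appended: the latent benchmark processes are
zero-mean, but spectral-radius series are strictly positive, and omitting
the intercept would bias every coefficient. The residual covariance is
Σ̂ = û′û / ((T−p) − (kp+1)), counting the intercept among the estimated
parameters; `sigma_df="lags-only"` switches to the (T−p) − kp denominator
for compatibility with conventions that ignore the intercept. The two
differ by a factor (T−p−kp−1)/(T−p−kp), immaterial at the series lengths
studied here but kept explicit.

Order selection minimizes AIC(p) = ln det Σ̃(p) + 2pk²/T_eff over p = 1..p_max,
where Σ̃ is the unadjusted (maximum-likelihood) covariance and every
candidate is fitted on the common sample aligned at p_max, so the
log-determinants are comparable. Ties break toward the smaller order. The
pipeline caps p_max at min(10, ⌊(T−1)/(k+1)⌋) to keep the design matrix
full rank on short series.

Rank handling: design columns whose smallest singular value falls below
1e−10 of the largest raise a singular-design error that names the
offending columns (a constant feature series — e.g. identical graphs at
every time point — is the typical cause).

## Testing

**Wald.** W = (Cβ̂_j)′ [C (Z′Z)⁻¹ C′]⁻¹ (Cβ̂_j) / Σ̂_{jj} is compared to
χ² with rank(C) = p degrees of freedom. C selects the p tested
coefficients under the ordering above; with the intercept present, C is
extended by a zero column, equivalently the relevant p×p block of (Z′Z)⁻¹
is extracted. This matches the single-equation Wald causality test of
standard VAR packages (statsmodels agrees to 1e−8 in the test suite, and
is used there purely as a cross-check).

**Parametric bootstrap.** For short series the χ² approximation is poor.
The bootstrap: fit the unrestricted VAR; compute the observed W; form the
null model by zeroing exactly the tested coefficients (all other
coefficients, including the intercept, stay at their estimates); simulate
each replicate by recursing the null model from the first p observed
values, driven by residual **rows** resampled with replacement — rows are
resampled jointly across series, preserving the contemporaneous error
correlation that per-series resampling would destroy; refit each replicate
and recompute W*; the p-value is #{W* ≥ W}/n_boot. A `smoothed` option
returns (1 + #{W* ≥ W})/(1 + n_boot), which never reports exactly zero and
is friendlier to downstream multiplicity corrections; the plain fraction
is the default. Replicates whose refit is singular are discarded with a
warning and the denominator reduced. No burn-in is added to replicates:
they are anchored at the observed initial p values and generate exactly
T − p new points, matching the fitted sample size.

Randomness: one master seed; each replicate draws its resampling indices
from its own `SeedSequence` substream, so results are reproducible and
independent of the (vectorized) batch evaluation. All-pairs runs derive a
substream per ordered pair, so the table equals per-pair calls.

Self-causality (i = j) is rejected as a parameter error: only cross-series
hypotheses are defined.

## Simulation scenarios

Five latent data-generating processes with coefficients ±0.5 and error
covariance diag 1 / off-diag 0.1 provide ground truth: (1) two independent
AR(1) series — the null; (2) y1 → y2; (3) one driver, two targets, with
opposite signs; (4) direct and indirect effects, including a lag-2 term;
(5) a feedback loop y2 → y3 → y4 → y2 fed by y1. Recursions start at zero
and discard a 50-step burn-in (the processes mix fast; 50 steps put the
retained sample within numerical distance of stationarity).

Latent values are mapped to graph parameters by the inverse logit
s = 1/(1+e^{−y}) alone (no further rescaling): ER p = s, geometric r = s,
regular deg = ⌊10 s⌋, Watts–Strogatz pw = s (nei = 3), Barabási–Albert
ps = 2s (m1 = 1). One independent graph is generated per series and time
point from a dedicated random substream. A regular graph with ⌊10 s⌋ = 0
has no edges; such graphs are kept with λ₁ = 0 and a warning by default
(an optional redraw flag resamples the graph seed), and the analysis
pipeline refuses edgeless graphs unless explicitly allowed, since the
framework assumes non-empty graphs. Infeasible regular pairs (n·deg odd)
decrement deg by one with a warning rather than failing silently — the
⌊10 s⌋ mapping can produce them legitimately.

The experiment driver repeats (simulate latent → generate graphs →
extract feature → fit VAR → test all pairs) and reports rejection rates
per directed pair at a chosen level. Full-scale defaults follow the study
design (grid n ∈ {60, 90, 120, 150, 200, 300}, T ∈ {25, 50, 75, 100},
1000 replicates, threshold 0.05); the shipped tests run desk-scale slices
(200–500 replicates at selected cells) chosen so each check completes in
minutes while keeping binomial noise well inside the asserted bounds.

## Time-varying correlation graphs

The front-end for signal data (e.g. per-region fMRI averages) builds one
weighted graph per time point with time-varying Pearson correlations as
edge weights. The estimator is spline-based: each channel's trend is a
cubic B-spline regression fit (basis dimension `df`, default T/10, minimum
4); instantaneous cross-products of the centered channels are projected
onto the same basis to give time-varying covariance and variance paths;
r_ab(t) = cov_ab(t)/√(var_a(t)·var_b(t)), clipped to [−1, 1]. `df = 1`
degenerates to a constant basis and reproduces the static Pearson
correlation exactly — a useful limit check. Smoothing a nonnegative square
can undershoot zero near the boundary; variances are floored at 1e−10 and
edges whose variance hits the floor get weight 0 with a warning. The knots,
basis and per-edge-vs-global smoothing policy are conventions of this
package (a single global basis applied identically to means, variances and
covariances); results of this module are convention-dependent, and its
tests are property-based (bounds, symmetry, limit behavior, sign tracking)
rather than value-based.

Weighted graphs feed the same pipeline: λ₁ is still the largest eigenvalue
(not the largest magnitude), which for correlation matrices with possible
negative weights is the meaningful extreme.

## What the simulations do and do not show

The generators produce graphs whose parameter processes are exactly VAR
and whose graphs are conditionally independent given the parameters. Real
dynamic networks (e.g. functional connectivity estimated from overlapping
smoothing windows) have serially dependent estimation noise, latent
parameters that need not follow a linear process, and edge weights rather
than edge indicators. Passing the calibration and power checks here
therefore validates the inference machinery under its own assumptions; it
does not certify calibration on real data, where the bootstrap variant and
order selection carry more of the load.

## Numerical choices

- Spectral radius: full symmetric eigen-decomposition up to n = 150,
  Lanczos (`eigsh`, largest-algebraic) above, with a dense fallback on
  non-convergence. Both agree to ~1e−14 on the graphs used here.
- Wald quadratic form: solves, not inverses, with a 1e−10 relative
  singular-value guard.
- Bootstrap refits: batched normal equations over replicates; replicates
  failing the same rank guard are discarded and counted.
- Degenerate inputs: constant series → singular-design error naming
  columns; empty graph series, ragged lengths, self-loops, duplicate
  edges → validation errors at the boundary, not deep in the numerics.

## Known limitations

- Only undirected simple (or weighted) graphs; no multigraphs, self-loops,
  directed graphs, or time-varying vertex sets.
- Asymptotic spectral-radius expressions for the geometric and
  Barabási–Albert families are order-of-magnitude reports, not calibrated
  predictions; the Watts–Strogatz law is unknown and reported as undefined.
- No multiple-testing correction across pairs: the all-pairs table reports
  raw p-values, and correction is the caller's responsibility.
- The bootstrap assumes the VAR residuals are exchangeable rows; heavy
  conditional heteroskedasticity would violate that.
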