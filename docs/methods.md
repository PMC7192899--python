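# Methods

`semil` estimates how much information a cellular biochemical reaction
network (BRN) transmits from an input stimulus (e.g. an inducer
concentration) to a single-cell gene-expression output, using only output
distributions measured at a handful of fixed input values — the form in
which flow-cytometry, microscopy and simulation data actually arrive.  The
result is a *mutual information landscape*: the mutual information
I(X; g), in bits, for every continuous input distribution in a
two-parameter design space.

## The design space

Input distributions are beta distributions in the normalised log coordinate
u = log10(x/x_min)/L with L = log10(x_max/x_min), so the input density is

    p(x) = rho_beta(u; alpha, beta) / (x ln(x_max/x_min)),   x in [x_min, x_max].

This family covers log-uniform, unimodal and antimodal shapes on one bounded
interval.  Landscape coordinates are the geometric mean E and geometric SD
sigma of the input; the map to (alpha, beta) is exact moment matching in
log10 space:

    m = log10(E/x_min)/L,  s = log10(sigma)/L,
    nu = m(1-m)/s^2 - 1,   alpha = m nu,  beta = (1-m) nu.

The map is closed-form and invertible; it fails (no such beta distribution
exists) exactly when s^2 >= m(1-m), which caps the representable geometric
SD at sigma_max(E) = 10^(L sqrt(m(1-m))).  Infeasible (E, sigma) cells are
masked in the grid, never raised mid-computation and never encoded as
0 bits.  Geometric SD is defined base-independently as 10^(SD of log10 X).
Grids are log-spaced in both coordinates because the landscape structure is
multiplicative in both.

**Placing the measured inputs.**  The input values at which output data are
collected must cover the design space: they should span the range of E in
the grid, and their log-spacing should be comparable to the smallest sigma
in the grid, otherwise the sparse approximation (next section) cannot
represent the narrowest design-space distributions and the landscape's
argmax saturates in sigma.  The packaged validation support is
`geomspace(1, 2048, n)` with n = 5 or 10; the small-noise sweep uses n = 20
because its grid extends down to sigma = 1.5 (spacing ratio 1.49).

## Sparse discrete approximation (reduced-order model)

Each continuous design-space distribution is replaced by probability masses
P_i on the fixed measured support {x_i}, chosen to minimise

    J(P) = ∫_0^1 (F_cont(u) - F_step(u; P))^2 du
           + w * sum_{r in {1,2}} (E[u^r]_cont - sum_i P_i u_i^r)^2

with both terms computed in the u coordinate, so they are dimensionless and
O(1); the default weight is w = 1 and both are exposed in the config.  The
step CDF is right-continuous.  The CDF integral uses a 1000-node midpoint
rule (refinement to 1e5 nodes moves values by < 1e-4).  J is a convex
quadratic on the probability simplex; it is minimised with SLSQP (analytic
gradient) from the deterministic cell-probability initialisation — the
continuous CDF differenced at log-midpoints between support points — and the
returned masses are never worse than that initialisation, so the fit needs
no random seed.  Zero input concentrations from experiments (uninduced
wells) are remapped to a user-chosen pseudo-value, typically x_min, before
log transforms; the reader refuses zeros unless a remap value is given.

## Mutual information and bias correction

The channel is estimated model-free: outputs are binned and the observed
bin frequencies per input group are used directly as
P(g = g_j | X = x_i), with no pseudocounts.  Continuous outputs get pooled
equal-frequency (quantile) bins, which equalise occupancy and keep the
small-count bias uniform across bins; the default bin count is
ceil(sqrt(min_i N_i)) capped at 256.  Naturally discrete outputs (molecule
counts) use the non-negative integers up to the observed maximum.
Duplicate quantile edges (heavy ties) are merged with a warning rather than
leaving silent empty bins.

For input masses P_i the plug-in estimate is the standard decomposition

    I(X; g) = H(g) - sum_i P_i H(g | x_i),   H in bits,

clamped at zero.  Plug-in MI is biased upward by an O(1/N) term, so each
landscape value is corrected by stratified subsampling: every input group
is subsampled without replacement to fractions {1.0, 0.8, 0.625, 0.5} of
its size (5 repeats per fraction, averaged), and MI is regressed linearly
on 1/(f N_total); the intercept is the infinite-data extrapolation.  The
subsampled conditional rows do not depend on the input weighting, so they
are drawn once per dataset and shared across all grid cells, while the
extrapolation is redone per cell because each cell weights the groups
differently.  All subsampling randomness derives from the single run seed.

On an analytic two-input binary channel at N = 1e5 per input the corrected
estimate lands within 0.01 bits of the exact value (asserted in the test
suite), and the error shrinks with N over 1e3–1e5.

## Landscape, optimum, contours, baseline

The pipeline per feasible grid cell is: (E, sigma) → log-beta distribution
→ sparse masses → bias-corrected MI.  The optimum is the argmax cell, with
deterministic tie-breaking (smallest sigma, then smallest E) and a boundary
flag set when the argmax touches the feasible-region edge.  The
near-optimal region is the set of cells within 0.05 bits of the maximum —
the contour convention used in all summaries.  Error landscapes
delta_I = I_estimated − I_correct are computed against an exact oracle when
one exists; accuracy claims are reported as the median |delta_I| over the
*high-information region*, operationalised as cells whose true MI is within
0.5 bits of the true maximum (the plateau of the landscape, where the
method's answer matters most).

The Blahut–Arimoto algorithm provides the unconstrained-input channel
capacity of the same estimated conditional model: an upper bound on every
landscape value (asserted in tests) and a baseline.  Its optimal input is
typically spiky — in the packaged example it zeroes out one of five inputs
almost exactly — which is the interpretability problem the smooth design
space avoids.  It is reported alongside landscapes, never used inside them.

## Synthetic ground truth

**Gamma dose–response model.**  Output at input x is gamma distributed with
Hill mean g(x) = g0 + g_max x^n/(K^n + x^n) and variance mean + c·mean²:
a Poissonian term plus a multiplicative term with squared coefficient of
variation c.  Packaged fixture: g0 = 50, g_max = 5000, K = 50, n = 2, with
c ∈ {1.0, 0.1, 0.01} as the decreasing-noise sweep; the default validation
model is the c = 1.0 member (see the support-placement note above for why
the sparse-input accuracy claim lives in the overlapping-output regime).
Exact MI for any design-space distribution is computed by 2-D quadrature:
equal-probability nodes in x (beta quantiles at midpoint probabilities,
which integrate the endpoint-singular antimodal densities exactly in
probability) times a uniform log-output grid spanning the 1e-8…1-1e-8
conditional quantiles, rows renormalised to kill truncation error.
`true_mi_numeric` doubles both resolutions until consecutive values agree
within 0.005 bits and raises otherwise; the default 400×800 grid agrees
with an independent 1e6-draw Monte-Carlo estimate within 0.02 bits and with
a linear-output-axis evaluation within 0.005 bits (reparameterisation
invariance), both asserted in tests.

**Gillespie simulator.**  An exact direct-method SSA, one independent
trajectory per cell, read out at a single fixed time (single-time-point
flow-cytometry semantics; no time averaging, no tau-leaping, no cell
division).  Trajectories advance synchronously through vectorised draws but
each keeps its own clock, so per-trajectory statistics are exactly those of
the sequential algorithm; birth–death (Poisson mean k/γ, Fano 1) and
two-stage bursting (Fano ≈ 1 + b/(1 + d_p/d_m)) closed forms are asserted.
The packaged induction circuit mimics the *E. coli* lactose operon: inducer
x inactivates a repressor, R_active = R_total K^m/(K^m + x^m), which
throttles transcription of a two-stage (mRNA, reporter) cascade with
propensity k_tx (1 − R/(R + θ)); defaults k_tx = 50, d_m = 10, k_p = 20,
d_p = 1, R_total = 50, θ = 5, K = 40, m = 2 give a basal→induced range of
roughly 9→100 reporter molecules over x ∈ [1, 2048].  The optional
positive-feedback variant scales the effective intracellular inducer by
(1 + 3 P/100), standing in for the lacY permease motif.  Rates are plain
constructor arguments so a different parameterisation can be dropped in.

## What the synthetic data do and do not show

The generators emulate the *statistical* structure of single-cell
dose–response data: heavy-tailed unimodal output distributions whose mean
and noise depend on the input, measured at log-spaced input values with
large per-input sample sizes.  They do not emulate instrument effects
(autofluorescence background, gating artefacts, saturation), extrinsic
noise correlations between cells, growth-rate coupling, or replicate-level
variability.  Passing the validation suite therefore demonstrates that the
estimation machinery is accurate when the conditional distributions are
smooth in the input; it does not certify accuracy for data whose
conditional distributions are corrupted upstream of the reader.

## Numerical choices and problem sizes

- Landscape accuracy runs use a 30×30 grid over E ∈ [2, 1024],
  sigma ∈ [1.1, 100] on bounds [1, 2048], 1e5 cells per input; the
  small-noise sweep uses a 45×45 grid on bounds [0.1, 2048] (wider, so
  geometric SDs up to ~140 are feasible) with 3e4 cells per input.  SSA
  demonstrations use 800–2000 cells per input.
- Ties at the landscape argmax are broken lowest-sigma-then-lowest-E;
  exact float ties essentially only occur in constructed fixtures.
- Degenerate inputs: constant outputs cannot be binned (error); groups
  smaller than 10 cells after subsampling are refused; empty feasible grids
  are an error at construction.
- All stochastic stages consume `numpy` Generator streams derived from the
  single run seed in a fixed order; identical config + seed reproduces
  byte-identical landscape CSVs.

## Known limitations

- The design space is a single two-parameter family; multimodal input
  distributions outside the log-beta family are not representable.
- Support locations are taken as given (fixed by the experiment); they are
  not optimised.
- Outputs are scalar; multivariate readouts and kernel/k-NN MI estimators
  are out of scope by design (the estimator is deliberately model-free and
  histogram-based).
- Near the lowest measured input value the sparse approximation degrades
  (mass piles onto the smallest support point); the error map tests assert
  this structure rather than hiding it.
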