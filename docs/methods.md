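# Methods

## Model

Fractional Brownian motion (FBM) `X_H(t)` is the centered, self-similar
Gaussian process with stationary increments, parameterized by the Hurst
exponent `H ∈ (0, 1)` and a diffusion coefficient `D > 0`:

    Cov(X(t), X(s)) = (D/2) (t^{2H} + s^{2H} − |t − s|^{2H}),
    Var X(t) = D t^{2H}.

Its unit-step increment process, fractional Gaussian noise (fGn)
`ξ(t) = X(t) − X(t−1)`, is stationary with autocovariance

    γ(τ) = (D/2) (|τ+1|^{2H} + |τ−1|^{2H} − 2 |τ|^{2H}).

`H` maps to the anomalous diffusion exponent as `α = 2H`: `H < 1/2` is
subdiffusion (negatively correlated increments), `H = 1/2` ordinary Brownian
motion (white increments), `H > 1/2` superdiffusion with long-range
dependence. Everything downstream works on the **biased** (divisor-`n`)
sample ACVF of the increments,

    γ̂(τ) = (1/n) Σ_{t=1}^{n−τ} ξ(t) ξ(t+τ),

chosen over the unbiased divisor-(n−τ) variant for its lower variance; its
expectation under the model is `((n−τ)/n) γ(τ)`, which the package exposes
for bias checks. No mean subtraction is applied by default (fGn is
centered); a de-meaning flag exists for real recordings with drift.

### Trajectory indexing

A "trajectory of length N" means N increments: paths start at `X(0) = 0`
and have `N + 1` points, so the increment vector entering the ACVF has
exactly `N` terms and lags `0..N−1` are defined.

## Simulation

fGn is simulated exactly: the n×n Toeplitz covariance assembled from `γ` is
factorized by Cholesky decomposition and the lower factor multiplies a
seeded standard-normal vector. This is exact for every `H ∈ (0, 1)`
including values near 1, where circulant-embedding (Davies–Harte-type)
generators can fail on short samples; for that reason no spectral generator
is provided. On a factorization failure (possible for `H` near 1 with large
`n`) a diagonal jitter of `1e−12 · trace/n` is added and escalated tenfold
up to three times before raising. Factors are not cached across
trajectories by default — in the benchmark every trajectory has its own
`H` — but an opt-in `CholeskyCache` serves fixed-parameter Monte Carlo,
and `simulate_fgn_many` amortizes one factorization over many replicates.
The sampling interval is 1 and `D` defaults to 1 throughout.

## Estimators

**M1 (lag-1 inversion).** `γ(1) = (D/2)(2^{2H} − 2)` inverts in closed form
to `Ĥ = (1/2) log₂(2 γ̂(1)/D + 2)`. If `D` is unknown it is replaced by the
sample variance of the increments, taken as `γ̂(0)` — the divisor-`n`
mean-of-squares, consistent with the biased ACVF convention. The logarithm
is undefined when `2 γ̂(1)/D + 2 ≤ 0` (possible by sampling noise at small
`H`); such estimates are flagged `valid=False` rather than raised, and the
benchmark excludes them from MAE with reported counts (a clamp-to-boundary
mode is available for sensitivity analysis). Estimates outside `(0, 1)` are
clipped to `[1e−6, 1 − 1e−6]` with a `clipped` flag and the raw value
retained.

**M2 (least-squares ACVF fit).** Minimizes
`Σ_{τ=1}^{τmax} (γ̂(τ) − (D/2)(|τ+1|^{2H}+|τ−1|^{2H}−2|τ|^{2H}))²` over
`H ∈ (0, 1)`, default `τmax = 31`. With `D` known, lag 0 carries no
information about `H` and is omitted; with `D` estimated jointly, lag 0
enters the objective and `D` is profiled out in closed form (the model is
linear in `D`, so `D̂(H) = Σ γ̂ g / Σ g²` with `g` the unit-`D` curve,
clamped at 0), reducing the joint problem to a 1-D search. An
`include_lag0` flag overrides the convention. Because the objective can be
multi-modal for noisy ACVFs, the search partitions `(1e−6, 1 − 1e−6)` into
21 equal cells and runs a bounded derivative-free (Brent) refinement in
each with `xatol = 1e−6`, keeping the global best; exact ties (within
1e−12) resolve to the smaller `Ĥ`, deterministically. A jointly estimated
`D̂` collapsing to the zero boundary (all-zero input) marks the estimate
invalid.

**M3 (feedforward network).** A dense stack 32 → 64 → 64 → 32 → 1 (8385
trainable scalars) reads the first 32 sample-ACVF lags (lags 0–31) and
outputs `Ĥ`. Hidden layers use Swish-1, `x·σ(x)`; the output unit is a
sigmoid, so predictions lie in `(0, 1)` by construction and every M3
estimate is valid. The sigmoid is part of the trained graph rather than a
post-hoc squashing: the MSE loss is then computed on the same `(0, 1)`
scale the targets live on, which is the optimum one actually wants.
Training uses Adam at its canonical defaults (step 1e−3, moment decays
0.9/0.999, epsilon 1e−8), mini-batches of 64, and early stopping on
validation MSE (patience 3, min-delta 1e−5, max 50 epochs) with the
best-validation-epoch weights restored. Weights are initialized
Glorot-uniform from a seed and biases start at zero; given one platform,
training is bit-for-bit reproducible from the seed. Inputs are raw ACVF
values with no standardization — lag 0 then encodes the variance scale —
and the training corpus fixes `D = 1`, so the trained model assumes
`D = 1`-scaled inputs (rescale trajectories accordingly before applying it
to data with a different diffusivity). The network is implemented directly
in NumPy (forward pass, backpropagation, Adam); at this size a framework
would add nothing but a dependency, and the array implementation keeps the
training loop exactly seeded.

One model is trained jointly for all trajectory lengths; the 32-lag input
makes the length visible only through the noise level of the ACVF.

## Training corpus

Each example draws `H ~ U(0, 1)` (endpoint draws rejected), simulates an
fGn of the given length exactly, computes the biased ACVF over all lags,
and keeps the first 32. Lengths are stratified exactly. Train, validation,
and test splits use disjoint child streams spawned from one seed. The
full-scale protocol — 262,144 training and 32,768 validation/test examples
per length over lengths {32, 64, 128, 256, 512, 1024} (1,572,864 /
196,608 / 196,608 examples) — is available as a plan/manifest and for long
offline runs; per-trajectory Cholesky at n = 1024 makes materializing it a
multi-hour job on one CPU. The working default throughout the package is
the reduced protocol: the same generative conditions at 2,000 training and
500 evaluation examples per length over lengths {32, 64, 128, 256}, which
builds in seconds and trains in under a minute.

## Benchmark

For each trajectory length and replicate: draw `H ~ U(0, 1)`, simulate,
compute the ACVF, and apply each method under its lag convention — M1 at
lag 1 only; M2 over lags 1..31 with `D = 1` known; M3 on lags 0..31. The
metric is the absolute error `|Ĥ − H|`, aggregated to MAE by method,
length, and true-`H` bin with half-open edges [0, 0.2), [0.2, 0.4),
[0.4, 0.6), [0.6, 0.8), [0.8, 1); binning uses the true `H`, and the last
bin is closed at 1 by construction of the uniform draw. The default
reduced-scale benchmark runs 2,000 replicates per length over lengths
{32, 64, 128, 256} — minutes, not hours. Box-plot-style summaries are
exported as quantile tables (quantiles plus 1.5·IQR outlier counts) rather
than rendered figures.

The lag-sensitivity sweep varies the information budget: M2 is refitted
per `τmax`; M3 keeps its trained weights while lags beyond the budget are
reset to exactly zero, which makes the input tail look like the
uncorrelated `H = 1/2` regime; M1 appears only at lag 1. The sweep shares
one simulated sample per length across budgets, so the full-budget cells
coincide bit-for-bit with the plain benchmark at the same seed. The
input-size study instead retrains one network per input width on a shared
corpus and reports per-example absolute-error quantiles (quantiles of the
error distribution, labelled as such).

## What the synthetic data do and do not show

All evaluation data are exact FBM: passing benchmarks demonstrate
estimator behavior under the pure model — bias, variance, and the relative
merits of the three methods across `H` regimes and trajectory lengths.
They say nothing about robustness to measurement noise, drift,
interleaved processes, non-Gaussian heavy tails, or irregular sampling,
all of which real single-particle-tracking data exhibit; the corpus also
fixes `D = 1`, so M3's accuracy on data at other scales depends on
rescaling first. Multi-dimensional trajectories and non-Gaussian anomalous
diffusion models are out of scope.

## Numerical choices and degenerate inputs

- Estimates clipped to `[1e−6, 1 − 1e−6]`; raw values retained.
- M2 ties broken toward the smaller `Ĥ`; optimizer tolerance 1e−6.
- All-zero ACVF with joint `D` estimation → invalid, `D̂ = 0`.
- M1 with nonpositive log argument → invalid, NaN estimate, no exception.
- Cholesky jitter ladder: 1e−12·trace/n, ×10, three retries, then a
  conditioning error naming `H` and `n`.
- Trajectory and ACVF text files round-trip doubles exactly (`%.17g`);
  model files are JSON with `repr`-faithful floats, so save → load →
  predict is bitwise.
- Monte Carlo assertions in the test suite use 3–3.5 standard-error bands
  on seeded draws.

## Known limitations

- Cholesky is O(n³) per distinct `(H, n, D)`; corpus generation dominates
  at n ≥ 512. A circulant-embedding fast path was deliberately not added
  (exactness near `H = 1` takes precedence).
- No confidence intervals for `Ĥ`; the benchmark characterizes error
  distributions empirically instead.
- The reduced-scale network (8,000 training examples) is noisier than a
  full-scale one; its MAE is accordingly a conservative reading of what
  the architecture achieves, and the qualitative method ordering is the
  meaningful output.
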