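# Methods

## Problem setting and model

The inverse ECG problem seeks the transmembrane potential (TMP)
distribution on the cardiac surface from body-surface potential (BSP)
recordings. The forward map (heart → torso) is smoothing, so its inverse
is ill-posed: small measurement perturbations map to large source
errors. Instead of inverting a transfer matrix with explicit
regularization, this package learns the inverse map by regression: for
each of the N cardiac nodes, an ε-insensitive support vector regression
(ε-SVR) model maps the feature vector of a time instant's BSP pattern to
that node's potential. Regularization is implicit in the SVR capacity
parameters and in the kernel-PCA compression of the input.

An ε-SVR minimizes ½‖ω‖² + C Σ(ξᵢ + ξᵢ*) subject to the targets lying
within an ε-tube of the prediction (slacks ξ beyond it). In dual form
the prediction is f(x) = Σᵢ βᵢ K(xᵢ, x) + b with Σβᵢ = 0, |βᵢ| ≤ C, and
RBF kernel K(x, y) = exp(−‖x−y‖²/2σ²). The triple (C, σ², ε) governs the
fit–smoothness trade-off and is selected per node by a population
metaheuristic (GA, DE, or PSO) minimizing a reconstruction-error fitness
over the box C ∈ [0, 10⁴], σ² ∈ [0, 2], ε ∈ [0, 10⁻⁴].

## Pipeline stages and parameters

**Row scaling.** Every time instant's potential pattern is min-max
scaled across leads (inputs) or nodes (targets) to [0, 1], per row — the
extremes belong to the time instant, so test rows scale with their own
extremes and no training statistics are needed. Constant rows map to
zero and are flagged so unscaling restores the constant.

**Kernel PCA.** Fitted once on the scaled training BSP block and shared
by all node models. Kernel: RBF; bandwidth defaults to the median
squared pairwise training distance (median heuristic) and is
configurable; a linear-kernel mode exists to validate against classical
PCA. The top-d eigenvectors of the double-centered kernel matrix are
scaled by inverse square-root eigenvalues, so training scores have
variance λₖ/n per component; eigenvector signs are fixed by making the
largest-magnitude loading positive, for backend-independent output.
Out-of-sample rows are projected through the centered cross-kernel.
Default d: 20 at desk scale (proportional to the full-scale 412 → 200
reduction).

**SVR solver.** Sequential minimal optimization over the 2N stacked
dual multipliers with second-order working-set selection (the selection
rule of modern SMO implementations; first-order maximal-violating-pair
selection needs orders of magnitude more iterations on the
near-singular Gram matrices that large-C/large-σ² candidates produce).
Ties break to the lowest index; the bias averages the KKT-implied value
over free vectors, falling back to the violation-interval midpoint. The
solver is verified on random instances against a generic box-constrained
QP solve (SLSQP) to 1e-4 relative dual-objective agreement and against
scikit-learn's libsvm backend. `svr_train` uses KKT gap tolerance 1e-3
(the libsvm convention) by default.

**Candidate evaluation.** During hyperparameter search each candidate
trains on a precomputed squared-distance matrix (only the
exponentiation depends on σ²), with gap tolerance 1e-5 and an iteration
cap of 5000. The tighter tolerance is deliberate: the fitness signal
lives at the ε scale (≤ 1e-4 on unit targets), and a 1e-3 gap leaves
solver noise two orders of magnitude above it. The cap bounds one
evaluation to a few milliseconds at the documented problem sizes;
candidates whose solve is truncated simply score worse, which
disadvantages the slowest-converging (most ill-conditioned) region of
the box.

**Fitness.** Mean absolute percentage error, in percent. Because scaled
targets contain exact zeros (each row's minimum), the raw ratio is
undefined; the pipeline therefore evaluates on offset values (a + 1,
p + 1). The offset is configurable (`fitness_offset`); the ranking of
candidates is insensitive to its exact value. `fitness()` itself guards
against near-zero denominators and instructs callers to use offset
targets. By default the fitness is **in-sample** — the candidate is
scored on its own training rows, which is the protocol the searchers
assume. `cv_folds = k ≥ 2` switches to strided k-fold cross-validation
(folds interleave along the time axis), at k times the cost per
candidate; see "Known limitations" for why this option matters.

**Searchers.** All three operate on the unit cube internally and map to
physical bounds at evaluation; out-of-box proposals are clipped, and a
clipped C or σ² of exactly zero is nudged to 1e-6 of the range above
the bound (training degenerates at zero). Common termination: 30
generations or best fitness ≤ 0.001 (absolute), population 20.

- **GA**: 20 bits per parameter (60-bit chromosomes, linear decode),
  stochastic universal sampling interpreted as a 0.9 generation gap with
  elitism filling the remainder, two-point crossover at 0.8 on adjacent
  pairs, per-bit mutation at 0.05 (the bitstring-compatible reading of
  the named breeder-GA operator).
- **DE** (DE/best/2/bin): mutant v = x_best + F[(x_r1 − x_r2) +
  (x_r3 − x_r4)] with r1..r4 distinct and ≠ i; F drawn once per run from
  [0.5, 1]; binomial crossover (CR 0.9) with one guaranteed mutant gene.
  The best-vs-best update is applied as written; in addition each trial
  replaces its parent when not worse (standard greedy selection), since
  the population update is otherwise unspecified and a static population
  cannot explore.
- **PSO**: velocity update V ← ωV + c₁r₁(pᵢ − X) + c₂r₂(p_g − X) with
  fresh r₁, r₂ per particle per dimension per step, inertia decaying
  linearly 0.9 → 0.4, c₁ = c₂ = 2, unit time step, velocities clamped to
  ±0.5 of the range per dimension, positions clipped to the box.

Each node's search draws a dedicated generator seeded by
(run seed, node index), so runs are reproducible bit for bit and nodes
are mutually uncorrelated. Budgets: at most NP·(iterations + 1)
evaluations (GA evaluates only offspring after the initial population).

**Split protocol.** Test rows follow an arithmetic schedule (default
start 3, step 6 ms, end-inclusive); at full scale (358 instants over
0..357 ms) this yields the canonical 60 test / 298 training partition.
Desk-scale runs use step 4 over 120 instants (30/90, i.e. a 75 %/25 %
split).

**Metrics.** Per test instant over nodes: MSE, RE = ‖φ_c − φ_e‖/‖φ_e‖,
and CC. CC is standard Pearson; the alternative normalization that
centers the reconstruction by the truth mean in one factor (not a true
correlation, bounded neither below nor above by ±1) is available behind
`printed_cc=True` for comparison. Zero-variance truth rows have no
defined correlation; they are reported as NaN, excluded from m-CC, and
counted. Aggregates are means and population standard deviations over
test instants. Reports are computed in scaled units; unscaling requires
the truth row extremes and is therefore meaningful only in synthetic
(truth-available) settings.

## Synthetic data generator

The generator emulates the structure the method assumes, not the
physics. Each node's TMP course is
rest + (plateau − rest) · s((t − τ)/w_up) · s((τ + d_plateau − t)/w_rep)
with logistic s — a smooth depolarization/repolarization pulse; defaults
rest −85 mV, plateau +15 mV, upstroke width 2 ms. Activation times τ
spread linearly (plus a small jitter) over the first 40 % of the window
starting at its origin — the window opens at the first breakthrough, so
excitation is already under way at t = 0, and every instant has spatial
contrast across nodes. Plateau duration and repolarization width scale
with the window (30 % and 10 % of the span) so the full
activation–recovery cycle fits any window length.

The BSP is tmp @ Aᵀ where A = U diag(e^{−decay·k}) Vᵀ with random
orthogonal U, V; decay 0.15 gives a condition number of a few hundred at
desk scale — genuinely ill-conditioned without being numerically
hopeless. Gaussian noise is added to the BSP at a configured SNR
(default 30 dB, measured over the whole matrix).

What the generator does **not** capture: realistic torso geometry and
lead placement, spatially correlated measurement noise, pathological
excitation patterns, and the nonlinearity of real tissue. Passing tests
on this data show the regression machinery and selection protocol work
as designed; they do not certify clinical reconstruction accuracy.

Desk-scale defaults (T = 120, L = 40, N = 50) keep a full
three-optimizer comparison in the minutes range on one CPU; a
paper-scale preset (T = 358, L = 412, N = 478) reproduces the full-size
matrix shapes.

## Numerical choices

- KKT gap tolerances: 1e-3 for standalone training, 1e-5 inside
  candidate evaluation (rationale above); iteration caps 200k and 5k.
- Quadratic terms in the SMO pair update are floored at 1e-12 to guard
  division on coincident points.
- Dual coefficients below 1e-12 in magnitude are truncated to zero, so
  "support vectors" are exactly the points with nonzero β.
- Degenerate scaling rows, degenerate hyperparameters, and CC on
  zero-variance rows all follow explicit rules (zeros, worst-fitness
  sentinel, NaN + exclusion) rather than raising mid-pipeline.
- Eigenvalues are considered positive above max(λ)·1e-12; requesting
  more KPCA components than positive eigenvalues reports the achievable
  rank.

## Known limitations

**In-sample selection rewards degenerate kernels.** The default fitness
evaluates candidates on their own training rows. With ε ≤ 1e-4 on unit
targets, essentially every candidate in the box can interpolate the
training set; the in-sample optimum lies at the smallest trainable
bandwidth, where the Gram matrix is nearest to the identity and the fit
is cleanest. An efficient searcher therefore selects σ² at the repair
floor (PSO and DE reach it in a few generations, because clipping
places particles exactly on the boundary); such models predict a
constant for any test row farther than a few bandwidths from every
training row, and reconstruction quality collapses (desk-scale m-CC
≈ 0.35). The binary-encoded GA cannot represent the exact corner and
stops at the smallest bandwidth it happens to sample, which is usually
still below the scale of the test-to-train feature distances
(m-CC ≈ 0.79 at desk scale). The cross-validated fitness option repels
degenerate bandwidths and recovers near-perfect reconstruction
(m-CC ≈ 1.00, m-RE ≈ 0.02 in the worked example), at k-fold cost. The
in-sample default is kept because it is the protocol this pipeline is
defined to follow; anyone using the package for actual reconstruction
should set `cv_folds`.

**Other limitations.** The solver slows markedly on near-singular Gram
matrices (large C with wide kernels); the evaluation cap handles this
inside searches, but standalone training at such hyperparameters may
need millions of iterations for tight tolerances. Wall-clock timings
are logged but never part of any assertion. The per-node searches are
embarrassingly parallel in principle, but the implementation is
single-threaded and ordering-independent by design.
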