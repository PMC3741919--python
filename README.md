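# invecg — inverse-ECG reconstruction by metaheuristically tuned SVR

`invecg` reconstructs cardiac **transmembrane potentials (TMPs)** from
**body surface potentials (BSPs)** — the inverse ECG problem — by treating
it as multi-output regression: one ε-support-vector-regression model per
cardiac surface node, mapping each time instant's torso-surface potential
pattern to that node's membrane potential. It is aimed at researchers in
computational electrophysiology and at anyone studying metaheuristic
hyperparameter selection for kernel regression on ill-posed inverse
problems.

## The method

Given paired temporal matrices Φ_B (T × L body-surface leads) and Φ_m
(T × N cardiac nodes):

1. **Row scaling.** Each time instant's pattern is min-max scaled across
   leads/nodes: φ′ = (φ − φ_min) / (φ_max − φ_min) ∈ [0, 1].
2. **Feature extraction.** Kernel PCA (RBF kernel, median-heuristic
   bandwidth) reduces the L leads to d feature dimensions, with exact
   out-of-sample projection for test rows.
3. **Per-node regression.** For each node, an ε-SVR with RBF kernel
   f(x) = Σᵢ βᵢ K(xᵢ, x) + b, K(x, y) = exp(−‖x−y‖²/2σ²), is trained by a
   sequential-minimal-optimization dual solver (second-order working-set
   selection, verified against a generic QP oracle).
4. **Hyperparameter search.** The triple (C, σ², ε) ∈ [0, 10⁴] × [0, 2] ×
   [0, 10⁻⁴] is selected per node by one of three population searchers —
   a binary-encoded **genetic algorithm** (stochastic universal sampling,
   two-point crossover 0.8, bit mutation 0.05), **differential evolution**
   DE/best/2/bin (F ∈ [0.5, 1], CR 0.9), or **particle swarm
   optimization** (linearly decaying inertia 0.9 → 0.4, c₁ = c₂ = 2) —
   each with population 20, at most 30 generations, fitness tolerance
   0.001. The fitness is the mean absolute percentage error of the
   candidate's reconstruction (in-sample by default; a k-fold
   cross-validated option exists, see below).
5. **Evaluation.** Per test instant, over nodes: MSE, relative error
   RE = ‖φ_c − φ_e‖/‖φ_e‖, and Pearson correlation CC, summarized as
   means (m-MSE, m-RE, m-CC) and standard deviations over the test
   schedule.

Because no heart-torso simulation data ships with the package, a
**synthetic generator** produces datasets with the structure the method
assumes: smooth action-potential-like TMP time courses (rest −85 mV,
plateau +15 mV, staggered activation) pushed through a linear transfer
matrix with exponentially decaying singular spectrum (the
ill-conditioning that makes the inverse problem hard), plus Gaussian
noise at a configurable SNR.

## Worked example

`examples/04_full_reconstruction.py` trains two PSO-tuned model banks on
the same synthetic dataset (120 instants, 40 leads, 20 nodes, 30 dB SNR,
75 %/25 % split) and prints:

```
in-sample fitness (paper protocol):
  selected sigma^2: median 2.00e-06 (range 2.00e-06 .. 2.00e-06)
  m-MSE 0.1285  m-RE 0.669  m-CC 0.346

5-fold cross-validated fitness:
  selected sigma^2: median 1.68e-01 (range 1.03e-01 .. 2.36e-01)
  m-MSE 0.0002  m-RE 0.020  m-CC 1.000
```

The contrast is the package's central caveat: scoring candidates on
their own training residuals rewards vanishing kernel bandwidths (any
narrow-kernel interpolator fits the training rows to within ε), so an
efficient searcher selects models that memorize and cannot generalize —
m-CC 0.346 means the reconstructed spatial patterns barely correlate
with the truth. Scoring the same candidates on held-out folds
(`RunConfig(cv_folds=5)`) selects moderate bandwidths and reconstructs
the test instants almost perfectly. See `docs/methods.md` for the full
analysis.

Other examples: `01_generate_dataset.py` (synthetic data and file I/O),
`02_scaling_kpca_svr.py` (the processing stages one by one),
`03_hyperparameter_search.py` (the three searchers on one tuning
problem).

A thin CLI wraps the same pipeline:

```bash
invecg simulate demo/ && invecg train demo/ bank/ && \
invecg reconstruct demo/ bank/ recon.csv && invecg evaluate demo/ recon.csv
```

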