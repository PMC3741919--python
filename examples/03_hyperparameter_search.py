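"""The three metaheuristic searchers on one SVR tuning problem.

All three optimize the same 3-D box (C in [0, 1e4], sigma^2 in [0, 2],
epsilon in [0, 1e-4]) with population 20 and at most 30 generations. The
evaluator here scores candidates by 5-fold cross-validation so the
fitness reflects generalization rather than training-set fit.
"""

import numpy as np

from invecg import RunConfig, generate_dataset, kpca_fit, kpca_transform, scale_rows
from invecg.optimizers import de_search, ga_search, make_svr_evaluator, pso_search

ds = generate_dataset(T=120, L=40, N=50, snr_db=30.0, seed=0)
bsp_scaled, _ = scale_rows(ds.bsp)
tmp_scaled, _ = scale_rows(ds.tmp)
features = kpca_transform(kpca_fit(bsp_scaled, d=20), bsp_scaled)
target = tmp_scaled[:, 25]

evaluator = make_svr_evaluator(features, target, cv_folds=5)
for name, fn in [("GA", ga_search), ("DE", de_search), ("PSO", pso_search)]:
    cfg = RunConfig(optimizer=name.lower(), seed=0)
    res = fn(cfg, evaluator)
    hp = res.best
    print(f"{name:>3}: best CV fitness {res.best_fitness:.4f}%  "
          f"(C={hp.C:.1f}, sigma2={hp.sigma2:.4f}, eps={hp.epsilon:.2e})  "
          f"{res.generations} generations, {res.evaluations} model fits")
    drop = res.trajectory[0] - res.trajectory[-1]
    print(f"     trajectory: {res.trajectory[0]:.4f}% -> {res.trajectory[-1]:.4f}% "
          f"(improvement {drop:.4f} percentage points, never increasing)")
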