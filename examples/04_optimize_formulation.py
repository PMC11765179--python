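"""Optimize (shear rate, A, G, T) against the structural-integrity window.

A random-forest surrogate predicts ln-viscosity; differential evolution
minimizes the squared deviation from the window midpoint (ln 12.32,
i.e. ~224 Pa.s) plus an out-of-window penalty.  Two scenarios: free
search, and shear rate constrained to at least 50 1/s (nozzle-tip
conditions), where the window is unreachable.
"""

import numpy as np

from bioinkflow import datasets
from bioinkflow.optimize import SearchBounds, optimize_formulation
from bioinkflow.surrogates import fit_forest, log_target

dataset = datasets.generate_dataset(noise_sigma=0.05, seed=42)
X, y = log_target(dataset)
forest = fit_forest(X, y, seed=7)
bounds = SearchBounds.from_dataset(dataset)

for scenario in ("free", "highshear"):
    res = optimize_formulation(forest, bounds, scenario=scenario, seed=0)
    o = res.optimum
    print(f"{scenario}:")
    print(f"  optimum: shear_rate={o['shear_rate']:.2f} 1/s, "
          f"A={o['A']:.2f}%, G={o['G']:.2f}%, T={o['T']:.2f}%")
    print(f"  ln(viscosity) = {res.eta_pred:.3f} "
          f"({np.exp(res.eta_pred):,.0f} mPa.s), "
          f"{'in window' if res.in_window else 'OUT of window'}; "
          f"F = {res.F:.4f} after {res.generations} generations")
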