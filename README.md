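# bioinkflow

Rheology-informed formulation design for alginate/gelatin/TO-NFC
bioinks: regenerate flow-curve datasets from characterized
shear-thinning parameters, fit Cross and Herschel–Bulkley models, train
viscosity surrogates, and optimize printable formulations with
differential evolution.

## The science in one paragraph

Extrusion bioprinting needs inks that flow through a nozzle but hold
their shape afterwards. The hydrogels modeled here mix alginate (A),
gelatin (G) and TEMPO-oxidized nano-fibrillated cellulose (T) at a
fixed 8 wt% total solids; they are strongly shear-thinning, with
viscosities falling three decades between rest and nozzle-tip shear
rates. Flow curves are described by the Cross model
`eta = eta_inf + (eta_0 − eta_inf)/(1 + (t·γ̇)^m)` and stress curves by
Herschel–Bulkley `tau = tau_0 + K·γ̇^n`. Structural integrity after
printing corresponds to a viscosity window of roughly 100–500 Pa·s —
ln 11.52 to 13.12 in mPa·s. `bioinkflow` regenerates the measurement
dataset from the eight characterized compositions, learns surrogate
models of ln-viscosity over (shear rate, A, G, T), and searches that
space for formulations whose predicted viscosity lands in the window.

## Quick start

Everything is available both as a library and through the `bioinkflow`
CLI:

```bash
bioinkflow generate --seed 42 --out flow_curves.csv
bioinkflow fit-rheology --in flow_curves.csv --out fits.json
bioinkflow train --in flow_curves.csv --model forest --seed 7 --out forest.json
bioinkflow evaluate --in flow_curves.csv --model forest --iterations 100
bioinkflow optimize --model forest.json --data flow_curves.csv --scenario free
bioinkflow printability --fw 0.58 --nd 0.41 --perimeter 3.8 --area 0.82
bioinkflow pipeline run --seed 0 --out run/
```

The `examples/` directory contains one narrative script per capability
(`01_generate_dataset.py` … `06_pipeline.py`).

## Worked example

Train the three surrogates and compare them by repeated 80/20 holdout
(`examples/03_train_surrogates.py`, 20 iterations shown; the full
protocol uses 100):

```text
AIC-selected polynomial degree: 4
CV-selected tree depth: 6
poly     mean R2 = 0.8980  mean MAE = 0.3309 (134/34 split)
tree     mean R2 = 0.9747  mean MAE = 0.1734 (134/34 split)
forest   mean R2 = 0.9854  mean MAE = 0.1273 (134/34 split)
forest importance ranking: ['shear_rate', 'G', 'T', 'A']
```

Then optimize the formulation against the integrity window
(`examples/04_optimize_formulation.py`):

```text
free:
  optimum: shear_rate=3.08 1/s, A=2.00%, G=3.00%, T=1.00%
  ln(viscosity) = 12.320 (224,149 mPa.s), in window; F = 0.0000 after 52 generations
highshear:
  optimum: shear_rate=50.00 1/s, A=5.13%, G=2.21%, T=0.85%
  ln(viscosity) = 10.545 (37,987 mPa.s), OUT of window; F = 4.1257 after 16 generations
```

The unconstrained search hits the window midpoint (ln 12.32 ≈ 224 Pa·s)
exactly; constrained to nozzle-tip shear rates (≥ 50 1/s) the best
attainable ink is an order of magnitude too thin and is correctly
reported out-of-window — the physical reason these inks rely on rapid
post-extrusion structural recovery rather than in-nozzle viscosity.

Noiseless round-trip of the rheological fits
(`examples/02_fit_rheology.py`) recovers every generating parameter
row, e.g. zero-shear viscosity 4,182,705 mPa·s and flow index 0.22 for
the A5G2T1 system.

## What's inside

| Module | Contents |
| --- | --- |
| `bioinkflow.datasets` | canonical parameter sets, Cross/Herschel evaluation, synthetic flow-curve generation, CSV contract |
| `bioinkflow.rheology` | Cross and Herschel–Bulkley least-squares fitting, adjusted R², three-interval thixotropic recovery |
| `bioinkflow.surrogates` | polynomial response surface with AIC order selection; hand-written CART regression tree with CV depth selection; bagged random forest with feature importances; repeated-holdout evaluation |
| `bioinkflow.optimize` | penalty-constrained rand/1/bin differential evolution, free and high-shear scenarios |
| `bioinkflow.printability` | diffusion rate, pore circularity/printability, gelatin/(alginate×TO-NFC) descriptor |
| `bioinkflow.pipeline` | seeded five-stage pipeline with persisted artifacts and a text report |

The regression tree, random forest and differential evolution are
implemented from scratch (scikit-learn and scipy appear in the test
suite only, as cross-check oracles). See `docs/methods.md` for the
numerical choices, a documented deviation on forest feature
subsampling, and known limitations — including why the degree-4
polynomial's holdout R² is structurally capped by the 8-point
composition design.

## Reproduction

```bash
python -m pytest -q tests/          # full suite incl. acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per headline claim
(parameter recovery, surrogate performance, both optimization
scenarios, worked values, structural properties). The surrogate
performance test states target levels of 0.95 (polynomial) and 0.99
(forest) mean holdout R²; the observed values on the default dataset
are ≈0.88 and ≈0.985, so that test currently fails by design rather
than having its thresholds loosened — the gap is analyzed in
`docs/methods.md`. The acceptance script recomputes the five numeric
targets (gelatin ratio, both scenario ln-viscosities, recovered
zero-shear viscosity and flow index) from scratch for any seed.

All randomness flows from explicit seeds; two pipeline runs with the
same config are byte-identical.
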