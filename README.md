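# bindfit

Equilibrium and kinetic analysis of ligand-receptor binding under
reactant depletion: exact competitive-binding equilibria, 1:1 biosensor
kinetics, steady-state Hill fits, IC50 → K_i conversion, displacement
model fitting with bootstrap confidence intervals, and a fully seeded
synthetic-experiment generator.

The package is written for quantitative binding experiments in which a
soluble ligand (e.g. a disulfide-linked growth-factor dimer) binds a
membrane receptor presented in nanodiscs, measured by biolayer
interferometry (BLI) and by bead-based competition assays. At the
concentrations these assays require, bound material is a large fraction
of total, so classical "free ≈ total" isotherms and the bare
Cheng-Prusoff conversion are biased; every model here is solved at exact
mass action.

## Models

**Ligand-depletion isotherm** — bound-site fraction for totals A
(ligand sites), R (receptor) and constant K_A:

Y₀ = (A + K_A + R − √((A + K_A + R)² − 4AR)) / (2A)

**Exact competitive three-species solution** — fraction of ligand sites
receptor-bound vs competitor concentration X, via the trigonometric root
of the governing cubic (h, k, l, t as in `docs/methods.md`):

Y(X) = (2√(h²−3k)·cos(t/3) − h) / (3K_A + 2√(h²−3k)·cos(t/3) − h)

**Allosteric ternary-complex model** — a modulator binding the ligand
rescales its receptor affinity by a cooperativity factor α (> 1 =
negative cooperativity), producing displacement to a *non-zero* plateau
equal to the depletion isotherm with K_A → α·K_A.

**1:1 Langmuir kinetics** — R(t) = R_eq(1 − e^(−K_obs t)) with
K_obs = K_on·C + K_off; K_on from the K_obs-vs-C line, K_off from
R²-filtered single-exponential decay fits, kinetic K_D = K_off/K_on.

**Hill steady state** — B_max·cʰ/(cʰ + K_Dʰ), with K_D the
half-saturation concentration for any slope h.

## Worked example

Simulate a depletion-level displacement experiment (64 nM ligand sites,
50 nM receptor, K_A = 10.4 nM, competitor K_B = 1060 nM, triplicate on a
0-100 µM grid) and refit it:

```python
import numpy as np
from bindfit import (CompetitionSystem, ExperimentDesign,
                     bound_fraction_no_competitor, fit_competition_model,
                     generate_competition, kinetic_kd)

truth = CompetitionSystem(a_total=64, r_total=50, ka=10.4, kb=1060)
print(f"bound fraction, no competitor: {bound_fraction_no_competitor(truth):.4f}")

design = ExperimentDesign(mode="competition", system=truth,
                          noise_sd=0.05, n_replicates=3, seed=101)
res = fit_competition_model(generate_competition(design), truth,
                            "competitive", n_boot=300, seed=7)
lo, hi = res.kb_ci
print(f"K_B = {res.kb/1e3:.2f} uM  (95% CI {lo/1e3:.2f}-{hi/1e3:.2f} uM)")

kd, sem = kinetic_kd(kon=0.00019, koff=0.0014, kon_sem=3e-5, koff_sem=1.6e-4)
print(f"kinetic K_D = {kd:.1f} +/- {sem:.1f} nM")
```

Output:

```
bound fraction, no competitor: 0.5678
K_B = 1.05 uM  (95% CI 0.63-1.66 uM)
kinetic K_D = 7.4 +/- 1.4 nM
```

The first line says that at this composition roughly half the ligand is
receptor-bound before competitor is added (the intended assay window).
The fitted K_B interval comfortably covers the generating 1.06 µM, and
the kinetic K_D combines the rate constants with quadrature-propagated
SEM.

A command-line interface wraps the same pipelines:

```bash
bindfit simulate --mode bli_kinetic --out traces.csv --seed 1
bindfit fit-kinetics --traces traces.csv --out kinetics.json
bindfit fit-competition --data comp.csv --a-total 64 --r-total 50 \
        --ka 10.4 --seed 7 --out fit.json
bindfit compare-models --data comp.csv --a-total 64 --r-total 50 \
        --ka 10.4 --out verdict.json
```

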