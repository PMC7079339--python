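# cisi

Tumor–immune interaction modeling: three nested ODE models (base,
saturating proliferation/exhaustion, NK+CTL), their full analytic
equilibrium and bistability/multistability apparatus, and a stochastic
tau-leaping simulator of combination immunotherapy (permanent
killing-efficacy ramp plus adoptive effector-cell transfer).

## What's inside

| module | purpose |
|---|---|
| `cisi.models` | immutable parameter containers, deterministic RHS of all three models, named presets (`table1`, `fig2`, `saturation_default`, `nkctl_default`) |
| `cisi.equilibria` | closed-form quadratic/cubic fixed points, numeric quintic fixed points (NK+CTL), killing-efficacy thresholds `k_l`/`k_u`, regime classification, cubic discriminant + trigonometric bistability/multistability conditions with numeric fallback, Jacobian-eigenvalue stability |
| `cisi.bifurcation` | 1-D parameter sweeps into branch tables, bifurcation-interval detection |
| `cisi.stochastic` | six-reaction birth/death decomposition of the base model, adaptive tau-leaping with midpoint propensity evaluation, critical-reaction exact firing and SSA fallback; replicate mean ± sd |
| `cisi.therapy` | treatment schedules (daily efficacy increments, daily transfer boluses), treated runs, combination dose-grid experiments |
| `cisi.config` / `cisi.cli` | YAML parameter/run configs, CSV + JSON-sidecar outputs, figure-data regeneration, `cisi` command-line tool |

States are in cells, time in days.  Stochastic states are integer counts,
so "cancer cleared" means exactly `T == 0` (an absorbing state).

## CLI

```bash
# all fixed points with stability for a preset or YAML parameter file
cisi equilibria --preset fig2 --out equilibria.csv
cisi equilibria --params my_params.yaml --out equilibria.csv

# killing-efficacy branch table (machine form of the bifurcation diagram)
cisi bifurcation --preset fig2 --sweep k --min 1e-4 --max 15 --n 200 --out branches.csv

# one seeded stochastic trajectory
cisi simulate --preset table1 --init 100,1000 --tmax 80 --seed 1 --out traj.csv

# single-day combination-therapy dose grid (120-day outcome)
cisi grid --preset table1 --reps 5 --seed 1 --out grid.csv

# regenerate the data behind a named figure (fig2|fig3a|fig3b|fig4)
cisi figure fig3b --out-dir figures --seed 1
```

Every output CSV gets a `<name>.meta.json` sidecar carrying the fully
resolved configuration and seed; deterministic operations re-run from the
sidecar reproduce the file bit-identically.

Parameter files are flat YAML: a `model: base|saturation|nkctl` key plus
the model's named rates (see `src/cisi/data/*.yaml` for the shipped
presets).  Note the two base-model presets differ only in the effector
death rate (`table1`: d = 1e-2, `fig2`: d = 2e-2); both are shipped
deliberately and not reconciled.  The saturation and NK+CTL presets are
documented plausible defaults (the canonical supplementary values are not
available) chosen in the exhaustion-dominated, bistable-capable regime.

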