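# admodel

Analysis toolkit for a five-species kinetic model coupling amyloid
aggregation to neuroinflammation: monomers (`m`), free oligomers (`u`),
plaque-bound oligomers (`up`), microglia (`M`) and interleukins (`I`).
Interleukins stimulate monomer production, oligomers activate microglia and
trigger a stress shutdown of production, and monomers are cleared at rate
`d` — the bifurcation parameter. For `d` below a critical value
`d_c ≈ 0.478` months⁻¹ (default parameter set) the system is bistable: a
disease-free equilibrium coexists with a stable "persistent" equilibrium,
and the outcome depends on the initial inflammation or monomer load
(hysteresis).

The package provides:

- `model_core` — parameters, state, the stress/recruitment functions and
  the ODE right-hand side;
- `equilibria` — full steady-state enumeration via a scalar reduction to
  the monomer axis (`F(m) = P(m) + d`), and the critical rate
  `critical_d = max (F − P)`;
- `stability` — analytic Jacobian and eigenvalue classification;
- `dynamics` — stiff-capable time integration (`scipy` LSODA, rtol 1e-8)
  and asymptotic-outcome labelling (`disease-free` / `persistent` /
  `undecided`);
- `hysteresis` — bifurcation branch tracing over a `d` grid,
  basin-boundary bisection of the critical initial interleukin/monomer
  level, and outcome-grid rasterization;
- `cli_io` — presets (`table2` parameters, `table3`/`table4` initial
  conditions), YAML/JSON config loading, deterministic CSV output with a
  JSON config sidecar, and the `admodel` CLI.

## CLI

```sh
# one trajectory (CSV: time,u,up,m,M,I)
admodel simulate --d 0.15 --I0 0.4 --t-end 2000 --out traj.csv

# steady states + stability at one d
admodel equilibria --d 0.15 --out eq.csv

# equilibrium branches over a d grid (bifurcation diagram data)
admodel bifurcate --d-min 0.02 --d-max 0.6 --d-steps 30 --out branch.csv

# outcome grid over (d, I0) or (d, m0), plus the bisected threshold curve
admodel basin --axis I0 --out basin.csv
```

Shared flags: `--preset` (parameter preset), `--param key=value`
(repeatable override), `--out`, `--plot` (PNG next to the CSV),
`--log-level`. Every run writes a `<out>.json` sidecar with the fully
resolved configuration; pipelines are deterministic, so identical configs
produce byte-identical outputs.

## Library

```python
from admodel import critical_d, find_steady_states, classify, classify_outcome
from admodel.cli_io import resolve_parameters, resolve_initial

p = resolve_parameters("table2", {"d": 0.15})
print(critical_d(p))                      # ~0.478
for eq in find_steady_states(p):          # disease-free + 2 positive
    print(eq.kind, eq.state, classify(eq, p).label)

init = resolve_initial("table3", {"I": 0.4})
print(classify_outcome(init, p))          # "persistent"
```

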