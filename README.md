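# schizocua

A Markov cohort cost-utility model comparing three antipsychotic treatment
strategies for schizophrenia — a 1-monthly long-acting injectable (PP1M), a
3-monthly long-acting injectable (PP3M), and an extended-release oral (ER) —
from a healthcare-system perspective, with base-case, one-way, probabilistic
and scenario analyses.

## Model

Five health states: non-stable, stable/adherent, stable/non-adherent,
relapse (a one-cycle tunnel back to non-stable), and death (absorbing).
3-month cycles over a 20-year horizon, half-cycle correction, 5%/year
discounting with a mid-cycle exponent, cohort entry in the non-stable state
at age 38. Death is an age-banded competing risk applied first each cycle;
published transition probabilities are conditional on survival.

Two interpretation decisions that materially shape results (both
configurable, see `ModelConfig`):

- **Utilities are per-cycle QALY weights** — 0.23/cycle stable (0.92/year)
  and 0.15/cycle non-stable/relapse (0.60/year). Scaling by cycle length in
  years instead would divide all QALY totals by four.
- **Relapse costing** (`relapse_hospitalization_policy`) defaults to
  `"never"`: the relapse state accrues non-stable outpatient cost only.
  Setting `"always"` adds one full hospital admission per relapse cycle.

## CLI

All commands accept `--config <yaml>` (defaults to the embedded reference
parameter set) and write CSV artifacts plus a `manifest.json` into `--out`.

```sh
schizocua base-case --out results/base          # totals, comparisons, traces
schizocua tornado --out results/tornado         # one-way sensitivity
schizocua psa --n 1000 --seed 1 --out results/psa
schizocua ceac --n 1000 --seed 1 --out results/ceac
schizocua scenarios --out results/scenarios     # price / hospitalization / horizon
schizocua icer-by-cycle --out results/cycles
schizocua convert --rate 0.1119 --window-months 12 --cycle-months 3
schizocua generate-synthetic --seed 7 --out synthetic.yaml
schizocua export-reference --out reference.csv --yaml-out reference.yaml
```

Add `--plots` to render PNG charts (tornado bars, acceptability curves,
incremental scatter with the WTP line, scenario lines) from the CSVs.

## Library sketch

```python
import schizocua as sc

arms, config = sc.load_reference_parameters()
results = {name: sc.run_cohort(arm, config)[1] for name, arm in arms.items()}
comparison = sc.compare(results["PP3M"], results["ER"])
print(comparison.icer, sc.wtp_verdict(comparison, config.wtp_per_qaly).verdict)

psa = sc.run_psa(arms, config, n_iterations=1000, seed=1)
curve = sc.ceac(psa.samples, range(0, 40_001, 1000), "PP3M_vs_ER")
```

Module map: `parameters` (types, conversions, reference fixture,
validation), `markov` (transition matrices, cohort trace, accrual,
microsimulation oracle), `economics` (ICER, dominance, NMB, WTP verdicts),
`sensitivity` (tornado, PSA, CEAC, scenarios), `synthetic` (random/degenerate
parameter sets for property testing), `config_io` + `cli` + `plots`
(strict YAML schema, commands, charts).
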