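# prophycea

Cost-effectiveness model for antifungal **prophy**laxis — a hybrid
decision-tree + Markov cohort analysis comparing posaconazole (oral
suspension and tablets) against first-generation triazoles
(fluconazole/itraconazole) for preventing invasive fungal infections
(IFIs) in high-risk hematological-malignancy patients (AML/MDS under
chemotherapy), from a healthcare-payer perspective in 2020 USD.

Intended users: health-economics and HTA analysts who want a scriptable,
testable re-implementation of this class of prophylaxis model — base
case, one-way deterministic sensitivity analysis (tornado),
probabilistic sensitivity analysis (PSA) with cost-effectiveness
acceptability curves (CEAC), and willingness-to-pay (WTP) scenario
sweeps — rather than a point-and-click tree package.

## The model

A decision tree covers the first 100 days: with strategy-specific IFI
probability *p*, the four terminal states are death from IFI
(*p* · *p*<sub>d,IFI</sub>), survival after IFI, death from other
causes, and IFI-free survival. Expected costs are drug acquisition
(Σ weight × daily cost × duration) plus IFI management
(*p* × unit cost); costs are undiscounted (all fall within 100 days).
Survivors enter a two-state Markov model with monthly cycles: the
subgroup 5-year survival *S*₅ becomes a constant monthly death
probability 1 − *S*₅^(1/60), the trace uses a trapezoidal half-cycle
correction, and benefits are discounted at 5%/year. Per strategy,

&nbsp;&nbsp;LY = LY₀ + *f*<sub>surv</sub> · LY<sub>Markov</sub>,&nbsp;
QALY = *u*₀ LY₀ + *f*<sub>surv</sub> · *u*<sub>rem</sub> LY<sub>Markov</sub>,

and the incremental cost-effectiveness ratio ICER = ΔCost/ΔQALY is
judged against WTP = 3 × GDP per capita ($31,315/QALY nationally). PSA
draws every input from Beta/Gamma distributions moment-matched to its
base value and range (read as a 95% interval) or uniformly on the range,
and judges cost-effectiveness per iteration by incremental net monetary
benefit (WTP × QALY − cost). See `docs/methods.md` for conventions,
assumptions and limitations.

## Worked example

```bash
prophycea basecase --out-dir out
```

```
                                first_generation_triazoles  posaconazole_suspension  posaconazole_tablet
Total costs ($)                                    616.000                 1571.000             3729.200
Drug costs for prophylaxis ($)                      15.500                 1321.200             3479.400
IFI management costs ($)                           600.600                  249.800              249.800
LYs                                                  4.176                    4.266                4.266
QALYs                                                3.416                    3.491                3.491
Incremental costs ($)                                  NaN                  955.000             3113.100
Incremental LYs                                        NaN                    0.090                0.090
Incremental QALYs                                      NaN                    0.075                0.075
ICER ($/LY)                                            NaN                10611.100            34591.700
ICER ($/QALY)                                          NaN                12784.400            41676.700
```

Reading the suspension column: prophylaxis costs $1,321.2 in drug
acquisition but, by preventing IFIs, cuts expected IFI-management costs
to $249.8 (vs $600.6 for the comparator) — a net extra spend of $955 per
patient buying 0.075 extra QALYs, i.e. an ICER of ≈ $12,784/QALY, well
below the $31,315/QALY threshold: the suspension is cost-effective. The
tablet formulation (same efficacy, higher price) lands above the
national threshold under these conventions. The `NaN` cells are the
reference column, which has no incremental results by construction.

```bash
prophycea psa --seed 11 --iterations 1000 --out-dir out
# probability cost-effective at $31,315/QALY (1000 iterations, seed 11): 0.960
```

Other subcommands: `dsa` (tornado CSV, `--plots` for a PNG), `scenario
--formulation tablet --provinces provinces.csv` (province-level WTP
sweep), `synth trial` / `synth provinces` (synthetic inputs),
`params-export` (editable YAML config; pass it back with `--config`).
Every run writes a `run_record.json` with the config digest and seed, so
any output can be reproduced exactly.

As a library:

```python
from prophycea import (default_parameters, base_case_draw,
                       builtin_strategies, evaluate_strategy,
                       compare_strategies)

params, settings = default_parameters()
draw = base_case_draw(params)
s = builtin_strategies(settings)
ref = evaluate_strategy(s["first_generation_triazoles"], draw, settings)
alt = evaluate_strategy(s["posaconazole_suspension"], draw, settings)
print(compare_strategies(ref, alt).icer_per_qaly)  # 12784.42...
```

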