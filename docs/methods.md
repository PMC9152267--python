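# Methods

## The decision problem

`prophycea` estimates the cost-effectiveness, from a healthcare-payer
perspective, of antifungal prophylaxis with posaconazole (oral suspension
or tablets) against first-generation triazoles (fluconazole/itraconazole)
in patients with acute myelogenous leukemia (AML) or myelodysplastic
syndrome (MDS) undergoing chemotherapy, who are at high risk of invasive
fungal infection (IFI). It reports total costs (2020 USD), life-years
(LY), quality-adjusted life-years (QALYs), and incremental
cost-effectiveness ratios (ICERs, $ per QALY or per LY) of each
posaconazole formulation against the first-generation comparator, judged
against a willingness-to-pay (WTP) threshold of three times GDP per
capita ($31,315/QALY nationally; province-level thresholds in the
scenario analysis).

## Model structure

The model is a hybrid of two components.

**Decision tree (first 100 days).** Each patient receives prophylaxis and
either develops an IFI (probability `p_ifi`, strategy-specific) or not.
Four terminal states follow: death from IFI, death from other causes,
survival after an IFI, and survival without an IFI. Two topologies are
implemented:

- `exclusive` (default): the two causes of death are mutually exclusive
  branches — an IFI case dies of IFI with probability `p_death_ifi` or
  survives; a non-IFI patient dies of other causes with probability
  `p_death_other` or survives. Survivor fraction:
  `p_ifi (1 − p_death_ifi) + (1 − p_ifi)(1 − p_death_other)`.
- `nested`: every patient not dying of IFI — including IFI survivors — is
  additionally exposed to other-cause death. Survivor fraction:
  `(1 − p_ifi · p_death_ifi)(1 − p_death_other)`.

The source results tables are slightly *better* reproduced by the
`nested` topology (the ratio of the two arms' survivor fractions implied
by the printed LY rows is ≈ 1.033; `nested` gives 1.030, `exclusive`
1.023), but the published four-outcome description is ambiguous and the
model diagram is not machine-readable, so the package defaults to the
plainer `exclusive` reading and exposes the choice as
`ModelSettings.tree_topology`.

Costs are fully contained in the tree: expected drug-acquisition cost
(Σ weight × daily cost × duration over the regimen's components) plus
expected IFI management cost (`p_ifi ×` unit treatment cost, attached to
IFI occurrence whether or not the patient later dies — this is what
reproduces the printed cost cells). Costs are never discounted, since
all of them fall inside the first 100 days. Adverse-event and
primary-disease treatment costs are out of scope.

All patients accrue the full 100-day initial period (100/365.25 years,
weighted by the induction-phase utility 0.648) regardless of in-period
death; `ModelSettings.initial_accrual = "half_for_decedents"` switches to
a half-period accrual for decedents.

**Markov model (lifetime).** Survivors of the first 100 days enter a
two-state (alive/dead) cohort model with one-month cycles. The 5-year
relative survival of each subgroup (0.44 AML, 0.52 MDS) is converted to a
constant monthly death probability `1 − S₅^(1/60)` and extrapolated
unchanged beyond five years — no cure point and no background life-table,
a deliberate choice because the small published life expectancies
(4.3–4.5 LY) are consistent only with a persistently high hazard. The
trace uses a trapezoidal half-cycle correction (half weight on the first
and last cycle). Life-years are discounted at 5%/year, compounded
monthly (`v = 1.05^(−1/12)`), with the clock starting at Markov entry;
QALYs weight each cycle by the remission utility 0.830. The cohort is a
0.86 : 0.14 AML : MDS mixture. The horizon is 600 cycles (50 years), by
which point under base-case hazards < 0.15% of the entering cohort is
alive; doubling the horizon moves base-case life expectancy by
≈ 2 × 10⁻⁴ years, well below the 0.001 reporting precision.

**Totals.** Per strategy: `LY = initial + survivor_fraction ×
per-survivor Markov LY`, and analogously for QALYs with the respective
utilities. ICERs are computed from unrounded internal deltas; rounding
(0.1 USD, 0.001 LY/QALY) is applied only in the report table.

## Inputs

All inputs live in `parameters.default_parameters()` and can be
overridden through a YAML config (`prophycea params-export` writes the
defaults). Probabilities whose published values derive from trial counts
(IFI occurrence 14/304 with posaconazole, 33/298 with first-generation
triazoles; IFI mortality pooled across arms, 21/47) carry those counts
and use the unrounded fractions in the base case — this is what makes
the published IFI-management cost cells ($249.8 / $600.8) come out
exactly; setting a rounded `base` in the config restores the 3-decimal
behaviour. Other-cause mortality (0.158) has no published counts.

Regimens: posaconazole suspension $45.56/day × 29 days; tablets
$119.98/day × 29 days (the flat daily price reproduces the printed
$3,479.4, so the day-1 loading dose is not costed separately);
fluconazole $0.26/day × 24 days and itraconazole $1.89/day × 29 days
blended 0.81 : 0.19. The fluconazole share is a structural setting (the
source text states both 81% and 89%; 0.81 reproduces the printed $15.5
blend cost and is the default). IFI treatment costs $5,423.3 per case.
CNY amounts are converted at ¥689.76 per $100.

## Sensitivity analyses

**One-way (tornado).** Each of the 17 tunable inputs is moved to the ends
of its stated range (base ± 25% when no range is stated, utilities capped
at 1; the discount rate uses its stated 0–8% range) with everything else
at base, and the suspension-vs-comparator ICER is recorded at both ends.
Bars are sorted by width, ties broken alphabetically. Structural
constants (cohort shares, horizon, WTP) are not varied.

**Probabilistic (PSA).** 1,000 Monte Carlo iterations by default, each
drawing every parameter independently from its fitted distribution and
running the full tree + Markov pipeline. Distribution families follow
the input table: Uniform rows sample uniformly on [low, high]; Beta and
Gamma rows are moment-matched so the analytic mean equals the base value
and the standard deviation equals (high − low)/3.92, i.e. the range is
read as a 95% interval (for Beta: `k = m(1−m)/σ² − 1`, `α = mk`,
`β = (1−m)k`; for Gamma: shape `m²/σ²`, scale `σ²/m`). Sampled
probabilities and utilities are clipped to [0, 1]; a degenerate range
collapses to a point mass. Cost-effectiveness at a WTP threshold is
judged per iteration by incremental net monetary benefit
(`NMB = WTP × QALY − cost`), which stays well defined when the QALY
difference is non-positive; the acceptability curve (CEAC) evaluates
this on a WTP grid of 0–60,000 in steps of 250.

## Synthetic data

`synthetic_data` generates the two inputs the analysis consumes that are
not printed constants: (i) two-arm trial counts at the published arm
sizes (304 / 298) — IFI events binomial per arm, IFI deaths binomial
among the simulated cases, other-cause deaths binomial among the
remainder (hierarchical, mirroring how the published probabilities
nest); (ii) uniform province GDP-per-capita tables for WTP sweeps.
`estimate_parameters` recovers the four tree probabilities from counts,
pooling both mortalities across arms exactly as the published analysis
does, and flags any estimate whose denominator is zero.

What the generator does *not* emulate: per-patient follow-up times,
censoring, non-binomial overdispersion, correlated arm outcomes, and
real province GDP values. Passing recovery tests therefore demonstrate
internal statistical consistency of the estimator/model pair, not
fidelity to any particular real-world dataset.

## Reproduction status and known limitations

- The 100-day cost arithmetic reproduces all printed cells to well
  within 0.5% (most exactly at printed rounding).
- The lifetime LY/QALY rows and hence the ICERs depend on conventions
  the source analysis does not state (survival-to-hazard conversion,
  horizon, discount timing, tree nesting). Under this package's
  documented defaults the suspension ICER is ≈ $12,800/QALY against the
  printed $8,784.4 — the same side of every decision threshold, but not
  a numeric match; the `nested` topology moves it to ≈ $9,300/QALY.
  These rows are therefore checked as structural properties (positive
  incremental QALYs, ICER below the national WTP, exact drug-cost
  consistency between the two formulations), not as numeric equalities.
- Problem sizes used by the test suite and the acceptance script: 600
  Markov cycles, 1,000 PSA iterations (10,000 for distributional
  checks), 500 trial-simulation replicates — each chosen so the relevant
  Monte-Carlo error is far below the quantity being checked.
- Single cohort, no age structure, no background mortality, constant
  utilities, no costs beyond day 100, and no correlation between PSA
  draws (no copulas); expected value of information is out of scope.
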