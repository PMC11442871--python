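# Methods

## Model structure

The model is a Markov cohort state-transition model with an embedded
per-cycle decision tree, comparing two biennial breast-screening
strategies: digital breast tomosynthesis combined with mammography
("DBT-MG") and mammography alone ("MG"). States:

- **screening** — asymptomatic, attends the biennial screen;
- **missed cancer, stage I–IV** (MG arm only) — cancer present but not
  detected at the last screen; one transient cycle before diagnosis;
- **cancer, stage 0–IV** — the diagnosis cycle (transient within a cycle),
  and, under the `remain_post` survivor pathway, persistent stage-specific
  post-cancer states;
- **death** — absorbing. Only breast-cancer mortality is modelled; death
  from other causes is assumed equal across arms and excluded, so the
  comparison isolates the screening effect.

Each cycle, screening-state occupants resolve through the decision tree
*screen → negative | recall; recall → negative | biopsy; biopsy →
negative | cancer*. The per-screen cancer detection probability is always
the chain product `recall × biopsy|recall × PPV2` (the shipped inputs
satisfy this identity to < 0.01‰), split across the strategy's
stage-at-diagnosis distribution. "Slice rate" in the input table is read
as the biopsy rate among recalled screenees — the only reading under which
the chain identity reproduces both printed detection rates exactly.

The MG arm's **missed-cancer rate is defined as the detection-rate gap**
`max(0, detection(DBT-MG) − detection(MG))` and is re-derived whenever
inputs are perturbed, so sensitivity analyses stay internally consistent.
Missed cancers use a stage-shifted distribution with zero stage-0 mass
(renormalised over stages I–IV).

## Cycle accounting

- **Cycle length** 2 years; **horizon** 15 cycles (30 years); both
  configurable.
- **Discounting**: factor (1+r)^(−2k) at cycle k, r = 2%/year, cycle 0
  undiscounted, applied identically to costs and QALYs. No half-cycle
  correction.
- **Pre-diagnosis cost** per screen: exam + recall×(revisit direct +
  indirect) + recall×biopsy|recall×(biopsy direct + indirect). Episode
  costs, including productivity losses, accrue in the cycle of the
  episode. The component sum ($177.54 DBT-MG, $68.18 MG per screen) is
  what the engine reports; the input table's derivation helpers
  (`indirect_episode_cost`) never override printed values.
- **Treatment cost**: the stage's lifetime direct + indirect treatment
  expenditure accrues once, at diagnosis, at that cycle's discount factor.
  Lifetime totals are deliberately not spread over future cycles — they
  are reported as lifetime sums in their source, and spreading them would
  double-discount.
- **Utilities**: a diagnosis cycle accrues `u_first + u_after` (one year
  each); later cancer cycles 2×`u_after`; screening and undiagnosed-missed
  states as below; death 0.
- **Death cost**: the indirect mortality cost accrues once, on the
  transition to death.

## Structural switches and defaults

Four mechanics are not pinned down by the published inputs. Each is an
explicit `ModelConfig` switch; every combination is a valid model, and the
defaults below are the documented combination under which the package
reproduces the published 30-year base case (see README):

1. `survival_conversion = "per_cycle_literal"` — the stage's 5-year
   survival probability is applied directly as the per-cycle (2-year)
   survival, i.e. death probability 1 − s5 per cycle. This mirrors the
   common decision-tree practice of plugging the published survival figure
   straight into the transition; the epidemiologically stricter
   `constant_hazard` alternative (1 − s5^(2/5)) is retained and tested.
   The choice matters: constant-hazard mortality roughly halves the QALY
   gap between the strategies.
2. `missed_cancer_handling = "one_cycle_delay"` — a missed cancer spends
   one cycle undiagnosed, bearing the stage's utility decrement (the
   disease burden does not wait for the diagnosis) but no treatment cost
   and no breast-cancer mortality (progression to death surfaces the
   cancer clinically first); diagnosis, costs and mortality follow in the
   next cycle. `immediate_stage_entry` collapses the delay.
3. `survivor_pathway = "return_to_screening"` — survivors of a cancer
   episode revert to the screening state (and can be re-detected later),
   consistent with a programme in which treated women resume routine
   surveillance. `remain_post` instead keeps them in stage-specific
   post-cancer states with continuing excess mortality and reduced
   utility; under that pathway `rescreen_survivors` controls whether they
   keep accruing screening costs.
4. `death_timing = "start_of_cycle"` — those dying in a cycle forfeit that
   cycle's QALYs (death is treated as occurring before the cycle's
   utility accrues); `end_of_cycle` grants the full cycle.

## Parameters

All inputs ship in `data/key_inputs.csv` (printed scales preserved; percent
and per-mille normalised to probabilities at load). Key groups: test
performance per strategy (recall, biopsy|recall, PPV2, detection),
stage-at-diagnosis distributions, missed-cancer stage distribution,
5-year survival by stage, costs (2021 USD at 30 NTD:USD — exam, recall
episode, biopsy episode, stage lifetime treatment, death; direct and
indirect), and stage utilities (first / after-first year). Global
settings: WTP $33,004/QALY, 2% annual discount, 10,000 Monte Carlo
trials. Validation enforces ranges, simplex sums, the detection identity,
survival monotonicity in stage, and the no-stage-0-missed assumption.

## Probabilistic sensitivity analysis

Families follow the input table's annotation: **beta** for probabilities,
**gamma** for costs and utilities. Dispersions are not published; the
default coefficient of variation is **0.20** (mirroring the ±20% one-way
band), configurable per parameter. Beta moment-matching applies the CV to
the distance to the nearer [0, 1] boundary, keeping the match feasible for
probabilities near 0 or 1 (a survival of 0.977 then gets sd ≈ 0.005 rather
than an infeasible 0.195). Gamma uses shape = CV⁻², scale = mean·CV².
Sampled utilities are clamped to [0, 1] (gamma mass above 1 for utilities
at or near 1 makes clamping unavoidable; the clamp rate, ≈ 0.26 of utility
draws at CV 0.20, is reported on the result). Stage distributions, when
sampled, are drawn per component and renormalised — a simplex-preserving
scheme that deviates from the table's per-component annotation.

**Which parameters are sampled.** By default the PSA samples the cost,
utility and survival parameters and holds the test-performance chains and
stage mixes at base. The performance chain *defines* the strategies under
comparison; sampling the two arms' chains independently makes the derived
missed-cancer rate the difference of two wide distributions, which
routinely produces draws where MG out-detects DBT-MG — a possibility the
underlying clinical comparison excludes — and dominates the CE-plane
scatter. `run_psa(..., include="all")` (CLI: `--vary-all`) samples
everything registered; an explicit key list is also accepted. Each draw
re-derives detection rates and the missed-cancer gap, then runs the full
deterministic cohort engine for both strategies.

CE-plane quadrants split the more-costly/more-effective quadrant at the
WTP line; ties (ΔNMB = 0) count as cost-effective, fixed for determinism.
The CEAC at each WTP grid point is exactly the fraction of draws with
non-negative incremental NMB.

## One-way (tornado) analysis

Each parameter in turn moves to (1±band)×base, band 0.20 by default,
probability- and utility-valued inputs capped at 1, everything else at
base; the deterministic ICER is recomputed at both ends and parameters are
ranked by |ICER(high) − ICER(low)|. Raw ratios are reported even past a
sign flip (a negative endpoint with positive ΔE means the variation makes
the comparator cost-saving), and the base ICER is carried alongside.
Caveat: the ICER responds *non-monotonically* to the six test-performance
parameters — varying any of them moves ΔC and ΔE together through the
detection-gap coupling, and both ±20% endpoints can push the ratio toward
or past dominance, so the one-way interval of such a parameter need not
contain the base ICER and its span understates its influence. Span
rankings should be read jointly with the CE-plane behaviour.

## Microsimulation

`run_microsim` pushes n individuals through the identical transition
structure with per-individual Bernoulli draws (vectorised, seeded). The
deterministic cohort trace is the exact expectation of these trajectories
and is used as the oracle in tests: Monte Carlo means must fall within
3 standard errors at n = 10,000, and the standard error shrinks ~1/√n.
Individual costs are heavy-tailed (rare cancer episodes carry most of the
mass), so cost comparisons converge more slowly than QALY comparisons.

## Synthetic parameter sets

`generate_parameter_set` draws random input bundles: uniform performance
chains (recall 0.01–0.30, biopsy|recall and PPV2 0.05–0.60 — roughly ±3×
the base-case territory), Dirichlet stage mixes, sorted-uniform survival
ladders, monotone utility pairs, log-uniform costs ($10–$200k). The
higher-detecting strategy is assigned arm A so a non-negative missed-cancer
rate always exists, and the missed distribution carries no stage-0 mass —
every generated set passes the full validator by construction. These sets
exercise structure (conservation, absorption, discounting bounds,
dominance arithmetic) far from the shipped values. They do not emulate
real-data features the model itself lacks — age structure, breast-density
strata, non-breast-cancer mortality, screening-round correlation — so
passing property tests supports the engine's internal correctness, not
the external validity of any particular parameterisation. Degenerate
fixtures (zero-recall, perfect-test, zero-discount, immortal, lethal)
give closed-form totals used as exact engine checks.

## Numerical choices

- Branch probabilities: the screen-negative branch is computed as the
  exact residual, so cycle-outcome probabilities sum to 1 to machine
  precision for any valid inputs.
- Stage distributions are renormalised at evaluation time (printed rows
  sum to 100.00% or 99.99%).
- ICERs with ΔE = 0 are flagged `indeterminate` (NaN value); ΔC < 0 with
  ΔE > 0 is `dominant`, ΔC > 0 with ΔE < 0 `dominated`. The raw ratio is
  always retained for plotting.
- All randomness flows through `numpy.random.default_rng` seeded from
  `ModelConfig.seed` or an explicit argument; equal seeds give
  bit-identical results.

## Known limitations

- The structural switches materially move the increments; results should
  always be read against the logged switch settings. Short-horizon
  increments are especially sensitive to the death-accrual timing, because
  a death early in the programme forfeits QALYs only up to the truncated
  horizon.
- No age-, density- or risk-stratified cohorts; a single homogeneous
  cohort enters at once.
- No other-cause mortality: life-years at long horizons are optimistic in
  both arms (differences are less affected, by design).
- Treated survivors under the default pathway carry no residual excess
  mortality or disutility once they re-enter screening; the `remain_post`
  pathway bounds the opposite assumption.
- PSA dispersions are assumptions (CV 0.20), not published estimates, so
  probabilistic summaries quantify sensitivity to *assumed* uncertainty.
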