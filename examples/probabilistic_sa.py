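"""Probabilistic sensitivity analysis on the cost-effectiveness plane.

Draws 10,000 joint parameter sets (beta for probabilities, gamma for costs
and utilities, CV 0.20), reruns both strategies per draw, and summarises
where the incremental (QALY, cost) pairs land relative to the willingness-
to-pay line, plus the cost-effectiveness acceptability curve (CEAC).
"""

import numpy as np

from screencea import load_default_parameters, run_psa

inputs = load_default_parameters()
psa = run_psa(inputs, n=10_000, seed=1)

print(f"draws: {psa.n_draws}, seed: {psa.seed}, WTP: ${psa.wtp:,.0f}/QALY")
for name, label in [
    ("ne_below_wtp", "more costly, more effective, below WTP (cost-effective)"),
    ("ne_above_wtp", "more costly, more effective, above WTP"),
    ("cost_saving", "less costly, more effective (cost-saving)"),
    ("dominated_nw", "more costly, less effective (dominated)"),
    ("sw", "less costly, less effective"),
]:
    print(f"  {100 * psa.quadrant_probs[name]:6.2f}%  {label}")
print(f"\nP(DBT-MG cost-effective or cost-saving) = {100 * psa.p_cost_effective_at_wtp:.2f}%")

crossing = psa.ceac.wtp[np.argmax(psa.ceac.p_dbt_mg.to_numpy() >= 0.5)]
print(f"CEAC: DBT-MG preferred in >50% of draws once WTP exceeds ~${crossing:,.0f}/QALY")
print(f"(utility draws clamped to [0, 1] at rate {psa.clamp_rate:.3f})")
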