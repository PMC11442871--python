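"""PSA sampling, acceptability curves, tornado and horizon analyses."""

import numpy as np
import pandas as pd
import pytest

from screencea import (
    DistributionSpec,
    ceac,
    evaluate_pair,
    horizon_analysis,
    run_base_case,
    run_owsa,
    run_psa,
)
from screencea.parameters import flat_from_inputs, inputs_from_flat
from screencea.sensitivity import _sample_one, default_psa_parameters


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "spec",
    [
        DistributionSpec("beta", 0.09, 0.20),
        DistributionSpec("beta", 0.35, 0.20),
        DistributionSpec("gamma", 150.0, 0.20),
        DistributionSpec("gamma", 5305.34, 0.20),
    ],
)
def test_sampling_moments_match_spec(spec):
    """Empirical mean and CV of 1e5 draws match the spec within 2%."""
    rng = np.random.default_rng(123)
    x = _sample_one(spec, 100_000, rng)
    assert x.mean() == pytest.approx(spec.mean, rel=0.02)
    target_sd = (
        spec.dispersion * min(spec.mean, 1 - spec.mean)
        if spec.family == "beta"
        else spec.dispersion * spec.mean
    )
    assert x.std() == pytest.approx(target_sd, rel=0.02)
    if spec.family == "beta":
        assert (x >= 0).all() and (x <= 1).all()
    else:
        assert (x >= 0).all()


def test_sampling_infeasible_beta_raises():
    with pytest.raises(ValueError):
        _sample_one(DistributionSpec("beta", 0.5, 1.5), 10, np.random.default_rng(0))


def test_fixed_spec_yields_constant():
    x = _sample_one(DistributionSpec("fixed", 3.0, 0.0), 5, np.random.default_rng(0))
    assert (x == 3.0).all()


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


def test_psa_reproducible_under_seed(base_inputs):
    a = run_psa(base_inputs, n=200, seed=5)
    b = run_psa(base_inputs, n=200, seed=5)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    assert a.quadrant_probs == b.quadrant_probs
    assert a.p_cost_effective_at_wtp == b.p_cost_effective_at_wtp


def test_psa_all_fixed_reproduces_base_case(base_inputs):
    base = run_base_case(base_inputs)
    psa = run_psa(base_inputs, n=50, seed=1, include=[])
    assert psa.draws.delta_cost.nunique() == 1
    assert psa.draws.delta_cost.iloc[0] == pytest.approx(base.delta_cost)
    assert psa.draws.delta_qaly.iloc[0] == pytest.approx(base.delta_qaly)
    assert max(psa.quadrant_probs.values()) == 1.0


def test_psa_quadrants_sum_to_one(base_inputs):
    psa = run_psa(base_inputs, n=300, seed=9)
    assert sum(psa.quadrant_probs.values()) == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= psa.p_cost_effective_at_wtp <= 1.0


def test_psa_default_samples_shared_parameters_only(base_inputs):
    keys = default_psa_parameters(base_inputs)
    assert all(k.startswith(("cost.", "utility.", "survival.")) for k in keys)
    assert "dbt.recall_rate" not in keys
    psa_shared = run_psa(base_inputs, n=100, seed=2)
    psa_all = run_psa(base_inputs, n=100, seed=2, include="all")
    # sampling the strategy-defining chains adds CE-plane dispersion
    assert psa_all.draws.delta_cost.std() > psa_shared.draws.delta_cost.std()


def test_ceac_equals_draw_recount(base_inputs):
    """At every grid point the CEAC is the fraction of draws with dNMB >= 0."""
    psa = run_psa(base_inputs, n=400, seed=3)
    dc = psa.draws.delta_cost.to_numpy()
    de = psa.draws.delta_qaly.to_numpy()
    for _, row in psa.ceac.iterrows():
        recount = float((de * row.wtp - dc >= 0).mean())
        assert row.p_dbt_mg == recount
        assert row.p_mg == pytest.approx(1.0 - recount)


def test_ceac_monotone_and_anchored_at_zero_wtp(base_inputs):
    psa = run_psa(base_inputs, n=400, seed=4)
    p = psa.ceac.p_dbt_mg.to_numpy()
    assert (np.diff(p) >= 0).all()
    assert (np.diff(psa.ceac.p_mg.to_numpy()) <= 0).all()
    # at WTP = 0 the curve is the fraction of cost-saving draws
    assert p[0] == (psa.draws.delta_cost <= 0).mean()


def test_ceac_rejects_empty_draws():
    with pytest.raises(ValueError):
        ceac(pd.DataFrame(columns=["delta_cost", "delta_qaly"]), np.array([0.0]))


def test_utility_clamp_rate_reported(base_inputs):
    psa = run_psa(base_inputs, n=200, seed=6)
    assert 0.0 < psa.clamp_rate < 1.0  # stage-0 after-first-year utility sits at 1.0


# ---------------------------------------------------------------------------
# one-way / tornado
# ---------------------------------------------------------------------------


def test_owsa_zero_band_collapses_to_base(base_inputs):
    tor = run_owsa(base_inputs, parameters=["cost.dbt_exam", "mg.recall_rate"], band=0.0)
    assert (tor.table.span == 0.0).all()
    assert np.allclose(tor.table.icer_low, tor.base_icer)
    assert np.allclose(tor.table.icer_high, tor.base_icer)


def test_owsa_sorted_by_span_descending(base_inputs):
    tor = run_owsa(base_inputs)
    spans = tor.table.span.to_numpy()
    assert (np.diff(spans) <= 1e-12).all()
    lo, hi = tor.global_range
    assert lo <= tor.base_icer <= hi


def test_owsa_unknown_parameter_rejected(base_inputs):
    with pytest.raises(KeyError):
        run_owsa(base_inputs, parameters=["cost.nonexistent"])


def test_owsa_caps_probabilities_at_one(base_inputs):
    tor = run_owsa(base_inputs, parameters=["survival.s5.0"])
    row = tor.table.iloc[0]
    assert row.high_input == 1.0


def test_icer_monotone_in_dbt_exam_cost(base_inputs):
    """Brute-force re-evaluation at intermediate values."""
    base = flat_from_inputs(base_inputs)
    icers = []
    for mult in (0.9, 1.0, 1.1, 1.2):
        flat = dict(base)
        flat["cost.dbt_exam"] = 150.0 * mult
        perturbed = inputs_from_flat(flat, base_inputs.config)
        icers.append(evaluate_pair(perturbed)[2].icer.raw)
    assert icers == sorted(icers)
    assert icers[0] < icers[-1]


# ---------------------------------------------------------------------------
# horizons
# ---------------------------------------------------------------------------


def test_horizon_analysis_table(base_inputs):
    table = horizon_analysis(base_inputs, horizons=(5, 10, 15))
    assert list(table.cycles) == [5, 10, 15]
    assert list(table.years) == [10, 20, 30]
    # longer programmes accentuate the comparator's cost-utility advantage
    assert table.icur.is_monotonic_decreasing
    assert (table.delta_cost > 0).all() and (table.delta_qaly > 0).all()


def test_one_cycle_horizon_runs(base_inputs):
    table = horizon_analysis(base_inputs, horizons=(1,))
    assert len(table) == 1
    assert np.isfinite(table.icur.iloc[0]) or np.isnan(table.icur.iloc[0])


def test_horizon_analysis_rejects_empty(base_inputs):
    with pytest.raises(ValueError):
        horizon_analysis(base_inputs, horizons=())


def test_horizon_psa_probability_column(base_inputs):
    table = horizon_analysis(base_inputs, horizons=(5,), psa_n=50, seed=11)
    assert "p_cost_effective" in table.columns
    assert 0.0 <= table.p_cost_effective.iloc[0] <= 1.0
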