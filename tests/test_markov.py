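"""Cohort trace and microsimulation engine checks.

The deterministic cohort trace is the exact expectation of the individual
microsimulation, so it serves as the oracle for the Monte Carlo paths.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screencea import (
    ModelConfig,
    cycle_qaly,
    discount_factor,
    load_default_parameters,
    per_cycle_death_probability,
    run_cohort,
    run_microsim,
)
from screencea.markov import STATE_LABELS


def _occupancy_sums(trace):
    return trace.occupancy.sum(axis=1)


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------


def test_per_cycle_death_probability_closed_forms():
    assert per_cycle_death_probability(1.0, 2, "constant_hazard") == 0.0
    assert per_cycle_death_probability(1.0, 2, "per_cycle_literal") == 0.0
    assert per_cycle_death_probability(0.257, 2, "constant_hazard") == pytest.approx(
        1 - 0.257 ** 0.4
    )
    assert per_cycle_death_probability(0.257, 2, "constant_hazard") == pytest.approx(
        0.4192, abs=1e-4
    )
    assert per_cycle_death_probability(0.977, 2, "constant_hazard") == pytest.approx(
        0.0093, abs=1e-4
    )
    assert per_cycle_death_probability(0.257, 2, "per_cycle_literal") == pytest.approx(0.743)
    with pytest.raises(ValueError):
        per_cycle_death_probability(1.2, 2, "constant_hazard")
    with pytest.raises(ValueError):
        per_cycle_death_probability(0.5, 2, "cloglog")


@settings(derandomize=True, max_examples=100)
@given(s5=st.floats(0.0, 1.0), mode=st.sampled_from(["constant_hazard", "per_cycle_literal"]))
def test_death_probability_is_probability_and_decreasing_in_survival(s5, mode):
    q = per_cycle_death_probability(s5, 2, mode)
    assert 0.0 <= q <= 1.0
    if s5 <= 0.99:
        assert per_cycle_death_probability(min(1.0, s5 + 0.01), 2, mode) <= q


def test_discount_factor_closed_forms():
    assert discount_factor(0, 0.02, 2) == 1.0
    assert discount_factor(1, 0.02, 2) == pytest.approx(1.02 ** -2)
    assert discount_factor(1, 0.02, 2) == pytest.approx(0.96117, abs=1e-5)
    assert discount_factor(15, 0.02, 2) == pytest.approx(0.55207, abs=1e-5)
    with pytest.raises(ValueError):
        discount_factor(-1, 0.02, 2)


def test_cycle_qaly_by_state(base_inputs):
    u = base_inputs.utilities
    assert cycle_qaly("screening", u) == 2.0
    assert cycle_qaly("death", u) == 0.0
    # one year at the first-year utility, one at the after-first-year utility
    assert cycle_qaly("cancer_new_0", u) == pytest.approx(0.904 + 1.000)
    assert cycle_qaly("cancer_new_4", u) == pytest.approx(0.753 + 0.832)
    assert cycle_qaly("cancer_post_3", u) == pytest.approx(2 * 0.932)
    with pytest.raises(ValueError):
        cycle_qaly("limbo", u)


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------


def test_cohort_occupancy_conserved_and_death_absorbing(base_inputs):
    for strat in (base_inputs.dbt, base_inputs.mg):
        trace = run_cohort(strat, base_inputs.survival, base_inputs.utilities, base_inputs.config)
        np.testing.assert_allclose(_occupancy_sums(trace), 1.0, atol=1e-12)
        dead = trace.occupancy[:, STATE_LABELS.index("death")]
        assert (np.diff(dead) >= -1e-15).all()
        assert trace.total_cost <= trace.total_cost_undiscounted
        assert trace.total_qaly <= trace.total_qaly_undiscounted


def test_identical_strategies_give_identical_traces(base_inputs):
    import copy

    clone = copy.deepcopy(base_inputs.dbt)
    clone.name = "MG"
    t1 = run_cohort(base_inputs.dbt, base_inputs.survival, base_inputs.utilities, base_inputs.config)
    t2 = run_cohort(clone, base_inputs.survival, base_inputs.utilities, base_inputs.config)
    assert t1.total_cost == t2.total_cost
    assert t1.total_qaly == t2.total_qaly


def test_dominance_direction_of_base_case(base_inputs):
    """DBT-MG costs more and yields more QALYs than MG over 15 cycles."""
    ta = run_cohort(base_inputs.dbt, base_inputs.survival, base_inputs.utilities, base_inputs.config)
    tb = run_cohort(base_inputs.mg, base_inputs.survival, base_inputs.utilities, base_inputs.config)
    assert ta.total_cost > tb.total_cost
    assert ta.total_qaly > tb.total_qaly


def test_discount_monotonicity(base_inputs):
    totals = []
    for rate in (0.0, 0.02, 0.05):
        cfg = ModelConfig(**{**base_inputs.config.__dict__, "annual_discount": rate})
        trace = run_cohort(base_inputs.dbt, base_inputs.survival, base_inputs.utilities, cfg)
        totals.append((trace.total_cost, trace.total_qaly))
    assert totals[0][0] > totals[1][0] > totals[2][0]
    assert totals[0][1] > totals[1][1] > totals[2][1]


def test_trace_frame_layout(base_inputs):
    trace = run_cohort(base_inputs.dbt, base_inputs.survival, base_inputs.utilities, base_inputs.config)
    df = trace.to_frame()
    assert len(df) == base_inputs.config.n_cycles
    assert df.cum_cost_discounted.iloc[-1] == pytest.approx(trace.total_cost)
    assert df.discount_factor.iloc[0] == 1.0
    assert set(STATE_LABELS) <= set(df.columns)


def test_structural_switches_change_results(base_inputs):
    base = run_cohort(
        base_inputs.mg, base_inputs.survival, base_inputs.utilities, base_inputs.config
    ).total_qaly
    for override in (
        {"survival_conversion": "constant_hazard"},
        {"missed_cancer_handling": "immediate_stage_entry"},
        {"survivor_pathway": "remain_post"},
        {"death_timing": "end_of_cycle"},
    ):
        cfg = ModelConfig(**{**base_inputs.config.__dict__, **override})
        alt = run_cohort(base_inputs.mg, base_inputs.survival, base_inputs.utilities, cfg)
        np.testing.assert_allclose(_occupancy_sums(alt), 1.0, atol=1e-12)
        assert alt.total_qaly != base


# ---------------------------------------------------------------------------
# microsimulation vs cohort oracle
# ---------------------------------------------------------------------------


def test_microsim_matches_cohort_expectation(base_inputs):
    """Monte Carlo means fall within 3 standard errors of the exact trace."""
    for strat in (base_inputs.dbt, base_inputs.mg):
        trace = run_cohort(strat, base_inputs.survival, base_inputs.utilities, base_inputs.config)
        ms = run_microsim(
            strat, base_inputs.survival, base_inputs.utilities, base_inputs.config,
            n=10_000, seed=20240315,
        )
        assert abs(ms.mean_cost - trace.total_cost) < 3 * ms.se_cost
        assert abs(ms.mean_qaly - trace.total_qaly) < 3 * ms.se_qaly


def test_microsim_error_shrinks_with_n(base_inputs):
    trace = run_cohort(
        base_inputs.mg, base_inputs.survival, base_inputs.utilities, base_inputs.config
    )
    errs = []
    for n in (100, 1_000, 10_000):
        ms = run_microsim(
            base_inputs.mg, base_inputs.survival, base_inputs.utilities,
            base_inputs.config, n=n, seed=7,
        )
        errs.append(ms.se_qaly)
    assert errs[0] > errs[1] > errs[2]
    # ~1/sqrt(n): one decade of n shrinks the SE by ~sqrt(10)
    # (the n=100 point is too event-starved for a stable std estimate)
    assert errs[1] / errs[2] == pytest.approx(math.sqrt(10), rel=0.5)


def test_microsim_deterministic_under_seed(base_inputs):
    kw = dict(n=5, seed=42)
    a = run_microsim(base_inputs.mg, base_inputs.survival, base_inputs.utilities, base_inputs.config, **kw)
    b = run_microsim(base_inputs.mg, base_inputs.survival, base_inputs.utilities, base_inputs.config, **kw)
    np.testing.assert_array_equal(a.cost, b.cost)
    np.testing.assert_array_equal(a.qaly, b.qaly)


def test_microsim_rejects_bad_n(base_inputs):
    with pytest.raises(ValueError):
        run_microsim(base_inputs.mg, base_inputs.survival, base_inputs.utilities, base_inputs.config, n=0)
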