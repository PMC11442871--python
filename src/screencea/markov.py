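"""Multi-cycle Markov state-transition engine.

States after entry into the biennial screening programme: screening
(healthy), cancer (stage 0-IV; the diagnosis cycle and, under the
``remain_post`` pathway, stage-specific post-cancer cycles), missed cancer
(mammography arm only), and death (absorbing; only breast-cancer mortality
is modelled).  The cohort trace is the exact expectation of the individual
microsimulation and serves as its oracle.

Within a cycle the order of events is: screening occupants accrue the
pre-diagnosis screening cost; detected (and, per configuration, missed)
cancers enter their stage, accruing lifetime treatment costs at entry and
stage first-/after-first-year utilities; stage-specific death probabilities
then apply, with the indirect death cost accrued on the transition.
Whether the dying accrue their final cycle's utilities is governed by the
``death_timing`` switch (forfeited by default); there is no half-cycle
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_tree import cycle_outcome
from .parameters import (
    STAGES,
    ModelConfig,
    StrategyParams,
    SurvivalRates,
    UtilitySet,
)

#: state labels of the cohort occupancy vector
STATE_LABELS = (
    ["screening"]
    + [f"missed_wait_{s}" for s in STAGES]
    + [f"cancer_post_{s}" for s in STAGES]
    + ["death"]
)


def per_cycle_death_probability(s5: float, cycle_years: float, mode: str = "constant_hazard") -> float:
    """Convert a 5-year stage survival into a per-cycle death probability.

    ``constant_hazard`` assumes a constant annual hazard, giving
    1 - s5**(cycle_years/5); ``per_cycle_literal`` applies 1 - s5 per cycle.
    """
    if not 0.0 <= s5 <= 1.0:
        raise ValueError(f"5-year survival {s5} outside [0, 1]")
    if mode == "constant_hazard":
        return 1.0 - s5 ** (cycle_years / 5.0)
    if mode == "per_cycle_literal":
        return 1.0 - s5
    raise ValueError(f"unknown survival conversion mode {mode!r}")


def discount_factor(cycle_index: int, annual_rate: float, cycle_years: float) -> float:
    """(1 + r)^(-k * cycle_years); cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle index must be non-negative")
    return (1.0 + annual_rate) ** (-cycle_index * cycle_years)


def cycle_qaly(state: str, utilities: UtilitySet, cycle_years: float = 2.0) -> float:
    """QALYs accrued over one cycle in a given state.

    A newly diagnosed cancer spends one year at the stage's first-year
    utility and the remainder of the cycle at its after-first-year utility;
    post-cancer cycles accrue the after-first-year utility throughout.
    """
    if state == "screening":
        return utilities.u_healthy * cycle_years
    if state == "death":
        return utilities.u_death * cycle_years
    kind, _, stage_txt = state.rpartition("_")
    stage = int(stage_txt)
    if kind == "cancer_new":
        return (
            utilities.u_first_year_by_stage[stage]
            + utilities.u_after_first_year_by_stage[stage] * (cycle_years - 1.0)
        )
    if kind == "cancer_post":
        return utilities.u_after_first_year_by_stage[stage] * cycle_years
    if kind == "missed_wait":
        # undiagnosed but sick: the stage's utility decrement already applies
        return (
            utilities.u_first_year_by_stage[stage]
            + utilities.u_after_first_year_by_stage[stage] * (cycle_years - 1.0)
        )
    raise ValueError(f"unknown state {state!r}")


@dataclass
class CycleTrace:
    """Per-cycle occupancy and (un)discounted accruals of a cohort run."""

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, n_states), start-of-cycle; last row terminal
    cost_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray
    discount_factors: np.ndarray
    cost_discounted: np.ndarray
    qaly_discounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_discounted.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost_undiscounted.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly_undiscounted.sum())

    def to_frame(self) -> pd.DataFrame:
        n = len(self.cost_undiscounted)
        df = pd.DataFrame(self.occupancy[:n], columns=STATE_LABELS)
        df.insert(0, "cycle", np.arange(n))
        df["discount_factor"] = self.discount_factors
        df["cost_undiscounted"] = self.cost_undiscounted
        df["qaly_undiscounted"] = self.qaly_undiscounted
        df["cost_discounted"] = self.cost_discounted
        df["qaly_discounted"] = self.qaly_discounted
        df["cum_cost_discounted"] = self.cost_discounted.cumsum()
        df["cum_qaly_discounted"] = self.qaly_discounted.cumsum()
        return df


def _stage_quantities(
    strategy: StrategyParams,
    survival: SurvivalRates,
    utilities: UtilitySet,
    config: ModelConfig,
):
    q_death = [
        per_cycle_death_probability(s5, config.cycle_years, config.survival_conversion)
        for s5 in survival.s5_by_stage
    ]
    treat_cost = [
        strategy.costs.treatment_direct_by_stage[s] + strategy.costs.treatment_indirect_by_stage[s]
        for s in STAGES
    ]
    qaly_new = [cycle_qaly(f"cancer_new_{s}", utilities, config.cycle_years) for s in STAGES]
    qaly_post = [cycle_qaly(f"cancer_post_{s}", utilities, config.cycle_years) for s in STAGES]
    death_cost = strategy.costs.death_direct + strategy.costs.death_indirect
    return q_death, treat_cost, qaly_new, qaly_post, death_cost


def run_cohort(
    strategy: StrategyParams,
    survival: SurvivalRates,
    utilities: UtilitySet,
    config: ModelConfig,
) -> CycleTrace:
    """Deterministic cohort trace of one strategy over the configured horizon.

    The cohort starts fully in the screening state.  Occupancy is conserved
    every cycle; death is absorbing.  Returns per-cycle discounted and
    undiscounted cost/QALY accruals per screenee.
    """
    if config.n_cycles < 1:
        raise ValueError("horizon must be at least one cycle")
    out = cycle_outcome(strategy)
    q_death, treat_cost, qaly_new, qaly_post, death_cost = _stage_quantities(
        strategy, survival, utilities, config
    )
    qaly_healthy = utilities.u_healthy * config.cycle_years
    qaly_wait = [cycle_qaly(f"missed_wait_{s}", utilities, config.cycle_years) for s in STAGES]
    immediate = config.missed_cancer_handling == "immediate_stage_entry"
    to_post = config.survivor_pathway == "remain_post"
    dying_qaly = 1.0 if config.death_timing == "end_of_cycle" else 0.0

    n_states = len(STATE_LABELS)
    occ = np.zeros((config.n_cycles + 1, n_states))
    costs_u = np.zeros(config.n_cycles)
    qalys_u = np.zeros(config.n_cycles)
    dfs = np.zeros(config.n_cycles)

    s_occ = 1.0
    wait = [0.0] * 5
    post = [0.0] * 5
    dead = 0.0

    p_detect = out.p_cancer_by_stage
    p_missed = out.p_missed_by_stage
    p_sick = sum(p_detect) + sum(p_missed)
    c_pre = out.expected_pre_diagnosis_cost

    for k in range(config.n_cycles):
        occ[k] = [s_occ, *wait, *post, dead]
        cost = 0.0
        qaly = 0.0
        deaths_now = 0.0
        s_next = s_occ * (1.0 - p_sick)
        qaly += s_next * qaly_healthy
        cost += s_occ * c_pre
        wait_next = [0.0] * 5
        post_next = list(post)

        for s in STAGES:
            # entering care this cycle: newly detected plus last cycle's missed
            entering = s_occ * p_detect[s] + wait[s]
            if immediate:
                entering += s_occ * p_missed[s]
            else:
                wait_next[s] = s_occ * p_missed[s]
                qaly += wait_next[s] * qaly_wait[s]
            if entering > 0.0:
                cost += entering * treat_cost[s]
                d = entering * q_death[s]
                deaths_now += d
                qaly += (entering - d + d * dying_qaly) * qaly_new[s]
                if to_post:
                    post_next[s] += entering - d
                else:
                    s_next += entering - d
            if post[s] > 0.0:
                if config.rescreen_survivors:
                    cost += post[s] * c_pre
                d = post[s] * q_death[s]
                deaths_now += d
                qaly += (post[s] - d + d * dying_qaly) * qaly_post[s]
                post_next[s] -= d

        cost += deaths_now * death_cost
        dead += deaths_now
        s_occ, wait, post = s_next, wait_next, post_next
        dfs[k] = discount_factor(k, config.annual_discount, config.cycle_years)
        costs_u[k] = cost
        qalys_u[k] = qaly

    occ[config.n_cycles] = [s_occ, *wait, *post, dead]
    return CycleTrace(
        strategy=strategy.name,
        occupancy=occ,
        cost_undiscounted=costs_u,
        qaly_undiscounted=qalys_u,
        discount_factors=dfs,
        cost_discounted=costs_u * dfs,
        qaly_discounted=qalys_u * dfs,
    )


@dataclass
class MicrosimResult:
    """Individual-level outcomes and Monte Carlo summary of one strategy."""

    strategy: str
    cost: np.ndarray  # discounted, per individual
    qaly: np.ndarray
    seed: int

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def se_cost(self) -> float:
        return float(self.cost.std(ddof=1) / np.sqrt(len(self.cost)))

    @property
    def se_qaly(self) -> float:
        return float(self.qaly.std(ddof=1) / np.sqrt(len(self.qaly)))


def run_microsim(
    strategy: StrategyParams,
    survival: SurvivalRates,
    utilities: UtilitySet,
    config: ModelConfig,
    n: int,
    seed: int | None = None,
) -> MicrosimResult:
    """First-order microsimulation: ``n`` individuals through the same
    transition structure as :func:`run_cohort`.

    Vectorised over individuals; reproducible under a fixed seed.  The cohort
    trace is the exact expectation of these trajectories.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    out = cycle_outcome(strategy)
    q_death, treat_cost, qaly_new, qaly_post, death_cost = _stage_quantities(
        strategy, survival, utilities, config
    )
    qaly_healthy = utilities.u_healthy * config.cycle_years
    qaly_wait = np.array(
        [cycle_qaly(f"missed_wait_{s}", utilities, config.cycle_years) for s in STAGES]
    )
    immediate = config.missed_cancer_handling == "immediate_stage_entry"
    to_post = config.survivor_pathway == "remain_post"
    dying_qaly = 1.0 if config.death_timing == "end_of_cycle" else 0.0

    # states: 0 screening; 1..5 missed-wait stage s; 6..10 post stage s; 11 dead
    SCREEN, WAIT0, POST0, DEAD = 0, 1, 6, 11
    # screening-branch outcome thresholds: [detect s=0..4, missed s=0..4, negative]
    probs = np.array(out.p_cancer_by_stage + out.p_missed_by_stage)
    edges = np.concatenate([np.cumsum(probs), [1.0]])

    state = np.zeros(n, dtype=np.int64)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    q_death = np.array(q_death)
    treat_cost = np.array(treat_cost)
    qaly_new = np.array(qaly_new)
    qaly_post = np.array(qaly_post)

    for k in range(config.n_cycles):
        df = discount_factor(k, config.annual_discount, config.cycle_years)
        new_state = state.copy()
        entering_stage = np.full(n, -1, dtype=np.int64)

        scr = state == SCREEN
        if scr.any():
            cost[scr] += df * out.expected_pre_diagnosis_cost
            branch = np.searchsorted(edges, rng.random(scr.sum()), side="right")
            idx = np.flatnonzero(scr)
            detected = branch < 5
            missed = (branch >= 5) & (branch < 10)
            negative = branch >= 10
            qaly[idx[negative]] += df * qaly_healthy
            entering_stage[idx[detected]] = branch[detected]
            if immediate:
                entering_stage[idx[missed]] = branch[missed] - 5
            else:
                qaly[idx[missed]] += df * qaly_wait[branch[missed] - 5]
                new_state[idx[missed]] = WAIT0 + branch[missed] - 5

        waiting = (state >= WAIT0) & (state < POST0)
        entering_stage[waiting] = state[waiting] - WAIT0

        ent = entering_stage >= 0
        if ent.any():
            stages = entering_stage[ent]
            cost[ent] += df * treat_cost[stages]
            die = rng.random(ent.sum()) < q_death[stages]
            idx = np.flatnonzero(ent)
            qaly[idx[~die]] += df * qaly_new[stages[~die]]
            qaly[idx[die]] += df * dying_qaly * qaly_new[stages[die]]
            new_state[idx[die]] = DEAD
            cost[idx[die]] += df * death_cost
            new_state[idx[~die]] = (POST0 + stages[~die]) if to_post else SCREEN

        in_post = (state >= POST0) & (state < DEAD)
        if in_post.any():
            stages = state[in_post] - POST0
            if config.rescreen_survivors:
                cost[in_post] += df * out.expected_pre_diagnosis_cost
            die = rng.random(in_post.sum()) < q_death[stages]
            idx = np.flatnonzero(in_post)
            qaly[idx[~die]] += df * qaly_post[stages[~die]]
            qaly[idx[die]] += df * dying_qaly * qaly_post[stages[die]]
            new_state[idx[die]] = DEAD
            cost[idx[die]] += df * death_cost

        state = new_state

    return MicrosimResult(strategy=strategy.name, cost=cost, qaly=qaly, seed=seed)
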