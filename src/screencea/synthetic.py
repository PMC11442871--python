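"""Random, invariant-satisfying parameter sets and degenerate fixtures.

The generator emulates the statistical structure of the shipped inputs —
probabilities in [0, 1], stage distributions on the simplex, survival
non-increasing with stage, utilities monotone in stage and year band,
positive costs — over ranges roughly 3x wider than the base case, so the
engines can be property-tested far from (and independently of) the shipped
values.  Strategy A is constructed to detect at least as many cancers as
strategy B, so a non-negative missed-cancer rate always exists, and the
missed-stage distribution carries no stage-0 mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    STAGES,
    CostSet,
    ModelConfig,
    ModelInputs,
    ScreeningPerformance,
    StageDistribution,
    StrategyParams,
    SurvivalRates,
    UtilitySet,
    link_missed_cancer,
)


@dataclass
class SyntheticSpec:
    """Ranges for random parameter generation (uniform unless noted)."""

    seed: int = 0
    recall_range: tuple[float, float] = (0.01, 0.30)
    biopsy_range: tuple[float, float] = (0.05, 0.60)
    ppv2_range: tuple[float, float] = (0.05, 0.60)
    cost_log_range: tuple[float, float] = (10.0, 2e5)  # log-uniform
    dirichlet_alpha: float = 2.0

    def __post_init__(self) -> None:
        for lo, hi in (self.recall_range, self.biopsy_range, self.ppv2_range, self.cost_log_range):
            if not lo < hi or lo <= 0:
                raise ValueError("ranges must be positive and increasing")


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    return float(rng.uniform(*rng_pair))


def _log_uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = np.log(rng_pair)
    return float(np.exp(rng.uniform(lo, hi)))


def _simplex(rng: np.random.Generator, alpha: float, k: int = 5) -> list[float]:
    return list(rng.dirichlet(np.full(k, alpha)))


def _random_performance(rng: np.random.Generator, spec: SyntheticSpec) -> ScreeningPerformance:
    r = _uniform(rng, spec.recall_range)
    b = _uniform(rng, spec.biopsy_range)
    p = _uniform(rng, spec.ppv2_range)
    return ScreeningPerformance(r, b, p, cancer_detection_rate=r * b * p)


def _random_costs(rng: np.random.Generator, spec: SyntheticSpec) -> CostSet:
    lu = lambda: _log_uniform(rng, spec.cost_log_range)
    return CostSet(
        exam_direct=lu(),
        revisit_direct=lu(),
        revisit_indirect=lu(),
        biopsy_direct=lu(),
        biopsy_indirect=lu(),
        treatment_direct_by_stage=[lu() for _ in STAGES],
        treatment_indirect_by_stage=[lu() for _ in STAGES],
        death_direct=0.0,
        death_indirect=lu(),
    )


def generate_parameter_set(spec: SyntheticSpec, config: ModelConfig | None = None) -> ModelInputs:
    """Draw one random input bundle satisfying every structural invariant.

    Reproducible under the spec's seed; detection rates hold the chain
    identity by construction, and the strategy with the lower detection rate
    carries the missed-cancer branch.
    """
    rng = np.random.default_rng(spec.seed)
    perf_a, perf_b = _random_performance(rng, spec), _random_performance(rng, spec)
    if perf_a.derived_detection_rate() < perf_b.derived_detection_rate():
        perf_a, perf_b = perf_b, perf_a

    # survival: sorted uniforms, non-increasing from stage 0 to IV
    s5 = sorted(rng.uniform(0.05, 0.999, size=5), reverse=True)
    # utilities: monotone non-increasing in stage; after-first-year >= first-year
    u_after = sorted(rng.uniform(0.5, 1.0, size=5), reverse=True)
    u_first = [rng.uniform(0.3, ua) for ua in u_after]

    missed = _simplex(rng, spec.dirichlet_alpha, k=4)
    costs = _random_costs(rng, spec)
    a = StrategyParams(
        name="A",
        performance=perf_a,
        diagnosed_stage_dist=StageDistribution(_simplex(rng, spec.dirichlet_alpha)),
        costs=costs,
    )
    exam_b = _log_uniform(rng, spec.cost_log_range)
    costs_b = CostSet(**{**costs.__dict__, "exam_direct": exam_b})
    b = StrategyParams(
        name="B",
        performance=perf_b,
        diagnosed_stage_dist=StageDistribution(_simplex(rng, spec.dirichlet_alpha)),
        costs=costs_b,
        missed_stage_dist=StageDistribution([0.0, *missed]),
    )
    link_missed_cancer(a, b)
    return ModelInputs(
        dbt=a,
        mg=b,
        survival=SurvivalRates([float(x) for x in s5]),
        utilities=UtilitySet([float(x) for x in u_first], [float(x) for x in u_after]),
        config=config if config is not None else ModelConfig(),
    )


def degenerate_fixtures(config: ModelConfig | None = None) -> dict[str, ModelInputs]:
    """Named closed-form fixtures for exact engine checks.

    - ``zero_recall``: no recalls, no cancers: cost = horizon x exam cost,
      QALYs = cycle length x horizon (before discounting).
    - ``perfect_test``: recall = biopsy|recall = PPV2 = 1 (everyone is a
      detected cancer on the first screen).
    - ``zero_discount``: base parameters with a 0% discount rate.
    - ``immortal``: all 5-year survivals 1 (death never occurs).
    - ``lethal``: stage IV only with zero survival (every detected case dies
      in its diagnosis cycle).
    """
    from .parameters import load_default_parameters

    base_cfg = config if config is not None else ModelConfig()
    fixtures: dict[str, ModelInputs] = {}

    def fresh(cfg: ModelConfig | None = None) -> ModelInputs:
        return load_default_parameters(cfg if cfg is not None else ModelConfig(**base_cfg.__dict__))

    zero = fresh()
    for strat in (zero.dbt, zero.mg):
        strat.performance = ScreeningPerformance(0.0, 0.0, 0.0, 0.0)
        strat.missed_cancer_rate = 0.0
    link_missed_cancer(zero.dbt, zero.mg)
    fixtures["zero_recall"] = zero

    perfect = fresh()
    for strat in (perfect.dbt, perfect.mg):
        strat.performance = ScreeningPerformance(1.0, 1.0, 1.0, 1.0)
    link_missed_cancer(perfect.dbt, perfect.mg)
    fixtures["perfect_test"] = perfect

    nodisc = fresh(ModelConfig(**{**base_cfg.__dict__, "annual_discount": 0.0}))
    fixtures["zero_discount"] = nodisc

    immortal = fresh()
    immortal.survival = SurvivalRates([1.0] * 5)
    fixtures["immortal"] = immortal

    lethal = fresh()
    lethal.survival = SurvivalRates([1.0, 1.0, 1.0, 1.0, 0.0])
    for strat in (lethal.dbt, lethal.mg):
        strat.diagnosed_stage_dist = StageDistribution([0.0, 0.0, 0.0, 0.0, 1.0])
    lethal.mg.missed_stage_dist = StageDistribution([0.0, 0.0, 0.0, 0.0, 1.0])
    fixtures["lethal"] = lethal

    return fixtures
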