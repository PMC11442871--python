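"""Model inputs for the biennial breast-screening cost-utility model.

Two screening strategies are compared: digital breast tomosynthesis combined
with mammography (``dbt``) and mammography alone (``mg``).  Every numeric
input — test performance, stage distributions at diagnosis, five-year
survival, costs (2021 USD, 30 NTD : 1 USD) and stage utilities — ships as a
machine-readable table (``data/key_inputs.csv``) and is exposed here as typed,
validated dataclasses.

Scales: percentages and per-mille values are normalised to plain
probabilities at load time; the CSV preserves the printed scales.

The cancer detection rate is internally always the product
``recall × biopsy|recall × PPV2`` (the shipped values satisfy this identity
to better than 0.01 per mille), and the mammography arm's missed-cancer rate
is the detection-rate gap between the two strategies.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

STAGES = (0, 1, 2, 3, 4)
STAGE_LABELS = ("0", "I", "II", "III", "IV")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScreeningPerformance:
    """Per-screen test performance of one strategy.

    ``biopsy_rate_given_recall`` is the fraction of recalled screenees who
    proceed to pathological biopsy (the "slice rate"); ``ppv2`` is the
    positive predictive value among biopsies.  ``cancer_detection_rate`` is
    the printed per-screen detection probability; :meth:`derived_detection_rate`
    recomputes it from the chain and is what the engines consume.
    """

    recall_rate: float
    biopsy_rate_given_recall: float
    ppv2: float
    cancer_detection_rate: float

    def derived_detection_rate(self) -> float:
        return self.recall_rate * self.biopsy_rate_given_recall * self.ppv2


@dataclass
class StageDistribution:
    """Probabilities over stages 0, I, II, III, IV (sum ~ 1)."""

    p_stage: list[float]

    def normalized(self) -> "StageDistribution":
        total = sum(self.p_stage)
        if total <= 0:
            raise ValueError("stage distribution has no mass")
        return StageDistribution([p / total for p in self.p_stage])


@dataclass
class SurvivalRates:
    """Five-year breast-cancer survival probability by stage at diagnosis."""

    s5_by_stage: list[float]


@dataclass
class CostSet:
    """Cost schedule in 2021 USD.

    Episode costs (exam, re-clinical visit, biopsy) are per event; treatment
    costs are lifetime totals per diagnosed case, accrued once at diagnosis.
    Indirect costs are productivity losses.
    """

    exam_direct: float
    revisit_direct: float
    revisit_indirect: float
    biopsy_direct: float
    biopsy_indirect: float
    treatment_direct_by_stage: list[float]
    treatment_indirect_by_stage: list[float]
    death_direct: float = 0.0
    death_indirect: float = 0.0
    currency_note: str = "2021 USD, 30 NTD : 1 USD, CPI-adjusted"


@dataclass
class UtilitySet:
    """Stage utilities: first year after diagnosis and subsequent years."""

    u_first_year_by_stage: list[float]
    u_after_first_year_by_stage: list[float]
    u_healthy: float = 1.0
    u_death: float = 0.0


@dataclass
class DistributionSpec:
    """Sampling distribution of one parameter for probabilistic analysis.

    ``dispersion`` is a coefficient of variation; beta parameters are
    moment-matched from (mean, CV), gamma uses shape = CV**-2.
    """

    family: str  # beta | gamma | dirichlet | fixed
    mean: float
    dispersion: float = 0.20

    def __post_init__(self) -> None:
        if self.family not in {"beta", "gamma", "dirichlet", "fixed"}:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "beta" and not 0.0 <= self.mean <= 1.0:
            raise ValueError("beta family requires mean in [0, 1]")
        if self.family == "gamma" and self.mean < 0:
            raise ValueError("gamma family requires non-negative mean")


@dataclass
class ModelConfig:
    """Global settings and structural switches.

    Defaults are the base case: two-year cycles, 15 cycles (30 years), 2%
    annual discounting of both costs and QALYs, willingness to pay $33,004
    per QALY (Taiwan's 2021 per-capita GDP), 10,000 Monte Carlo trials.

    Structural switches cover model mechanics the source data do not pin
    down; see docs/methods.md for the rationale behind each default:

    - ``survival_conversion``: how 5-year stage survival maps to a per-cycle
      death probability (``constant_hazard``: 1 - s5**(cycle/5);
      ``per_cycle_literal``: 1 - s5 per cycle).
    - ``missed_cancer_handling``: missed cancers enter care in the screening
      cycle itself (``immediate_stage_entry``) or spend one undiagnosed
      cycle first — bearing the stage's utility decrement but no treatment
      cost or breast-cancer mortality until diagnosis (``one_cycle_delay``).
    - ``survivor_pathway``: survivors of a cancer episode revert to the
      screening state (``return_to_screening``) or stay in a stage-specific
      post-cancer state (``remain_post``).
    - ``rescreen_survivors``: whether post-cancer occupants keep accruing
      screening costs (only meaningful under ``remain_post``).
    - ``death_timing``: whether those dying in a cycle forfeit that cycle's
      QALYs (``start_of_cycle``) or accrue them in full (``end_of_cycle``).
    """

    cycle_years: float = 2.0
    n_cycles: int = 15
    annual_discount: float = 0.02
    wtp: float = 33004.0
    n_trials: int = 10_000
    seed: int = 20210630
    survival_conversion: str = "per_cycle_literal"
    missed_cancer_handling: str = "one_cycle_delay"
    survivor_pathway: str = "return_to_screening"
    death_timing: str = "start_of_cycle"
    rescreen_survivors: bool = True
    psa_cv: float = 0.20

    def __post_init__(self) -> None:
        if self.cycle_years <= 0:
            raise ValueError("cycle_years must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if self.annual_discount < 0:
            raise ValueError("annual_discount must be non-negative")
        if self.survival_conversion not in {"constant_hazard", "per_cycle_literal"}:
            raise ValueError(f"unknown survival_conversion {self.survival_conversion!r}")
        if self.missed_cancer_handling not in {"immediate_stage_entry", "one_cycle_delay"}:
            raise ValueError(
                f"unknown missed_cancer_handling {self.missed_cancer_handling!r}"
            )
        if self.survivor_pathway not in {"return_to_screening", "remain_post"}:
            raise ValueError(f"unknown survivor_pathway {self.survivor_pathway!r}")
        if self.death_timing not in {"start_of_cycle", "end_of_cycle"}:
            raise ValueError(f"unknown death_timing {self.death_timing!r}")


@dataclass
class StrategyParams:
    """One screening strategy: performance, stage mix and cost schedule."""

    name: str
    performance: ScreeningPerformance
    diagnosed_stage_dist: StageDistribution
    costs: CostSet
    missed_cancer_rate: float = 0.0
    missed_stage_dist: StageDistribution | None = None


@dataclass
class ModelInputs:
    """The full input bundle: both strategies plus shared inputs."""

    dbt: StrategyParams
    mg: StrategyParams
    survival: SurvivalRates
    utilities: UtilitySet
    config: ModelConfig
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_SCALE_FACTOR = {"percent": 1e-2, "permille": 1e-3, "usd": 1.0, "utility": 1.0}


def load_key_inputs() -> pd.DataFrame:
    """Return the shipped key-input table (printed scales preserved)."""
    with resources.files("screencea.data").joinpath("key_inputs.csv").open() as fh:
        return pd.read_csv(fh)


def _flat_from_table(table: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    for row in table.itertuples(index=False):
        out[row.parameter] = float(row.value) * _SCALE_FACTOR[row.scale]
    return out


def link_missed_cancer(dbt: StrategyParams, mg: StrategyParams) -> float:
    """Set the MG missed-cancer rate to the detection-rate gap.

    A "missed cancer" is a cancer the better-performing strategy would have
    found: rate = max(0, detection(dbt) - detection(mg)).  Mutates ``mg`` and
    returns the rate.
    """
    gap = dbt.performance.derived_detection_rate() - mg.performance.derived_detection_rate()
    mg.missed_cancer_rate = max(0.0, gap)
    return mg.missed_cancer_rate


def _stage_values(flat: dict[str, float], prefix: str, stages: Iterable[int] = STAGES) -> list[float]:
    return [flat.get(f"{prefix}.{s}", 0.0) for s in stages]


def inputs_from_flat(flat: dict[str, float], config: ModelConfig | None = None) -> ModelInputs:
    """Assemble a :class:`ModelInputs` bundle from a flat parameter mapping.

    The flat keys are the rows of ``data/key_inputs.csv`` (detection rates may be
    omitted; they are derived).  Shared costs (revisit, biopsy, treatment,
    death) are applied to both strategies; only the examination cost differs.
    """
    config = config if config is not None else ModelConfig()

    def costset(exam_key: str) -> CostSet:
        return CostSet(
            exam_direct=flat[exam_key],
            revisit_direct=flat["cost.revisit_direct"],
            revisit_indirect=flat["cost.revisit_indirect"],
            biopsy_direct=flat["cost.biopsy_direct"],
            biopsy_indirect=flat["cost.biopsy_indirect"],
            treatment_direct_by_stage=_stage_values(flat, "cost.treatment_direct"),
            treatment_indirect_by_stage=_stage_values(flat, "cost.treatment_indirect"),
            death_direct=flat.get("cost.death_direct", 0.0),
            death_indirect=flat["cost.death_indirect"],
        )

    def performance(arm: str) -> ScreeningPerformance:
        perf = ScreeningPerformance(
            recall_rate=flat[f"{arm}.recall_rate"],
            biopsy_rate_given_recall=flat[f"{arm}.slice_rate"],
            ppv2=flat[f"{arm}.ppv2"],
            cancer_detection_rate=flat.get(f"{arm}.cancer_detection_rate", 0.0),
        )
        if perf.cancer_detection_rate == 0.0:
            perf.cancer_detection_rate = perf.derived_detection_rate()
        return perf

    dbt = StrategyParams(
        name="DBT-MG",
        performance=performance("dbt"),
        diagnosed_stage_dist=StageDistribution(_stage_values(flat, "dbt.stage_dist")),
        costs=costset("cost.dbt_exam"),
    )
    mg = StrategyParams(
        name="MG",
        performance=performance("mg"),
        diagnosed_stage_dist=StageDistribution(_stage_values(flat, "mg.stage_dist")),
        costs=costset("cost.mg_exam"),
        missed_stage_dist=StageDistribution(_stage_values(flat, "mg.missed_stage_dist")),
    )
    link_missed_cancer(dbt, mg)

    survival = SurvivalRates(_stage_values(flat, "survival.s5"))
    utilities = UtilitySet(
        u_first_year_by_stage=_stage_values(flat, "utility.first_year"),
        u_after_first_year_by_stage=_stage_values(flat, "utility.after_first_year"),
        u_healthy=flat.get("utility.healthy", 1.0),
        u_death=flat.get("utility.death", 0.0),
    )
    return ModelInputs(dbt=dbt, mg=mg, survival=survival, utilities=utilities, config=config)


def flat_from_inputs(inputs: ModelInputs) -> dict[str, float]:
    """Flatten a bundle back to the table's key space (round-trip of load)."""
    flat: dict[str, float] = {}
    for arm, strat in (("dbt", inputs.dbt), ("mg", inputs.mg)):
        perf = strat.performance
        flat[f"{arm}.recall_rate"] = perf.recall_rate
        flat[f"{arm}.slice_rate"] = perf.biopsy_rate_given_recall
        flat[f"{arm}.ppv2"] = perf.ppv2
        for s in STAGES:
            flat[f"{arm}.stage_dist.{s}"] = strat.diagnosed_stage_dist.p_stage[s]
    for s in STAGES:
        flat[f"mg.missed_stage_dist.{s}"] = (
            inputs.mg.missed_stage_dist.p_stage[s] if inputs.mg.missed_stage_dist else 0.0
        )
        flat[f"survival.s5.{s}"] = inputs.survival.s5_by_stage[s]
        flat[f"cost.treatment_direct.{s}"] = inputs.dbt.costs.treatment_direct_by_stage[s]
        flat[f"cost.treatment_indirect.{s}"] = inputs.dbt.costs.treatment_indirect_by_stage[s]
        flat[f"utility.first_year.{s}"] = inputs.utilities.u_first_year_by_stage[s]
        flat[f"utility.after_first_year.{s}"] = inputs.utilities.u_after_first_year_by_stage[s]
    flat["cost.dbt_exam"] = inputs.dbt.costs.exam_direct
    flat["cost.mg_exam"] = inputs.mg.costs.exam_direct
    for key, attr in (
        ("cost.revisit_direct", "revisit_direct"),
        ("cost.revisit_indirect", "revisit_indirect"),
        ("cost.biopsy_direct", "biopsy_direct"),
        ("cost.biopsy_indirect", "biopsy_indirect"),
        ("cost.death_direct", "death_direct"),
        ("cost.death_indirect", "death_indirect"),
    ):
        flat[key] = getattr(inputs.dbt.costs, attr)
    flat["utility.healthy"] = inputs.utilities.u_healthy
    flat["utility.death"] = inputs.utilities.u_death
    return flat


def default_distributions(table: pd.DataFrame, cv: float = 0.20) -> dict[str, DistributionSpec]:
    """Distribution registry from the table's distribution column.

    Beta for probability-scaled rows, gamma for costs and utilities, as
    annotated in the source table; detection rates are derived, not sampled.
    Dispersion (CV) is not published and defaults to 0.20.
    """
    registry: dict[str, DistributionSpec] = {}
    for row in table.itertuples(index=False):
        family = str(row.distribution)
        if family == "derived":
            continue
        mean = float(row.value) * _SCALE_FACTOR[row.scale]
        if family == "fixed" or mean == 0.0:
            registry[row.parameter] = DistributionSpec("fixed", mean, 0.0)
        else:
            registry[row.parameter] = DistributionSpec(family, mean, cv)
    return registry


def load_default_parameters(config: ModelConfig | None = None) -> ModelInputs:
    """Load the shipped base-case inputs for both strategies."""
    table = load_key_inputs()
    config = config if config is not None else ModelConfig()
    inputs = inputs_from_flat(_flat_from_table(table), config)
    # keep the printed per-mille detection rates alongside the derived chain
    flat = _flat_from_table(table)
    inputs.dbt.performance.cancer_detection_rate = flat["dbt.cancer_detection_rate"]
    inputs.mg.performance.cancer_detection_rate = flat["mg.cancer_detection_rate"]
    inputs.distributions = default_distributions(table, cv=config.psa_cv)
    return inputs


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationIssue:
    field: str
    message: str
    fatal: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "FATAL" if self.fatal else "warn"
        return f"[{tag}] {self.field}: {self.message}"


def _check_prob(issues: list[ValidationIssue], path: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        issues.append(ValidationIssue(path, f"probability {value} outside [0, 1]", fatal=True))


def validate(
    params: StrategyParams,
    survival: SurvivalRates,
    utilities: UtilitySet,
    detection_tol: float = 1e-3,
) -> list[ValidationIssue]:
    """Check every structural invariant of one strategy's inputs.

    Returns an empty list iff the inputs are internally consistent: all
    probabilities in range, stage distributions on the simplex, the
    detection-rate chain identity, survival non-increasing with stage,
    non-negative costs, utilities in [0, 1] with after-first-year at least
    first-year, and no stage-0 mass among missed cancers.
    """
    issues: list[ValidationIssue] = []
    perf = params.performance
    base = f"{params.name}.performance"
    _check_prob(issues, f"{base}.recall_rate", perf.recall_rate)
    _check_prob(issues, f"{base}.biopsy_rate_given_recall", perf.biopsy_rate_given_recall)
    _check_prob(issues, f"{base}.ppv2", perf.ppv2)
    _check_prob(issues, f"{base}.cancer_detection_rate", perf.cancer_detection_rate)
    if abs(perf.derived_detection_rate() - perf.cancer_detection_rate) > detection_tol:
        issues.append(
            ValidationIssue(
                f"{base}.cancer_detection_rate",
                "detection rate differs from recall x biopsy|recall x PPV2 "
                f"({perf.derived_detection_rate():.6f} vs {perf.cancer_detection_rate:.6f})",
            )
        )

    dists = [(f"{params.name}.diagnosed_stage_dist", params.diagnosed_stage_dist)]
    if params.missed_stage_dist is not None:
        dists.append((f"{params.name}.missed_stage_dist", params.missed_stage_dist))
    for path, dist in dists:
        for s, p in zip(STAGES, dist.p_stage):
            _check_prob(issues, f"{path}.p_stage[{s}]", p)
        total = sum(dist.p_stage)
        if not 0.999 <= total <= 1.001:
            issues.append(ValidationIssue(path, f"stage distribution sums to {total:.6f}"))
    if params.missed_cancer_rate < 0:
        issues.append(
            ValidationIssue(f"{params.name}.missed_cancer_rate", "negative rate", fatal=True)
        )
    if params.missed_stage_dist is not None and params.missed_stage_dist.p_stage[0] != 0.0:
        issues.append(
            ValidationIssue(
                f"{params.name}.missed_stage_dist.p_stage[0]",
                "missed cancers must carry no stage-0 mass",
            )
        )

    for s, s5 in zip(STAGES, survival.s5_by_stage):
        _check_prob(issues, f"survival.s5_by_stage[{s}]", s5)
    for a, b in zip(survival.s5_by_stage, survival.s5_by_stage[1:]):
        if b > a + 1e-12:
            issues.append(
                ValidationIssue("survival.s5_by_stage", "survival increases with stage")
            )
            break

    c = params.costs
    for path, value in [
        ("exam_direct", c.exam_direct),
        ("revisit_direct", c.revisit_direct),
        ("revisit_indirect", c.revisit_indirect),
        ("biopsy_direct", c.biopsy_direct),
        ("biopsy_indirect", c.biopsy_indirect),
        ("death_direct", c.death_direct),
        ("death_indirect", c.death_indirect),
        *[(f"treatment_direct_by_stage[{s}]", v) for s, v in enumerate(c.treatment_direct_by_stage)],
        *[(f"treatment_indirect_by_stage[{s}]", v) for s, v in enumerate(c.treatment_indirect_by_stage)],
    ]:
        if value < 0:
            issues.append(
                ValidationIssue(f"{params.name}.costs.{path}", "negative cost", fatal=True)
            )

    for s in STAGES:
        uf = utilities.u_first_year_by_stage[s]
        ua = utilities.u_after_first_year_by_stage[s]
        _check_prob(issues, f"utilities.u_first_year_by_stage[{s}]", uf)
        _check_prob(issues, f"utilities.u_after_first_year_by_stage[{s}]", ua)
        if ua < uf - 1e-12:
            issues.append(
                ValidationIssue(
                    f"utilities[{s}]", "after-first-year utility below first-year utility"
                )
            )
    return issues


def indirect_episode_cost(hours_lost: float, hourly_wage: float, participation: float) -> float:
    """Productivity loss of one care episode.

    lost labour hours x hourly wage x labour-force participation rate.
    Provided as a derivation helper; the shipped table's printed indirect
    costs remain the authoritative model inputs.
    """
    if hours_lost < 0 or hourly_wage < 0 or participation < 0:
        raise ValueError("indirect cost inputs must be non-negative")
    return hours_lost * hourly_wage * participation
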