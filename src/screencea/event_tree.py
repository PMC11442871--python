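"""Single-cycle screening decision tree.

One biennial screen resolves as: screen -> negative | recall; recall ->
negative | biopsy; biopsy -> negative | cancer (by stage at diagnosis).  In
the mammography arm an additional slice of the screen-negative mass is a
missed cancer (stage-shifted, no stage 0).  The tree yields the per-cycle
branch probabilities and the expected pre-diagnosis cost per screenee.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import STAGES, StrategyParams


@dataclass
class CycleOutcome:
    """Branch probabilities and pre-diagnosis cost of one screening cycle.

    ``p_negative`` is the residual screen-negative-and-truly-negative mass,
    so the five components always sum to exactly 1.
    """

    p_negative: float
    p_recall_negative: float
    p_biopsy_negative: float
    p_cancer_by_stage: list[float]
    p_missed_by_stage: list[float]
    expected_pre_diagnosis_cost: float

    def total(self) -> float:
        return (
            self.p_negative
            + self.p_recall_negative
            + self.p_biopsy_negative
            + sum(self.p_cancer_by_stage)
            + sum(self.p_missed_by_stage)
        )


def expected_pre_diagnosis_cost(strategy: StrategyParams) -> float:
    """Expected cost per screen before any cancer diagnosis.

    exam + recall x (revisit direct + indirect)
         + recall x biopsy|recall x (biopsy direct + indirect).
    Recall and biopsy episode costs (including productivity losses) accrue in
    the cycle of the episode.
    """
    perf, costs = strategy.performance, strategy.costs
    p_biopsy = perf.recall_rate * perf.biopsy_rate_given_recall
    return (
        costs.exam_direct
        + perf.recall_rate * (costs.revisit_direct + costs.revisit_indirect)
        + p_biopsy * (costs.biopsy_direct + costs.biopsy_indirect)
    )


def cycle_outcome(strategy: StrategyParams) -> CycleOutcome:
    """Resolve one screening cycle into its branch probabilities.

    Detection is the chain product recall x biopsy|recall x PPV2 split over
    the stage-at-diagnosis distribution; missed cancers (if the strategy has
    a missed-cancer rate) are carved out of the screen-negative mass using
    the stage-shifted missed distribution.
    """
    perf = strategy.performance
    r = perf.recall_rate
    b = perf.biopsy_rate_given_recall
    detection = perf.derived_detection_rate()

    p_recall_negative = r * (1.0 - b)
    p_biopsy_negative = r * b * (1.0 - perf.ppv2)
    p_cancer = [detection * p for p in strategy.diagnosed_stage_dist.normalized().p_stage]

    if strategy.missed_cancer_rate > 0 and strategy.missed_stage_dist is not None:
        p_missed = [
            strategy.missed_cancer_rate * p
            for p in strategy.missed_stage_dist.normalized().p_stage
        ]
    else:
        p_missed = [0.0] * len(STAGES)

    accounted = p_recall_negative + p_biopsy_negative + sum(p_cancer) + sum(p_missed)
    if accounted > 1.0 + 1e-12:
        raise ValueError(
            f"strategy {strategy.name!r}: branch probabilities sum to {accounted:.6f} > 1"
        )
    return CycleOutcome(
        p_negative=1.0 - accounted,
        p_recall_negative=p_recall_negative,
        p_biopsy_negative=p_biopsy_negative,
        p_cancer_by_stage=p_cancer,
        p_missed_by_stage=p_missed,
        expected_pre_diagnosis_cost=expected_pre_diagnosis_cost(strategy),
    )


def early_detection_rate(strategy: StrategyParams, early_stages: set[int] = frozenset({0, 1})) -> float:
    """Per-screen probability of detecting a cancer in the given stages.

    Defaults to stages 0 and I ("early" breast cancer).
    """
    early = set(early_stages)
    if not early:
        raise ValueError("early_stages must be non-empty")
    if not early <= set(STAGES):
        raise ValueError(f"unknown stages {early - set(STAGES)}")
    dist = strategy.diagnosed_stage_dist.normalized().p_stage
    return strategy.performance.derived_detection_rate() * sum(dist[s] for s in early)


def outcome_frame(outcomes: dict[str, CycleOutcome]) -> pd.DataFrame:
    """One audit row per strategy (CSV-ready)."""
    rows = []
    for name, o in outcomes.items():
        row = {
            "strategy": name,
            "p_negative": o.p_negative,
            "p_recall_negative": o.p_recall_negative,
            "p_biopsy_negative": o.p_biopsy_negative,
            "expected_pre_diagnosis_cost": o.expected_pre_diagnosis_cost,
        }
        for s in STAGES:
            row[f"p_cancer_stage_{s}"] = o.p_cancer_by_stage[s]
            row[f"p_missed_stage_{s}"] = o.p_missed_by_stage[s]
        rows.append(row)
    return pd.DataFrame(rows)
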