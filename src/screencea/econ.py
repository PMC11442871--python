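"""Incremental cost-effectiveness arithmetic.

ICER = incremental cost / incremental QALYs; NMB = QALYs x WTP - cost.  The
strategy ranking by NMB flips exactly at WTP = ICER.  Negative ratios are
ambiguous without quadrant context, so dominance is reported as an explicit
flag while the raw ratio is retained for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .markov import CycleTrace

#: dominance flags
RATIO = "ratio"
DOMINANT = "dominant"  # less costly, more effective
DOMINATED = "dominated"  # more costly, less effective
INDETERMINATE = "indeterminate"  # equal effectiveness


@dataclass
class Icer:
    """An ICER with its dominance classification.

    ``value`` is the ratio when ``flag == "ratio"`` (it may legitimately be
    negative only when both increments are negative); ``raw`` always carries
    delta_cost / delta_qaly where defined, for tornado/plot fidelity.
    """

    value: float
    flag: str
    raw: float


def icer(delta_cost: float, delta_qaly: float) -> Icer:
    """Classify and compute the incremental cost-effectiveness ratio."""
    if delta_qaly == 0.0:
        return Icer(math.nan, INDETERMINATE, math.inf if delta_cost > 0 else -math.inf)
    raw = delta_cost / delta_qaly
    if delta_qaly > 0 and delta_cost < 0:
        return Icer(raw, DOMINANT, raw)
    if delta_qaly < 0 and delta_cost > 0:
        return Icer(raw, DOMINATED, raw)
    return Icer(raw, RATIO, raw)


def nmb(qalys: float, cost: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return qalys * wtp - cost


def quadrant(delta_cost: float, delta_qaly: float, wtp: float) -> str:
    """CE-plane quadrant of an increment pair, split at the WTP line.

    NE (more costly, more effective) is split into ``ne_below_wtp``
    (cost-effective) and ``ne_above_wtp``; SE is ``cost_saving``.
    Boundary ties count toward the cost-effective side.
    """
    if delta_qaly > 0 and delta_cost <= 0:
        return "cost_saving"
    if delta_qaly >= 0 and delta_cost > 0:
        return "ne_below_wtp" if delta_cost <= wtp * delta_qaly else "ne_above_wtp"
    if delta_qaly < 0 and delta_cost > 0:
        return "dominated_nw"
    return "sw"


@dataclass
class CEResult:
    """Paired totals and increments of strategy A vs strategy B."""

    strategy_a: str
    strategy_b: str
    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_a - self.cost_b

    @property
    def delta_qaly(self) -> float:
        return self.qaly_a - self.qaly_b

    @property
    def icer(self) -> Icer:
        return icer(self.delta_cost, self.delta_qaly)

    @property
    def nmb_a(self) -> float:
        return nmb(self.qaly_a, self.cost_a, self.wtp)

    @property
    def nmb_b(self) -> float:
        return nmb(self.qaly_b, self.cost_b, self.wtp)

    @property
    def quadrant(self) -> str:
        return quadrant(self.delta_cost, self.delta_qaly, self.wtp)

    def to_record(self) -> dict:
        rec = asdict(self)
        rec.update(
            delta_cost=self.delta_cost,
            delta_qaly=self.delta_qaly,
            icer=self.icer.value,
            icer_flag=self.icer.flag,
            nmb_a=self.nmb_a,
            nmb_b=self.nmb_b,
            quadrant=self.quadrant,
        )
        return rec


def compare(trace_a: CycleTrace, trace_b: CycleTrace, wtp: float) -> CEResult:
    """Build a :class:`CEResult` from two cohort traces."""
    return CEResult(
        strategy_a=trace_a.strategy,
        strategy_b=trace_b.strategy,
        cost_a=trace_a.total_cost,
        cost_b=trace_b.total_cost,
        qaly_a=trace_a.total_qaly,
        qaly_b=trace_b.total_qaly,
        wtp=wtp,
    )


def population_projection(
    per_screen_delta_cost: float,
    early_detection_delta: float,
    n_screened: int,
) -> tuple[float, float]:
    """Scale per-screen increments to a screened population.

    Returns (additional cost in USD, additional early-stage cancers
    detected) for ``n_screened`` women.
    """
    if n_screened < 0:
        raise ValueError("n_screened must be non-negative")
    return (
        n_screened * per_screen_delta_cost,
        n_screened * early_detection_delta,
    )
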