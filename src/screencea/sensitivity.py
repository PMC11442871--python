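"""Uncertainty and scenario analysis around the base-case comparison.

- probabilistic sensitivity analysis (PSA): second-order Monte Carlo over
  the parameter distribution registry, summarised on the cost-effectiveness
  plane and as acceptability curves (CEAC);
- one-way (tornado) analysis: each parameter varied to (1 +/- band) x base
  with everything else held fixed;
- horizon analysis: the base case and its increments at truncated horizons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import econ
from .markov import CycleTrace, run_cohort
from .parameters import (
    DistributionSpec,
    ModelConfig,
    ModelInputs,
    flat_from_inputs,
    inputs_from_flat,
    link_missed_cancer,
)

# ---------------------------------------------------------------------------
# shared runner
# ---------------------------------------------------------------------------


def evaluate_pair(
    inputs: ModelInputs, n_cycles: int | None = None
) -> tuple[CycleTrace, CycleTrace, econ.CEResult]:
    """Run both strategies and return traces plus the paired comparison.

    The mammography missed-cancer rate is refreshed from the current
    detection-rate gap before running, so perturbed inputs stay internally
    consistent.
    """
    config = inputs.config
    if n_cycles is not None and n_cycles != config.n_cycles:
        config = ModelConfig(**{**config.__dict__, "n_cycles": n_cycles})
    link_missed_cancer(inputs.dbt, inputs.mg)
    trace_a = run_cohort(inputs.dbt, inputs.survival, inputs.utilities, config)
    trace_b = run_cohort(inputs.mg, inputs.survival, inputs.utilities, config)
    return trace_a, trace_b, econ.compare(trace_a, trace_b, config.wtp)


def run_base_case(inputs: ModelInputs) -> econ.CEResult:
    """Deterministic base-case comparison at the configured horizon."""
    return evaluate_pair(inputs)[2]


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


def _sample_one(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from one parameter's distribution.

    Beta parameters are moment-matched from (mean, sd) where the sd is the
    CV applied to the distance to the nearer boundary of [0, 1], keeping the
    match feasible for means near 0 or 1.  Gamma uses shape = CV**-2,
    scale = mean x CV**2.
    """
    m, cv = spec.mean, spec.dispersion
    if spec.family == "fixed" or cv == 0.0 or m == 0.0:
        return np.full(n, m)
    if spec.family == "beta":
        sd = cv * min(m, 1.0 - m)
        var = sd * sd
        nu = m * (1.0 - m) / var - 1.0
        if nu <= 0.0:
            raise ValueError(
                f"infeasible beta moment match: mean={m}, cv={cv} (variance too large)"
            )
        return rng.beta(m * nu, (1.0 - m) * nu, size=n)
    if spec.family == "gamma":
        shape = 1.0 / (cv * cv)
        return rng.gamma(shape, m / shape, size=n)
    raise ValueError(f"cannot sample family {spec.family!r}")


def default_psa_parameters(inputs: ModelInputs) -> list[str]:
    """Parameters sampled by default in the probabilistic analysis.

    All cost, utility and survival parameters — the inputs whose uncertainty
    is parametric.  The test-performance chains and stage mixes define the
    strategies under comparison and are explored in the one-way analysis
    instead; sampling them independently would routinely produce draws in
    which mammography alone out-detects the combined modality, a possibility
    the underlying clinical evidence excludes.  Pass ``include="all"`` to
    :func:`run_psa` to sample every registered parameter anyway.
    """
    return [
        k
        for k, spec in inputs.distributions.items()
        if spec.family != "fixed" and k.startswith(("cost.", "utility.", "survival."))
    ]


def sample_parameter_draws(
    inputs: ModelInputs,
    n: int,
    rng: np.random.Generator,
    include: list[str] | None = None,
) -> tuple[dict[str, np.ndarray], float]:
    """Sample ``n`` joint parameter draws from the distribution registry.

    Returns (flat key -> array of n values, utility clamp rate).  Keys not in
    the registry (or not in ``include``, when given) stay at their base
    value.  Sampled utilities are clamped to [0, 1]; stage distributions are
    renormalised at evaluation time, which keeps them on the simplex.
    """
    base_flat = flat_from_inputs(inputs)
    draws: dict[str, np.ndarray] = {}
    clamped = 0
    n_utility = 0
    for key, base in base_flat.items():
        spec = inputs.distributions.get(key)
        if include is not None and key not in include:
            spec = None
        if spec is None:
            draws[key] = np.full(n, base)
            continue
        values = _sample_one(spec, n, rng)
        if key.startswith("utility."):
            n_utility += n
            clamped += int((values > 1.0).sum() + (values < 0.0).sum())
            values = np.clip(values, 0.0, 1.0)
        draws[key] = values
    clamp_rate = clamped / n_utility if n_utility else 0.0
    return draws, clamp_rate


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-draw CE-plane points with quadrant and acceptability summaries."""

    draws: pd.DataFrame  # delta_cost, delta_qaly, cost/qaly per strategy
    quadrant_probs: dict[str, float]
    p_cost_effective_at_wtp: float
    ceac: pd.DataFrame  # wtp, p_dbt_mg, p_mg
    wtp: float
    seed: int
    n_draws: int
    clamp_rate: float = 0.0

    @property
    def p_cost_saving(self) -> float:
        return self.quadrant_probs.get("cost_saving", 0.0)


def default_wtp_grid(wtp: float, n_points: int = 61) -> np.ndarray:
    """WTP grid from 0 to twice the threshold."""
    return np.linspace(0.0, 2.0 * wtp, n_points)


def ceac(draws: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA draws.

    For each WTP, the probability that the comparator-vs-baseline increment
    has non-negative incremental NMB (ties count as cost-effective); the
    baseline curve is its complement.
    """
    if len(draws) == 0:
        raise ValueError("no PSA draws")
    dc = draws["delta_cost"].to_numpy()
    de = draws["delta_qaly"].to_numpy()
    p = [(de * w - dc >= 0.0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "p_dbt_mg": p, "p_mg": 1.0 - np.asarray(p)})


def run_psa(
    inputs: ModelInputs,
    n: int | None = None,
    seed: int | None = None,
    wtp_grid: np.ndarray | None = None,
    n_cycles: int | None = None,
    include: list[str] | str | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over the parameter distribution registry.

    Each draw samples the included parameters (default: the cost, utility
    and survival inputs, see :func:`default_psa_parameters`; ``"all"``
    samples everything registered), rebuilds both strategies (detection
    rates re-derived from the sampled chain, missed-cancer rate re-linked to
    the sampled detection gap) and runs the deterministic cohort engine for
    both.  Reproducible under a fixed seed.
    """
    config = inputs.config
    n = config.n_trials if n is None else n
    if n < 1:
        raise ValueError("n must be at least 1")
    seed = config.seed if seed is None else seed
    if n_cycles is not None and n_cycles != config.n_cycles:
        config = ModelConfig(**{**config.__dict__, "n_cycles": n_cycles})
    if include is None:
        include_keys = default_psa_parameters(inputs)
    elif include == "all":
        include_keys = [k for k, s in inputs.distributions.items() if s.family != "fixed"]
    else:
        include_keys = list(include)
    rng = np.random.default_rng(seed)
    sampled, clamp_rate = sample_parameter_draws(inputs, n, rng, include=include_keys)

    records = np.empty((n, 4))
    keys = list(sampled)
    for i in range(n):
        flat = {k: float(sampled[k][i]) for k in keys}
        draw_inputs = inputs_from_flat(flat, config)
        ta = run_cohort(draw_inputs.dbt, draw_inputs.survival, draw_inputs.utilities, config)
        tb = run_cohort(draw_inputs.mg, draw_inputs.survival, draw_inputs.utilities, config)
        records[i] = (ta.total_cost, tb.total_cost, ta.total_qaly, tb.total_qaly)

    draws = pd.DataFrame(records, columns=["cost_dbt_mg", "cost_mg", "qaly_dbt_mg", "qaly_mg"])
    draws["delta_cost"] = draws["cost_dbt_mg"] - draws["cost_mg"]
    draws["delta_qaly"] = draws["qaly_dbt_mg"] - draws["qaly_mg"]
    draws["quadrant"] = [
        econ.quadrant(dc, de, config.wtp)
        for dc, de in zip(draws["delta_cost"], draws["delta_qaly"])
    ]
    counts = draws["quadrant"].value_counts(normalize=True)
    quadrant_probs = {
        q: float(counts.get(q, 0.0))
        for q in ("ne_below_wtp", "ne_above_wtp", "cost_saving", "dominated_nw", "sw")
    }
    grid = default_wtp_grid(config.wtp) if wtp_grid is None else np.asarray(wtp_grid, float)
    curves = ceac(draws, grid)
    return PSAResult(
        draws=draws,
        quadrant_probs=quadrant_probs,
        p_cost_effective_at_wtp=quadrant_probs["ne_below_wtp"] + quadrant_probs["cost_saving"],
        ceac=curves,
        wtp=config.wtp,
        seed=seed,
        n_draws=n,
        clamp_rate=clamp_rate,
    )


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------

#: flat-key prefixes whose values live on [0, 1]
_UNIT_INTERVAL_PREFIXES = ("dbt.", "mg.", "survival.", "utility.")


@dataclass
class TornadoResult:
    """Sorted one-way sensitivity table around the base-case ICER."""

    table: pd.DataFrame  # parameter, base, low/high inputs, low/high ICER, span
    base_icer: float
    band: float

    @property
    def global_range(self) -> tuple[float, float]:
        lo = float(np.minimum(self.table["icer_low"], self.table["icer_high"]).min())
        hi = float(np.maximum(self.table["icer_low"], self.table["icer_high"]).max())
        return lo, hi


def run_owsa(
    inputs: ModelInputs,
    parameters: list[str] | None = None,
    band: float = 0.20,
) -> TornadoResult:
    """One-way sensitivity analysis: each parameter to (1 +/- band) x base.

    Probability- and utility-valued parameters are capped at 1.  The table is
    sorted by descending ICER span.  Raw ratios are reported even when an
    extreme flips the sign (a negative ratio with positive incremental QALYs
    means the comparator became cost-saving).
    """
    if band < 0:
        raise ValueError("band must be non-negative")
    base_flat = flat_from_inputs(inputs)
    if parameters is None:
        parameters = [
            k
            for k, spec in inputs.distributions.items()
            if spec.family != "fixed" and k in base_flat
        ]
    unknown = [p for p in parameters if p not in base_flat]
    if unknown:
        raise KeyError(f"unknown parameter path(s): {unknown}")

    base_icer = run_base_case(inputs).icer.raw

    def icer_at(key: str, value: float) -> float:
        flat = dict(base_flat)
        if key.startswith(_UNIT_INTERVAL_PREFIXES):
            value = min(value, 1.0)
        flat[key] = value
        perturbed = inputs_from_flat(flat, inputs.config)
        return evaluate_pair(perturbed)[2].icer.raw

    rows = []
    for key in parameters:
        base = base_flat[key]
        low_in, high_in = base * (1.0 - band), base * (1.0 + band)
        icer_low = icer_at(key, low_in)
        icer_high = icer_at(key, high_in)
        rows.append(
            {
                "parameter": key,
                "base_value": base,
                "low_input": low_in,
                "high_input": min(high_in, 1.0) if key.startswith(_UNIT_INTERVAL_PREFIXES) else high_in,
                "icer_low": icer_low,
                "icer_high": icer_high,
                "span": abs(icer_high - icer_low),
            }
        )
    table = pd.DataFrame(rows).sort_values("span", ascending=False, ignore_index=True)
    return TornadoResult(table=table, base_icer=base_icer, band=band)


# ---------------------------------------------------------------------------
# horizon analysis
# ---------------------------------------------------------------------------


def horizon_analysis(
    inputs: ModelInputs,
    horizons: tuple[int, ...] = (5, 10, 15),
    psa_n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Base-case comparison truncated at each horizon (in cycles).

    With ``psa_n`` set, also reports the PSA probability that the comparator
    is cost-effective or cost-saving at each horizon.
    """
    if not horizons:
        raise ValueError("horizons must be non-empty")
    rows = []
    for h in horizons:
        _, _, ce = evaluate_pair(inputs, n_cycles=h)
        row = {
            "cycles": h,
            "years": h * inputs.config.cycle_years,
            "cost_dbt_mg": ce.cost_a,
            "cost_mg": ce.cost_b,
            "delta_cost": ce.delta_cost,
            "qaly_dbt_mg": ce.qaly_a,
            "qaly_mg": ce.qaly_b,
            "delta_qaly": ce.delta_qaly,
            "icur": ce.icer.raw,
        }
        if psa_n:
            psa = run_psa(inputs, n=psa_n, seed=seed, n_cycles=h)
            row["p_cost_effective"] = psa.p_cost_effective_at_wtp
        rows.append(row)
    return pd.DataFrame(rows)
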