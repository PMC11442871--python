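"""Configuration files, result serialisation, plotting and run manifests.

CSV is the canonical tabular output; plots (CE plane, CEAC, tornado, NMB
curves) are best-effort renderings and are never parsed back.  Every
persisted run carries a manifest (config hash, seed, version, command,
outputs) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import __version__
from .econ import CEResult, nmb
from .parameters import (
    ModelConfig,
    ModelInputs,
    flat_from_inputs,
    inputs_from_flat,
    load_key_inputs,
    _flat_from_table,
    default_distributions,
)
from .sensitivity import PSAResult, TornadoResult

log = logging.getLogger("screencea")

_CONFIG_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}


def load_config(path: str | Path | None = None) -> ModelInputs:
    """Load model inputs from a YAML config file.

    The file may contain a ``config`` section (any :class:`ModelConfig`
    field) and a ``parameters`` section of flat-key overrides of the shipped
    base case.  An empty or missing file yields the base case.  Unknown keys
    are rejected by name.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown_sections = set(raw) - {"config", "parameters"}
    if unknown_sections:
        raise KeyError(f"unknown config section(s): {sorted(unknown_sections)}")

    cfg_over = raw.get("config", {}) or {}
    unknown = set(cfg_over) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    config = ModelConfig(**cfg_over)

    table = load_key_inputs()
    flat = _flat_from_table(table)
    overrides = raw.get("parameters", {}) or {}
    unknown = set(overrides) - set(flat)
    if unknown:
        raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
    flat.update({k: float(v) for k, v in overrides.items()})
    inputs = inputs_from_flat(flat, config)
    inputs.distributions = default_distributions(table, cv=config.psa_cv)
    return inputs


def save_config(inputs: ModelInputs, path: str | Path) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    payload = {
        "config": dataclasses.asdict(inputs.config),
        "parameters": {k: float(v) for k, v in flat_from_inputs(inputs).items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_hash(inputs: ModelInputs) -> str:
    payload = {
        "config": dataclasses.asdict(inputs.config),
        "parameters": flat_from_inputs(inputs),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written next to every persisted result."""

    command: str
    seed: int
    config_hash: str
    version: str
    timestamp: str
    outputs: list[str]

    @classmethod
    def create(cls, command: str, inputs: ModelInputs, outputs: list[str]) -> "RunManifest":
        return cls(
            command=command,
            seed=inputs.config.seed,
            config_hash=config_hash(inputs),
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            outputs=outputs,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def log_structural_settings(config: ModelConfig) -> None:
    log.info(
        "structural switches: survival_conversion=%s missed_cancer_handling=%s "
        "survivor_pathway=%s rescreen_survivors=%s",
        config.survival_conversion,
        config.missed_cancer_handling,
        config.survivor_pathway,
        config.rescreen_survivors,
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_ce_plane(psa: PSAResult, path: str | Path) -> None:
    """Incremental cost-utility scatter with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.draws["delta_qaly"], psa.draws["delta_cost"], s=4, alpha=0.3, color="seagreen")
    xs = np.array(ax.get_xlim())
    ax.plot(xs, psa.wtp * xs, "k--", lw=1, label=f"WTP ${psa.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(psa: PSAResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(psa.ceac["wtp"], psa.ceac["p_dbt_mg"], label="DBT-MG")
    ax.plot(psa.ceac["wtp"], psa.ceac["p_mg"], label="MG")
    ax.axvline(psa.wtp, color="grey", ls=":", lw=1)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(tornado: TornadoResult, path: str | Path, top: int = 15) -> None:
    table = tornado.table.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
    for i, row in enumerate(table.itertuples(index=False)):
        lo, hi = sorted((row.icer_low, row.icer_high))
        ax.barh(i, hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.axvline(tornado.base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels(table["parameter"])
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_nmb(ce: CEResult, path: str | Path, wtp_max: float | None = None) -> None:
    """NMB of both strategies against the WTP threshold."""
    wtp_max = 2.0 * ce.wtp if wtp_max is None else wtp_max
    grid = np.linspace(0.0, wtp_max, 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, [nmb(ce.qaly_a, ce.cost_a, w) for w in grid], label=ce.strategy_a)
    ax.plot(grid, [nmb(ce.qaly_b, ce.cost_b, w) for w in grid], label=ce.strategy_b)
    ax.axvline(ce.wtp, color="grey", ls=":", lw=1)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("net monetary benefit (USD)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
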