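"""Configuration files, output writers, and the reproducibility manifest.

Configs are YAML (JSON is valid YAML) with four optional sections —
``fiber``, ``rates``, ``sim``, ``ensemble`` — whose missing fields fall back
to the baseline parameter set (72.7 nm fiber, k_unbind=0.05, k_crawl=57.6,
k_deg=k_exp=5 1/s, cleavage fraction 2/3, 10,000 runs). Unknown keys are
rejected so typos fail loudly. Every output directory written by the CLI
carries a manifest sufficient to reproduce it bitwise.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import FiberSpec
from .ssa import RateSet, SimConfig

__all__ = [
    "Config",
    "RunManifest",
    "load_config",
    "save_config",
    "write_summary_csv",
    "write_map_json",
]

_SECTIONS = {
    "fiber": ("diameter_nm", "protein_fraction", "protofibril_diameter_nm"),
    "rates": ("k_unbind", "k_crawl", "k_deg", "k_exp"),
    "sim": (
        "cleavage_fraction",
        "record_fractions",
        "record_events",
        "stop_at_cleavage",
        "max_events",
    ),
    "ensemble": ("n_runs", "master_seed"),
}


@dataclass(frozen=True)
class Config:
    fiber: FiberSpec = field(default_factory=lambda: FiberSpec(72.7))
    rates: RateSet = field(default_factory=RateSet)
    sim: SimConfig = field(default_factory=SimConfig)
    n_runs: int = 10_000
    master_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fiber": dataclasses.asdict(self.fiber),
            "rates": dataclasses.asdict(self.rates),
            "sim": dataclasses.asdict(self.sim),
            "ensemble": {"n_runs": self.n_runs, "master_seed": self.master_seed},
        }


def _check_keys(section: str, data: dict) -> None:
    unknown = set(data) - set(_SECTIONS[section])
    if unknown:
        raise ValueError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}"
        )


def load_config(path: str | Path) -> Config:
    """Load a YAML/JSON config, filling omitted fields with baseline defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for sec in _SECTIONS:
        sec_data = raw.get(sec) or {}
        if not isinstance(sec_data, dict):
            raise ValueError(f"config section '{sec}' must be a mapping")
        _check_keys(sec, sec_data)
    ens = raw.get("ensemble") or {}
    n_runs = int(ens.get("n_runs", 10_000))
    if n_runs < 1:
        raise ValueError("ensemble.n_runs must be >= 1")
    return Config(
        fiber=FiberSpec(**{"diameter_nm": 72.7, **(raw.get("fiber") or {})}),
        rates=RateSet(**(raw.get("rates") or {})),
        sim=SimConfig(**(raw.get("sim") or {})),
        n_runs=n_runs,
        master_seed=int(ens.get("master_seed", 0)),
    )


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce an output bitwise."""

    config: dict
    master_seed: int
    n_runs: int
    command: str
    software: str
    timestamp: str

    @classmethod
    def create(cls, cfg: Config, command: str) -> "RunManifest":
        from . import __version__

        return cls(
            config=cfg.to_dict(),
            master_seed=cfg.master_seed,
            n_runs=cfg.n_runs,
            command=command,
            software=f"fiberlysis {__version__}",
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def write_summary_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Comma-delimited, header row, '.' decimal, UTF-8, POSIX newlines."""
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_map_json(counts: np.ndarray, side: int, path: str | Path, **meta) -> None:
    """A degradation map as a JSON grid of degraded-doublet counts."""
    payload = {
        "side": side,
        "grid": np.asarray(counts).reshape(side, side).tolist(),
        **meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
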