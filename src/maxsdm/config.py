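"""Run configuration: a YAML/JSON file of fitting defaults."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Fitting defaults shared by the CLI subcommands.

    Fields mirror the library's keyword arguments; unknown keys in a
    config file are rejected so typos fail loudly.
    """

    classes: str = "LHT"
    rm: float = 2.0
    n_knots: int = 50
    n_background: int = 10_000
    max_iter: int = 5000
    tol: float = 1e-4
    train_fraction: float = 0.75
    correlation_threshold: float = 0.8
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a ``.yaml``/``.yml`` or ``.json`` file."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    data = data or {}
    known = set(asdict(RunConfig()))
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
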