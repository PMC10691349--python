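"""Run configuration: YAML loading, validation, and parameter resolution.

A run config names one model section (``mito``, ``account``, ``channel``,
``net`` or ``aval``), carries the run-level settings (duration, dt, seed,
output directory) and a ``params`` mapping of overrides for that model's
parameter dataclass.  Unknown keys are rejected with the offending key
path so configuration typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .accounting import AccountingParams
from .channel import ChannelParams
from .errors import ConfigError
from .mito import EnergyBudget, MitoParams
from .network import NetworkConfig

MODELS = ("mito", "account", "channel", "net", "aval")

_PARAM_CLASSES = {
    "mito": MitoParams,
    "account": AccountingParams,
    "channel": ChannelParams,
    "net": NetworkConfig,
    "aval": None,  # avalanche analysis takes per-command options, not a dataclass
}


@dataclass
class RunConfig:
    """Validated run-level configuration."""

    model: str
    params: dict = field(default_factory=dict)
    budget: dict = field(default_factory=dict)   #: EnergyBudget overrides (mito/account)
    duration: float = 1000.0
    dt: float | None = None
    seed: int = 0
    outdir: str = "."
    record_subsample: int = 10

    def __post_init__(self):
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigError("seed must be a nonnegative integer")
        if self.dt is not None and self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolve_params(self):
        """Build the model's parameter dataclass with overrides applied."""
        cls = _PARAM_CLASSES[self.model]
        if cls is None:
            if self.params:
                raise ConfigError("model 'aval' takes no params section")
            return None
        _check_keys(cls, self.params, f"params ({self.model})")
        kwargs = dict(self.params)
        if self.budget:
            _check_keys(EnergyBudget, self.budget, "budget")
            if self.model == "account":
                kwargs["budget"] = EnergyBudget(**self.budget)
            elif self.model != "mito":
                raise ConfigError("budget section applies only to mito/account models")
        return cls(**kwargs)

    def resolve_budget(self) -> EnergyBudget:
        _check_keys(EnergyBudget, self.budget, "budget")
        return EnergyBudget(**self.budget)


def _check_keys(cls, mapping: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in mapping:
        if key not in valid:
            raise ConfigError(f"unknown key {where}.{key!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; defaults fill missing keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise ConfigError(f"{path}: empty config")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in valid:
            raise ConfigError(f"{path}: unknown key {key!r}")
    if "model" not in raw:
        raise ConfigError(f"{path}: missing required key 'model'")
    cfg = RunConfig(**raw)
    cfg.resolve_params()  # surface bad nested keys at load time
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a config back to YAML; ``load_config(save_config(c)) == c``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
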