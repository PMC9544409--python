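"""Run configuration: schema, defaults, YAML/JSON loading.

One flat config object carries the partition-model parameters, the
fractionation protocol volumes and the densitometry defaults used across
the CLI. Defaults reproduce the typical bench protocol: 40 µL dispersion,
2 µL droplet phase, retained volumes 15, 15, 5 µL over three rounds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .densitometry import (
    DEFAULT_ALS_ASYMMETRY,
    DEFAULT_ALS_ITERATIONS,
    DEFAULT_ALS_SMOOTHNESS,
)
from .errors import ConfigurationError
from .partition import DEFAULT_K_CAP, DEFAULT_LAMBDA_EFF, PartitionModel, Protocol

__all__ = ["RunConfig", "load_config", "dump_config"]

logger = logging.getLogger("wwfrac")


@dataclass(frozen=True)
class RunConfig:
    lambda_eff: float = DEFAULT_LAMBDA_EFF
    K_cap: float = DEFAULT_K_CAP
    V_total_uL: float = 40.0
    V_droplet_uL: float = 2.0
    retained_volumes_uL: tuple[float, ...] = (15.0, 15.0, 5.0)
    keep_supernatant_share: bool = True
    als_smoothness: float = DEFAULT_ALS_SMOOTHNESS
    als_asymmetry: float = DEFAULT_ALS_ASYMMETRY
    als_iterations: int = DEFAULT_ALS_ITERATIONS
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "retained_volumes_uL", tuple(float(f) for f in self.retained_volumes_uL)
        )
        # constructing these validates all cross-field invariants
        self.model()
        self.protocol()
        if self.verbosity not in ("debug", "info", "warning", "error"):
            raise ConfigurationError(f"unknown verbosity {self.verbosity!r}")

    def model(self) -> PartitionModel:
        return PartitionModel(lambda_eff=self.lambda_eff, K_cap=self.K_cap)

    def protocol(self) -> Protocol:
        return Protocol(
            V_total=self.V_total_uL,
            V_droplet=self.V_droplet_uL,
            retained_volumes=self.retained_volumes_uL,
            keep_supernatant_share=self.keep_supernatant_share,
        )

    def digest(self) -> str:
        """Stable hash of the config, logged for reproducibility."""
        payload = json.dumps(dump_config(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing keys take defaults.

    An empty file (or ``path=None``) yields the all-defaults config.
    Unknown keys are rejected with a message listing them.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        data = raw
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys: {unknown}; valid keys: {sorted(_FIELDS)}"
        )
    cfg = RunConfig(**data)
    logger.debug(
        "config %s: lambda_eff=%g /nm^2, K_cap=%g, V_total=%g uL, V_droplet=%g uL, "
        "retained volumes %s uL (typical bench protocol defaults)",
        cfg.digest(), cfg.lambda_eff, cfg.K_cap, cfg.V_total_uL, cfg.V_droplet_uL,
        list(cfg.retained_volumes_uL),
    )
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """Config as a plain dict; ``load``/``dump`` round-trips."""
    out = dataclasses.asdict(cfg)
    out["retained_volumes_uL"] = list(out["retained_volumes_uL"])
    return out
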