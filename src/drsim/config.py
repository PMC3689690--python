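"""Configuration schema and file I/O.

Configs are YAML (JSON is a YAML subset and parses too).  Unknown keys
are rejected so typos fail loudly.  The packaged default
``training_cohort.yaml`` carries the training-cohort distribution
moments, the published odds ratios, and the constant transition rates.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

from .cohort import CohortConfig, ConfigurationError, DistributionSpec
from .domain import LogisticHazard, TransitionRates

__all__ = ["load_config", "config_from_dict", "default_config_path", "RunManifest"]

_TOP_KEYS = {
    "n",
    "seed",
    "predictors",
    "rates",
    "hazard",
    "target_pdr_prevalence",
    "annual_hazard_scale",
    "include_no_dr",
    "no_dr_prob",
    "record_history",
    "life_table",
}
_SPEC_KEYS = {"family", "mean", "sd", "lower", "upper", "p"}
_RATE_KEYS = {"onset_annual", "vl_annual", "entrant_no_dr", "prp_annual"}
_HAZARD_KEYS = {"beta", "odds_ratios", "intercept"}


def default_config_path() -> Path:
    return Path(str(resources.files("drsim").joinpath("data/training_cohort.yaml")))


def _reject_unknown(given: dict, allowed: set[str], context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def config_from_dict(raw: dict[str, Any]) -> CohortConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    _reject_unknown(raw, _TOP_KEYS, "config")

    kwargs: dict[str, Any] = {}
    for key in ("n", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in (
        "target_pdr_prevalence",
        "annual_hazard_scale",
        "no_dr_prob",
    ):
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in ("include_no_dr", "record_history"):
        if key in raw:
            kwargs[key] = bool(raw[key])
    if raw.get("life_table") is not None:
        kwargs["life_table_path"] = str(raw["life_table"])

    if "predictors" in raw:
        specs = {}
        for name, spec in raw["predictors"].items():
            if not isinstance(spec, dict):
                raise ConfigurationError(f"predictor {name!r} must map to a spec mapping")
            _reject_unknown(spec, _SPEC_KEYS, f"predictor {name!r}")
            if "family" not in spec:
                raise ConfigurationError(f"predictor {name!r} is missing 'family'")
            specs[name] = DistributionSpec(**spec)
        kwargs["specs"] = specs

    if "rates" in raw:
        _reject_unknown(raw["rates"], _RATE_KEYS, "rates")
        kwargs["rates"] = TransitionRates(**{k: float(v) for k, v in raw["rates"].items()})

    if "hazard" in raw:
        hz = raw["hazard"]
        _reject_unknown(hz, _HAZARD_KEYS, "hazard")
        if ("beta" in hz) == ("odds_ratios" in hz):
            raise ConfigurationError("hazard needs exactly one of 'beta' or 'odds_ratios'")
        intercept = hz.get("intercept")
        if isinstance(intercept, str):
            if intercept != "calibrate":
                raise ConfigurationError(
                    f"hazard intercept must be a number or 'calibrate', got {intercept!r}"
                )
            intercept = None
        elif intercept is not None:
            intercept = float(intercept)
            if not math.isfinite(intercept):
                raise ConfigurationError("hazard intercept must be finite")
        if "beta" in hz:
            hazard = LogisticHazard({k: float(v) for k, v in hz["beta"].items()}, intercept)
        else:
            hazard = LogisticHazard.from_odds_ratios(
                {k: float(v) for k, v in hz["odds_ratios"].items()}, intercept
            )
        kwargs["hazard"] = hazard

    return CohortConfig(**kwargs)


def load_config(path) -> CohortConfig:
    """Load and schema-validate a cohort configuration from YAML/JSON."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raise ConfigurationError(f"config file is empty: {path}")
    return config_from_dict(raw)


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run: command, config hash,
    seed and output paths suffice to reproduce the outputs."""

    command: str
    config_path: Optional[str]
    config_sha256: Optional[str]
    seed: int
    package_version: str
    timestamp: str
    outputs: list[str]

    @classmethod
    def create(
        cls, command: str, config_path: Optional[Path], seed: int, outputs: list[str]
    ) -> "RunManifest":
        from . import __version__

        sha = None
        if config_path is not None:
            sha = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        return cls(
            command=command,
            config_path=str(config_path) if config_path else None,
            config_sha256=sha,
            seed=seed,
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            outputs=outputs,
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2) + "\n")
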