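"""YAML run configuration: parsing, validation and hashing.

A run config is a nested mapping with sections ``feature``, ``phantom``,
``admittance``, ``policy``, ``scan`` and ``dataset`` plus a top-level
``seed``. Every key is validated against the corresponding module type
before any computation; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .control import AdmittanceParams, ForcePolicy, critical_damping
from .features import FeatureConfig
from .phantom import PhantomConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


_TOP_SECTIONS = ("feature", "phantom", "admittance", "policy", "scan", "dataset", "seed")

_SCAN_DEFAULTS = {"rate_hz": 30.0, "max_ticks": 600, "convergence_window": 10}
_DATASET_DEFAULTS = {"n_per_class": 500, "train_frac": 0.8}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for an end-to-end run."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    admittance: AdmittanceParams = field(default_factory=AdmittanceParams)
    policy: ForcePolicy = field(default_factory=ForcePolicy)
    scan: dict = field(default_factory=lambda: dict(_SCAN_DEFAULTS))
    dataset: dict = field(default_factory=lambda: dict(_DATASET_DEFAULTS))
    seed: int = 0


def _build(cls, section: dict, name: str, defaults: dict | None = None):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    kwargs = dict(defaults or {})
    kwargs.update(section)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def _build_dict(section: dict, name: str, defaults: dict) -> dict:
    unknown = set(section) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(section)
    return out


def parse_run_config(data: dict | None) -> RunConfig:
    """Validate a nested mapping into a RunConfig."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_TOP_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    feature_sec = dict(data.get("feature") or {})
    if "wiener_window" in feature_sec:
        feature_sec["wiener_window"] = tuple(feature_sec["wiener_window"])
    feature = _build(FeatureConfig, feature_sec, "feature")

    phantom_sec = dict(data.get("phantom") or {})
    for key in ("shape", "quality_band_n"):
        if key in phantom_sec:
            phantom_sec[key] = tuple(phantom_sec[key])
    phantom = _build(PhantomConfig, phantom_sec, "phantom")

    adm_sec = dict(data.get("admittance") or {})
    if "damping" not in adm_sec:
        mass = adm_sec.get("mass", AdmittanceParams.mass)
        stiffness = adm_sec.get("stiffness", AdmittanceParams.stiffness)
        adm_sec["damping"] = critical_damping(mass, stiffness)
    admittance = _build(AdmittanceParams, adm_sec, "admittance")

    policy = _build(ForcePolicy, dict(data.get("policy") or {}), "policy")
    scan = _build_dict(dict(data.get("scan") or {}), "scan", _SCAN_DEFAULTS)
    dataset = _build_dict(dict(data.get("dataset") or {}), "dataset", _DATASET_DEFAULTS)

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(
        feature=feature,
        phantom=phantom,
        admittance=admittance,
        policy=policy,
        scan=scan,
        dataset=dataset,
        seed=seed,
    )


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration; None gives defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_run_config(data)


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "feature": dataclasses.asdict(cfg.feature),
        "phantom": dataclasses.asdict(cfg.phantom),
        "admittance": dataclasses.asdict(cfg.admittance),
        "policy": dataclasses.asdict(cfg.policy),
        "scan": dict(cfg.scan),
        "dataset": dict(cfg.dataset),
        "seed": cfg.seed,
    }


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of the config."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()
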