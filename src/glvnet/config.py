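"""YAML pipeline configuration: schema, validation, defaults."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

from glvnet.simulate import DEFAULT_TIME_GRID


class ConfigError(ValueError):
    """One or more configuration problems; message lists all of them."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


_DEFAULTS: dict[str, Any] = {
    "input": None,          # {"shared": path, "metadata": path}
    "synthetic": None,      # synthetic-design block, see _SYNTHETIC_DEFAULTS
    "groups": None,         # group labels to analyze; None = all in table
    "ensemble": {
        "mode": "subsample",
        "n_subsample": 2000,
        "ceiling": 200000,
    },
    "consensus_cutoff": 0.7,
    "regression": {
        "backend": "pls",
        "n_components": 2,
        "ridge_lambda": 1.0,
        "pseudocount": None,
    },
    "membership": {
        "high_cutoff": 0.01,
        "rare_cutoff": 0.001,
        "scope": "per_group",
    },
    "focal_taxa": [],
    "outdir": "glvnet_out",
    "seed": 0,
}

_SYNTHETIC_DEFAULTS: dict[str, Any] = {
    "n_taxa": 20,
    "replicates_per_group": 3,
    "time_grid": list(DEFAULT_TIME_GRID),
    "library_size": 10000,
    "noise_sd": 0.05,
    "density": 0.15,
    "strength_scale": 0.25,
    "positive_fractions": [0.5, 0.5],
    "group_labels": ["group1", "group2"],
}


@dataclass
class PipelineConfig:
    """Validated, defaults-filled pipeline configuration."""

    input: dict | None
    synthetic: dict | None
    groups: list[str] | None
    ensemble: dict
    consensus_cutoff: float
    regression: dict
    membership: dict
    focal_taxa: list[str]
    outdir: str
    seed: int
    extras: dict = field(default_factory=dict)

    def snapshot(self) -> dict:
        """JSON-serializable copy of the effective configuration."""
        return {
            "input": self.input,
            "synthetic": self.synthetic,
            "groups": self.groups,
            "ensemble": self.ensemble,
            "consensus_cutoff": self.consensus_cutoff,
            "regression": self.regression,
            "membership": self.membership,
            "focal_taxa": self.focal_taxa,
            "outdir": str(self.outdir),
            "seed": self.seed,
        }


def _merge_block(
    name: str, raw: Any, defaults: dict, errors: list[str]
) -> dict:
    merged = copy.deepcopy(defaults)
    if raw is None:
        return merged
    if not isinstance(raw, dict):
        errors.append(f"{name}: expected a mapping, got {type(raw).__name__}")
        return merged
    for key, value in raw.items():
        if key not in defaults:
            errors.append(f"{name}.{key}: unknown key")
        else:
            merged[key] = value
    return merged


def normalize_config(raw: dict | None) -> PipelineConfig:
    """Validate a raw config mapping, filling defaults.

    Every unknown key at any level is an error; exactly one of ``input``
    and ``synthetic`` must be present.
    """
    raw = raw or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError([f"top level: expected a mapping, got {type(raw).__name__}"])
    for key in raw:
        if key not in _DEFAULTS:
            errors.append(f"{key}: unknown key")

    merged = {k: copy.deepcopy(v) for k, v in _DEFAULTS.items()}
    for key in _DEFAULTS:
        if key in raw:
            merged[key] = raw[key]

    has_input = raw.get("input") is not None
    has_synth = raw.get("synthetic") is not None
    if has_input == has_synth:
        errors.append(
            "exactly one of 'input' and 'synthetic' must be provided"
        )
    if has_input:
        inp = _merge_block("input", raw["input"], {"shared": None, "metadata": None}, errors)
        for k in ("shared", "metadata"):
            if not inp.get(k):
                errors.append(f"input.{k}: required path missing")
        merged["input"] = inp
    if has_synth:
        merged["synthetic"] = _merge_block(
            "synthetic", raw["synthetic"], _SYNTHETIC_DEFAULTS, errors
        )
        synth = merged["synthetic"]
        if len(synth["positive_fractions"]) != len(synth["group_labels"]):
            errors.append(
                "synthetic.positive_fractions and synthetic.group_labels "
                "must have equal length"
            )

    merged["ensemble"] = _merge_block(
        "ensemble", raw.get("ensemble"), _DEFAULTS["ensemble"], errors
    )
    if merged["ensemble"]["mode"] not in ("full", "subsample"):
        errors.append("ensemble.mode: must be 'full' or 'subsample'")
    merged["regression"] = _merge_block(
        "regression", raw.get("regression"), _DEFAULTS["regression"], errors
    )
    if merged["regression"]["backend"] not in ("pls", "ridge", "ols"):
        errors.append("regression.backend: must be 'pls', 'ridge' or 'ols'")
    merged["membership"] = _merge_block(
        "membership", raw.get("membership"), _DEFAULTS["membership"], errors
    )
    if merged["membership"]["scope"] not in ("per_group", "all_samples"):
        errors.append("membership.scope: must be 'per_group' or 'all_samples'")

    cutoff = merged["consensus_cutoff"]
    if not isinstance(cutoff, (int, float)) or not 0 < cutoff < 1:
        errors.append(f"consensus_cutoff: must be in (0, 1), got {cutoff!r}")
    if not isinstance(merged["seed"], int):
        errors.append(f"seed: must be an integer, got {merged['seed']!r}")
    if merged["groups"] is not None and not isinstance(merged["groups"], list):
        errors.append("groups: must be a list of labels or null")
    if not isinstance(merged["focal_taxa"], list):
        errors.append("focal_taxa: must be a list")

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        input=merged["input"],
        synthetic=merged["synthetic"],
        groups=merged["groups"],
        ensemble=merged["ensemble"],
        consensus_cutoff=float(cutoff),
        regression=merged["regression"],
        membership=merged["membership"],
        focal_taxa=[str(t) for t in merged["focal_taxa"]],
        outdir=str(merged["outdir"]),
        seed=int(merged["seed"]),
    )


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return normalize_config(raw)
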