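"""Run configuration and seed management.

All tunable defaults live in one hierarchical dictionary keyed by dotted
names (``glove.window``, ``network.dropout_rate`` ...).  A run resolves its
configuration from defaults < YAML file < command-line overrides, rejects
unknown keys (listing every offending key at once), and writes the resolved
snapshot alongside its outputs so any artifact directory is reproducible
from (config, seed, version) alone.

The global seed fans out to per-stage sub-seeds through a splittable
counter scheme (``numpy.random.SeedSequence([seed, stage_id])``), so adding
a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = ["DEFAULTS", "RunConfig", "stage_seed", "ConfigError"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "log_level": "INFO",
    "encoding": {
        "base_order": "ACGT",
    },
    "glove": {
        "dim": 100,
        "window": 5,
        "distance_weighting": "inverse_distance",
        "x_max": 100.0,
        "alpha": 0.75,
        "iterations": 1000,
        "learning_rate": 0.05,
        "combine": "sum",
    },
    "sampler": {
        "batch_size": 256,
        "composition": "balanced",
    },
    "network": {
        "variant": "CnnCrispr",
        "head": "classification",
        "recurrent_units": 30,
        "conv_filters": [10, 20, 40, 80, 100],
        "conv_kernel_sizes": [5, 5, 3, 3, 3],
        "dropout_rate": 0.3,
        "learning_rate": 0.01,
        "epochs": 100,
        "early_stopping": True,
        "validation_fraction": 0.1,
        "patience": 10,
        "freeze_embedding": False,
    },
    "eval": {
        "threshold": 0.5,
        "test_fraction": 0.2,
        "stratify_by": "none",
    },
    "cfd": {
        "strict": True,
        "pam_distal_first": True,
    },
    "simulate": {
        "n_sgrnas": 29,
        "sites_per_sgrna": 1000,
        "mismatch_min": 1,
        "mismatch_max": 5,
        "imbalance_ratio": 250.0,
        "noise_sd": 0.05,
        "cell_line": "synthetic",
    },
}

_STAGE_IDS = {
    "simulate": 11,
    "split": 12,
    "glove": 13,
    "sampler": 14,
    "network": 15,
    "eval": 16,
    "loso": 17,
}


class ConfigError(ValueError):
    """Raised with every offending key listed at once."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, independent across stages."""
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(_STAGE_IDS)}")
    child = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(child.generate_state(1)[0] % (2 ** 31))


def _flatten(tree: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in tree.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, Mapping):
            flat.update(_flatten(value, dotted + "."))
        else:
            flat[dotted] = value
    return flat


class RunConfig:
    """Resolved configuration for one run."""

    def __init__(self, overrides: Mapping[str, Any] | None = None):
        self._tree = copy.deepcopy(DEFAULTS)
        if overrides:
            self.update(overrides)

    @classmethod
    def from_yaml(cls, path, overrides: Mapping[str, Any] | None = None) -> "RunConfig":
        config = cls()
        with open(path) as handle:
            loaded = yaml.safe_load(handle) or {}
        config.update(_flatten(loaded))
        if overrides:
            config.update(overrides)
        return config

    def update(self, overrides: Mapping[str, Any]) -> None:
        """Apply dotted-key overrides; unknown keys raise ConfigError."""
        known = _flatten(DEFAULTS)
        flat = {}
        for key, value in overrides.items():
            if isinstance(value, Mapping):
                flat.update(_flatten({key: value}))
            else:
                flat[key] = value
        unknown = sorted(k for k in flat if k not in known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        for key, value in flat.items():
            node = self._tree
            parts = key.split(".")
            for part in parts[:-1]:
                node = node[part]
            default = known[key]
            if default is not None and value is not None and not isinstance(value, type(default)):
                # coerce scalars parsed from the command line
                if isinstance(default, bool):
                    value = str(value).lower() in ("1", "true", "yes", "on")
                elif isinstance(default, (int, float)):
                    value = type(default)(value)
                elif isinstance(default, list) and isinstance(value, str):
                    value = [int(v) for v in value.split(",")]
            node[parts[-1]] = value

    def __getitem__(self, dotted: str) -> Any:
        node: Any = self._tree
        for part in dotted.split("."):
            node = node[part]
        return node

    def section(self, name: str) -> dict[str, Any]:
        return copy.deepcopy(self._tree[name])

    @property
    def seed(self) -> int:
        return int(self._tree["seed"])

    def to_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self._tree)

    def write_snapshot(self, out_dir) -> Path:
        """Persist the resolved configuration next to a run's outputs."""
        from . import __version__

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.json"
        payload = {"version": __version__, "config": self.to_dict()}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path
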