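"""Hierarchical YAML run configuration with strict key validation.

Unknown keys are rejected; CLI flags override config values; the effective
config (defaults + overrides) is echoed into the run manifest.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

DEFAULTS: Dict[str, Dict[str, Any]] = {
    "profile": {"local_window": 100, "local_step": 100},
    "scan_windows": {"window": 1000, "step": None, "max_n_fraction": 0.1},
    "twins": {"top_k": 5, "weights": [1.0, 1.0, 1.0], "step": 1,
              "max_n_fraction": 0.1},
    "shuffle": {"target_mismatch": "maximize", "local_gc_window": 100,
                "local_gc_tolerance": 0.0, "forbid_new_cpg": True,
                "forbid_motifs": ["TGCCGC"], "max_iterations": 100000},
    "motifs": {"pattern": "TGCCGC", "scan_both_strands": True,
               "pwm_threshold": None},
    "walk_swap": {"window": 10, "step": 1, "scorer": "motif-count"},
    "bisulfite": {"mode": "non_directional", "min_conversion": 0.95,
                  "min_identity": 0.90, "min_coverage": 1,
                  "match": 1.0, "mismatch": -1.0, "gap": -2.0},
    "simulate": {"length": 3000, "gc_fraction": 0.6, "n_cpg": 120,
                 "spacing_model": "clustered", "n_molecules": 100,
                 "mode": "disordered", "p": 0.5, "f_methylated": 0.5,
                 "conversion_rate": 1.0, "error_rate": 0.0},
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: Dict[str, Any]) -> None:
    """Reject unknown sections or keys."""
    for section, values in cfg.items():
        if section not in DEFAULTS:
            raise ConfigError(
                f"unknown config section {section!r} "
                f"(known: {', '.join(sorted(DEFAULTS))})"
            )
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key in values:
            if key not in DEFAULTS[section]:
                raise ConfigError(
                    f"unknown key {key!r} in section {section!r} "
                    f"(known: {', '.join(sorted(DEFAULTS[section]))})"
                )


def load_config(path: Optional[str] = None,
                overrides: Optional[Dict[str, Dict[str, Any]]] = None
                ) -> Dict[str, Dict[str, Any]]:
    """Defaults, overlaid with an optional YAML file, overlaid with CLI
    overrides. Returns the effective config."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping at top level")
        validate_config(loaded)
        for section, values in loaded.items():
            cfg[section].update(values)
    if overrides:
        validate_config(overrides)
        for section, values in overrides.items():
            cfg[section].update({k: v for k, v in values.items() if v is not None})
    return cfg
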