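"""Pipeline configuration: one YAML document drives every stage.

Every tunable default of the analysis (axis grid, preprocessing knobs,
population statistics, unmix mode, classifier protocol, embedding grid)
lives here, so a run is fully described by its config plus one seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .spectra import AxisSpec

__all__ = ["PipelineConfig", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "axis": {"start": 250.0, "stop": 3000.0, "step": 7.0},
    "preprocess": {
        "enabled": True,
        "n_segments": 4,
        "degree": 3,
        "n_iterations": 50,
        "boxcar_window": 5,
        "floor_at_zero": True,
    },
    "references": {
        # "simulate" builds the default five-reporter library; a path reads
        # a five-column reference spectrum table instead.
        "source": "simulate",
    },
    "panel": {
        "designs": [
            [1, 1, 1, 1, 1],
            [1, 1, 1, 6, 1],
            [6, 1, 1, 1, 1],
            [1, 6, 1, 1, 1],
            [1, 1, 6, 1, 1],
            [1, 1, 1, 1, 6],
            [2, 1, 4, 1, 2],
            [5, 3, 1, 0, 1],
        ],
        "noise_sd": 0.015,
    },
    "population": {
        "n_per_line": 300,
        "sd": 0.06,
        "bounds": [0.0, 0.79],
        "noise_sd": 0.015,
        "baseline_amp": 0.02,
        "means": None,  # None -> library defaults per cell line
    },
    "unmix": {"mode": "nnls"},
    "classifier": {
        "train_fraction": 0.7,
        "n_iterations": 200,
        "n_trees": 100,
        "max_depth": None,
    },
    "mixed_population": {"n_per_line": 150},
    "embedding": {
        "enabled": True,
        "perplexities": [5, 10, 20, 30, 45, 60, 90, 120, 150, 200, 250, 300],
        "n_replicates": 5,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class PipelineConfig:
    """Validated configuration; unspecified keys fall back to the defaults."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        unknown = set(self.data) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.data = _deep_merge(DEFAULT_CONFIG, self.data)
        self.axis_spec()  # validates the axis triple

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return cls(data=data or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def axis_spec(self) -> AxisSpec:
        a = self.data["axis"]
        return AxisSpec(a["start"], a["stop"], a["step"])
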