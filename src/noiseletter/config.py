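"""Experiment configuration: defaults, YAML/JSON loading, strict validation.

The configuration mirrors the in-silico experiment: one stimulus block, one
viewing-geometry block per stimulus type (9 m for LM, 4.5 m for CM), the
staircase parameters (0.125 logMAR steps, 2-down/1-up, stop at 8 reversals,
estimate from the last 6, 4 runs averaged) and the cohort design.  Unknown
keys are rejected with their dotted path; a loaded config round-trips
losslessly through YAML.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .geometry import ViewingGeometry
from .observers import CohortSpec, STUDY_CONDITION_MEANS
from .staircase import StaircaseConfig
from .stimulus import StimulusSpec

__all__ = ["ExperimentConfig", "load_config", "default_config_dict", "config_hash"]


def default_config_dict() -> dict[str, Any]:
    return {
        "stimulus": {
            "mean_luminance": 1.0,
            "noise_contrast": 0.2,
            "lm_amplitude": 0.3,
            "cm_amplitude": 1.0,
            "bipolar_modulation": False,
        },
        "geometry": {
            "LM": {"distance_m": 9.0, "pixel_pitch_mm": 0.47, "checks_per_stroke": 3},
            "CM": {"distance_m": 4.5, "pixel_pitch_mm": 0.47, "checks_per_stroke": 3},
        },
        "staircase": {
            "step_logmar": 0.125,
            "n_down": 2,
            "n_up": 1,
            "n_reversals_stop": 8,
            "n_reversals_used": 6,
            "n_alternatives": 4,
            "max_trials": 200,
            "start_logmar": {"LM": 0.2, "CM": 0.8},
        },
        "cohort": {
            "n_per_group": 5,
            "n_runs": 4,
            "condition_means": {
                f"{g}/{s}/{v}": m for (g, s, v), m in STUDY_CONDITION_MEANS.items()
            },
            "between_subject_sd": None,  # null -> per-cell SE*sqrt(5)
            "run_sd": 0.05,
            "nd_transmission": 1.0,
            "nd_coefficient": 0.0,
            "slope": 0.08,
            "lapse_rate": 0.01,
            "quantize_levels": False,
        },
        "seed": 0,
        "out_dir": "out",
    }


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict) and key != "condition_means":
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config dict (provenance tag for output files)."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment configuration with typed accessors."""

    raw: dict[str, Any]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def out_dir(self) -> str:
        return str(self.raw["out_dir"])

    @property
    def hash(self) -> str:
        return config_hash(self.raw)

    def stimulus_spec(self, stimulus_type: str) -> StimulusSpec:
        s = self.raw["stimulus"]
        common = {
            "mean_luminance": s["mean_luminance"],
            "noise_contrast": s["noise_contrast"],
            "bipolar_modulation": s["bipolar_modulation"],
        }
        if stimulus_type == "LM":
            return StimulusSpec.lm(s["lm_amplitude"], **common)
        return StimulusSpec.cm(s["cm_amplitude"], **common)

    def viewing_geometry(self, stimulus_type: str) -> ViewingGeometry:
        g = self.raw["geometry"][stimulus_type]
        return ViewingGeometry(
            distance_m=g["distance_m"],
            pixel_pitch_mm=g["pixel_pitch_mm"],
            checks_per_stroke=g["checks_per_stroke"],
        )

    def staircase_config(self, stimulus_type: str) -> StaircaseConfig:
        s = self.raw["staircase"]
        return StaircaseConfig(
            start_logmar=s["start_logmar"][stimulus_type],
            step_logmar=s["step_logmar"],
            n_down=s["n_down"],
            n_up=s["n_up"],
            n_reversals_stop=s["n_reversals_stop"],
            n_reversals_used=s["n_reversals_used"],
            n_alternatives=s["n_alternatives"],
            max_trials=s["max_trials"],
        )

    def cohort_spec(self, nd: bool = False) -> CohortSpec:
        c = self.raw["cohort"]
        means = {}
        for key, value in c["condition_means"].items():
            group, stim, view = key.split("/")
            means[(group, stim, view)] = float(value)
        return CohortSpec(
            n_per_group=c["n_per_group"],
            n_runs=c["n_runs"],
            condition_means=means,
            between_subject_sd=c["between_subject_sd"],
            run_sd=c["run_sd"],
            nd_transmission=c["nd_transmission"] if not nd else 0.19,
            nd_coefficient=c["nd_coefficient"],
            slope=c["slope"],
            lapse_rate=c["lapse_rate"],
        )

    @property
    def quantize_levels(self) -> bool:
        return bool(self.raw["cohort"]["quantize_levels"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def _validate(raw: dict[str, Any]) -> None:
    n = raw["stimulus"]["noise_contrast"]
    if not 0.0 <= n <= 1.0:
        raise ValueError(f"stimulus.noise_contrast must lie in [0, 1], got {n}")
    cfg = ExperimentConfig(raw)
    for stim in ("LM", "CM"):
        cfg.stimulus_spec(stim)
        cfg.viewing_geometry(stim)
        cfg.staircase_config(stim)
    cfg.cohort_spec()


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load a YAML (or JSON) config file, fill defaults, validate.

    An empty or missing file yields the all-defaults configuration.
    """
    defaults = default_config_dict()
    override: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            override = loaded
    raw = _merge(defaults, override)
    _validate(raw)
    return ExperimentConfig(raw)
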