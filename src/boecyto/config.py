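"""YAML configuration schema shared by the CLI and the pipeline.

One document with per-stage sections; every key has a default, so an empty
config is a valid full run.  All values are plain scalars/lists, so
parse → serialize → parse is the identity.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "spot": "R1",
        "wavelength_nm": 488.0,
        "focal_length_mm": 10.0,
        "aperture_side_mm": 3.0,
        "zones_per_side": 128,
        "phase_levels": 16,
        "refractive_index": 1.4632,
        "oversampling": 1,
        "pad_factor": 4,
        "gaussian_beam": False,
        "max_iterations": 200,
        "free_iterations": 100,
        "stage_levels": [64, 32, 16],
        "stage_iterations": 25,
        "convergence_tol": 1.0e-6,
        "feedback_strength": 0.5,
    },
    "flow": {
        "kinematic_viscosity_m2_s": 1.004e-6,
        "density_kg_m3": 998.0,
        "sample_rate_ul_min": 60.0,
        "sheath_rate_ml_min": 7.2,
        "k_q": 0.75,
        "straight_channel_um": [310.0, 163.0],
        "series_terms": 100,
        "include_sample_flow": True,
    },
    "simulate": {
        "velocity_m_s": 4.8,
        "duration_s": 0.05,
        "bead_diameter_um": 5.0,
        "concentration_per_ml": 5.0e6,
        "brightness_cv": 0.05,
        "stream_width_um": 15.0,
        "sampling_rate_hz": 10.0e6,
        "shot_counts_per_unit": 400.0,
        "additive_sd": 0.01,
        "baseline": 0.02,
    },
    "analyze": {
        "edge_separation_um": 110.0,
        "threshold": None,
        "hysteresis": None,
        "gate_fraction": 0.9,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by the YAML file, overlaid by ``overrides``."""
    config = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a YAML mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    return config


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
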