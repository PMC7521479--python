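"""Run configuration: every model and quantification parameter with defaults.

A config is a flat mapping (key: value, no nesting) that can be loaded
from YAML text. Unknown keys are rejected by name; a manifest written from
a config round-trips to an identical config.
"""

from __future__ import annotations

from pathlib import Path

import yaml

#: Defaults for every tunable parameter (units in comments).
DEFAULTS: dict = {
    # 1D domain
    "domain_length": 80.0,      # μm
    "domain_dx": 0.2,           # μm
    "periodic": True,
    # LGN kinetics
    "D": 0.01,                  # μm²/min
    "koff_near": 0.1,           # 1/min (timescale ~10 min)
    "koff_far": 1.0 / 90.0,     # 1/min (timescale ~90 min)
    "transition_width": 0.5,    # μm
    "lgn_scale": 1.0,           # binding-flux multiplier (RNAi emulation)
    # DNA footprint
    "w_dna": 4.0,               # μm, DNA interval half-extent (1D)
    "d_inh": 4.0,               # μm, inhibition range from the DNA edge
    # microtubules
    "mt_mean": 6.0,             # μm, mean astral MT length
    "mt_max": 20.0,             # μm, truncation
    # 1D spindle
    "v0": 6.7,                  # μm/min
    "offset": 0.0,              # μm, centrosome - DNA
    "pole_half_separation": 5.0,  # μm (bipolar)
    "perturbation": 1e-3,       # relative amplitude of the seeded bump
    # time stepping / sampling
    "T": 450.0,                 # min
    "dt": 0.05,                 # min
    "frame_interval": 3.0,      # min
    # 2D rounding & orientation
    "a0": 20.0, "b0": 8.0, "R": 10.0,       # μm
    "tau_round": 4.0,                        # min
    "t_bipolar": 9.0,                        # min after NEB
    "axis_angle": 0.0,                       # rad
    "phi0": 0.7853981633974483,              # rad (π/4)
    "plate_half_length": 4.0,                # μm
    "dna_disc_radius": 5.0,                  # μm
    "rot_mobility": 0.1,                     # rad/(min·torque unit)
    "n_nodes": 256,
    "n_directions": 720,
    "T_2d": 49.0,                            # min
    "cue_angle": None,                       # rad (None: no cue)
    "cue_strength": 0.0,
    "cue_width": 0.3,                        # rad
    # synthetic-data noise
    "noise_mult_sd": 0.1,
    "noise_bg_mean": 0.05,
    "noise_bg_sd": 0.02,
    # cohort
    "n_cells": 12,
    "v0_mean": 6.7, "v0_sd": 6.7,            # μm/min across cells
    "length_min": 60.0, "length_max": 100.0,  # μm
    # quantification
    "quantile": 0.975,
    "background": 0.0,
    "smoothing_window": 5,
    # reproducibility
    "seed": 0,
}


class RunConfig(dict):
    """Flat parameter mapping validated against :data:`DEFAULTS`."""

    def __init__(self, overrides: dict | None = None):
        super().__init__(DEFAULTS)
        for key, value in (overrides or {}).items():
            if key not in DEFAULTS:
                raise KeyError(f"unknown configuration key: {key!r}")
            self[key] = value

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} is not a flat key: value mapping")
        return cls(loaded)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dict(self), sort_keys=True))
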