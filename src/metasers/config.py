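"""Run configuration: defaults for every tunable, with YAML override files.

A fully defaulted configuration reproduces the packaged worked example: a
silver metasurface at 785 nm (eps_Ag = -29.8 + 0.38i) with period 400 nm,
modulation 80 nm and crest thickness 15 nm, air in front (eps = 1) and a
polycarbonate substrate (eps = 2.5).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "dump_config"]

DEFAULTS: dict = {
    "optics": {
        "wavelength_nm": 785.0,
        "epsilon_metal": {"re": -29.8, "im": 0.38},
        "eps_front": 1.0,
        "eps_substrate": 2.5,
    },
    "geometry": {"L_nm": 400.0, "h_nm": 80.0, "d_nm": 15.0},
    "spectra": {
        "quiet_windows": [[600.0, 650.0], [1650.0, 1700.0]],
        "band_center_cm1": 1589.0,
        "band_half_width_cm1": 15.0,
        "lod_criterion": 3.0,
        "baseline_lam": 1.0e5,
    },
    "correlate": {
        "drop_fraction": 0.9,
        "min_bump_height_nm": 15.0,
        "size_gate_nm": [30.0, 150.0],
        "match_radius_nm": 200.0,
    },
    "simulate": {
        "seed": 0,
        "concentrations_uM": [50.0, 5.0, 0.5, 0.05],
        "sn_slope_per_uM": 15.0,
        "noise_sigma": 5.0,
        "n_pixels": 1024,
        "pixel_size_nm": 10000.0 / 1024,
        "roughness_nm": 8.0,
        "n_exosomes": 5,
        "n_defects": 3,
        "n_imperfections": 3,
    },
    "io": {"map_format": "tsv", "spectrum_format": "csv"},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Defaults, deep-merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _merge(DEFAULTS, data)


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def epsilon_metal(cfg: dict) -> complex:
    em = cfg["optics"]["epsilon_metal"]
    return complex(em["re"], em["im"])
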