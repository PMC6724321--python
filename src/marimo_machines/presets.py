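"""Shipped parameter presets (versioned YAML) and their loaders."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .photosynthesis import PhotosynthesisParams


@lru_cache(maxsize=1)
def _load() -> dict:
    text = (resources.files("marimo_machines") / "presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_version() -> int:
    return _load()["version"]


def default_photosynthesis_params() -> PhotosynthesisParams:
    p = _load()["photosynthesis"]["params"]
    return PhotosynthesisParams(
        r_max=p["r_max_ml_per_day"],
        half_saturation=p["half_saturation_umol_m2_s"],
        induction_lag_h=p["induction_lag_h"],
        decline_timescale_days=p["decline_timescale_days"],
        damage_threshold=p["damage_threshold_umol_m2_s"],
    )


def preset_irradiance(name: str) -> float:
    """PAR (µmol m⁻² s⁻¹) of a named lighting preset.

    Shipped names: 'strong_sunlight', 'moderate_sunlight',
    'led_growth_light'.
    """
    table = _load()["photosynthesis"]["irradiance"]
    try:
        return float(table[name])
    except KeyError:
        raise KeyError(
            f"unknown irradiance preset {name!r}; available: {sorted(table)}"
        ) from None
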