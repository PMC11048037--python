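"""Run configuration: schema-validated YAML/JSON scenario configs.

Canonical internal units are SI (W/m^2, cd/m^2, m) with degrees for
angles; the eye-irradiance display unit is configurable.  Unknown keys
are rejected by name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: section -> {key: (type, default)}; None default means required-if-section-used
_SCHEMA: dict[str, dict[str, tuple]] = {
    "observer": {
        "age": (float, 30.0),
        "pigmentation": (float, 0.5),
    },
    "scene": {
        "ambient_luminance_cd_m2": (float, 13.14),
        "target_contrast": (float, 0.89),
        "target_size_deg": (float, 2.75),
    },
    "laser": {
        "wavelength_nm": (float, 532.0),
        "power_mW": (float, 100.0),
        "divergence_mrad": (float, 1.5),
        "initial_beam_diameter_m": (float, 0.0),
        "distance_m": (float, 0.0),
        "incidence_angle_deg": (float, 0.5),
        "eye_irradiance_mW_cm2": (float, 0.0),
    },
    "run": {
        "seed": (int, 42),
        "output_dir": (str, "."),
        "verbosity": (str, "info"),
        "irradiance_unit": (str, "mW/cm2"),
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with defaults filled in."""

    observer: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)
    laser: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "observer": dict(self.observer),
            "scene": dict(self.scene),
            "laser": dict(self.laser),
            "run": dict(self.run),
        }


def _validate(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown_sections = set(raw) - set(_SCHEMA)
    if unknown_sections:
        raise ValueError(
            "unknown config section(s): " + ", ".join(sorted(unknown_sections))
        )
    sections: dict[str, dict] = {}
    for section, keys in _SCHEMA.items():
        given = raw.get(section, {}) or {}
        if not isinstance(given, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        unknown = set(given) - set(keys)
        if unknown:
            raise ValueError(
                f"unknown key(s) in {section!r}: " + ", ".join(sorted(unknown))
            )
        out = {}
        for key, (typ, default) in keys.items():
            value = given.get(key, default)
            try:
                out[key] = typ(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"config key {section}.{key} must be {typ.__name__}: {exc}"
                ) from exc
        sections[section] = out
    if sections["run"]["irradiance_unit"] not in ("mW/cm2", "W/m2"):
        raise ValueError("run.irradiance_unit must be 'mW/cm2' or 'W/m2'")
    return RunConfig(**sections)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _validate(raw or {})


def dump_config(config: RunConfig, path) -> None:
    """Write a config back to YAML; round-trips semantically."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
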