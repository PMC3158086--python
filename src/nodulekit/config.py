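"""Run configuration: versioned defaults, schema validation, provenance.

The package ships a single calibrated default configuration
(``defaults.yaml``); user configs are shallow-merged over it section by
section. Every pipeline run serializes its fully resolved configuration
into the output directory.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic.dose import DoseResponseModel
from .synthetic.render import NoiseModel
from .synthetic.spectral import PhProfile, SnarfModel

__all__ = ["RunConfig", "load_config", "default_config"]

_SECTIONS = {
    "dose_response",
    "render",
    "noise",
    "ph_profile",
    "snarf",
    "uptake",
    "apoptosis",
    "pipeline",
    "version",
}


@dataclass
class RunConfig:
    """Validated, fully resolved run configuration."""

    raw: dict = field(repr=False)
    version: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _SECTIONS
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        missing = _SECTIONS - set(self.raw) - {"version"}
        if missing:
            raise ConfigError(f"missing config sections: {sorted(missing)}")
        try:
            self.dose_response  # construct everything once to validate
            self.noise
            self.ph_profile
            self.snarf
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        for key in ("pixel_size", "brightness", "rim_depth"):
            if self.render[key] <= 0:
                raise ConfigError(f"render.{key} must be positive")

    @property
    def dose_response(self) -> DoseResponseModel:
        return DoseResponseModel(**self.raw["dose_response"])

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(**self.raw["noise"])

    @property
    def ph_profile(self) -> PhProfile:
        return PhProfile(**self.raw["ph_profile"])

    @property
    def snarf(self) -> SnarfModel:
        params = dict(self.raw["snarf"])
        return SnarfModel(**params)

    @property
    def render(self) -> dict:
        return self.raw["render"]

    @property
    def uptake(self) -> dict:
        return self.raw["uptake"]

    @property
    def apoptosis(self) -> dict:
        return self.raw["apoptosis"]

    @property
    def pipeline(self) -> dict:
        return self.raw["pipeline"]

    def with_overrides(self, **sections) -> "RunConfig":
        """Return a copy with the given sections' keys updated."""
        raw = {k: (dict(v) if isinstance(v, dict) else v) for k, v in self.raw.items()}
        for section, overrides in sections.items():
            if section not in _SECTIONS:
                raise ConfigError(f"unknown config section: {section}")
            raw[section].update(overrides)
        return RunConfig(raw=raw, version=self.version)

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)
        return path


def _builtin_defaults() -> dict:
    text = (
        importlib.resources.files("nodulekit").joinpath("defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


def default_config() -> RunConfig:
    """The package's calibrated default configuration."""
    raw = _builtin_defaults()
    return RunConfig(raw=raw, version=int(raw.get("version", 1)))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a config file, merged section-wise over the built-in defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config file must contain a mapping")
    raw = _builtin_defaults()
    for section, value in user.items():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section: {section}")
        if isinstance(value, dict):
            raw[section].update(value)
        else:
            raw[section] = value
    return RunConfig(raw=raw, version=int(raw.get("version", 1)))
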