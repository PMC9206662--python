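"""Configuration files and run manifests.

Configs are flat YAML with sections mirroring the module structure
(geometry, fluxes, carbon, chem, scenario, ranges). An empty or absent
file yields the full default configuration; unknown keys are rejected
by name; values outside the documented sampling ranges raise unless
explicitly allowed (with a warning either way).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__ as _code_version
from .core import Geometry
from .ensemble import ParameterRanges, ParamRange, default_ranges
from .fluxes import FluxParams
from .params import CarbonParams, ChemOptions, ParameterSet, modern_defaults, permian_defaults
from .scenario import ExtinctionScenario, RwOverrides


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


#: sampled ranges the loader checks scalar overrides against
VALIDATED_RANGES = {
    ("fluxes", "n_si"): (0.2, 0.5),
    ("fluxes", "n_carb"): (0.1, 0.3),
    ("fluxes", "isi_threshold"): (0.6, 0.9),
    ("fluxes", "rw_bsi_ratio"): (0.022, 0.099),
    ("carbon", "climate_sensitivity"): (2.0, 5.0),
    ("scenario", "carbon_mass"): (3.0e4, 5.5e4),
    ("scenario", "release_duration"): (0.8e5, 2.4e5),
    ("scenario", "full_duration"): (2.0e6, 7.0e6),
    ("scenario", "recovery_duration"): (1.0e6, 6.0e6),
}


@dataclass
class FullConfig:
    """Everything a pipeline invocation needs."""

    params: ParameterSet
    scenario: ExtinctionScenario
    ranges: ParameterRanges

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.params.geometry),
            "fluxes": dataclasses.asdict(self.params.fluxes),
            "carbon": dataclasses.asdict(self.params.carbon),
            "chem": dataclasses.asdict(self.params.chem),
            "scenario": dataclasses.asdict(self.scenario),
            "ranges": {
                k: {"lo": r.lo, "hi": r.hi, "scale": r.scale}
                for k, r in self.ranges.ranges.items()
            },
        }


def _apply_section(obj, section: str, values: dict, allow_out_of_range: bool):
    known = {f.name for f in dataclasses.fields(obj)}
    for key, value in values.items():
        if key not in known:
            raise ConfigError(f"unknown key '{section}.{key}'")
        rng = VALIDATED_RANGES.get((section, key))
        if rng is not None and not (rng[0] <= value <= rng[1]):
            msg = (
                f"'{section}.{key}' = {value} outside the sampled range "
                f"[{rng[0]}, {rng[1]}]"
            )
            warnings.warn(msg)
            if not allow_out_of_range:
                raise ConfigError(msg + " (pass allow_out_of_range to accept)")
        setattr(obj, key, value)
    return obj


def load_config(
    path: str | Path | None = None,
    mode: str = "permian",
    allow_out_of_range: bool = False,
) -> FullConfig:
    """Load and validate a configuration file.

    mode selects the default baseline ('permian' or 'modern') that the
    file's keys override. Dataclass invariants are re-checked after
    applying overrides.
    """
    raw: dict = {}
    if path is not None and Path(path).exists():
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")

    base = permian_defaults() if mode == "permian" else modern_defaults()
    scenario = ExtinctionScenario()
    ranges = ParameterRanges(default_ranges())

    known_sections = {"geometry", "fluxes", "carbon", "chem", "scenario", "ranges"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown section '{sorted(unknown)[0]}'")

    geo_kwargs = dataclasses.asdict(base.geometry)
    _apply_section_dict(geo_kwargs, "geometry", raw.get("geometry", {}),
                        Geometry, allow_out_of_range)
    try:
        geometry = Geometry(**geo_kwargs)
    except ValueError as exc:
        raise ConfigError(f"geometry: {exc}") from exc

    flux_kwargs = dataclasses.asdict(base.fluxes)
    _apply_section_dict(flux_kwargs, "fluxes", raw.get("fluxes", {}),
                        FluxParams, allow_out_of_range)
    try:
        fluxes = FluxParams(**flux_kwargs)
    except ValueError as exc:
        raise ConfigError(f"fluxes: {exc}") from exc

    carbon = _apply_section(base.carbon, "carbon", raw.get("carbon", {}), allow_out_of_range)
    chem = _apply_section(base.chem, "chem", raw.get("chem", {}), allow_out_of_range)

    scn_raw = dict(raw.get("scenario", {}))
    rw_raw = scn_raw.pop("extinction_rw", None)
    scenario = _apply_section(scenario, "scenario", scn_raw, allow_out_of_range)
    if rw_raw is not None:
        scenario.extinction_rw = _apply_section(
            RwOverrides(), "extinction_rw", rw_raw, allow_out_of_range
        )

    for key, spec in raw.get("ranges", {}).items():
        try:
            ranges.ranges[key] = ParamRange(
                lo=spec["lo"], hi=spec["hi"], scale=spec.get("scale", "linear")
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"ranges.{key}: need lo/hi (+optional scale)") from exc
        except ValueError as exc:
            raise ConfigError(f"ranges.{key}: {exc}") from exc

    params = ParameterSet(geometry=geometry, fluxes=fluxes, carbon=carbon, chem=chem)
    return FullConfig(params=params, scenario=scenario, ranges=ranges)


def _apply_section_dict(target: dict, section: str, values: dict, cls,
                        allow_out_of_range: bool):
    known = {f.name for f in dataclasses.fields(cls)}
    for key, value in values.items():
        if key not in known:
            raise ConfigError(f"unknown key '{section}.{key}'")
        rng = VALIDATED_RANGES.get((section, key))
        if rng is not None and not (rng[0] <= value <= rng[1]):
            msg = (
                f"'{section}.{key}' = {value} outside the sampled range "
                f"[{rng[0]}, {rng[1]}]"
            )
            warnings.warn(msg)
            if not allow_out_of_range:
                raise ConfigError(msg + " (pass allow_out_of_range to accept)")
        target[key] = value


def save_config(config: FullConfig, path: str | Path) -> None:
    """Write a configuration; save -> load is the identity."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to re-execute a run bit-identically."""

    config: dict
    seed: int | None = None
    code_version: str = _code_version
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    created: str = field(default_factory=lambda: _time.strftime("%Y-%m-%dT%H:%M:%S"))
    extra: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.input_digests[str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append({"path": str(path), "sha256": file_digest(path)})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def verify(self) -> list[str]:
        """Names of recorded files whose on-disk digest no longer matches."""
        bad = []
        for path, digest in self.input_digests.items():
            if not Path(path).exists() or file_digest(path) != digest:
                bad.append(path)
        for out in self.outputs:
            if not Path(out["path"]).exists() or file_digest(out["path"]) != out["sha256"]:
                bad.append(out["path"])
        return bad
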