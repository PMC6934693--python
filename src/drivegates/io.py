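"""Configuration loading and output serialization.

Configurations are flat JSON objects whose keys mirror the CLI flags;
unknown keys and out-of-range values are rejected with the offending field
named.  Outputs are CSV payloads (trajectory or long-format grid) paired
with a JSON manifest carrying the fully resolved configuration, so any
output file can be regenerated exactly from its manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from . import __version__
from .models import DriveParams, InductionSettings, ModelVariant
from .simulate import SimulationConfig, Trajectory
from .sweeps import OutcomeGrid

__all__ = [
    "ConfigError",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "write_trajectory",
    "write_grid",
    "read_manifest",
]

#: Significant digits for serialized frequencies — enough that a value
#: survives a write/read round-trip at oracle-comparison precision.
FLOAT_FMT = "%.12g"

_PARAM_KEYS = ("e_W", "f", "h", "e_W_induced", "f_induced", "e_D", "e_D_induced")
_INDUCTION_KEYS = ("alpha", "start_generation")
_CONFIG_KEYS = ("variant", "initial_q_D", "max_generations", "fixation_threshold")
_ALL_KEYS = set(_PARAM_KEYS) | set(_INDUCTION_KEYS) | set(_CONFIG_KEYS)


class ConfigError(ValueError):
    """A configuration field is missing, unknown, or out of range."""


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a flat mapping.

    ``e_W`` and ``f`` are required; everything else defaults to the study
    conditions (h = 0.5, initial frequency 0.001, threshold 0.99999, cap
    1,000 generations, no induction).  Supplying ``alpha`` without
    ``start_generation`` (or vice versa) is rejected so a half-specified
    signal cannot silently mean "never induce".
    """
    unknown = set(data) - _ALL_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
    for req in ("e_W", "f"):
        if req not in data:
            raise ConfigError(f"missing required field: {req!r}")

    try:
        params = DriveParams(**{k: data[k] for k in _PARAM_KEYS if k in data})
    except (TypeError, ValueError) as err:
        raise ConfigError(f"params: {err}") from err

    has_alpha = "alpha" in data
    has_start = "start_generation" in data
    if has_alpha != has_start:
        missing = "start_generation" if has_alpha else "alpha"
        raise ConfigError(f"induction requires both alpha and start_generation; missing {missing!r}")
    try:
        induction = InductionSettings(
            alpha=data.get("alpha", 0.0),
            start_generation=data.get("start_generation", 0),
            enabled=has_alpha,
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"induction: {err}") from err

    try:
        variant = ModelVariant(data.get("variant", "standard"))
    except ValueError as err:
        raise ConfigError(
            f"variant: {data.get('variant')!r} is not one of "
            f"{[v.value for v in ModelVariant]}"
        ) from err

    try:
        return SimulationConfig(
            params=params,
            variant=variant,
            induction=induction,
            initial_q_D=data.get("initial_q_D", 0.001),
            max_generations=data.get("max_generations", 1000),
            fixation_threshold=data.get("fixation_threshold", 0.99999),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"simulation: {err}") from err


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> SimulationConfig:
    """Load a JSON config file and apply flag overrides (flags win)."""
    data: dict[str, Any] = {}
    if path is not None:
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must hold a JSON object")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(data)


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    """Flat mapping that :func:`config_from_dict` maps back to `config`."""
    out: dict[str, Any] = {k: getattr(config.params, k) for k in _PARAM_KEYS}
    out["variant"] = config.variant.value
    out["initial_q_D"] = config.initial_q_D
    out["max_generations"] = config.max_generations
    out["fixation_threshold"] = config.fixation_threshold
    if config.induction.enabled:
        out["alpha"] = config.induction.alpha
        out["start_generation"] = config.induction.start_generation
    return out


def _manifest_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".manifest.json")


def _write_manifest(csv_path: Path, config: SimulationConfig, extra: dict[str, Any]) -> Path:
    manifest = {
        "tool": "drivegates",
        "version": __version__,
        "config": config_to_dict(config),
        "output": csv_path.name,
        **extra,
    }
    path = _manifest_path(csv_path)
    try:
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except OSError as err:
        raise OSError(f"cannot write manifest {path}: {err}") from err
    return path


def write_trajectory(trajectory: Trajectory, config: SimulationConfig, path: str | Path) -> tuple[Path, Path]:
    """Write `generation,q_D,q_W,induced` CSV plus its JSON manifest.

    Byte-stable: rerunning the same configuration reproduces identical
    files (the manifest carries no timestamp for the same reason).
    """
    csv_path = Path(path)
    try:
        trajectory.to_frame().to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    except OSError as err:
        raise OSError(f"cannot write trajectory {csv_path}: {err}") from err
    extra = {
        "outcome": trajectory.outcome.value,
        "fixation_generation": trajectory.fixation_generation,
    }
    return csv_path, _write_manifest(csv_path, config, extra)


def write_grid(grid: OutcomeGrid, base_config: SimulationConfig, path: str | Path) -> tuple[Path, Path]:
    """Write the long-format grid CSV plus its JSON manifest."""
    csv_path = Path(path)
    try:
        grid.to_frame().to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    except OSError as err:
        raise OSError(f"cannot write grid {csv_path}: {err}") from err
    extra = {
        "x_axis": {"name": grid.x_axis.name, "lower": grid.x_axis.lower,
                   "upper": grid.x_axis.upper, "count": grid.x_axis.count},
        "y_axis": {"name": grid.y_axis.name, "lower": grid.y_axis.lower,
                   "upper": grid.y_axis.upper, "count": grid.y_axis.count},
    }
    return csv_path, _write_manifest(csv_path, base_config, extra)


def read_manifest(path: str | Path) -> dict[str, Any]:
    """Read a manifest back; its ``config`` key feeds :func:`config_from_dict`."""
    return json.loads(Path(path).read_text())
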