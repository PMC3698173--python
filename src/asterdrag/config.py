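"""Run configuration: defaults, YAML round-tripping, validation.

The configuration file is a flat ``key: value`` YAML mapping.  Every key is
optional — an empty file yields the baseline embryo conditions — and unknown
keys are rejected so typos cannot silently fall back to defaults.  The
effective values are echoed to the module logger when a file is loaded.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .model_core import EmbryoGeometry, ModelParams

__all__ = ["RunConfig", "load_config", "save_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All simulation inputs: geometry, transport parameters, run control.

    Defaults are the baseline embryo conditions: a 1000 µm diameter cell,
    centrosome (radius 2 µm) starting 4 µm from the wall, 100 microtubules
    of seed length 2 µm growing at 250 nm/s, 100 nm diameter vesicles at
    2 vesicles/µm hauled at 2 µm/s, viscosity ratio 3, explicit-Euler step
    0.5 s over 45 simulated minutes.
    """

    # geometry (µm)
    cell_radius: float = 500.0
    centrosome_radius: float = 2.0
    initial_wall_distance: float = 4.0
    # transport / aster parameters
    vesicle_radius: float = 0.05
    vesicle_speed: float = 2.0
    vesicle_density: float = 2.0
    viscosity_ratio: float = 3.0
    polymerization_rate: float = 0.25
    mt_count: int = 100
    mt_initial_length: float = 2.0
    mt_radius: float = 0.0125
    aster_dimension: int = 2
    # run control
    time_step: float = 0.5
    duration: float = 2700.0
    seed: int = 0
    seeds: tuple[int, ...] | None = None
    output_dir: str = "asterdrag_out"

    def to_geometry(self) -> EmbryoGeometry:
        return EmbryoGeometry(
            cell_radius=self.cell_radius,
            centrosome_radius=self.centrosome_radius,
            initial_wall_distance=self.initial_wall_distance,
        )

    def to_params(self) -> ModelParams:
        return ModelParams(
            vesicle_radius=self.vesicle_radius,
            vesicle_speed=self.vesicle_speed,
            vesicle_density=self.vesicle_density,
            viscosity_ratio=self.viscosity_ratio,
            polymerization_rate=self.polymerization_rate,
            mt_count=self.mt_count,
            mt_initial_length=self.mt_initial_length,
            mt_radius=self.mt_radius,
            time_step=self.time_step,
            duration=self.duration,
            seed=self.seed,
            aster_dimension=self.aster_dimension,
        )

    def ensemble_seeds(self) -> tuple[int, ...]:
        """The seed list to run: explicit ``seeds`` or the single ``seed``."""
        return self.seeds if self.seeds else (self.seed,)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["seeds"] is not None:
            d["seeds"] = list(d["seeds"])
        return d


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}
_INT_FIELDS = {"mt_count", "seed", "aster_dimension"}
_FLOAT_FIELDS = {
    "cell_radius",
    "centrosome_radius",
    "initial_wall_distance",
    "vesicle_radius",
    "vesicle_speed",
    "vesicle_density",
    "viscosity_ratio",
    "polymerization_rate",
    "mt_initial_length",
    "mt_radius",
    "time_step",
    "duration",
}


def _coerce(key: str, value):
    """Coerce a YAML scalar to the field's type; ConfigError on mismatch."""
    try:
        if key in _INT_FIELDS:
            if isinstance(value, bool) or int(value) != float(value):
                raise ValueError
            return int(value)
        if key in _FLOAT_FIELDS:
            if isinstance(value, bool):
                raise ValueError
            return float(value)
        if key == "seeds":
            if value is None:
                return None
            return tuple(int(v) for v in value)
        if key == "output_dir":
            return str(value)
    except (TypeError, ValueError):
        raise ConfigError(f"config key {key!r}: cannot interpret {value!r}") from None
    raise ConfigError(f"unknown config key {key!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults.  Unknown keys, type mismatches and
    physical-invariant violations raise ``ConfigError`` naming the key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key: value mapping")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    values = {key: _coerce(key, value) for key, value in raw.items()}
    config = RunConfig(**values)
    try:
        config.to_params()
        config.to_geometry()
    except ValueError as exc:  # ParameterError names the offending field
        raise ConfigError(f"{path}: {exc}") from exc
    for key, value in sorted(config.to_dict().items()):
        logger.info("config %s = %r", key, value)
    return config


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it losslessly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
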