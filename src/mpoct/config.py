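"""Run configuration: YAML loading, validation, serialization.

Unknown keys are rejected so that typos fail loudly; every sub-config
round-trips through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import OCTGeometry
from .quantify.discs import QuantConfig
from .synthgen.eye import PhenotypeConfig
from .synthgen.grid import GridLayout, Ring
from .synthgen.sensitivity import SensitivityModel
from .synthgen.staircase import ObserverModel


class ConfigError(ValueError):
    pass


def _build(cls, data: dict, path: str):
    """Instantiate a (frozen) dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys under '{path}': {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{path}' config: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    n_patients: int = 20
    mode: str = "direct"             # direct | psychophysical
    render_fundus: bool = False
    use_true_transforms: bool = True
    out_dir: str = "runs/default"
    geometry: OCTGeometry = field(default_factory=OCTGeometry)
    grid: GridLayout = field(default_factory=GridLayout.default)
    model: SensitivityModel = field(default_factory=SensitivityModel)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    observer: ObserverModel = field(default_factory=ObserverModel)
    quant: QuantConfig = field(default_factory=QuantConfig)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.mode not in ("direct", "psychophysical"):
            raise ConfigError("mode must be 'direct' or 'psychophysical'")
        if not self.render_fundus and not self.use_true_transforms:
            raise ConfigError(
                "use_true_transforms=false requires render_fundus=true")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_SECTIONS = {
    "geometry": OCTGeometry,
    "model": SensitivityModel,
    "phenotype": PhenotypeConfig,
    "observer": ObserverModel,
    "quant": QuantConfig,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ConfigError(f"'{name}' must be a mapping")
            kwargs[name] = _build(cls, section, name)
    if "grid" in data:
        g = dict(data.pop("grid") or {})
        rings = g.pop("rings", None)
        if rings is not None:
            g["rings"] = tuple(_build(Ring, dict(r), "grid.rings")
                               for r in rings)
            kwargs["grid"] = _build(GridLayout, g, "grid")
        else:
            names = {f.name for f in dataclasses.fields(GridLayout)}
            unknown = set(g) - names
            if unknown:
                raise ConfigError(f"unknown keys under 'grid': {sorted(unknown)}")
            kwargs["grid"] = dataclasses.replace(GridLayout.default(), **g)
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs.update(data)
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file -> defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level YAML must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
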