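"""Pipeline configuration: YAML loading, validation, defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .density import CutoffScheme
from .errors import ConfigurationError
from .evalstats import AgreementConfig, ROCConfig
from .nests import NestConfig
from .nuclei import InstanceSeparationConfig, JunctionalFilterConfig


def _from_dict(cls, d: dict | None, where: str):
    d = d or {}
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {where}: {sorted(unknown)}")
    try:
        return cls(**d)
    except TypeError as e:  # wrong value type
        raise ConfigurationError(f"invalid {where}: {e}") from e


@dataclass
class PipelineConfig:
    """Everything a slide run needs, with the published defaults filled in.

    Oracle flags route segmentation to the fixture ground truth instead of
    a trained checkpoint (useful for validation and for running without
    trained models).
    """

    microns_per_pixel: float | None = None  # None: read from image metadata
    epidermis_checkpoint: str | None = None
    nuclei_checkpoint: str | None = None
    oracle_masks: bool = False
    orientation_hint: str | None = None
    stride_mm: float = 0.1
    seed: int = 0
    output_dir: str = "."
    borderline_positive: bool = False
    separation: InstanceSeparationConfig = field(default_factory=InstanceSeparationConfig)
    junctional: JunctionalFilterConfig = field(default_factory=JunctionalFilterConfig)
    cutoffs: CutoffScheme = field(default_factory=CutoffScheme)
    nests: NestConfig = field(default_factory=NestConfig)
    roc: ROCConfig = field(default_factory=ROCConfig)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)

    _NESTED = {
        "separation": InstanceSeparationConfig,
        "junctional": JunctionalFilterConfig,
        "cutoffs": CutoffScheme,
        "nests": NestConfig,
        "roc": ROCConfig,
        "agreement": AgreementConfig,
    }

    def validate(self) -> None:
        if self.stride_mm <= 0:
            raise ConfigurationError("stride_mm must be positive")
        for name in ("epidermis_checkpoint", "nuclei_checkpoint"):
            p = getattr(self, name)
            if p is not None and not self.oracle_masks and not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")

    @classmethod
    def from_dict(cls, d: dict | None) -> "PipelineConfig":
        d = dict(d or {})
        top = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - top
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, sub in cls._NESTED.items():
            if key in d:
                kwargs[key] = _from_dict(sub, d.pop(key), key)
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc"]["cutoff_grid"] = list(self.roc.cutoff_grid)
        return d


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; an empty file gives defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
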