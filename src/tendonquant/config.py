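"""Run configuration: the pipeline's tunable parameters and their defaults.

The defaults reproduce the published analysis parameters exactly: vessel
threshold 0.9 with 8-px dilation, collagen stain threshold 0.12, elastin dot
threshold 0.7 with 5-px dilation and roundness cutoff 0.5, elastin stain
threshold 0.2.  Every override is recorded in the report for audit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class QuantConfig:
    """Parameters of the per-section quantification stage."""

    vessel_threshold: float = 0.9
    vessel_dilation_px: int = 8
    collagen_threshold: float = 0.12
    elastin_threshold: float = 0.2
    dot_threshold: float = 0.7
    dot_dilation_px: int = 5
    roundness_cutoff: float = 0.5
    #: None = Otsu on the non-vessel DAPI pixels; else a fraction of range
    dapi_threshold: float | None = None
    min_nucleus_area_px: int = 5
    bin_width_deg: float = 10.0


@dataclass
class RunConfig:
    """Full pipeline configuration (paths, quantification parameters, statistics)."""

    manifest: str = "manifest.csv"
    output_dir: str = "out"
    quant: QuantConfig = field(default_factory=QuantConfig)
    alpha: float = 0.05
    seed: int = 0
    image_size: tuple[int, int] = (256, 256)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        quant_fields = {f.name for f in fields(QuantConfig)}
        quant_kwargs = {k: raw.pop(k) for k in list(raw) if k in quant_fields}
        nested = raw.pop("quant", {}) or {}
        quant_kwargs.update(nested)
        run_fields = {f.name for f in fields(cls)}
        unknown = set(raw) - run_fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        return cls(quant=QuantConfig(**quant_kwargs), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d
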