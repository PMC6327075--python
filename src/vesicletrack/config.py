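"""Run configuration: one flat key-value file, overridable per option."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .detection import DetectionParams
from .errors import ParameterError


@dataclass
class RunConfig:
    """Flat pipeline configuration; defaults match the detector defaults."""

    input: str = "."
    output_dir: str = "out"
    log_sigma: float = 2.0
    log_kernel_size: int | None = None
    response_lower_bound: float = 0.5
    min_blob_size: int = 4
    connectivity: int = 8
    cutoffs: list[float] = field(default_factory=lambda: [5.0, 10.0, 20.0])
    dt: float = 1.0
    min_life: int = 3
    pixel_size: float | None = None  # length units per px; None keeps px
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        self.cutoffs = [float(c) for c in self.cutoffs]

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            log_sigma=self.log_sigma,
            log_kernel_size=self.log_kernel_size,
            response_lower_bound=self.response_lower_bound,
            min_blob_size=self.min_blob_size,
            connectivity=self.connectivity,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config (optional) and apply non-None keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config {path} must be a flat mapping")
        data.update(loaded)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    return RunConfig(**data)
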