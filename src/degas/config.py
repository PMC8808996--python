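"""Training configuration and run manifests.

Defaults follow the published reference settings used throughout the
original experiments: 2000 training steps, cell batch 200, patient batch
50, 50 hidden units, dropout retention 0.5, loss weights
(cell, patient, MMD, L2) = (2, 3, 3, 3), a three-layer DenseNet hidden
block, bootstrap-aggregated five times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VARIANTS = ("ClassCox", "ClassClass", "ClassBlank", "BlankClass", "BlankCox")
ARCHITECTURES = ("single_layer", "densenet3")


@dataclass
class DegasConfig:
    model_variant: str = "ClassClass"
    train_steps: int = 2000
    cell_batch: int = 200
    patient_batch: int = 50
    hidden_units: int = 50
    dropout_keep: float = 0.5
    lambda0: float = 2.0  # cell classification loss weight
    lambda1: float = 3.0  # patient (classification or Cox) loss weight
    lambda2: float = 3.0  # MMD domain-adaptation loss weight
    lambda3: float = 3.0  # L2 weight-decay strength
    n_bootstrap: int = 5
    architecture: str = "densenet3"
    seed: int = 0
    learning_rate: float = 3e-3
    mmd_kernel_scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)

    def __post_init__(self) -> None:
        if self.model_variant not in VARIANTS:
            raise ValueError(f"model_variant must be one of {VARIANTS}, got {self.model_variant!r}")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        for name in ("train_steps", "cell_batch", "patient_batch", "hidden_units", "n_bootstrap"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
            setattr(self, name, int(getattr(self, name)))
        if not 0 < self.dropout_keep <= 1:
            raise ValueError("dropout_keep must be in (0, 1]")
        for name in ("lambda0", "lambda1", "lambda2", "lambda3"):
            if float(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.mmd_kernel_scales = tuple(float(s) for s in self.mmd_kernel_scales)
        if any(s <= 0 for s in self.mmd_kernel_scales):
            raise ValueError("mmd_kernel_scales must be positive")

    @property
    def uses_cell_labels(self) -> bool:
        return self.model_variant.startswith("Class")

    @property
    def patient_head(self) -> str:
        tail = self.model_variant[5:] if self.model_variant.startswith("Class") else self.model_variant[5:]
        return {"Cox": "cox", "Class": "class", "Blank": "none"}[tail]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mmd_kernel_scales"] = list(self.mmd_kernel_scales)
        return d

    def replace(self, **kw) -> "DegasConfig":
        return dataclasses.replace(self, **kw)


def load_config(path: str | Path) -> DegasConfig:
    """Load a YAML/JSON config; unspecified fields take the defaults above."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(DegasConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return DegasConfig(**data)


def save_config(config: DegasConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run."""

    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


__all__ = ["DegasConfig", "load_config", "save_config", "RunManifest", "VARIANTS", "file_digest"]
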