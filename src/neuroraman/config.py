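"""Declarative run configuration with lossless YAML round-trip.

A :class:`RunConfig` bundles everything one reproducible run needs: the
synthetic design, the preprocessing parameters, the chemometric options,
the dose-statistics options and a single global seed.  Every stochastic
stage derives its own seed deterministically from the global seed and the
stage name, so any stage can be re-run in isolation and still reproduce the
full-pipeline numbers bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from neuroraman.exceptions import InvalidParameterError
from neuroraman.preprocess import PreprocessConfig
from neuroraman.synth import BandSpec, CalciumDesign, SyntheticDesign

__all__ = ["RunConfig", "stage_seed", "config_hash"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of ``"<seed>:<stage>"``, below 2³¹."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


@dataclass
class RunConfig:
    """Full specification of one pipeline run."""

    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    calcium: CalciumDesign = field(default_factory=CalciumDesign)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    dataset_mode: str = "two_class"          # or "dose_series"
    cells_per_spectrum: int = 1
    null_effect: bool = False
    n_components: int = 5
    train_fraction: float = 0.8
    kfold_k: int = 5
    ridge_lambda: float | None = None
    alpha: float = 0.05
    n_null: int = 10000
    make_figures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset_mode not in ("two_class", "dose_series"):
            raise InvalidParameterError(
                f"dataset_mode: unknown mode {self.dataset_mode!r}")
        if not 0 < self.train_fraction < 1:
            raise InvalidParameterError("train_fraction: must be in (0, 1)")
        if self.kfold_k < 2:
            raise InvalidParameterError("kfold_k: must be >= 2")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha: must be in (0, 1)")
        if self.n_null < 100:
            raise InvalidParameterError("n_null: must be >= 100")
        if self.cells_per_spectrum < 1:
            raise InvalidParameterError("cells_per_spectrum: must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "design" in data:
            d = dict(data["design"])
            if "bands" in d:
                d["bands"] = tuple(BandSpec(**b) for b in d["bands"])
            if "grid_cm1" in d:
                d["grid_cm1"] = np.asarray(d["grid_cm1"], dtype=float)
            data["design"] = SyntheticDesign(**d)
        if "calcium" in data:
            data["calcium"] = CalciumDesign(**dict(data["calcium"]))
        if "preprocess" in data:
            p = dict(data["preprocess"])
            if "norm_range_cm1" in p:
                p["norm_range_cm1"] = tuple(p["norm_range_cm1"])
            data["preprocess"] = PreprocessConfig(**p)
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            data = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 fingerprint of the configuration content."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
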