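"""Configuration loading, validation and run manifests.

A pipeline run is configured from defaults < YAML file < command-line
flags (later wins).  Unknown keys are rejected.  Every run can write a
manifest — config snapshot, derived seeds, input hashes, stage timings,
output list — atomically at the end, so a run can be reproduced and its
outputs verified by hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field, asdict

import yaml

from ._utils import derive_seed
from .masked_gat import ModelConfig
from .local_alignment import TransformOptConfig
from .pipeline import PipelineConfig

__all__ = ["parse_and_validate", "load_yaml_config", "RunManifest",
           "write_manifest", "sha256_file"]


def _dataclass_from_dict(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return data


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def parse_and_validate(overrides: dict | None = None,
                       yaml_path: str | None = None) -> PipelineConfig:
    """Merge defaults, YAML config and explicit overrides into a validated
    PipelineConfig.  Override keys may target the model subsection as
    ``model.<key>`` or via a nested ``model`` mapping."""
    merged: dict = {}
    if yaml_path is not None:
        merged.update(load_yaml_config(yaml_path))
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key.startswith("model."):
            merged.setdefault("model", {})[key.split(".", 1)[1]] = value
        else:
            merged[key] = value
    model_data = merged.pop("model", {}) or {}
    topt_data = merged.pop("transform_opt", {}) or {}
    _dataclass_from_dict(PipelineConfig, merged, "pipeline config")
    _dataclass_from_dict(ModelConfig, model_data, "model config")
    _dataclass_from_dict(TransformOptConfig, topt_data, "transform_opt config")
    cfg = PipelineConfig(model=ModelConfig(**model_data),
                         transform_opt=TransformOptConfig(**topt_data),
                         **merged)
    if cfg.unification == "horizontal" and cfg.variant == "softlink_only":
        warnings.warn("unification='horizontal' with variant='softlink_only': "
                      "hard-link edges are dropped, slices stay unconnected "
                      "spatially", RuntimeWarning, stacklevel=2)
    return cfg


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written at the end of a run."""

    config: dict
    seed: int
    stage_seeds: dict
    input_hashes: dict
    software_version: str
    stage_seconds: dict
    outputs: dict = field(default_factory=dict)  # path -> sha256


def build_manifest(cfg: PipelineConfig, inputs: list[str],
                   stage_seconds: dict, outputs: list[str]) -> RunManifest:
    from . import __version__
    stages = ["initial", "initial.triplets", "cluster", "final",
              "final.triplets", "cluster2", "transform_opt", "viz"]
    return RunManifest(
        config=asdict(cfg), seed=cfg.seed,
        stage_seeds={s: derive_seed(cfg.seed, s) for s in stages},
        input_hashes={p: sha256_file(p) for p in inputs},
        software_version=__version__,
        stage_seconds=dict(stage_seconds),
        outputs={p: sha256_file(p) for p in outputs})


def write_manifest(manifest: RunManifest, path: str) -> None:
    """Atomic write: temp file in the target directory, then rename."""
    payload = json.dumps(asdict(manifest), indent=2, default=str)
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
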