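"""Pipeline configuration: a single validated mapping with a stable hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import CohortConfig


@dataclass
class Thresholds:
    fc_threshold: float = 1.5
    alpha: float = 0.05
    link_distance: int = 15_000
    min_occupancy_fraction: float = 0.10
    high_score: float = 4.0
    conservation: float = 1.0
    min_peaks: int = 50
    pseudocount: float = 1.0
    common_max_fc: float = 1.2     # first-pass common-element band for M-A fit

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and abs(v) < float("inf")):
                raise ValueError(f"threshold {f.name} must be finite, got {v!r}")


@dataclass
class Switches:
    kit_context_penalty: bool = True
    conservation_bonus: bool = True
    merge_contexts: bool = True


@dataclass
class PipelineConfig:
    workdir: str = "kre_run"
    seed: int = 0
    k_folds: int = 5
    smote_k_neighbors: int = 5
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    switches: Switches = field(default_factory=Switches)
    hyperparams: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.thresholds.validate()
        self.cohort.validate()
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["seed"] = self.seed   # the pipeline seed governs the cohort
        return d

    def config_hash(self) -> str:
        """Stable hash over the semantically meaningful fields.

        The output location (workdir) is excluded: two runs of the same
        configuration in different directories are the same run.
        """
        d = self.to_dict()
        d.pop("workdir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("cohort", "thresholds", "switches"):
            sub = {"cohort": CohortConfig, "thresholds": Thresholds,
                   "switches": Switches}[f.name]
            if not isinstance(v, dict):
                raise ValueError(f"config section {f.name} must be a mapping")
            if f.name == "cohort" and "planted_features" in v:
                v["planted_features"] = [tuple(t) for t in v["planted_features"]]
            if f.name == "cohort" and "egr1_planted_features" in v:
                v["egr1_planted_features"] = [tuple(t) for t in v["egr1_planted_features"]]
            if f.name == "cohort" and "baseline_log2_clip" in v:
                v["baseline_log2_clip"] = tuple(v["baseline_log2_clip"])
            kwargs[f.name] = _build(sub, v, f"{path}.{f.name}")
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    cfg = _build(PipelineConfig, data, "config")
    cfg.validate()
    return cfg
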