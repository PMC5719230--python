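"""Run configuration: one YAML/JSON document driving simulate + analyze.

The config round-trips losslessly (load -> dump -> load is identity) and the
effective configuration of every run is echoed into the output directory so
results are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .analysis import AnalysisConfig
from .cohort import CohortConfig
from .ssrt import SSRTConfig
from .task_engine import TaskConfig


@dataclass
class RunConfig:
    """Root configuration: seed, task, cohort and analysis parameters."""

    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["seed"] = self.seed
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        task = _build(TaskConfig, d.get("task", {}))
        cohort = _build(CohortConfig, d.get("cohort", {}))
        analysis_d = dict(d.get("analysis", {}))
        ssrt = _build(SSRTConfig, analysis_d.pop("ssrt", {}))
        analysis = _build(AnalysisConfig, {**analysis_d, "ssrt": ssrt})
        seed = int(d.get("seed", 0))
        cohort = dataclasses.replace(cohort, seed=seed)
        return cls(seed=seed, task=task, cohort=cohort, analysis=analysis)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def dump(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _build(cls, d: dict):
    """Construct a (possibly nested) config dataclass from a plain dict,
    rejecting unknown keys so typos fail loudly."""
    if isinstance(d, cls):
        return d
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def _plain(obj):
    """Make a config tree YAML/JSON-safe (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
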