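"""Declarative YAML configuration for end-to-end experiments.

A config file has up to four sections::

    generator:
      f: 1.0
      samples_per_class: 9000
      trace_length: 60
      seed: 0
      behaviors:           # optional per-behavior overrides
        running:
          gyro_amplitude: 1.2
    classifiers:
      - kind: gnb
      - kind: svm_rbf
        params: {C: 10.0, gamma: 1.0}
    k: 10
    seed: 0
    views: [quat4, raw6]

Missing sections fall back to the package defaults (the full
four-classifier, two-view benchmark). Every value can also be
overridden by a CLI flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from .classifiers import ClassifierSpec, default_specs
from .exceptions import ConfigurationError
from .simulate import BehaviorModel, GeneratorConfig, default_behaviors

__all__ = ["ExperimentConfig", "load_config"]


@dataclass
class ExperimentConfig:
    """Generator settings plus the classifier/fold/view protocol."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    classifiers: List[ClassifierSpec] = field(default_factory=default_specs)
    k: int = 10
    seed: int = 0
    views: Sequence[str] = ("quat4", "raw6")

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        self.generator.validate()

    def to_dict(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        gen["behaviors"] = {
            name: dataclasses.asdict(m) for name, m in self.generator.behaviors.items()
        }
        return {
            "generator": gen,
            "classifiers": [
                {"kind": s.kind, "params": dict(s.params)} for s in self.classifiers
            ],
            "k": self.k,
            "seed": self.seed,
            "views": list(self.views),
        }

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build_generator(section: dict) -> GeneratorConfig:
    section = dict(section)
    overrides: Dict[str, dict] = section.pop("behaviors", {}) or {}
    behaviors = default_behaviors()
    for name, fields in overrides.items():
        if name not in behaviors:
            raise ConfigurationError(f"unknown behavior {name!r}")
        behaviors[name] = dataclasses.replace(behaviors[name], **fields)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)} - {"behaviors"}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(f"unknown generator settings: {sorted(unknown)}")
    return GeneratorConfig(behaviors=behaviors, **section)


def load_config(path: Optional[str] = None, **overrides) -> ExperimentConfig:
    """Load an experiment config from YAML, applying keyword overrides.

    ``path=None`` yields the package defaults. Recognized overrides:
    ``seed``, ``k``, ``samples_per_class``, ``views``.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigurationError(f"{path}: top level must be a mapping")
            data = loaded

    gen = _build_generator(data.get("generator", {}))
    specs = [
        ClassifierSpec(entry["kind"], dict(entry.get("params", {})))
        for entry in data.get("classifiers", [])
    ] or default_specs()
    cfg = ExperimentConfig(
        generator=gen,
        classifiers=specs,
        k=int(data.get("k", 10)),
        seed=int(data.get("seed", 0)),
        views=tuple(data.get("views", ("quat4", "raw6"))),
    )

    if overrides.get("samples_per_class") is not None:
        cfg.generator.samples_per_class = int(overrides["samples_per_class"])
    if overrides.get("seed") is not None:
        cfg.seed = int(overrides["seed"])
        cfg.generator.seed = int(overrides["seed"])
    if overrides.get("k") is not None:
        cfg.k = int(overrides["k"])
    if overrides.get("views") is not None:
        cfg.views = tuple(overrides["views"])
    cfg.validate()
    return cfg
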