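"""Pipeline configuration: nested, schema-checked, YAML-loadable.

Every default equals the pipeline's documented operating point (acquisition
rate, filter band, artifact-detection thresholds, analysis parameters), so
an empty config file reproduces the standard analysis. Unknown keys are
rejected to catch typos early; a config hash plus the run seed is embedded
in every output manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .screening import MODEL_NAMES, ReducerConfig

__all__ = ["PipelineConfig", "VERSION"]

VERSION = "0.1.0"


@dataclass
class SynthSection:
    group_sizes: dict = field(
        default_factory=lambda: {"NC": 48, "SCD": 65, "MCI": 90}
    )
    duration_s: float = 300.0
    sampling_rate_hz: float = 8.138
    artifact_rate_per_min: float = 0.5
    noise_sd: float = 0.005
    coupling_base: float = 0.3
    coupling_deltas: dict = field(
        default_factory=lambda: {"NC": 0.0, "SCD": 0.2, "MCI": 0.4}
    )


@dataclass
class FCSection:
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    coh_seg_len_s: float = 120.0


@dataclass
class StatsSection:
    alpha: float = 0.05
    fdr_family: str = "per"  # "per" (estimator x chromophore) or "pooled"
    normality_alpha: float = 0.05


@dataclass
class ModelsSection:
    models: list = field(default_factory=lambda: list(MODEL_NAMES))
    fold_schemes: list = field(default_factory=lambda: [5, 10])
    feature_sets: list = field(
        default_factory=lambda: ["fc_only", "fc_plus_neuro"]
    )
    n_perm: int = 200
    variance_threshold: float = 1.0
    on_empty: str = "keep_all"
    pca_variance: float = 0.95

    def reducer(self) -> ReducerConfig:
        return ReducerConfig(
            variance_threshold=self.variance_threshold,
            on_empty=self.on_empty,
            pca_variance=self.pca_variance,
        )


@dataclass
class PipelineConfig:
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fc: FCSection = field(default_factory=FCSection)
    stats: StatsSection = field(default_factory=StatsSection)
    models: ModelsSection = field(default_factory=ModelsSection)
    version: str = VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, f in known.items():
            if name not in raw:
                continue
            section_cls = f.type if isinstance(f.type, type) else _SECTION_TYPES[name]
            sub = raw[name]
            if name == "version":
                kwargs[name] = str(sub)
                continue
            allowed = {sf.name for sf in fields(section_cls)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
            kwargs[name] = section_cls(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "synth": SynthSection,
    "preprocess": PreprocessConfig,
    "fc": FCSection,
    "stats": StatsSection,
    "models": ModelsSection,
}
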