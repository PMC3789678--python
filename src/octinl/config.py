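"""Pipeline configuration: one YAML-serializable object holding every knob.

Every parameter has a documented default; a config round-trips through its
YAML file losslessly, and its SHA-256 hash is stamped into every output
sidecar so results are traceable to the exact configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .microcysts import CystDetectionParams
from .protocol import RadialProtocol
from .render import AcquisitionModel, CystSpec
from .segmentation import QualityThresholds, SegmentationConfig


@dataclass
class StatsOptions:
    equal_var: bool = True  # pooled-variance Student t-test
    holm_correction: bool = False  # no multiple-testing correction by default
    signed_deviation_correlation: bool = True


@dataclass
class SimulateOptions:
    n_per_group: int = 8
    cyst_prevalence: float = 5.0 / 36.0
    eye_model: str = "shared_latent"
    eye_coupling: float = 0.7
    n_binocular: int = 0


@dataclass
class PipelineConfig:
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    protocol: RadialProtocol = field(default_factory=RadialProtocol)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    cyst_detection: CystDetectionParams = field(default_factory=CystDetectionParams)
    cyst_injection: CystSpec = field(default_factory=CystSpec)
    stats: StatsOptions = field(default_factory=StatsOptions)
    simulate: SimulateOptions = field(default_factory=SimulateOptions)
    fail_on_quality: bool = False
    rng_seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(tp, sub):
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in sub:
                    continue
                v = sub[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                kwargs[f.name] = v
            return tp(**kwargs)

        d = dict(d or {})
        sections = {
            "acquisition": AcquisitionModel,
            "protocol": RadialProtocol,
            "segmentation": SegmentationConfig,
            "quality": QualityThresholds,
            "cyst_detection": CystDetectionParams,
            "cyst_injection": CystSpec,
            "stats": StatsOptions,
            "simulate": SimulateOptions,
        }
        kwargs = {
            name: build(tp, d.get(name, {})) for name, tp in sections.items()
        }
        kwargs["fail_on_quality"] = bool(d.get("fail_on_quality", False))
        kwargs["rng_seed"] = int(d.get("rng_seed", 0))
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
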