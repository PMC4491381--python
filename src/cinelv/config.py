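"""Run configuration: every tunable constant of the pipeline in one
serializable object.

The defaults reproduce the documented behaviour of each stage; a config
file only needs to state the values it overrides. YAML round-trips are
lossless.
"""

from __future__ import annotations

from dataclasses import MISSING, asdict, dataclass, field, fields, is_dataclass

import yaml

from .deformable import DeformConfig, ForceWeights


@dataclass
class CenterConfig:
    smooth_sigma_mm: float = 5.0
    min_area_mm2: float = 100.0


@dataclass
class BloodInitConfig:
    radius_mm: float = 10.0
    min_pixels: int = 30


@dataclass
class EMConfig:
    n_components: int = 3
    tol: float = 1e-6
    max_iter: int = 200
    sd_floor_frac: float = 0.01
    n_bins: int = 512
    roi_radius_mm: float = 55.0  # heart-sized pooling disk for the histogram


@dataclass
class InitConfig:
    node_count: int = 80
    wall_fallback_mm: float = 8.0
    pool_search_radius_mm: float = 10.0


@dataclass
class EdgeConfig:
    sigma_px: float = 1.5


@dataclass
class DeformStageConfig:
    numerics: DeformConfig = field(default_factory=DeformConfig)
    endo_weights: ForceWeights = field(default_factory=lambda: ForceWeights(
        w_balloon=1.0, w_edge=0.3, w_curv_inplane=0.5,
        w_curv_interslice=0.2, w_temporal=0.1, w_damping=1.0,
    ))
    epi_weights: ForceWeights = field(default_factory=lambda: ForceWeights(
        w_balloon=1.0, w_edge=0.3, w_curv_inplane=0.5,
        w_curv_interslice=0.2, w_temporal=0.1, w_damping=1.0,
    ))


@dataclass
class OutflowConfig:
    basal_fraction: float = 0.4
    intensity_sd_mult: float = 2.0
    thickness_min_mm: float = 2.0


@dataclass
class PapillaryConfig:
    volume_tol: float = 0.10
    step_mm: float = 0.25
    cap_mm: float = 3.0
    min_reference_mm3: float = 30.0


@dataclass
class RunConfig:
    """All tunable constants of the segmentation pipeline."""

    center: CenterConfig = field(default_factory=CenterConfig)
    blood_init: BloodInitConfig = field(default_factory=BloodInitConfig)
    em: EMConfig = field(default_factory=EMConfig)
    init: InitConfig = field(default_factory=InitConfig)
    edge: EdgeConfig = field(default_factory=EdgeConfig)
    deform: DeformStageConfig = field(default_factory=DeformStageConfig)
    outflow: OutflowConfig = field(default_factory=OutflowConfig)
    papillary: PapillaryConfig = field(default_factory=PapillaryConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build(cls, d or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build(cls, d: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        proto = f.default_factory() if f.default_factory is not MISSING else None
        if is_dataclass(proto) and isinstance(v, dict):
            kwargs[f.name] = _build(type(proto), v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)
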