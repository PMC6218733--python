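"""Run configuration: texture, factorization and stage settings.

Loadable from / dumpable to YAML so runs are reproducible from a single
file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class GLCMConfig:
    levels: int = 32
    window: int = 11
    distance: int = 1
    central_difference_variance: bool = False


@dataclass
class NMFConfig:
    tol: float = 1e-5
    max_iter: int = 500
    init: str = "spa"  # spa | maxnorm | random
    seed: int | None = None


@dataclass
class StageConfig:
    """One hierarchical segmentation stage.

    ``modalities`` contribute feature rows; ``guide_modality`` with
    ``polarity`` decides which NMF component is the region of interest.
    Slices with fewer masked pixels than ``min_region_voxels`` are
    skipped (a rank-two split of a handful of columns is meaningless).
    """

    name: str
    modalities: tuple
    guide_modality: str
    polarity: str  # bright | dark
    min_region_voxels: int = 64


def default_stages() -> list:
    return [
        StageConfig("edema", ("T2", "FLAIR"), "FLAIR", "bright"),
        StageConfig("necrosis", ("T1c",), "T1c", "dark"),
        StageConfig("enhanced", ("T1c",), "T1c", "bright"),
        StageConfig("nonenhanced", ("T1c",), "T1c", "bright"),
    ]


@dataclass
class PipelineConfig:
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    nmf: NMFConfig = field(default_factory=NMFConfig)
    stages: list = field(default_factory=default_stages)
    include_intensity_rows: bool = False

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "glcm" in raw:
            cfg.glcm = GLCMConfig(**raw["glcm"])
        if "nmf" in raw:
            cfg.nmf = NMFConfig(**raw["nmf"])
        if "stages" in raw:
            cfg.stages = [
                StageConfig(
                    name=s["name"],
                    modalities=tuple(s["modalities"]),
                    guide_modality=s["guide_modality"],
                    polarity=s["polarity"],
                    min_region_voxels=s.get("min_region_voxels", 64),
                )
                for s in raw["stages"]
            ]
        cfg.include_intensity_rows = raw.get("include_intensity_rows", False)
        return cfg
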