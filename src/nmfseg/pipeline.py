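"""Four-stage hierarchical segmentation.

Stage 1 splits the brain mask into edema vs rest using T2+FLAIR
texture; stage 2 splits the edema mask into necrosis vs rest on T1c
(dark polarity); stage 3 runs inside I1 = edema - necrosis for the
enhancing tumor (T1c, bright); stage 4 runs inside
I2 = edema - necrosis - enhanced for the nonenhancing tumor.  Each
stage works axial-slice-by-slice: texture feature maps feed a
nonnegative feature-by-voxel matrix, a rank-two factorization splits
its columns in two, and the region-of-interest cluster is scattered
back into a binary mask.  The final label map applies the standard
convention: 1 necrosis, 2 edema, 3 nonenhancing, 4 enhancing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import glcm as _glcm
from . import lmm as _lmm
from . import rank2nmf as _nmf
from .config import PipelineConfig, StageConfig
from .errors import (
    DegenerateMatrixError,
    EmptyMaskError,
    MaskOverlapError,
    ShapeMismatchError,
)
from .metrics import evaluate  # re-exported convenience
from .volume_io import BinaryMask, LabelMap, Volume, brain_mask

logger = logging.getLogger(__name__)


@dataclass
class StageResult:
    """Output of one stage: its region mask and run diagnostics."""

    name: str
    mask: BinaryMask
    input_mask: BinaryMask
    diagnostics: list = field(default_factory=list)  # per-slice dicts


def segment_stage(
    volumes: dict,
    input_mask: BinaryMask,
    cfg: StageConfig,
    glcm_cfg=None,
    nmf_cfg=None,
    include_intensity_rows: bool = False,
) -> StageResult:
    """Run one rank-two split inside ``input_mask``, slice by slice."""
    from .config import GLCMConfig, NMFConfig

    glcm_cfg = glcm_cfg or GLCMConfig()
    nmf_cfg = nmf_cfg or NMFConfig()

    shapes = {v.shape for v in volumes.values()} | {input_mask.shape}
    if len(shapes) != 1:
        raise ShapeMismatchError("volumes and mask must share a shape")
    shape = input_mask.shape
    out = np.zeros(shape, dtype=bool)
    diagnostics = []

    any_slice = False
    for z in range(shape[2]):
        sm = input_mask.data[:, :, z]
        n_masked = int(sm.sum())
        if n_masked < cfg.min_region_voxels:
            continue
        any_slice = True
        fmaps = {}
        for mod in cfg.modalities:
            fmaps[mod] = _glcm.feature_maps(
                volumes[mod].data[:, :, z],
                sm,
                window_size=glcm_cfg.window,
                levels=glcm_cfg.levels,
                d=glcm_cfg.distance,
                central_difference_variance=glcm_cfg.central_difference_variance,
            )
        intensity = (
            {mod: volumes[mod].data[:, :, z] for mod in cfg.modalities}
            if include_intensity_rows
            else None
        )
        fm = _lmm.build_matrix(fmaps, sm, intensity_slices=intensity)

        # zero feature columns carry no texture signal: straight to C2
        nonzero = fm.M.any(axis=0)
        sub = fm.M[:, nonzero]
        rows, cols = fm.voxel_index[:, 0], fm.voxel_index[:, 1]
        guide_slice = volumes[cfg.guide_modality].data[:, :, z]
        guide = guide_slice[rows, cols]

        if sub.shape[1] < 2:
            continue
        try:
            F = _nmf.factorize(
                sub,
                tol=nmf_cfg.tol,
                max_iter=nmf_cfg.max_iter,
                init=nmf_cfg.init,
                seed=nmf_cfg.seed,
            )
        except DegenerateMatrixError:
            logger.warning("stage %s slice %d: degenerate matrix, skipped", cfg.name, z)
            continue
        assignment = _nmf.assign_clusters(F)
        assignment = _nmf.select_roi_component(
            F, assignment, guide[nonzero], polarity=cfg.polarity
        )
        sub_idx = np.nonzero(nonzero)[0]
        roi_cols = sub_idx[assignment.C1]
        out[rows[roi_cols], cols[roi_cols], z] = True
        diagnostics.append(
            {
                "slice": z,
                "n_voxels": n_masked,
                "n_roi": int(roi_cols.size),
                "residual": F.residual,
                "iterations": F.iterations,
            }
        )

    if not any_slice:
        logger.warning(
            "stage %s: no slice reached the %d-voxel floor; empty mask",
            cfg.name,
            cfg.min_region_voxels,
        )
    out &= input_mask.data
    return StageResult(
        name=cfg.name,
        mask=BinaryMask(data=out),
        input_mask=input_mask,
        diagnostics=diagnostics,
    )


def assemble_labels(
    edema: BinaryMask,
    necrosis: BinaryMask,
    enhanced: BinaryMask,
    nonenhanced: BinaryMask,
) -> LabelMap:
    """Combine the four stage masks into one label map.

    The three core masks must be pairwise disjoint and inside edema;
    remaining edema voxels keep label 2.
    """
    cores = {"necrosis": necrosis, "enhanced": enhanced, "nonenhanced": nonenhanced}
    names = list(cores)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (cores[a].data & cores[b].data).any():
                raise MaskOverlapError(f"{a} and {b} masks overlap")
    for name, m in cores.items():
        if (m.data & ~edema.data).any():
            raise MaskOverlapError(f"{name} mask extends outside edema")
    labels = np.zeros(edema.shape, dtype=np.uint8)
    labels[edema.data] = 2
    labels[nonenhanced.data] = 3
    labels[enhanced.data] = 4
    labels[necrosis.data] = 1
    return LabelMap(data=labels)


def run_pipeline(
    t2: Volume,
    flair: Volume,
    t1c: Volume,
    config: PipelineConfig | None = None,
):
    """Full hierarchical segmentation of one co-registered case.

    Returns (LabelMap, {stage_name: StageResult}).
    """
    config = config or PipelineConfig()
    volumes = {"T2": t2, "FLAIR": flair, "T1c": t1c}
    shapes = {v.shape for v in volumes.values()}
    if len(shapes) != 1:
        raise ShapeMismatchError("input volumes must be co-registered (same shape)")

    stage_by_name = {s.name: s for s in config.stages}
    results = {}

    def run(name, mask):
        cfg = stage_by_name[name]
        res = segment_stage(
            volumes,
            mask,
            cfg,
            glcm_cfg=config.glcm,
            nmf_cfg=config.nmf,
            include_intensity_rows=config.include_intensity_rows,
        )
        logger.info(
            "stage %s: %d / %d voxels selected",
            name,
            res.mask.count(),
            mask.count(),
        )
        results[name] = res
        return res

    guide = volumes[stage_by_name["edema"].guide_modality]
    mask0 = brain_mask(guide)
    edema = run("edema", mask0)
    necrosis = run("necrosis", edema.mask)
    i1 = BinaryMask(data=edema.mask.data & ~necrosis.mask.data)
    enhanced = run("enhanced", i1)
    i2 = BinaryMask(data=i1.data & ~enhanced.mask.data)
    nonenhanced = run("nonenhanced", i2)

    label_map = assemble_labels(
        edema.mask, necrosis.mask, enhanced.mask, nonenhanced.mask
    )
    label_map.spacing = t2.spacing
    return label_map, results
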