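"""Assembly of the nonnegative feature-by-voxel matrix.

Each column of M is the texture-feature signature of one masked voxel;
rows stack the 16 features of each contributing modality (optionally
plus a raw-intensity row per modality).  Rows are min-max rescaled to
[0, 1] so M is nonnegative regardless of feature sign and so features
with wildly different magnitudes weigh comparably in the factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, ShapeMismatchError
from .glcm import FEATURE_NAMES, N_FEATURES


@dataclass
class FeatureMatrix:
    """Nonnegative m-by-n feature matrix with voxel bookkeeping.

    Attributes
    ----------
    M : ndarray, shape (m, n)
        Row-rescaled nonnegative matrix; n = masked voxel count.
    voxel_index : ndarray, shape (n, 2)
        (row, col) slice coordinate of each column, raster order.
    row_labels : list of (modality, feature_name)
    row_scaling : ndarray, shape (m, 2)
        (min, max) used to rescale each row.
    """

    M: np.ndarray
    voxel_index: np.ndarray
    row_labels: list
    row_scaling: np.ndarray

    def __post_init__(self):
        if self.M.size and self.M.min() < 0:
            raise ValueError("feature matrix must be nonnegative")
        if self.M.shape[1] != self.voxel_index.shape[0]:
            raise ValueError("voxel_index length must equal column count")


def rescale_rows(M_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max rescale each row to [0, 1]; constant rows map to zeros.

    Returns the rescaled matrix and an (m, 2) array of the (min, max)
    applied per row.
    """
    M_raw = np.asarray(M_raw, dtype=float)
    if M_raw.ndim != 2 or min(M_raw.shape) < 1:
        raise ValueError("expected a nonempty 2D matrix")
    lo = M_raw.min(axis=1, keepdims=True)
    hi = M_raw.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(M_raw)
    nz = span[:, 0] > 0
    out[nz] = (M_raw[nz] - lo[nz]) / span[nz]
    return out, np.hstack([lo, hi])


def build_matrix(
    feature_maps: dict,
    mask: np.ndarray,
    intensity_slices: dict | None = None,
) -> FeatureMatrix:
    """Stack per-modality feature maps into a rescaled feature matrix.

    Parameters
    ----------
    feature_maps : dict
        modality -> (16, H, W) feature stack, in the modality order the
        rows should appear.
    mask : 2D bool array
        Voxels to enumerate (raster order).
    intensity_slices : dict, optional
        modality -> (H, W) raw intensity slice; when given, one
        intensity row per modality is appended after all feature rows.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("build_matrix requires a non-empty mask")
    for mod, fm in feature_maps.items():
        if fm.shape != (N_FEATURES,) + mask.shape:
            raise ShapeMismatchError(
                f"feature map for {mod} has shape {fm.shape}, "
                f"expected {(N_FEATURES,) + mask.shape}"
            )
    rows_idx, cols_idx = np.nonzero(mask)
    blocks, labels = [], []
    for mod, fm in feature_maps.items():
        blocks.append(fm[:, rows_idx, cols_idx])
        labels.extend((mod, name) for name in FEATURE_NAMES)
    if intensity_slices:
        for mod, sl in intensity_slices.items():
            if sl.shape != mask.shape:
                raise ShapeMismatchError("intensity slice shape mismatch")
            blocks.append(np.asarray(sl, dtype=float)[rows_idx, cols_idx][None])
            labels.append((mod, "intensity"))
    raw = np.vstack(blocks)
    if np.isnan(raw).any():
        raise ValueError("feature maps contain NaN inside the mask")
    M, scaling = rescale_rows(raw)
    voxel_index = np.stack([rows_idx, cols_idx], axis=1)
    return FeatureMatrix(
        M=M, voxel_index=voxel_index, row_labels=labels, row_scaling=scaling
    )
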