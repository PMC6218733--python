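"""Gray-level co-occurrence matrices and Haralick texture features.

A slice is first quantized over its mask to ``levels`` integer gray
levels, then a symmetric, direction-averaged, normalized GLCM is built
for the sliding window centered at every masked pixel, and 16 texture
statistics are evaluated on each.

Conventions (configurable where noted):

* gray levels are indexed 1..N inside the feature formulas (quantized
  data itself is stored 0..N-1);
* pairs are counted symmetrically (both orderings) before averaging the
  0/45/90/135-degree direction matrices and normalizing to sum 1;
* windows are cropped at slice and mask borders — only pairs with both
  pixels inside mask-and-window count; nothing is padded or fabricated;
* logarithms are natural; 0*log(0) = 0;
* correlation uses (i - mu_x)(j - mu_y)/(sigma_x*sigma_y) with sigma the
  standard deviations of the marginal means; dissimilarity weights by
  |i - j|; variance measures deviation from the GLCM mean gray level;
  sum variance weights by (k - SumEntropy)^2.  The raw-moment form of
  difference variance (sum of k^2 * p_diff(k)) is the default, with the
  central-moment form behind ``central_difference_variance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError, NoPairsError, ShapeMismatchError

#: Feature order used everywhere a feature axis appears.
FEATURE_NAMES = (
    "contrast",
    "energy",
    "dissimilarity",
    "entropy",
    "correlation",
    "homogeneity",
    "variance",
    "difference_entropy",
    "sum_average",
    "cluster_shade",
    "cluster_prominence",
    "maximum_probability",
    "difference_variance",
    "autocorrelation",
    "sum_entropy",
    "sum_variance",
)
N_FEATURES = len(FEATURE_NAMES)

DEFAULT_DIRECTIONS = (0, 45, 90, 135)

# (drow, dcol) unit offsets per direction; rows grow downward.
_DIR_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class QuantizedSlice:
    """2D grid of integer gray levels in [0, levels-1]."""

    data: np.ndarray
    levels: int

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.data.size and (
            self.data.min() < 0 or self.data.max() >= self.levels
        ):
            raise ValueError("quantized values out of [0, levels-1]")


@dataclass
class GLCMatrix:
    """Normalized, direction-averaged co-occurrence matrix."""

    G: np.ndarray
    d: int = 1
    directions: tuple = DEFAULT_DIRECTIONS

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("GLCM must be square")

    @property
    def levels(self) -> int:
        return self.G.shape[0]


@dataclass
class GLCMMarginals:
    """Marginal statistics of a normalized GLCM (1-based gray levels)."""

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_sum: np.ndarray  # index k-2 holds p_{x+y}(k), k = 2..2N
    p_diff: np.ndarray  # index k holds p_{x-y}(k), k = 0..N-1
    sum_entropy: float


@dataclass
class FeatureVector:
    """The 16 named texture statistics of one GLCM."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features")

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in zip(FEATURE_NAMES, self.values)}


def quantize(slice_data: np.ndarray, mask: np.ndarray, levels: int) -> QuantizedSlice:
    """Linearly rescale masked intensities to integer levels 0..levels-1.

    The min/max are taken over the mask only; unmasked pixels are set to
    level 0 and never influence the scaling.  A constant masked slice
    maps everything to level 0.
    """
    slice_data = np.asarray(slice_data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if slice_data.shape != mask.shape:
        raise ShapeMismatchError("slice and mask shapes differ")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not mask.any():
        raise EmptyMaskError("quantize requires at least one masked pixel")
    vals = slice_data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(slice_data.shape, dtype=np.int32)
    if hi > lo:
        q[mask] = np.rint((vals - lo) / (hi - lo) * (levels - 1)).astype(np.int32)
    return QuantizedSlice(data=q, levels=levels)


def co_occurrence_counts(
    window: QuantizedSlice,
    d: int,
    direction: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric integer pair counts for one direction.

    Each valid pixel pair at offset (d, direction) contributes to both
    (a, b) and (b, a).  Pairs with either end outside the mask are
    skipped.
    """
    if direction not in _DIR_OFFSETS:
        raise ValueError(f"unsupported direction {direction}")
    q = window.data
    N = window.levels
    h, w = q.shape
    dr, dc = (o * d for o in _DIR_OFFSETS[direction])
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    counts = np.zeros((N, N), dtype=np.int64)
    if r1 <= r0 or c1 <= c0:
        return counts
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a, b = a[valid], b[valid]
    else:
        a, b = a.ravel(), b.ravel()
    flat = np.bincount(a * N + b, minlength=N * N).reshape(N, N)
    return counts + flat + flat.T


def compute_glcm(
    window: QuantizedSlice,
    d: int = 1,
    directions: tuple = DEFAULT_DIRECTIONS,
    mask: np.ndarray | None = None,
) -> GLCMatrix:
    """Direction-averaged, normalized symmetric GLCM of one window."""
    total = np.zeros((window.levels, window.levels), dtype=float)
    for phi in directions:
        total += co_occurrence_counts(window, d, phi, mask=mask)
    s = total.sum()
    if s == 0:
        raise NoPairsError(
            "no valid co-occurrence pairs in any requested direction"
        )
    return GLCMatrix(G=total / s, d=d, directions=tuple(directions))


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def marginals(G: GLCMatrix) -> GLCMMarginals:
    """Marginal statistics used by the sum/difference features."""
    stats = _batch_marginal_stats(G.G[None])
    return GLCMMarginals(
        mu_x=float(stats["mu_x"][0]),
        mu_y=float(stats["mu_y"][0]),
        sigma_x=float(stats["sigma_x"][0]),
        sigma_y=float(stats["sigma_y"][0]),
        p_sum=stats["p_sum"][0],
        p_diff=stats["p_diff"][0],
        sum_entropy=float(stats["sum_entropy"][0]),
    )


def _batch_marginal_stats(P: np.ndarray) -> dict:
    """Marginal stats for a stack of normalized GLCMs, shape (n, N, N)."""
    n, N, _ = P.shape
    i = np.arange(1, N + 1)
    I = i[:, None] * np.ones((1, N))  # row index, 1-based
    J = I.T
    mu_x = (J * P).sum(axis=(1, 2))
    mu_y = (I * P).sum(axis=(1, 2))
    sigma_x = np.sqrt(
        ((J - mu_x[:, None, None]) ** 2 * P).sum(axis=(1, 2))
    )
    sigma_y = np.sqrt(
        ((I - mu_y[:, None, None]) ** 2 * P).sum(axis=(1, 2))
    )
    sum_idx = (I + J - 2).astype(np.intp)  # k-2, k = 2..2N
    diff_idx = np.abs(I - J).astype(np.intp)  # k = 0..N-1
    p_sum = np.zeros((n, 2 * N - 1))
    p_diff = np.zeros((n, N))
    rows = np.broadcast_to(np.arange(n)[:, None, None], P.shape)
    np.add.at(p_sum, (rows, np.broadcast_to(sum_idx, P.shape)), P)
    np.add.at(p_diff, (rows, np.broadcast_to(diff_idx, P.shape)), P)
    sum_entropy = -_xlogx(p_sum).sum(axis=1)
    return {
        "mu_x": mu_x,
        "mu_y": mu_y,
        "sigma_x": sigma_x,
        "sigma_y": sigma_y,
        "p_sum": p_sum,
        "p_diff": p_diff,
        "sum_entropy": sum_entropy,
    }


def _features_batch(
    P: np.ndarray, central_difference_variance: bool = False
) -> np.ndarray:
    """All 16 features for a stack of normalized GLCMs.

    Parameters
    ----------
    P : ndarray, shape (n, N, N)
        Stack of normalized co-occurrence matrices.

    Returns
    -------
    ndarray, shape (16, n), ordered per FEATURE_NAMES.
    """
    n, N, _ = P.shape
    i = np.arange(1, N + 1, dtype=float)
    I = np.repeat(i[:, None], N, axis=1)
    J = I.T
    st = _batch_marginal_stats(P)
    mu_x = st["mu_x"][:, None, None]
    mu_y = st["mu_y"][:, None, None]
    sx, sy = st["sigma_x"], st["sigma_y"]
    p_sum, p_diff = st["p_sum"], st["p_diff"]
    k_sum = np.arange(2, 2 * N + 1, dtype=float)
    k_diff = np.arange(0, N, dtype=float)

    contrast = ((I - J) ** 2 * P).sum(axis=(1, 2))
    energy = (P**2).sum(axis=(1, 2))
    dissimilarity = (np.abs(I - J) * P).sum(axis=(1, 2))
    entropy = -_xlogx(P).sum(axis=(1, 2))
    denom = sx * sy
    corr_num = ((I - mu_x) * (J - mu_y) * P).sum(axis=(1, 2))
    correlation = np.where(denom > 0, corr_num / np.where(denom > 0, denom, 1.0), 0.0)
    homogeneity = (P / (1.0 + (I - J) ** 2)).sum(axis=(1, 2))
    mu = 0.5 * (mu_x + mu_y)
    variance = ((I - mu) ** 2 * P).sum(axis=(1, 2))
    difference_entropy = -_xlogx(p_diff).sum(axis=1)
    sum_average = (k_sum * p_sum).sum(axis=1)
    cluster_shade = ((I + J - mu_x - mu_y) ** 3 * P).sum(axis=(1, 2))
    cluster_prominence = ((I + J - mu_x - mu_y) ** 4 * P).sum(axis=(1, 2))
    maximum_probability = P.max(axis=(1, 2))
    if central_difference_variance:
        mu_d = (k_diff * p_diff).sum(axis=1)
        difference_variance = ((k_diff - mu_d[:, None]) ** 2 * p_diff).sum(axis=1)
    else:
        difference_variance = (k_diff**2 * p_diff).sum(axis=1)
    autocorrelation = (I * J * P).sum(axis=(1, 2))
    sum_entropy = st["sum_entropy"]
    sum_variance = ((k_sum - sum_entropy[:, None]) ** 2 * p_sum).sum(axis=1)

    return np.stack(
        [
            contrast,
            energy,
            dissimilarity,
            entropy,
            correlation,
            homogeneity,
            variance,
            difference_entropy,
            sum_average,
            cluster_shade,
            cluster_prominence,
            maximum_probability,
            difference_variance,
            autocorrelation,
            sum_entropy,
            sum_variance,
        ]
    )


def haralick_features(
    G: GLCMatrix, central_difference_variance: bool = False
) -> FeatureVector:
    """Evaluate the 16 texture statistics of one normalized GLCM."""
    vals = _features_batch(
        G.G[None], central_difference_variance=central_difference_variance
    )[:, 0]
    return FeatureVector(values=vals)


def feature_maps(
    slice_data: np.ndarray,
    mask: np.ndarray,
    window_size: int = 11,
    levels: int = 32,
    d: int = 1,
    directions: tuple = DEFAULT_DIRECTIONS,
    central_difference_variance: bool = False,
) -> np.ndarray:
    """Per-pixel texture features from sliding-window GLCMs.

    For every masked pixel the GLCM of the window centered there
    (cropped at the slice border, restricted to masked pixels) is
    computed on the globally quantized slice and its 16 features are
    assigned to the pixel.  Masked pixels whose window contains no valid
    pair get all-zero features; unmasked pixels carry NaN.

    Returns
    -------
    ndarray, shape (16, H, W)
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 3")
    mask = np.asarray(mask, dtype=bool)
    qs = quantize(slice_data, mask, levels)  # raises EmptyMaskError
    q = qs.data
    h, w = q.shape
    half = window_size // 2
    rows, cols = np.nonzero(mask)
    n = rows.size
    N = levels

    offsets = [tuple(o * d for o in _DIR_OFFSETS[phi]) for phi in directions]
    stack = np.zeros((n, N, N), dtype=float)
    for idx in range(n):
        r, c = rows[idx], cols[idx]
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        sub = q[r0:r1, c0:c1]
        msub = mask[r0:r1, c0:c1]
        sh, sw = sub.shape
        acc = None
        for dr, dc in offsets:
            rr0, rr1 = max(0, -dr), sh - max(0, dr)
            cc0, cc1 = max(0, -dc), sw - max(0, dc)
            if rr1 <= rr0 or cc1 <= cc0:
                continue
            valid = msub[rr0:rr1, cc0:cc1] & msub[rr0 + dr : rr1 + dr, cc0 + dc : cc1 + dc]
            if not valid.any():
                continue
            a = sub[rr0:rr1, cc0:cc1][valid]
            b = sub[rr0 + dr : rr1 + dr, cc0 + dc : cc1 + dc][valid]
            flat = np.bincount(a * N + b, minlength=N * N)
            acc = flat if acc is None else acc + flat
        if acc is not None:
            g = acc.reshape(N, N)
            g = g + g.T
            stack[idx] = g / g.sum()

    degenerate = stack.sum(axis=(1, 2)) == 0
    feats = _features_batch(
        stack, central_difference_variance=central_difference_variance
    )
    feats[:, degenerate] = 0.0

    out = np.full((N_FEATURES, h, w), np.nan)
    out[:, rows, cols] = feats
    return out
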