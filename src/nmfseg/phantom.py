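"""Synthetic co-registered T2/FLAIR/T1c phantoms with ground truth.

The phantom is a brain ellipsoid containing nested tumor compartments:
an edema ellipsoid, inside it a tumor core, and inside the core a
necrotic ellipsoid wrapped by an enhancing rim plus a separate
nonenhancing ellipsoid.  Each compartment gets, per modality, a mean
intensity plus spatially correlated noise (smoothed white noise with a
per-compartment correlation scale), so compartments differ in texture
as well as in brightness — exactly what windowed co-occurrence features
discriminate on.

Default contrasts follow the usual clinical appearance: edema is
hyperintense on T2/FLAIR, the enhancing rim hyperintense on T1c,
necrosis hypointense on T1c.  Compartment z-radii exceed the grid depth
so all axial slices carry comparable cross-sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import PhantomGeometryError
from .volume_io import LabelMap, Volume

MODALITY_ORDER = ("T2", "FLAIR", "T1c")
COMPARTMENTS = ("background", "brain", "edema", "nonenhanced", "enhancing", "necrosis")


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid given by center and radii (voxels)."""

    center: tuple
    radii: tuple

    def contains_grid(self, shape) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        acc = np.zeros(shape, dtype=float)
        for g, c, r in zip(grids, self.center, self.radii):
            acc = acc + ((g - c) / r) ** 2
        return acc <= 1.0

    def inside(self, other: "Ellipsoid", margin: float = 0.0) -> bool:
        """Conservative test: self fits inside other along every axis."""
        return all(
            abs(cs - co) + rs + margin <= ro
            for cs, co, rs, ro in zip(
                self.center, other.center, self.radii, other.radii
            )
        )

    def disjoint(self, other: "Ellipsoid", margin: float = 0.0) -> bool:
        """Conservative axis-wise separation test."""
        return any(
            abs(cs - co) >= rs + ro + margin
            for cs, co, rs, ro in zip(
                self.center, other.center, self.radii, other.radii
            )
        )


@dataclass
class Tissue:
    """Per-compartment appearance: means per modality plus texture.

    ``noise_amplitude`` may be a scalar or a per-modality dict; texture
    contrast between tissues is modality-specific just like mean
    intensity contrast.
    """

    means: dict  # modality -> mean intensity
    noise_amplitude: float | dict = 0.0
    correlation_scale: float = 1.0

    def __post_init__(self):
        if any(v < 0 for v in self.means.values()):
            raise ValueError("mean intensities must be nonnegative")

    def amplitude(self, modality: str) -> float:
        if isinstance(self.noise_amplitude, dict):
            return float(self.noise_amplitude.get(modality, 0.0))
        return float(self.noise_amplitude)


def _default_geometry(shape):
    sx, sy = shape[0], shape[1]
    cx, cy = (sx - 1) / 2.0, (sy - 1) / 2.0
    cz = (shape[2] - 1) / 2.0
    deep = 10.0 * shape[2]  # quasi-cylindrical in z
    return {
        "brain": Ellipsoid((cx, cy, cz), (0.46 * sx, 0.44 * sy, deep * 1.5)),
        "edema": Ellipsoid((cx - 0.016 * sx, cy + 0.016 * sy, cz), (0.34 * sx, 0.30 * sy, deep * 1.2)),
        "core": Ellipsoid((cx - 0.016 * sx, cy + 0.016 * sy, cz), (0.31 * sx, 0.29 * sy, deep * 1.1)),
        "necrosis": Ellipsoid((cx - 0.0625 * sx, cy - 0.016 * sy, cz), (0.115 * sx, 0.105 * sy, deep)),
        "enhancing": Ellipsoid((cx - 0.0625 * sx, cy - 0.016 * sy, cz), (0.20 * sx, 0.185 * sy, deep * 1.05)),
        "nonenhanced": Ellipsoid((cx + 0.164 * sx, cy + 0.195 * sy, cz), (0.105 * sx, 0.10 * sy, deep)),
    }


def _default_tissues():
    return {
        "background": Tissue({"T2": 0.0, "FLAIR": 0.0, "T1c": 0.0}, 0.0, 1.0),
        "brain": Tissue(
            {"T2": 90.0, "FLAIR": 80.0, "T1c": 110.0},
            {"T2": 3.0, "FLAIR": 3.0, "T1c": 5.0},
            2.0,
        ),
        "edema": Tissue(
            {"T2": 210.0, "FLAIR": 220.0, "T1c": 150.0},
            {"T2": 30.0, "FLAIR": 30.0, "T1c": 12.0},
            0.8,
        ),
        "necrosis": Tissue(
            {"T2": 230.0, "FLAIR": 205.0, "T1c": 20.0},
            {"T2": 25.0, "FLAIR": 25.0, "T1c": 5.0},
            0.9,
        ),
        "enhancing": Tissue(
            {"T2": 200.0, "FLAIR": 215.0, "T1c": 250.0},
            {"T2": 28.0, "FLAIR": 28.0, "T1c": 15.0},
            0.7,
        ),
        "nonenhanced": Tissue(
            {"T2": 205.0, "FLAIR": 210.0, "T1c": 200.0},
            {"T2": 26.0, "FLAIR": 26.0, "T1c": 12.0},
            1.1,
        ),
    }


@dataclass
class PhantomSpec:
    """Full description of one synthetic case; output is a pure function
    of this object (including the seed)."""

    shape: tuple = (64, 64, 8)
    seed: int = 0
    geometry: dict = None
    tissues: dict = None
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.geometry is None:
            self.geometry = _default_geometry(self.shape)
        if self.tissues is None:
            self.tissues = _default_tissues()
        self._validate()

    def _validate(self):
        g = self.geometry
        if not g["edema"].inside(g["brain"]):
            raise PhantomGeometryError("edema must lie inside the brain ellipsoid")
        if not g["core"].inside(g["edema"]):
            raise PhantomGeometryError("core must lie inside the edema ellipsoid")
        for name in ("necrosis", "enhancing", "nonenhanced"):
            if not g[name].inside(g["core"]):
                raise PhantomGeometryError(f"{name} must lie inside the core")
        if not g["necrosis"].inside(g["enhancing"]):
            raise PhantomGeometryError("necrosis must lie inside the enhancing outer ellipsoid")
        # disjointness is checked exactly on the voxel grid (the
        # axis-wise test is too conservative for diagonal offsets)
        overlap = g["nonenhanced"].contains_grid(self.shape) & g[
            "enhancing"
        ].contains_grid(self.shape)
        if overlap.any():
            raise PhantomGeometryError("nonenhanced must be disjoint from the enhancing region")


def _compartment_masks(spec: PhantomSpec) -> dict:
    g = spec.geometry
    shape = spec.shape
    brain = g["brain"].contains_grid(shape)
    edema = g["edema"].contains_grid(shape) & brain
    enh_outer = g["enhancing"].contains_grid(shape) & edema
    necrosis = g["necrosis"].contains_grid(shape) & enh_outer
    enhancing = enh_outer & ~necrosis  # rim around the necrotic center
    nonenhanced = g["nonenhanced"].contains_grid(shape) & edema & ~enh_outer
    masks = {
        "necrosis": necrosis,
        "enhancing": enhancing,
        "nonenhanced": nonenhanced,
        "edema": edema & ~necrosis & ~enhancing & ~nonenhanced,
        "brain": brain & ~edema,
        "background": ~brain,
    }
    return masks


def generate_phantom(spec: PhantomSpec):
    """Render the phantom.

    Returns
    -------
    (Volume T2, Volume FLAIR, Volume T1c, LabelMap)
    """
    rng = np.random.default_rng(spec.seed)
    masks = _compartment_masks(spec)
    shape = spec.shape

    labels = np.zeros(shape, dtype=np.uint8)
    labels[masks["edema"]] = 2
    labels[masks["nonenhanced"]] = 3
    labels[masks["enhancing"]] = 4
    labels[masks["necrosis"]] = 1

    volumes = {m: np.zeros(shape, dtype=float) for m in MODALITY_ORDER}
    for name in COMPARTMENTS:
        tissue = spec.tissues[name]
        region = masks[name]
        if not region.any():
            continue
        fields = {}
        for mod in MODALITY_ORDER:
            # white noise is always drawn so amplitude choices never
            # shift the RNG stream of later compartments
            white = rng.standard_normal(shape)
            amp = tissue.amplitude(mod)
            if amp > 0:
                smooth = gaussian_filter(white, sigma=tissue.correlation_scale)
                sd = smooth.std()
                fields[mod] = smooth / sd * amp if sd > 0 else np.zeros(shape)
            else:
                fields[mod] = np.zeros(shape)
        for mod in MODALITY_ORDER:
            volumes[mod][region] = tissue.means[mod] + fields[mod][region]

    out = []
    for mod in MODALITY_ORDER:
        data = np.clip(volumes[mod], 0, None)
        data[masks["background"]] = 0.0
        out.append(Volume(data=data, spacing=spec.spacing, modality=mod))
    label_map = LabelMap(data=labels, spacing=spec.spacing)
    return out[0], out[1], out[2], label_map
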