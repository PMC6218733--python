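"""Volume and label-map I/O plus brain-mask derivation.

Volumes are handled in the index order delivered by the file header;
slice-wise processing elsewhere iterates the third index as the axial
axis.  NIfTI is handled by nibabel; MetaImage (.mha with LOCAL raw
payload) by a small built-in codec since no MetaImage library is a
declared dependency.

Negative intensities are clipped to zero on read: the data convention is
that volumes are stored as signed integers but only positive values
carry signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import (
    InvalidLabelError,
    NonVolumeDataError,
    ShapeMismatchError,
    UnsupportedFormatError,
    VolumeFileMissingError,
)

MODALITIES = ("T1", "T1c", "T2", "FLAIR")
VALID_LABELS = frozenset({0, 1, 2, 3, 4})

_MET_TO_DTYPE = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_LONG": np.int64,
    "MET_ULONG": np.uint64,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


@dataclass
class Volume:
    """One modality's 3D nonnegative intensity grid.

    Attributes
    ----------
    data : ndarray, shape (X, Y, Z)
        Nonnegative intensities in arbitrary scanner units.
    spacing : tuple of float
        Per-axis voxel size in mm.
    modality : str
        One of ``MODALITIES``.
    axis_order : str
        Convention tag; always header index order, third axis axial.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    modality: str = "T2"
    axis_order: str = "header"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NonVolumeDataError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        if self.data.size and self.data.min() < 0:
            raise ValueError("volume intensities must be nonnegative")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class BinaryMask:
    """3D boolean grid with the same shape as its parent volume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise NonVolumeDataError("mask must be 3D")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelMap:
    """Integer 3D grid over {0,1,2,3,4}.

    1 necrosis, 2 edema, 3 nonenhancing tumor, 4 enhancing tumor,
    0 everything else.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NonVolumeDataError("label map must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise InvalidLabelError("label map values must be integers")
            self.data = rounded.astype(np.uint8)
        bad = set(np.unique(self.data)) - VALID_LABELS
        if bad:
            raise InvalidLabelError(f"invalid labels present: {sorted(bad)}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self):
        return self.data.shape


def _read_mha(path: str):
    """Decode an uncompressed MetaImage file with a LOCAL payload."""
    header = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise UnsupportedFormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", "replace").partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
        payload = fh.read()
    if header.get("CompressedData", "False").lower() == "true":
        raise UnsupportedFormatError(f"{path}: compressed MetaImage not supported")
    if header.get("ElementDataFile", "LOCAL") != "LOCAL":
        raise UnsupportedFormatError(f"{path}: only LOCAL MetaImage payloads supported")
    ndims = int(header.get("NDims", "0"))
    if ndims != 3:
        raise NonVolumeDataError(f"{path}: expected 3D data, got NDims={ndims}")
    dims = tuple(int(x) for x in header["DimSize"].split())
    met_type = header.get("ElementType", "MET_SHORT")
    if met_type not in _MET_TO_DTYPE:
        raise UnsupportedFormatError(f"{path}: unknown ElementType {met_type}")
    dtype = np.dtype(_MET_TO_DTYPE[met_type])
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")
    n = int(np.prod(dims))
    arr = np.frombuffer(payload[: n * dtype.itemsize], dtype=dtype)
    if arr.size != n:
        raise UnsupportedFormatError(f"{path}: payload shorter than DimSize implies")
    # MetaImage stores the first listed dimension fastest.
    data = arr.reshape(dims[::-1]).transpose(range(ndims - 1, -1, -1))
    spacing = tuple(
        float(x) for x in header.get("ElementSpacing", "1 1 1").split()
    )
    return np.ascontiguousarray(data), spacing


def _write_mha(path: str, data: np.ndarray, spacing) -> None:
    data = np.ascontiguousarray(data)
    met = _DTYPE_TO_MET.get(data.dtype.newbyteorder("="))
    if met is None:
        raise UnsupportedFormatError(f"cannot write dtype {data.dtype} as MetaImage")
    dims = " ".join(str(d) for d in data.shape)
    sp = " ".join(f"{s:g}" for s in spacing)
    header = (
        "ObjectType = Image\n"
        f"NDims = {data.ndim}\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {dims}\n"
        f"ElementSpacing = {sp}\n"
        f"ElementType = {met}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        # first dimension fastest on disk
        fh.write(data.transpose(range(data.ndim - 1, -1, -1)).tobytes())


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _read_any(path: str):
    if not os.path.exists(path):
        raise VolumeFileMissingError(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data) if data.ndim > 3 and all(
            s == 1 for s in data.shape[3:]
        ) else data
        if data.ndim != 3:
            raise NonVolumeDataError(f"{path}: expected 3D data, got {data.ndim}D")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, spacing
    if path.endswith(".mha"):
        return _read_mha(path)
    raise UnsupportedFormatError(f"{path}: expected .nii, .nii.gz or .mha")


def read_volume(path: str, modality: str = "T2") -> Volume:
    """Read a NIfTI or MetaImage volume, clipping negatives to zero."""
    data, spacing = _read_any(path)
    data = np.clip(data, 0, None)
    return Volume(data=data, spacing=spacing, modality=modality)


def write_volume(vol: Volume, path: str) -> None:
    """Write a Volume as NIfTI or MetaImage, chosen by extension."""
    if _is_nifti(path):
        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), path)
    elif path.endswith(".mha"):
        _write_mha(path, np.asarray(vol.data), vol.spacing)
    else:
        raise UnsupportedFormatError(f"{path}: expected .nii, .nii.gz or .mha")


def read_label_map(path: str) -> LabelMap:
    """Read a label map; values are validated against {0..4}."""
    data, spacing = _read_any(path)
    return LabelMap(data=data, spacing=spacing)


def write_label_map(label_map: LabelMap, path: str) -> None:
    """Write a LabelMap as uint8; round-trips integer-exactly."""
    data = np.asarray(label_map.data, dtype=np.uint8)
    if _is_nifti(path):
        affine = np.diag(list(label_map.spacing) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), path)
    elif path.endswith(".mha"):
        _write_mha(path, data, label_map.spacing)
    else:
        raise UnsupportedFormatError(f"{path}: expected .nii, .nii.gz or .mha")


def brain_mask(volume: Volume) -> BinaryMask:
    """Mask of strictly positive intensities (input is skull-stripped)."""
    return BinaryMask(data=np.asarray(volume.data) > 0)


def check_same_shape(*arrays) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"shapes differ: {sorted(shapes)}")
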