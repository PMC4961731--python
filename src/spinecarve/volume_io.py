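"""Volumes, masks, bounding boxes, and their on-disk formats.

Conventions used throughout the package:

* array axes are ``(x, y, z)`` with ``z`` the axial (cranio-caudal) axis;
* voxel indices are 0-based; bounding boxes are half-open
  (inclusive lower, exclusive upper);
* all physical distances are ``index * spacing`` millimetres;
* CT intensities are signed Hounsfield Units and are never rescaled at
  I/O time — normalization is an explicit pipeline step.

Supported formats: NIfTI-1 (``.nii``, ``.nii.gz``) and MetaImage
(``.mha``, ``.mhd``) through SimpleITK; bounding boxes and algorithm
parameters are JSON or YAML.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
import yaml

from .errors import ConfigError, DimensionalityError

__all__ = [
    "ScalarVolume",
    "BinaryMask",
    "BoundingBox",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_bounding_boxes",
]


@dataclass(eq=False)
class ScalarVolume:
    """A 3D scalar intensity grid (HU) with physical geometry.

    Attributes
    ----------
    data
        3D float array of intensities, axes ``(x, y, z)``.
    spacing
        Per-axis voxel size in mm/voxel; all components > 0.
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} axes"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(eq=False)
class BinaryMask:
    """A boolean grid on the same lattice as a :class:`ScalarVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got {self.data.ndim} axes"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def like(self, data: np.ndarray) -> "BinaryMask":
        """A new mask with this mask's geometry and the given voxel data."""
        return BinaryMask(data, self.spacing, self.origin)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel-index box, inclusive lower / exclusive upper."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", tuple(int(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(int(v) for v in self.upper))
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ConfigError(f"box {self.label!r}: lower/upper must have 3 entries")
        for lo, up in zip(self.lower, self.upper):
            if lo >= up:
                raise ConfigError(
                    f"box {self.label!r}: lower {self.lower} not strictly below "
                    f"upper {self.upper}"
                )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, up) for lo, up in zip(self.lower, self.upper))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(up - lo for lo, up in zip(self.lower, self.upper))

    def voxel_count(self) -> int:
        return int(np.prod(self.shape))

    def check_within(self, volume_shape: tuple[int, int, int]) -> None:
        for ax, (lo, up, n) in enumerate(zip(self.lower, self.upper, volume_shape)):
            if lo < 0 or up > n:
                raise ConfigError(
                    f"box {self.label!r} exceeds volume extent on axis {ax}: "
                    f"[{lo}, {up}) vs size {n}"
                )

    def to_mask(self, volume: ScalarVolume) -> BinaryMask:
        """Binary mask of this box on the volume's lattice."""
        self.check_within(volume.shape)
        data = np.zeros(volume.shape, dtype=bool)
        data[self.slices] = True
        return BinaryMask(data, volume.spacing, volume.origin)


_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _read_image(path: str) -> sitk.Image:
    if not os.path.exists(path):
        raise IOError(f"no such image file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise IOError(f"could not read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {img.GetDimension()}D"
        )
    return img


def read_volume(path: str) -> ScalarVolume:
    """Read a NIfTI or MetaImage scalar volume.

    Spacing and origin are taken from the file header; intensities are
    returned exactly as stored (HU).
    """
    img = _read_image(path)
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z).
    data = sitk.GetArrayFromImage(img).T.astype(np.float64)
    return ScalarVolume(data, img.GetSpacing(), img.GetOrigin())


def read_mask(path: str) -> BinaryMask:
    """Read a binary mask; any non-zero voxel counts as True."""
    img = _read_image(path)
    data = sitk.GetArrayFromImage(img).T != 0
    return BinaryMask(data, img.GetSpacing(), img.GetOrigin())


def _write(data: np.ndarray, spacing, origin, path: str) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write image {path}: {exc}") from exc


def write_volume(volume: ScalarVolume, path: str) -> None:
    _write(volume.data.astype(np.float32), volume.spacing, volume.origin, path)


def write_mask(mask: BinaryMask, path: str) -> None:
    """Write a mask as a {0,1}-valued image with the mask's geometry."""
    _write(mask.data.astype(np.uint8), mask.spacing, mask.origin, path)


def load_bounding_boxes(path: str) -> list[BoundingBox]:
    """Load a JSON/YAML list of ``{label, lower[3], upper[3]}`` boxes."""
    with open(path) as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        entries = json.loads(text)
    else:
        entries = yaml.safe_load(text)
    if entries is None:
        return []
    if not isinstance(entries, list):
        raise ConfigError(f"{path}: expected a list of boxes")
    boxes = []
    for i, entry in enumerate(entries):
        try:
            boxes.append(
                BoundingBox(
                    lower=entry["lower"],
                    upper=entry["upper"],
                    label=str(entry.get("label", i)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: malformed box entry #{i}: {entry!r}") from exc
    return boxes
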