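"""Seeded synthetic CT vertebra phantoms with exact ground truth.

The phantom emulates the input the segmentation tool expects: a bright
vertebra-shaped object at bone Hounsfield values on a soft-tissue
background, additive Gaussian noise matching the HMC emission
assumption, optional anisotropic spacing, and a menu of pathological
alterations (hypo-/hyper-dense lesions, cementoplasty, air pockets,
vertebral-body compression) mirroring the non-standard cases a
clinical tool must survive.

The geometry is deliberately schematic — an ellipsoidal vertebral
body, a torus arch around the spinal canal and a box-shaped spinous
process — because the method under test claims *no* shape prior; what
matters is the intensity statistics and a compact, non-convex target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .volume_io import BinaryMask, BoundingBox, ScalarVolume

__all__ = ["PathologySpec", "PhantomSpec", "generate_phantom", "apply_pathology",
           "default_box"]


@dataclass(frozen=True)
class PathologySpec:
    """One pathological alteration.

    kind: "hypodense_lesion" | "hyperdense_lesion" | "cementoplasty" |
    "air_pockets" | "compressed_body". ``centers_mm``/``radius_mm``
    locate sphere-shaped alterations; ``intensity`` is the HU delta
    (lesions) or absolute value (cementoplasty ~1500, air -1000);
    ``factor`` is the axial scaling of the compressed body.
    """

    kind: str
    centers_mm: tuple[tuple[float, float, float], ...] = ()
    radius_mm: float = 7.0
    intensity: float = 0.0
    factor: float = 0.6

    _KINDS = ("hypodense_lesion", "hyperdense_lesion", "cementoplasty",
              "air_pockets", "compressed_body")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigError(f"unknown pathology kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic vertebra.

    Defaults give a 96 x 96 x 64 grid at 1 mm isotropic spacing with a
    bone mean of 400 HU over a 40 HU soft-tissue background and 30 HU
    Gaussian noise — generated in seconds yet tall enough for several
    carving iterations at the default supervoxel schedule.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_center_mm: tuple[float, float, float] = (48.0, 38.0, 32.0)
    body_radii_mm: tuple[float, float, float] = (24.0, 18.0, 14.0)
    arch: bool = True
    arch_ring_radius_mm: float = 9.0
    arch_tube_radius_mm: float = 3.5
    process_length_mm: float = 14.0
    process_halfwidth_mm: tuple[float, float] = (3.5, 4.0)
    bone_hu: float = 400.0
    tissue_hu: float = 40.0
    noise_sd: float = 30.0
    pathology: PathologySpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.body_radii_mm):
            raise ConfigError("body radii must be positive")
        if self.bone_hu <= self.tissue_hu:
            raise ConfigError("bone mean must exceed tissue mean")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")


def _grids_mm(spec: PhantomSpec):
    sp = np.asarray(spec.spacing, float)
    ax = [np.arange(n) * s for n, s in zip(spec.shape, sp)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid(spec: PhantomSpec, center, radii) -> np.ndarray:
    X, Y, Z = _grids_mm(spec)
    cx, cy, cz = center
    rx, ry, rz = radii
    extents_ok = all(
        c - r >= 0 and c + r <= (n - 1) * s
        for c, r, n, s in zip(center, radii, spec.shape, spec.spacing)
    )
    if not extents_ok:
        raise ConfigError(f"primitive at {center} with radii {radii} exceeds grid")
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0


def _sphere(spec: PhantomSpec, center, radius) -> np.ndarray:
    return _ellipsoid(spec, center, (radius, radius, radius))


def _arch(spec: PhantomSpec) -> np.ndarray:
    """Torus around the spinal canal plus a posterior spinous process."""
    X, Y, Z = _grids_mm(spec)
    cx, cy, cz = spec.body_center_mm
    canal_cy = cy + spec.body_radii_mm[1] + spec.arch_ring_radius_mm * 0.6
    R, r = spec.arch_ring_radius_mm, spec.arch_tube_radius_mm
    ring = (np.sqrt((X - cx) ** 2 + (Y - canal_cy) ** 2) - R) ** 2 \
        + (Z - cz) ** 2 <= r**2
    py0 = canal_cy + R
    hw_x, hw_z = spec.process_halfwidth_mm
    proc = (
        (np.abs(X - cx) <= hw_x)
        & (Y >= py0 - 1.0)
        & (Y <= py0 + spec.process_length_mm)
        & (np.abs(Z - cz) <= hw_z)
    )
    far = py0 + spec.process_length_mm
    if far > (spec.shape[1] - 1) * spec.spacing[1]:
        raise ConfigError("arch/process extends beyond the grid")
    return ring | proc


def generate_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, BinaryMask]:
    """Build the phantom volume and its exact ground-truth mask.

    The noise-free volume takes exactly two values (tissue and bone
    means) outside pathology regions; seeded Gaussian noise is added
    last, so the same spec and seed always reproduce the identical
    volume.
    """
    body_radii = spec.body_radii_mm
    pathology = spec.pathology
    if pathology is not None and pathology.kind == "compressed_body":
        body_radii = (body_radii[0], body_radii[1],
                      body_radii[2] * pathology.factor)
    truth = _ellipsoid(spec, spec.body_center_mm, body_radii)
    if spec.arch:
        truth |= _arch(spec)

    base = np.full(spec.shape, spec.tissue_hu, dtype=float)
    base[truth] = spec.bone_hu
    if pathology is not None and pathology.kind != "compressed_body":
        base, truth = _apply_intensity_pathology(base, truth, spec, pathology)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = ScalarVolume(base, spec.spacing)
    mask = BinaryMask(truth, spec.spacing)
    return volume, mask


def _default_centers(spec: PhantomSpec, kind: str):
    cx, cy, cz = spec.body_center_mm
    if kind == "air_pockets":
        return ((12.0, 12.0, 16.0), (84.0, 14.0, 40.0), (14.0, 80.0, 46.0))
    # lesion/cement default: inside the vertebral body
    return ((cx + 4.0, cy, cz),)


def _apply_intensity_pathology(
    base: np.ndarray,
    truth: np.ndarray,
    spec: PhantomSpec,
    pathology: PathologySpec,
) -> tuple[np.ndarray, np.ndarray]:
    centers = pathology.centers_mm or _default_centers(spec, pathology.kind)
    out = base.copy()
    for c in centers:
        region = _sphere(spec, c, pathology.radius_mm)
        if pathology.kind == "hypodense_lesion":
            out[region & truth] += (pathology.intensity or -300.0)
        elif pathology.kind == "hyperdense_lesion":
            out[region & truth] += (pathology.intensity or 300.0)
        elif pathology.kind == "cementoplasty":
            out[region & truth] = pathology.intensity or 1500.0
        elif pathology.kind == "air_pockets":
            if (region & truth).any():
                raise ConfigError(
                    f"air pocket at {c} overlaps the vertebra ground truth"
                )
            out[region] = pathology.intensity or -1000.0
    return out, truth


def apply_pathology(
    volume: ScalarVolume,
    truth: BinaryMask,
    pathology: PathologySpec,
    spec: PhantomSpec,
    seed: int | None = None,
) -> tuple[ScalarVolume, BinaryMask]:
    """Apply one pathological alteration to an existing phantom.

    Intensity pathologies (lesions, cementoplasty, air pockets) modify
    the given volume in place of the stated regions and leave the truth
    unchanged; ``compressed_body`` rebuilds the phantom with the body
    axially scaled (the truth changes), reusing ``seed`` (default: the
    spec's own seed) for the noise.
    """
    if pathology.kind == "compressed_body":
        new_spec = replace(spec, pathology=pathology,
                           seed=spec.seed if seed is None else seed)
        return generate_phantom(new_spec)
    data, t = _apply_intensity_pathology(
        np.asarray(volume.data, float), truth.data, spec, pathology
    )
    return ScalarVolume(data, volume.spacing, volume.origin), truth.like(t)


def default_box(spec: PhantomSpec, margin: int = 2) -> BoundingBox:
    """Bounding box enclosing the whole phantom grid minus a margin."""
    return BoundingBox(
        lower=(margin, margin, margin),
        upper=tuple(n - margin for n in spec.shape),
        label="phantom",
    )
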