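"""Volume data model, axis conventions, standard-format I/O and plane resampling.

Coordinate convention used throughout the package
-------------------------------------------------
A 3D ultrasound volume is stored in axis order ``(lateral, axial, elevational)``:

* **lateral** — in-plane transducer width (array axis 0),
* **axial** — beam/depth direction (array axis 1); increasing index is deeper,
* **elevational** — out-of-plane sweep direction (array axis 2).

"Coronal" planes are lateral–elevational planes, i.e. perpendicular to the
axial (beam) direction.  Voxel indexing is 0-based and a voxel's physical
centre is ``origin_mm + (index + 0.5) * voxel_size_mm`` (half-voxel centre
convention), so that point/plane metrics are computed in millimetres.  The
frame is right-handed in the storage order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

AXES = ("lateral", "axial", "elevational")

#: Unit vectors of the three anatomical axes, in storage order.
LATERAL_UNIT = np.array([1.0, 0.0, 0.0])
AXIAL_UNIT = np.array([0.0, 1.0, 0.0])
ELEVATIONAL_UNIT = np.array([0.0, 0.0, 1.0])

_FORMAT_EXTENSIONS = {
    "nrrd": (".nrrd", ".nhdr"),
    "nifti": (".nii", ".nii.gz"),
    "metaimage": (".mha", ".mhd"),
}


class VolumeFormatError(RuntimeError):
    """Raised when a volume file cannot be read or written under its format."""


def _check_grid(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{name} must be a 3D array, got shape {arr.shape}")
    if any(s < 1 for s in arr.shape):
        raise ValueError(f"{name} must have all dimensions >= 1, got {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class UltrasoundVolume:
    """A 3D scalar intensity grid with isotropic voxel size.

    Parameters
    ----------
    intensities
        3D array in ``(lateral, axial, elevational)`` order; arbitrary
        non-negative units.
    voxel_size_mm
        Isotropic voxel edge length in mm (> 0).
    origin_mm
        Physical position of the corner of voxel (0, 0, 0); voxel centres sit
        half a voxel further in.  Defaults to the zero vector.
    meta
        Free-form provenance notes (e.g. spacing warnings on read).
    """

    intensities: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = _check_grid(self.intensities, "intensities")
        self.voxel_size_mm = float(self.voxel_size_mm)
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.origin_mm.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the volume, in mm."""
        return np.asarray(self.shape) * self.voxel_size_mm

    def voxel_center_mm(self, index: Sequence[float]) -> np.ndarray:
        """Physical centre of a voxel (accepts fractional indices)."""
        return self.origin_mm + (np.asarray(index, dtype=float) + 0.5) * self.voxel_size_mm

    def mm_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical point."""
        return (np.asarray(point_mm, dtype=float) - self.origin_mm) / self.voxel_size_mm - 0.5

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(min corner, max corner) of the physical bounding box."""
        return self.origin_mm.copy(), self.origin_mm + self.extent_mm


@dataclass
class LabelVolume:
    """Per-voxel binary decision aligned to a source volume."""

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = _check_grid(self.labels, "labels")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("labels must contain only 0/1 values")
        self.labels = arr.astype(np.uint8)
        self.voxel_size_mm = float(self.voxel_size_mm)
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    voxel_center_mm = UltrasoundVolume.voxel_center_mm
    mm_to_index = UltrasoundVolume.mm_to_index
    bounds_mm = UltrasoundVolume.bounds_mm

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size_mm


@dataclass
class ProbabilityVolume:
    """Per-voxel needle probability in [0, 1], aligned to a source volume."""

    probabilities: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = _check_grid(self.probabilities, "probabilities")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.probabilities = arr.astype(np.float32)
        self.voxel_size_mm = float(self.voxel_size_mm)
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probabilities.shape  # type: ignore[return-value]

    voxel_center_mm = UltrasoundVolume.voxel_center_mm
    mm_to_index = UltrasoundVolume.mm_to_index
    bounds_mm = UltrasoundVolume.bounds_mm

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size_mm


def same_geometry(a, b, atol: float = 1e-9) -> bool:
    """True if two volume-like objects share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and abs(a.voxel_size_mm - b.voxel_size_mm) <= atol
        and np.allclose(a.origin_mm, b.origin_mm, atol=atol)
    )


@dataclass
class PlaneSpec:
    """An oriented plane with an orthonormal in-plane frame.

    ``normal`` is a unit 3-vector; ``in_plane_axes`` is a (2, 3) array of two
    orthonormal vectors spanning the plane, both orthogonal to ``normal``.
    """

    point_mm: np.ndarray
    normal: np.ndarray
    in_plane_axes: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.point_mm = np.asarray(self.point_mm, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=float).reshape(2, 3)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-8:
            raise ValueError("plane normal must have unit norm")
        gram = self.in_plane_axes @ self.in_plane_axes.T
        if not np.allclose(gram, np.eye(2), atol=1e-8):
            raise ValueError("in_plane_axes must be orthonormal")
        if np.max(np.abs(self.in_plane_axes @ self.normal)) > 1e-8:
            raise ValueError("in_plane_axes must be orthogonal to the normal")

    def signed_distance(self, point_mm: np.ndarray) -> float:
        return float(np.dot(np.asarray(point_mm, dtype=float) - self.point_mm, self.normal))

    def to_world(self, u: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Map in-plane coordinates (u, w) in mm to 3D points."""
        u = np.asarray(u, dtype=float)
        w = np.asarray(w, dtype=float)
        return (
            self.point_mm
            + u[..., None] * self.in_plane_axes[0]
            + w[..., None] * self.in_plane_axes[1]
        )


# ---------------------------------------------------------------------------
# File I/O (NRRD / NIfTI-1 / MetaImage via SimpleITK)
# ---------------------------------------------------------------------------
#
# On disk the image x/y/z axes are lateral/axial/elevational respectively.
# SimpleITK returns arrays in (z, y, x) order, so arrays are transposed with
# (2, 1, 0) in both directions.


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    for fmt, exts in _FORMAT_EXTENSIONS.items():
        if any(name.endswith(e) for e in exts):
            return fmt
    raise VolumeFormatError(f"cannot infer volume format from filename: {path}")


def read_volume(path, format: str | None = None, kind: str = "intensity"):
    """Read a volume file into an :class:`UltrasoundVolume` (default),
    :class:`LabelVolume` (``kind='label'``) or :class:`ProbabilityVolume`
    (``kind='probability'``).

    Anisotropic spacing triggers a warning; the mean spacing is used and the
    decision is recorded in ``meta['spacing_warning']`` for intensity volumes.
    """
    import SimpleITK as sitk

    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMAT_EXTENSIONS:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - exercised via bad file test
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc

    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    meta: dict = {}
    if not np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-9):
        warnings.warn(
            f"anisotropic spacing {tuple(spacing)} in {path.name}; using mean",
            stacklevel=2,
        )
        meta["spacing_warning"] = {"file_spacing": spacing.tolist(), "used": float(spacing.mean())}
    voxel = float(spacing.mean())

    if kind == "intensity":
        return UltrasoundVolume(arr, voxel, origin, meta)
    if kind == "label":
        return LabelVolume(arr, voxel, origin)
    if kind == "probability":
        return ProbabilityVolume(np.clip(arr, 0.0, 1.0), voxel, origin)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(v, path, format: str | None = None) -> None:
    """Write an intensity/label/probability volume to NRRD, NIfTI or MetaImage.

    Integer grids round-trip bit-exactly; float grids are stored as float32.
    """
    import SimpleITK as sitk

    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMAT_EXTENSIONS:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    if format is not None and not any(path.name.lower().endswith(e) for e in _FORMAT_EXTENSIONS[fmt]):
        raise VolumeFormatError(f"path {path} does not match format {fmt!r}")

    if isinstance(v, LabelVolume):
        arr = v.labels.astype(np.uint8)
    elif isinstance(v, ProbabilityVolume):
        arr = v.probabilities.astype(np.float32)
    elif isinstance(v, UltrasoundVolume):
        arr = v.intensities
        if np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")

    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing((v.voxel_size_mm,) * 3)
    img.SetOrigin(tuple(np.asarray(v.origin_mm, dtype=float)))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:  # pragma: no cover
        raise VolumeFormatError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Arbitrary-plane extraction
# ---------------------------------------------------------------------------


def extract_plane(
    v: UltrasoundVolume,
    plane: PlaneSpec,
    extent_mm: tuple[float, float],
    sample_step_mm: float,
    order: int = 1,
) -> np.ndarray:
    """Resample a volume on a plane's orthonormal grid.

    The grid is centred on ``plane.point_mm`` and spans ``extent_mm`` along the
    two in-plane axes, sampled every ``sample_step_mm``.  Interpolation is
    trilinear (``order=1``; use 0 for nearest-neighbour on label volumes) with
    zero fill outside the volume.

    Returns a 2D array of shape ``(n_u, n_w)``.
    """
    if sample_step_mm <= 0:
        raise ValueError("sample_step_mm must be > 0")
    n_u = int(round(extent_mm[0] / sample_step_mm)) + 1
    n_w = int(round(extent_mm[1] / sample_step_mm)) + 1
    u = (np.arange(n_u) - (n_u - 1) / 2.0) * sample_step_mm
    w = (np.arange(n_w) - (n_w - 1) / 2.0) * sample_step_mm
    uu, ww = np.meshgrid(u, w, indexing="ij")
    pts = plane.to_world(uu, ww)  # (n_u, n_w, 3)
    idx = (pts - v.origin_mm) / v.voxel_size_mm - 0.5
    data = v.intensities if isinstance(v, UltrasoundVolume) else np.asarray(v.labels, dtype=float)
    return map_coordinates(
        np.asarray(data, dtype=float),
        [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order,
        mode="constant",
        cval=0.0,
    )
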