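"""Volumetric data model, NIfTI-1 I/O, affine transforms and resampling.

Conventions
-----------
* World coordinates are RAS+ millimetres as encoded in the NIfTI affine.
* Voxel indices are 0-based; index ``(i, j, k)`` maps to world coordinates
  through ``affine @ (i, j, k, 1)`` with no half-voxel shift.
* Resampling is pull-back: iterate over target voxels, map their world
  coordinates into the source volume, interpolate there.  Out-of-field
  voxels receive 0 (background intensity and background probability are
  both 0 in this toolkit).
* Deformations are restricted to affine transforms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Degenerate geometry (singular affine, mismatched grids)."""


class FormatError(ValueError):
    """Malformed or unsupported image file."""


@dataclass
class Volume3D:
    """A 3-D scalar lattice with a voxel-to-world affine.

    Carrier for intensity images, probability maps, binary masks and bias
    fields alike; ``space_tag`` records whether the grid lives in subject
    native space or in the standard (template) space.
    """

    voxels: np.ndarray
    affine: np.ndarray
    space_tag: str = "native"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise FormatError(
                f"expected a 3-D lattice, got shape {self.voxels.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-300:
            raise GeometryError("affine has a singular 3x3 linear part")
        if self.space_tag not in ("native", "standard"):
            raise ValueError(f"unknown space_tag {self.space_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def like(self, voxels: np.ndarray) -> "Volume3D":
        """New volume with the same geometry and different voxel data."""
        return replace(self, voxels=voxels)

    def copy_geometry(self) -> "Volume3D":
        """Empty (zero) volume on the same grid — a pure geometry carrier."""
        return replace(self, voxels=np.zeros(self.shape))


@dataclass
class AffineTransform:
    """A 4x4 homogeneous world-mm to world-mm map."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise GeometryError(f"transform must be 4x4, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-300:
            raise GeometryError("transform is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of world points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self∘other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)


def invert_affine(t: AffineTransform) -> AffineTransform:
    """Invert a world-to-world affine transform.

    The inverse composed with the forward map equals the identity to within
    1e-10 per matrix entry for well-conditioned inputs.
    """
    try:
        inv = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise GeometryError("transform is singular") from exc
    return AffineTransform(inv)


def voxel_volume(vol: Volume3D) -> float:
    """Volume of a single voxel in mm³: |det| of the affine's linear part."""
    det = np.linalg.det(vol.affine[:3, :3])
    if abs(det) < 1e-300:
        raise GeometryError("affine has a singular 3x3 linear part")
    return float(abs(det))


def read_nifti(path: str | os.PathLike) -> Volume3D:
    """Read a 3-D NIfTI-1 volume (optionally gzipped).

    The affine is taken from the sform when present, else the qform; a file
    carrying neither is rejected.  No reorientation is applied.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    hdr = img.header
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"field 'dim': expected 3-D data, got {data.ndim}-D in {path}"
        )
    if hdr["sform_code"] > 0:
        affine = img.get_sform()
    elif hdr["qform_code"] > 0:
        affine = img.get_qform()
    else:
        raise FormatError(
            f"field 'sform_code'/'qform_code': no valid affine in {path}"
        )
    return Volume3D(voxels=np.asarray(data), affine=affine)


def write_nifti(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as little-endian NIfTI-1; round-trips with read_nifti."""
    data = vol.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.set_sform(vol.affine, code=1)
    img.set_qform(vol.affine, code=1)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


_INTERP_ORDER = {"nearest": 0, "linear": 1}


def resample(
    src: Volume3D,
    t: AffineTransform,
    target_grid: Volume3D,
    mode: str = "linear",
) -> Volume3D:
    """Pull a source volume onto a target grid through a world-space affine.

    ``t`` maps *target* world coordinates into *source* world coordinates
    (pull-back convention).  Nearest mode preserves the source value set,
    so binary masks stay binary; out-of-field voxels are 0.
    """
    if mode not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    # target voxel index -> source voxel index, as one homogeneous matrix
    full = (
        np.linalg.inv(src.affine) @ t.matrix @ target_grid.affine
    )
    out = ndimage.affine_transform(
        np.asarray(src.voxels, dtype=float),
        matrix=full[:3, :3],
        offset=full[:3, 3],
        output_shape=target_grid.shape,
        order=_INTERP_ORDER[mode],
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return Volume3D(voxels=out, affine=target_grid.affine.copy(),
                    space_tag=target_grid.space_tag)


def gaussian_blur_mm(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Isotropic Gaussian blur with kernel width given as FWHM in mm.

    Assumes the voxel grid is (near-)isotropic in world space, which holds
    for every grid this toolkit constructs.
    """
    if fwhm_mm <= 0:
        return vol.like(np.asarray(vol.voxels, dtype=float).copy())
    voxel_mm = float(np.cbrt(voxel_volume(vol)))
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    return vol.like(ndimage.gaussian_filter(
        np.asarray(vol.voxels, dtype=float), sigma=sigma_vox))


def check_same_grid(*vols: Volume3D, what: str = "volumes") -> None:
    """Raise GeometryError unless all volumes share shape and affine."""
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape or not np.allclose(v.affine, ref.affine,
                                                   atol=1e-6):
            raise GeometryError(f"{what} do not share a grid")


def world_coordinates(vol: Volume3D) -> np.ndarray:
    """World (mm) coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
    idx = np.indices(vol.shape).astype(float)
    lin = vol.affine[:3, :3]
    return np.einsum("ab,b...->...a", lin, idx) + vol.affine[:3, 3]
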