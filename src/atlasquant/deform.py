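"""Dense deformation fields, warping and Jacobian volumetry.

A :class:`DeformationField` lives on the *reference* grid and stores, for
every reference voxel, the corresponding physical coordinate (mm) in
subject space (a pull-back / reference-to-subject mapping).  This choice
makes VOI readout in reference space a single-interpolation operation and
makes the Jacobian determinant of the mapping the local subject/reference
volume ratio, so that ``sum(|J|) * voxel_volume`` over a reference VOI is
the subject-space tissue volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .core import DynamicImage4D, ImageGrid, LabelMap, ScalarImage3D

__all__ = [
    "DeformationField",
    "identity_field",
    "affine_field",
    "jacobian_determinant",
    "warp_scalar",
    "warp_labels",
    "warp_dynamic",
    "save_field",
    "load_field",
]


@dataclass
class DeformationField:
    """Reference-grid voxel -> subject physical coordinate (mm)."""

    grid: ImageGrid
    mapping: np.ndarray  # (*grid.shape, 3)

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=np.float64)
        if self.mapping.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"mapping shape {self.mapping.shape} does not match grid {self.grid.shape} + (3,)"
            )

    def displacement(self) -> np.ndarray:
        """Displacement from the identity mapping, in mm."""
        return self.mapping - self.grid.identity_mapping()


def identity_field(grid: ImageGrid) -> DeformationField:
    return DeformationField(grid, grid.identity_mapping())


def affine_field(
    grid: ImageGrid,
    matrix: np.ndarray,
    offset: np.ndarray | None = None,
    center: np.ndarray | None = None,
) -> DeformationField:
    """Field ``x -> center + M (x - center) + offset`` on physical coords."""
    matrix = np.asarray(matrix, dtype=float).reshape(3, 3)
    offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    center = (
        np.asarray(grid.physical_center()) if center is None else np.asarray(center, dtype=float)
    )
    ident = grid.identity_mapping()
    rel = ident - center
    mapped = center + np.einsum("ij,...j->...i", matrix, rel) + offset
    return DeformationField(grid, mapped)


def jacobian_determinant(field: DeformationField) -> ScalarImage3D:
    """Determinant of the spatial gradient of the mapping.

    Central differences in the interior, one-sided at the borders.  The
    result is the dimensionless local volume ratio subject/reference.
    """
    sp = field.grid.spacing
    # J[..., i, j] = d mapping_i / d x_j
    J = np.empty((*field.grid.shape, 3, 3))
    for i in range(3):
        grads = np.gradient(field.mapping[..., i], sp[0], sp[1], sp[2], edge_order=1)
        for j in range(3):
            J[..., i, j] = grads[j]
    a = J
    det = (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )
    return ScalarImage3D(field.grid, det)


def _sample_coords(field: DeformationField, image_grid: ImageGrid) -> np.ndarray:
    idx = image_grid.physical_to_index(field.mapping)
    return np.moveaxis(idx, -1, 0)


def _support_mask(coords: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    ok = np.ones(coords.shape[1:], dtype=bool)
    for a in range(3):
        ok &= (coords[a] >= 0) & (coords[a] <= shape[a] - 1)
    return ok


def warp_scalar(
    image: ScalarImage3D,
    field: DeformationField,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> tuple[ScalarImage3D, np.ndarray]:
    """Pull a subject-space image onto the reference grid.

    ``output(v) = image(T(v))`` with linear or nearest interpolation.
    Returns the warped image and a boolean support mask; out-of-support
    voxels carry ``fill``.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    order = 1 if interpolation == "linear" else 0
    coords = _sample_coords(field, image.grid)
    out = map_coordinates(image.values, coords, order=order, mode="constant", cval=fill)
    support = _support_mask(coords, image.grid.shape)
    out[~support] = fill
    return ScalarImage3D(field.grid, out), support


def warp_labels(labelmap: LabelMap, field: DeformationField) -> LabelMap:
    """Nearest-neighbour pull-back of a subject label image (0 outside)."""
    coords = _sample_coords(field, labelmap.grid)
    out = map_coordinates(labelmap.labels, coords, order=0, mode="constant", cval=0)
    out[~_support_mask(coords, labelmap.grid.shape)] = 0
    return LabelMap(field.grid, out.astype(np.int32))


def warp_dynamic(
    pet: DynamicImage4D, field: DeformationField, interpolation: str = "linear"
) -> tuple[DynamicImage4D, np.ndarray]:
    """Frame-wise pull-back of a dynamic series."""
    frames = []
    support = None
    for i in range(pet.n_frames):
        img, support = warp_scalar(pet.frame(i), field, interpolation)
        frames.append(img.values)
    warped = DynamicImage4D(
        field.grid, pet.frame_mids, pet.frame_durations, np.stack(frames, axis=-1)
    )
    return warped, support


def save_field(field: DeformationField, path: str | Path) -> Path:
    """Store a field as a 4-D NIfTI (3 components on the reference grid)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(field.mapping, field.grid.affine), str(path))
    return path


def load_field(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError("deformation field files must be 4-D with 3 components")
    rot = img.affine[:3, :3]
    if np.max(np.abs(rot - np.diag(np.diag(rot)))) > 1e-6:
        raise ValueError("only axis-aligned field grids are supported")
    grid = ImageGrid(tuple(data.shape[:3]), tuple(np.abs(np.diag(rot))), tuple(img.affine[:3, 3]))
    return DeformationField(grid, data)
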