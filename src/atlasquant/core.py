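"""Image containers and physical-grid geometry.

All images in the package live on axis-aligned 3-D voxel grids with
physical spacing in millimetres.  Voxel indices are 0-based and the
physical coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``
(no rotation; oblique acquisitions are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarImage3D",
    "DynamicImage4D",
    "LabelMap",
    "TissueVOI",
    "TISSUE_CLASSES",
]

TISSUE_CLASSES = ("lean", "adipose", "other")


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of an axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis (three positive integers).
    spacing
        Voxel size along each axis in mm (three positive reals).
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("ImageGrid is strictly 3-D")
        if any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->physical affine (diagonal; axis-aligned)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices ``(..., 3)`` to mm."""
        index = np.asarray(index, dtype=float)
        return index * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_index(self, physical: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates ``(..., 3)`` to fractional indices."""
        physical = np.asarray(physical, dtype=float)
        return (physical - np.asarray(self.origin)) / np.asarray(self.spacing)

    def identity_mapping(self) -> np.ndarray:
        """Physical coordinate of every voxel, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def normalized_coordinates(self) -> np.ndarray:
        """Voxel-centre coordinates scaled to [0, 1) per axis, ``(*shape, 3)``."""
        axes = [(np.arange(self.shape[a]) + 0.5) / self.shape[a] for a in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def physical_center(self) -> np.ndarray:
        """Physical coordinate of the grid centre (mm)."""
        return self.index_to_physical((np.asarray(self.shape, dtype=float) - 1) / 2)


def _check_values(grid: ImageGrid, values: np.ndarray, ndim: int = 3) -> None:
    if values.shape[:3] != grid.shape:
        raise ValueError(
            f"value array shape {values.shape[:3]} does not match grid {grid.shape}"
        )
    if values.ndim != ndim:
        raise ValueError(f"expected {ndim}-D value array, got {values.ndim}-D")


@dataclass
class ScalarImage3D:
    """A real-valued volume (water/fat MR channel, fat fraction, Ki, ...)."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_values(self.grid, self.values, 3)

    def with_values(self, values: np.ndarray) -> "ScalarImage3D":
        return ScalarImage3D(self.grid, values)


@dataclass
class LabelMap:
    """Integer-labelled segmentation; 0 is background."""

    grid: ImageGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("label map requires integer values")
            labels = np.round(labels).astype(np.int32)
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32)
        _check_values(self.grid, self.labels, 3)

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def present_labels(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class DynamicImage4D:
    """A dynamic PET series: one activity volume per timing frame.

    ``values`` has shape ``(*grid.shape, n_frames)`` in kBq/ml;
    ``frame_mids``/``frame_durations`` are in minutes.
    """

    grid: ImageGrid
    frame_mids: np.ndarray
    frame_durations: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frame_mids = np.asarray(self.frame_mids, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.frame_mids.ndim != 1 or self.frame_durations.shape != self.frame_mids.shape:
            raise ValueError("frame mids and durations must be 1-D and equal length")
        if np.any(np.diff(self.frame_mids) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")
        if np.any(self.frame_durations <= 0):
            raise ValueError("frame durations must be positive")
        if self.values.ndim != 4:
            raise ValueError("dynamic image requires a 4-D value array")
        _check_values(self.grid, self.values[..., 0], 3)
        if self.values.shape[3] != self.frame_mids.size:
            raise ValueError(
                f"{self.values.shape[3]} value frames but "
                f"{self.frame_mids.size} timing entries"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frame_mids.size)

    @property
    def frame_starts(self) -> np.ndarray:
        return self.frame_mids - self.frame_durations / 2

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_mids + self.frame_durations / 2

    def frame(self, i: int) -> ScalarImage3D:
        return ScalarImage3D(self.grid, self.values[..., i])


@dataclass(frozen=True)
class TissueVOI:
    """A tissue volume-of-interest declaration.

    ``tissue_class`` drives fat-fraction filtering of propagated
    segmentations: lean VOIs keep voxels with FF < 0.5, adipose VOIs keep
    FF >= 0.5, class "other" is left unfiltered.
    """

    label_id: int
    name: str
    tissue_class: str

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("VOI label_id must be a positive integer")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"tissue_class must be one of {TISSUE_CLASSES}, got {self.tissue_class!r}"
            )


def check_voi_table(vois: Iterable[TissueVOI]) -> list[TissueVOI]:
    """Validate uniqueness of label ids in a VOI table."""
    vois = list(vois)
    ids = [v.label_id for v in vois]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate label_id in VOI table")
    return vois
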