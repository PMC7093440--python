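"""Fat-fraction computation from water/fat channel pairs and VOI readouts.

The proton-density fat fraction is ``FF = fat / (water + fat)`` per voxel,
stored as a fraction in [0, 1]; conversion to percent happens only at
report-formatting time so that the 50% lean/adipose filter threshold stays
unambiguous.  Voxels with negligible total signal (air, lung) are set to 0
and flagged invalid instead of producing 0/0 artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, ScalarImage3D

__all__ = ["FatFractionImage", "compute_fat_fraction", "voi_readout"]

#: Default signal floor: this fraction of the 99th-percentile total signal.
DEFAULT_FLOOR_FRACTION = 0.01


@dataclass
class FatFractionImage:
    """Fat-fraction volume with a validity mask.

    ``valid`` is False where the combined water+fat signal fell below the
    signal floor (air/background); those voxels carry FF = 0.
    """

    grid: ImageGrid
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise ValueError("fat-fraction arrays must match the grid shape")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("fat fraction values must lie in [0, 1]")

    def as_scalar(self) -> ScalarImage3D:
        return ScalarImage3D(self.grid, self.values)


def compute_fat_fraction(
    water: ScalarImage3D,
    fat: ScalarImage3D,
    signal_floor: float | None = None,
) -> FatFractionImage:
    """Voxel-wise ``FF = fat / (water + fat)``.

    Parameters
    ----------
    water, fat
        Non-negative channel images on one shared grid.
    signal_floor
        Absolute total-signal threshold below which a voxel is flagged
        invalid and assigned FF = 0.  Defaults to 1% of the volume's
        99th-percentile total signal.
    """
    if water.grid != fat.grid:
        raise ValueError("water and fat images must share one grid")
    w = water.values
    f = fat.values
    if w.min() < 0 or f.min() < 0:
        raise ValueError("water/fat channel values must be non-negative")
    total = w + f
    if signal_floor is None:
        scale = float(np.percentile(total, 99))
        signal_floor = DEFAULT_FLOOR_FRACTION * scale
    valid = total > signal_floor
    ff = np.zeros_like(total)
    np.divide(f, total, out=ff, where=valid)
    ff = np.clip(ff, 0.0, 1.0)
    ff[~valid] = 0.0
    return FatFractionImage(water.grid, ff, valid)


def voi_readout(
    image: ScalarImage3D | FatFractionImage,
    mask: np.ndarray,
    statistic: str = "mean",
) -> float:
    """Mean or median of image values inside a voxel mask.

    Raises if the mask is empty (a VOI that vanished after filtering must
    surface as an error, not a NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.grid.shape:
        raise ValueError("mask must be on the image grid")
    if not mask.any():
        raise ValueError("empty VOI mask (did fat-fraction filtering remove all voxels?)")
    vals = image.values[mask]
    if statistic == "mean":
        return float(np.mean(vals))
    if statistic == "median":
        return float(np.median(vals))
    raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
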