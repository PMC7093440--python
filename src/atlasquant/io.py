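"""NIfTI and CSV sidecar input/output.

Volumes are stored as NIfTI-1 (``.nii`` / ``.nii.gz``) with a diagonal
affine (axis-aligned grids only).  Dynamic series carry their frame timing
in a plain-text CSV sidecar with fixed columns ``mid_time_min,duration_min``
because NIfTI has no standard PET timing extension; by default the sidecar
sits next to the image as ``<stem>_timing.csv``.  VOI tables are CSV with
columns ``label_id,name,tissue_class``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicImage4D, ImageGrid, LabelMap, ScalarImage3D, TissueVOI, check_voi_table

__all__ = [
    "read_image",
    "write_image",
    "read_labelmap",
    "read_voi_table",
    "write_voi_table",
    "default_timing_path",
]


def _stem(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path.with_suffix("")


def default_timing_path(path: str | Path) -> Path:
    """Sidecar location for a 4-D image: ``<stem>_timing.csv``."""
    path = Path(path)
    return _stem(path).with_name(_stem(path).name + "_timing.csv")


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGrid:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6:
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError("non-positive voxel spacing in NIfTI affine")
    return ImageGrid(tuple(shape[:3]), tuple(spacing), tuple(affine[:3, 3]))


def read_image(
    path: str | Path, timing_path: str | Path | None = None
) -> ScalarImage3D | DynamicImage4D:
    """Read a 3-D or 4-D NIfTI volume.

    4-D volumes require a frame-timing sidecar (CSV with columns
    ``mid_time_min,duration_min``), either passed explicitly or found at
    :func:`default_timing_path`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad content
        raise ValueError(f"{path} is not a readable NIfTI volume: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    grid = _grid_from_affine(img.affine, data.shape)
    if data.ndim == 3:
        return ScalarImage3D(grid, data)
    if data.ndim != 4:
        raise ValueError(f"expected a 3-D or 4-D volume, got {data.ndim}-D in {path}")
    timing = Path(timing_path) if timing_path is not None else default_timing_path(path)
    if not timing.exists():
        raise FileNotFoundError(
            f"4-D volume {path} requires a frame-timing sidecar CSV "
            f"(mid_time_min,duration_min); expected at {timing}"
        )
    table = pd.read_csv(timing)
    for col in ("mid_time_min", "duration_min"):
        if col not in table.columns:
            raise ValueError(f"timing sidecar {timing} lacks required column {col!r}")
    if len(table) != data.shape[3]:
        raise ValueError(
            f"{data.shape[3]} frames in {path} but {len(table)} rows in timing sidecar {timing}"
        )
    return DynamicImage4D(
        grid,
        table["mid_time_min"].to_numpy(float),
        table["duration_min"].to_numpy(float),
        data,
    )


def write_image(
    image: ScalarImage3D | DynamicImage4D | LabelMap,
    path: str | Path,
    timing_path: str | Path | None = None,
) -> Path:
    """Write an image as NIfTI; round-trips through :func:`read_image`.

    Label maps are stored as int32 (bit-exact round trip); scalar and
    dynamic volumes as float64.  Dynamic series also write their timing
    sidecar CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, LabelMap):
        data = image.labels.astype(np.int32)
    elif isinstance(image, DynamicImage4D):
        data = image.values
    else:
        data = image.values
    nifti = nib.Nifti1Image(data, image.grid.affine)
    nib.save(nifti, str(path))
    if isinstance(image, DynamicImage4D):
        timing = Path(timing_path) if timing_path is not None else default_timing_path(path)
        pd.DataFrame(
            {"mid_time_min": image.frame_mids, "duration_min": image.frame_durations}
        ).to_csv(timing, index=False)
    return path


def read_labelmap(path: str | Path) -> LabelMap:
    """Read an integer label volume."""
    img = read_image(path)
    if not isinstance(img, ScalarImage3D):
        raise ValueError("label maps must be 3-D volumes")
    return LabelMap(img.grid, np.round(img.values).astype(np.int32))


def read_voi_table(path: str | Path) -> list[TissueVOI]:
    table = pd.read_csv(path)
    vois = [
        TissueVOI(int(r.label_id), str(r.name), str(r.tissue_class))
        for r in table.itertuples(index=False)
    ]
    return check_voi_table(vois)


def write_voi_table(vois: list[TissueVOI], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "label_id": [v.label_id for v in vois],
            "name": [v.name for v in vois],
            "tissue_class": [v.tissue_class for v in vois],
        }
    ).to_csv(path, index=False)
    return path
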