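"""Atlas-propagated VOI quantification: FF filtering, Jacobian volumetry,
tissue uptake readouts.

A single reference-space VOI set serves every registered subject.  False
positive voxels are removed with a prior on expected tissue fat content:
lean VOIs keep voxels with FF < 0.5, adipose VOIs keep FF >= 0.5 (the two
rules partition FF space, so no voxel is orphaned at the boundary), class
"other" is unfiltered.  Tissue volume in subject space is recovered from
the Jacobian determinant of the deformation:
``V = sum_{v in VOI} |J(v)| * voxel_volume``, converted to litres.  The
total tissue uptake rate combines uptake and morphology:
``TTUR = Ki_mean * volume`` (units: Ki-unit x L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ImageGrid, LabelMap, ScalarImage3D, TissueVOI
from .deform import DeformationField, jacobian_determinant, warp_labels
from .dixon import FatFractionImage, voi_readout

__all__ = [
    "FilteredVOI",
    "filter_voi",
    "voi_volume",
    "quantify_subject",
    "propagate_subject_voi_to_reference",
    "QUANT_COLUMNS",
]

QUANT_COLUMNS = [
    "n_voxels",
    "n_removed",
    "volume_l",
    "ff_mean",
    "ff_median",
    "ki_mean",
    "ki_median",
    "ttur",
]


@dataclass
class FilteredVOI:
    """A reference VOI after fat-fraction filtering."""

    voi: TissueVOI
    mask: np.ndarray  # boolean, reference grid
    n_removed: int
    rule: str

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def filter_voi(
    voi_mask: np.ndarray,
    ff: FatFractionImage,
    voi: TissueVOI,
    threshold: float = 0.5,
) -> FilteredVOI:
    """Apply the tissue-class fat-fraction criterion to a VOI mask.

    Lean keeps FF < threshold, adipose keeps FF >= threshold, other is the
    identity.  Raises if filtering removes every voxel.
    """
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if voi_mask.shape != ff.grid.shape:
        raise ValueError("VOI mask must be on the fat-fraction grid")
    if voi.tissue_class == "lean":
        kept = voi_mask & (ff.values < threshold)
        rule = f"FF<{threshold}"
    elif voi.tissue_class == "adipose":
        kept = voi_mask & (ff.values >= threshold)
        rule = f"FF>={threshold}"
    else:
        kept = voi_mask
        rule = "none"
    n_removed = int(voi_mask.sum() - kept.sum())
    if voi_mask.any() and not kept.any():
        raise ValueError(
            f"fat-fraction filter removed every voxel of VOI {voi.name!r} ({rule})"
        )
    return FilteredVOI(voi, kept, n_removed, rule)


def voi_volume(filtered: FilteredVOI | np.ndarray, jacobian: ScalarImage3D) -> float:
    """Subject-space VOI volume in litres via the Jacobian determinant."""
    mask = filtered.mask if isinstance(filtered, FilteredVOI) else np.asarray(filtered, bool)
    if mask.shape != jacobian.grid.shape:
        raise ValueError("jacobian must live on the reference grid of the VOI")
    dets = jacobian.values[mask]
    n_bad = int(np.sum(dets <= 0))
    if n_bad:
        warnings.warn(f"{n_bad} voxels with non-positive Jacobian inside VOI")
    return float(np.sum(np.abs(dets)) * jacobian.grid.voxel_volume / 1e6)


def quantify_subject(
    field: DeformationField,
    reference_labels: LabelMap,
    vois: list[TissueVOI],
    ff_reference_space: FatFractionImage,
    ki_reference_space: ScalarImage3D,
    jacobian: ScalarImage3D | None = None,
) -> pd.DataFrame:
    """Per-VOI automated measurements for one registered subject.

    ``ff_reference_space`` / ``ki_reference_space`` are the subject's fat
    fraction and Patlak Ki images warped onto the reference grid with
    ``field``.  Returns one row per VOI with volume (L), FF and Ki
    mean/median readouts over the filtered VOI, and TTUR = Ki_mean x
    volume.
    """
    if jacobian is None:
        jacobian = jacobian_determinant(field)
    rows = {}
    for voi in vois:
        base = reference_labels.mask(voi.label_id)
        filtered = filter_voi(base, ff_reference_space, voi)
        vol = voi_volume(filtered, jacobian)
        ff_mean = voi_readout(ff_reference_space, filtered.mask, "mean")
        ff_median = voi_readout(ff_reference_space, filtered.mask, "median")
        ki_mean = voi_readout(ki_reference_space, filtered.mask, "mean")
        ki_median = voi_readout(ki_reference_space, filtered.mask, "median")
        rows[voi.name] = {
            "n_voxels": filtered.n_voxels,
            "n_removed": filtered.n_removed,
            "volume_l": vol,
            "ff_mean": ff_mean,
            "ff_median": ff_median,
            "ki_mean": ki_mean,
            "ki_median": ki_median,
            "ttur": ki_mean * vol,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "voi"
    return out[QUANT_COLUMNS]


def propagate_subject_voi_to_reference(
    subject_labels: LabelMap, field: DeformationField
) -> LabelMap:
    """Nearest-neighbour pull-back of subject-space labels to reference space.

    This is the Dice-score input: the subject's own segmentation mapped
    through the estimated deformation for comparison with the reference
    VOI set.
    """
    return warp_labels(subject_labels, field)
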