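"""Hierarchical deformable registration of subject water/fat images to a
reference.

The scheme is a multi-resolution demons-style update with Gaussian
regularisation of the displacement field, run in three stages that follow
the skeleton-first anatomy prior: bones are matched first under heavy
regularisation, then non-adipose tissue, and last adipose tissue, with
strictly decreasing smoothing ("gradually allowing more elasticity").
Each stage weights the sum-of-squared-differences similarity with a tissue
mask computed from the reference fat fraction and signal intensity:

* bone    - high-signal water voxels (the bright scaffold),
* lean    - body voxels with FF < 0.5,
* adipose - body voxels with FF >= 0.5.

The similarity metric is SSD on intensity-normalised water and fat
channels jointly (equal weight).  The estimated field maps each reference
voxel to its corresponding subject physical coordinate (pull-back
convention, see :mod:`atlasquant.deform`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .core import ImageGrid, ScalarImage3D
from .deform import DeformationField, jacobian_determinant
from .dixon import compute_fat_fraction

__all__ = ["StageConfig", "RegistrationConfig", "register", "stage_masks"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageConfig:
    name: str  # bone | lean | adipose
    sigma_voxels: float  # elastic regularisation of the field

    def __post_init__(self) -> None:
        if self.name not in ("bone", "lean", "adipose"):
            raise ValueError("stage name must be bone, lean or adipose")
        if self.sigma_voxels <= 0:
            raise ValueError("regularisation sigma must be positive")


@dataclass(frozen=True)
class RegistrationConfig:
    """Stage schedule and numerical knobs.

    ``pyramid`` lists downsampling factors coarse-to-fine; ``iterations``
    gives the per-level iteration caps (same order).  Defaults follow the
    bone/lean/adipose elasticity schedule with sigma 4/2/1 voxels.
    """

    stages: tuple[StageConfig, ...] = (
        StageConfig("bone", 4.0),
        StageConfig("lean", 2.0),
        StageConfig("adipose", 1.0),
    )
    pyramid: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (80, 40, 15)
    sigma_fluid_voxels: float = 1.0  # smoothing of each update
    step: float = 1.0
    bone_water_threshold: float = 0.7  # of normalised water p99
    body_signal_fraction: float = 0.05  # body mask floor on total signal
    convergence_tol: float = 1e-5  # relative SSD change
    weight_floor: float = 0.05  # similarity weight outside the stage mask
    seed: int = 0

    def __post_init__(self) -> None:
        sig = [s.sigma_voxels for s in self.stages]
        if not all(a > b for a, b in zip(sig, sig[1:])):
            raise ValueError(
                "stage regularisation must be strictly decreasing "
                "(gradually allowing more elasticity)"
            )
        if len(self.pyramid) != len(self.iterations):
            raise ValueError("pyramid and iterations must have equal length")


def _normalise(values: np.ndarray) -> np.ndarray:
    scale = np.percentile(values, 99)
    if scale <= 0:
        scale = values.max() if values.max() > 0 else 1.0
    return values / scale


def stage_masks(
    reference_water: ScalarImage3D,
    reference_fat: ScalarImage3D,
    config: RegistrationConfig,
) -> dict[str, np.ndarray]:
    """Bone / lean / adipose similarity masks from the reference images."""
    w = _normalise(reference_water.values)
    f = _normalise(reference_fat.values)
    total = w + f
    body = total > config.body_signal_fraction * np.percentile(total, 99)
    ff = compute_fat_fraction(
        reference_water.with_values(np.maximum(reference_water.values, 0.0)),
        reference_fat.with_values(np.maximum(reference_fat.values, 0.0)),
    )
    bone = body & (w > config.bone_water_threshold * np.percentile(w, 99))
    lean = body & (ff.values < 0.5) & ~bone
    adipose = body & (ff.values >= 0.5) & ~bone
    return {"bone": bone, "lean": lean, "adipose": adipose}


def _level_grid(grid: ImageGrid, factor: int) -> ImageGrid:
    if factor == 1:
        return grid
    shape = tuple(max(4, int(round(n / factor))) for n in grid.shape)
    spacing = tuple(sp * n / m for sp, n, m in zip(grid.spacing, grid.shape, shape))
    origin = tuple(o + (s_l - s) / 2 for o, s_l, s in zip(grid.origin, spacing, grid.spacing))
    return ImageGrid(shape, spacing, origin)


def _resample_to(values: np.ndarray, shape: tuple[int, ...], smooth: float = 0.0) -> np.ndarray:
    if values.shape == tuple(shape):
        return values.copy()
    src = gaussian_filter(values, smooth) if smooth > 0 else values
    factors = [m / n for m, n in zip(shape, values.shape)]
    out = zoom(src, factors, order=1, mode="nearest", grid_mode=False)
    # zoom can be off by one voxel from rounding; enforce the target shape
    if out.shape != tuple(shape):
        out = out[tuple(slice(0, s) for s in shape)]
        pad = [(0, s - o) for s, o in zip(shape, out.shape)]
        if any(p[1] for p in pad):
            out = np.pad(out, pad, mode="edge")
    return out


def _masked_ssd(
    fixed: list[np.ndarray],
    moving: list[np.ndarray],
    weights: np.ndarray,
    mapping: np.ndarray,
    moving_grid: ImageGrid,
) -> float:
    idx = np.moveaxis(moving_grid.physical_to_index(mapping), -1, 0)
    ssd = 0.0
    for fx, mv in zip(fixed, moving):
        warped = map_coordinates(mv, idx, order=1, mode="constant", cval=0.0)
        ssd += float(np.sum(weights * (warped - fx) ** 2))
    return ssd


def register(
    subject_water: ScalarImage3D,
    subject_fat: ScalarImage3D,
    reference_water: ScalarImage3D,
    reference_fat: ScalarImage3D,
    config: RegistrationConfig | None = None,
) -> DeformationField:
    """Estimate the dense reference->subject deformation field.

    Stages run in the configured order, each initialised from the previous
    stage's result; each stage's weighted SSD is non-increasing between its
    first and last iteration (a worsening stage reverts to its starting
    field).  Updates that would fold the field (non-positive Jacobian) are
    rejected and the regularisation temporarily increased.
    """
    config = config or RegistrationConfig()
    if subject_water.grid != subject_fat.grid:
        raise ValueError("subject water/fat must share one grid")
    if reference_water.grid != reference_fat.grid:
        raise ValueError("reference water/fat must share one grid")
    ref_grid = reference_water.grid
    sub_grid = subject_water.grid

    fixed_full = [_normalise(reference_water.values), _normalise(reference_fat.values)]
    moving_full = [_normalise(subject_water.values), _normalise(subject_fat.values)]
    masks = stage_masks(reference_water, reference_fat, config)

    u_full = np.zeros((*ref_grid.shape, 3))  # displacement (mm) on reference grid

    for stage in config.stages:
        weights_full = config.weight_floor + (1.0 - config.weight_floor) * masks[
            stage.name
        ].astype(float)
        ssd_start = _masked_ssd(
            fixed_full, moving_full, weights_full, ref_grid.identity_mapping() + u_full, sub_grid
        )
        u_stage_start = u_full.copy()
        for factor, n_iter in zip(config.pyramid, config.iterations):
            grid_l = _level_grid(ref_grid, factor)
            sub_grid_l = _level_grid(sub_grid, factor)
            smooth = (factor - 1) / 2
            fixed_l = [_resample_to(ch, grid_l.shape, smooth) for ch in fixed_full]
            moving_l = [_resample_to(ch, sub_grid_l.shape, smooth) for ch in moving_full]
            weights_l = _resample_to(weights_full, grid_l.shape, smooth)
            u_l = np.stack(
                [_resample_to(u_full[..., c], grid_l.shape) for c in range(3)], axis=-1
            )
            u_l = _demons_level(
                u_l,
                fixed_l,
                weights_l,
                grid_l,
                moving_l,
                sub_grid_l,
                config,
                n_iter,
                sigma_elastic=max(0.5, stage.sigma_voxels / factor),
                sigma_fluid=max(0.25, config.sigma_fluid_voxels / factor),
            )
            u_full = np.stack(
                [_resample_to(u_l[..., c], ref_grid.shape) for c in range(3)], axis=-1
            )
        ssd_end = _masked_ssd(
            fixed_full, moving_full, weights_full, ref_grid.identity_mapping() + u_full, sub_grid
        )
        if ssd_end > ssd_start:
            warnings.warn(
                f"registration stage {stage.name!r} did not improve its similarity; "
                "keeping the pre-stage field"
            )
            u_full = u_stage_start
        log.info("stage %s: SSD %.4g -> %.4g", stage.name, ssd_start, ssd_end)

    return DeformationField(ref_grid, ref_grid.identity_mapping() + u_full)


def _demons_level(
    u: np.ndarray,
    fixed: list[np.ndarray],
    weights: np.ndarray,
    grid_l: ImageGrid,
    moving: list[np.ndarray],
    moving_grid: ImageGrid,
    config: RegistrationConfig,
    n_iter: int,
    sigma_elastic: float,
    sigma_fluid: float,
) -> np.ndarray:
    """Demons iterations for one stage at one pyramid level.

    ``sigma_elastic``/``sigma_fluid`` are already expressed in level
    voxels.
    """
    sp = np.asarray(grid_l.spacing)
    mean_sp = float(sp.mean())
    ident = grid_l.identity_mapping()
    grads = [np.stack(np.gradient(fx, *sp), axis=-1) for fx in fixed]
    max_step = 0.4 * mean_sp

    best_u = u.copy()
    best_ssd = np.inf
    prev_ssd = np.inf
    sigma_now = sigma_elastic
    for it in range(n_iter):
        idx = np.moveaxis(moving_grid.physical_to_index(ident + u), -1, 0)
        du = np.zeros_like(u)
        ssd = 0.0
        for fx, gr, mv in zip(fixed, grads, moving):
            warped = map_coordinates(mv, idx, order=1, mode="constant", cval=0.0)
            diff = warped - fx
            ssd += float(np.sum(weights * diff**2))
            g2 = np.sum(gr * gr, axis=-1)
            denom = g2 + (diff / mean_sp) ** 2
            coef = np.zeros_like(diff)
            np.divide(diff * weights, denom, out=coef, where=denom > 1e-12)
            du -= coef[..., None] * gr
        if ssd < best_ssd:
            best_ssd = ssd
            best_u = u.copy()
        if prev_ssd < np.inf and abs(prev_ssd - ssd) < config.convergence_tol * prev_ssd:
            break
        prev_ssd = ssd
        # fluid smoothing of the update, then take a bounded step
        for c in range(3):
            du[..., c] = gaussian_filter(du[..., c], sigma_fluid)
        mag = np.sqrt(np.sum(du * du, axis=-1))
        peak = mag.max()
        if peak > 0:
            du *= config.step * max_step / max(peak, 1e-12)
        u_new = u + du
        for c in range(3):
            u_new[..., c] = gaussian_filter(u_new[..., c], sigma_now)
        det = jacobian_determinant(DeformationField(grid_l, ident + u_new)).values
        if det.min() <= 0.01:
            # folding update: reject and regularise harder
            sigma_now *= 1.5
            for c in range(3):
                u_new[..., c] = gaussian_filter(u[..., c], sigma_now)
            det = jacobian_determinant(DeformationField(grid_l, ident + u_new)).values
            if det.min() <= 0.01:
                u_new = u  # keep previous field
        u = u_new
    # final check: keep best-so-far by SSD
    idx = np.moveaxis(moving_grid.physical_to_index(ident + u), -1, 0)
    ssd = 0.0
    for fx, mv in zip(fixed, moving):
        warped = map_coordinates(mv, idx, order=1, mode="constant", cval=0.0)
        ssd += float(np.sum(weights * (warped - fx) ** 2))
    if ssd > best_ssd:
        u = best_u
    return u
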