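"""Synthetic whole-body phantom with known deformations, volumes, fat
fractions and FDG kinetics.

The phantom stands in for a whole-body PET/MRI cohort: a reference
"subject" built from geometric primitives (bright bone scaffold, lean
organs, adipose depots, an aorta tube carrying the arterial input, low
signal lungs), plus deformed subjects generated by known smooth invertible
fields.  Every stage of the analysis pipeline can therefore be checked
against exact ground truth: per-tissue voxel-count volumes, the generating
fat fractions, and influx rates ``Ki = K1*k3/(k2+k3)``.

Geometry is parameterised in normalized [0,1]^3 coordinates so one
anatomy definition serves any grid size.  Default kinetic parameters give
tissue influx rates in the few-x-10^-3..10^-2 /min range typical of
clamped FDG studies (brain highest, adipose lowest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import DynamicImage4D, ImageGrid, LabelMap, ScalarImage3D, TissueVOI
from .deform import DeformationField, jacobian_determinant
from .kinetics import (
    PlasmaInput,
    TimeActivityCurve,
    dense_plasma_input,
    frame_average,
    simulate_tissue_curve,
    whole_blood_from_plasma,
)

__all__ = [
    "Ellipsoid",
    "Tube",
    "TissueSpec",
    "FrameSchedule",
    "PhantomSpec",
    "DeformParams",
    "SyntheticSubject",
    "default_phantom_spec",
    "default_frame_schedule",
    "make_reference",
    "make_subject",
    "simulate_dynamic_pet",
    "random_deform_params",
    "build_true_field",
]


# --------------------------------------------------------------------------
# geometric primitives (normalized coordinates)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def mask(self, ncoords: np.ndarray) -> np.ndarray:
        r = (ncoords - np.asarray(self.center)) / np.asarray(self.semiaxes)
        return np.sum(r * r, axis=-1) < 1.0


@dataclass(frozen=True)
class Tube:
    """Elliptic cylinder along z, optionally hollow (annulus)."""

    center_xy: tuple[float, float]
    radius_xy: tuple[float, float]
    z_range: tuple[float, float]
    inner_radius_xy: tuple[float, float] | None = None

    def mask(self, ncoords: np.ndarray) -> np.ndarray:
        dx = (ncoords[..., 0] - self.center_xy[0]) / self.radius_xy[0]
        dy = (ncoords[..., 1] - self.center_xy[1]) / self.radius_xy[1]
        inside = dx * dx + dy * dy < 1.0
        if self.inner_radius_xy is not None:
            ix = (ncoords[..., 0] - self.center_xy[0]) / self.inner_radius_xy[0]
            iy = (ncoords[..., 1] - self.center_xy[1]) / self.inner_radius_xy[1]
            inside &= ix * ix + iy * iy >= 1.0
        z = ncoords[..., 2]
        return inside & (z >= self.z_range[0]) & (z < self.z_range[1])


Primitive = Ellipsoid | Tube


@dataclass(frozen=True)
class TissueSpec:
    """One phantom tissue: geometry, MR signal model and FDG kinetics.

    ``signal`` is the total proton signal (arbitrary units); the water and
    fat channels are ``(1-ff)*signal`` and ``ff*signal``.  ``is_voi``
    distinguishes quantified tissues from the soft-tissue filler.
    """

    name: str
    tissue_class: str  # lean | adipose | other
    primitives: tuple[Primitive, ...]
    ff: float
    signal: float
    K1: float  # ml/ml/min
    k2: float  # 1/min
    k3: float  # 1/min
    Vb: float  # blood volume fraction
    is_voi: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError(f"{self.name}: FF must lie in [0, 1]")
        if min(self.K1, self.k2, self.k3, self.Vb) < 0:
            raise ValueError(f"{self.name}: kinetic parameters must be non-negative")
        if self.k2 + self.k3 <= 0:
            raise ValueError(f"{self.name}: k2 + k3 must be positive")

    @property
    def ki_true(self) -> float:
        """Ground-truth influx rate K1*k3/(k2+k3), 1/min."""
        return self.K1 * self.k3 / (self.k2 + self.k3)


@dataclass(frozen=True)
class FrameSchedule:
    """PET frame timing: ``starts``/``durations`` in minutes.

    The default mirrors a clamped whole-body protocol: a 10-min early
    dynamic period followed by five contiguous whole-body passes.
    ``n_body_frames`` marks how many trailing frames are whole-body passes
    (the default Patlak window).
    """

    starts: tuple[float, ...]
    durations: tuple[float, ...]
    n_body_frames: int = 5

    def __post_init__(self) -> None:
        s = np.asarray(self.starts)
        d = np.asarray(self.durations)
        if s.shape != d.shape or s.ndim != 1:
            raise ValueError("starts and durations must be equal-length 1-D")
        if np.any(d <= 0) or np.any(np.diff(s + d / 2) <= 0):
            raise ValueError("frames must be ordered with positive durations")

    @property
    def mids(self) -> np.ndarray:
        return np.asarray(self.starts) + np.asarray(self.durations) / 2

    @property
    def ends(self) -> np.ndarray:
        return np.asarray(self.starts) + np.asarray(self.durations)

    @property
    def t_star_default(self) -> float:
        """Mid-time of the first whole-body frame."""
        return float(self.mids[-self.n_body_frames])


def default_frame_schedule() -> FrameSchedule:
    starts = [0.25 * i for i in range(8)] + [2.0 + i for i in range(8)]
    durs = [0.25] * 8 + [1.0] * 8
    for i in range(5):  # five whole-body passes, 12 min each, 10-70 min
        starts.append(10.0 + 12.0 * i)
        durs.append(12.0)
    return FrameSchedule(tuple(starts), tuple(durs), n_body_frames=5)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic study conditions."""

    grid: ImageGrid
    tissues: tuple[TissueSpec, ...]
    envelope: tuple[Primitive, ...]  # body outline; remainder becomes filler
    frames: FrameSchedule = field(default_factory=default_frame_schedule)
    seed: int = 0
    mr_sigma: float = 0.02  # MR channel noise sd (signal units)
    pet_noise_scale: float = 0.3  # kBq/ml * sqrt(min); sd = scale*sqrt(C/dur)
    hematocrit: float = 0.45
    rbc_partition: float = 0.8
    input_scale: float = 1.0  # scales the Feng input function
    aorta_name: str = "aorta"
    filler_name: str = "soft_tissue"

    def label_of(self, name: str) -> int:
        for i, t in enumerate(self.tissues, start=1):
            if t.name == name:
                return i
        raise KeyError(name)

    def tissue_by_label(self) -> dict[int, TissueSpec]:
        return {i: t for i, t in enumerate(self.tissues, start=1)}

    def voi_table(self) -> list[TissueVOI]:
        return [
            TissueVOI(i, t.name, t.tissue_class)
            for i, t in enumerate(self.tissues, start=1)
            if t.is_voi
        ]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.tissues, start=1):
            rows.append(
                {
                    "label_id": i,
                    "voi": t.name,
                    "tissue_class": t.tissue_class,
                    "ff_true": t.ff,
                    "ki_true": t.ki_true,
                }
            )
        return pd.DataFrame(rows).set_index("voi")


def _default_tissues() -> tuple[TissueSpec, ...]:
    E, T = Ellipsoid, Tube
    leg_r, leg_l = (0.31, 0.5), (0.69, 0.5)
    return (
        TissueSpec(
            "skeleton",
            "other",
            (
                T((0.50, 0.36), (0.048, 0.048), (0.19, 0.57)),  # spine
                T(leg_r, (0.048, 0.048), (0.59, 0.92)),
                T(leg_l, (0.048, 0.048), (0.59, 0.92)),
            ),
            ff=0.15,
            signal=2.0,  # brightest class: bone scaffold drives the first stage
            K1=0.04,
            k2=0.20,
            k3=0.038,
            Vb=0.04,
        ),
        TissueSpec(
            "brain",
            "lean",
            (E((0.50, 0.50, 0.115), (0.145, 0.135, 0.058)),),
            ff=0.05,
            signal=1.0,
            K1=0.08,
            k2=0.115,
            k3=0.040,
            Vb=0.04,
        ),
        TissueSpec(
            "lung_right",
            "other",
            (E((0.34, 0.50, 0.26), (0.115, 0.150, 0.060)),),
            ff=0.20,
            signal=0.15,
            K1=0.010,
            k2=0.25,
            k3=0.040,
            Vb=0.15,
        ),
        TissueSpec(
            "lung_left",
            "other",
            (E((0.66, 0.50, 0.26), (0.115, 0.150, 0.060)),),
            ff=0.20,
            signal=0.15,
            K1=0.010,
            k2=0.25,
            k3=0.040,
            Vb=0.15,
        ),
        TissueSpec(
            "heart",
            "lean",
            (E((0.50, 0.56, 0.265), (0.055, 0.065, 0.045)),),
            ff=0.12,
            signal=1.0,
            K1=0.09,
            k2=0.12,
            k3=0.060,
            Vb=0.10,
        ),
        TissueSpec(
            "liver",
            "lean",
            (E((0.65, 0.49, 0.385), (0.120, 0.130, 0.055)),),
            ff=0.10,
            signal=1.0,
            K1=0.07,
            k2=0.35,
            k3=0.033,
            Vb=0.08,
        ),
        TissueSpec(
            "pancreas",
            "lean",
            (E((0.38, 0.42, 0.41), (0.070, 0.030, 0.025)),),
            ff=0.25,
            signal=1.0,
            K1=0.03,
            k2=0.18,
            k3=0.025,
            Vb=0.05,
        ),
        TissueSpec(
            "aorta",
            "other",
            (T((0.46, 0.54), (0.070, 0.070), (0.33, 0.46)),),
            ff=0.02,
            signal=1.0,
            K1=0.0,
            k2=0.10,
            k3=0.0,
            Vb=1.0,  # pure blood pool: carries the input function
        ),
        TissueSpec(
            "vat",
            "adipose",
            (
                E((0.52, 0.50, 0.50), (0.090, 0.070, 0.032)),
                E((0.36, 0.55, 0.51), (0.080, 0.065, 0.030)),
                E((0.66, 0.56, 0.51), (0.075, 0.065, 0.030)),
            ),
            ff=0.85,
            signal=1.0,
            K1=0.020,
            k2=0.25,
            k3=0.075,
            Vb=0.03,
        ),
        TissueSpec(
            "sat",
            "adipose",
            (T((0.50, 0.50), (0.40, 0.36), (0.19, 0.57), inner_radius_xy=(0.33, 0.29)),),
            ff=0.92,
            signal=1.0,
            K1=0.012,
            k2=0.25,
            k3=0.065,
            Vb=0.02,
        ),
        TissueSpec(
            "muscle_right",
            "lean",
            (T(leg_r, (0.145, 0.145), (0.59, 0.92), inner_radius_xy=(0.055, 0.055)),),
            ff=0.08,
            signal=1.0,
            K1=0.045,
            k2=0.12,
            k3=0.036,
            Vb=0.03,
        ),
        TissueSpec(
            "muscle_left",
            "lean",
            (T(leg_l, (0.145, 0.145), (0.59, 0.92), inner_radius_xy=(0.055, 0.055)),),
            ff=0.08,
            signal=1.0,
            K1=0.045,
            k2=0.12,
            k3=0.036,
            Vb=0.03,
        ),
        # soft-tissue filler: fills the body envelope around the organs
        TissueSpec(
            "soft_tissue",
            "other",
            (),
            ff=0.30,
            signal=1.0,
            K1=0.05,
            k2=0.20,
            k3=0.032,
            Vb=0.04,
            is_voi=False,
        ),
    )


def _default_envelope() -> tuple[Primitive, ...]:
    return (
        Ellipsoid((0.50, 0.50, 0.115), (0.170, 0.160, 0.070)),  # head
        Tube((0.50, 0.50), (0.42, 0.38), (0.185, 0.575)),  # torso
        Tube((0.31, 0.50), (0.155, 0.155), (0.575, 0.94)),  # right leg
        Tube((0.69, 0.50), (0.155, 0.155), (0.575, 0.94)),  # left leg
    )


def default_phantom_spec(
    shape: tuple[int, int, int] = (64, 48, 160),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """The study-condition phantom on the default desk-scale grid."""
    grid = ImageGrid(shape, spacing)
    return PhantomSpec(
        grid=grid,
        tissues=_default_tissues(),
        envelope=_default_envelope(),
        seed=seed,
        **overrides,
    )


# --------------------------------------------------------------------------
# reference construction


def labels_at_points(
    spec: PhantomSpec, ncoords: np.ndarray, check_overlap: bool = False
) -> np.ndarray:
    """Evaluate analytic tissue membership at normalized points.

    ``ncoords`` has shape ``(..., 3)`` in the phantom's [0,1]^3 anatomy
    space.  With ``check_overlap`` a collision of two tissue primitives
    raises, naming the pair.
    """
    labels = np.zeros(ncoords.shape[:-1], dtype=np.int32)
    filler_id = None
    for i, tissue in enumerate(spec.tissues, start=1):
        if not tissue.primitives:
            filler_id = i
            continue
        mask = np.zeros(labels.shape, dtype=bool)
        for prim in tissue.primitives:
            mask |= prim.mask(ncoords)
        if check_overlap:
            clash = mask & (labels != 0)
            if clash.any():
                other = spec.tissue_by_label()[int(labels[clash][0])]
                raise ValueError(
                    f"phantom tissues overlap: {other.name!r} and {tissue.name!r}"
                )
        labels[mask & (labels == 0) if not check_overlap else mask] = i
    envelope = np.zeros(labels.shape, dtype=bool)
    for prim in spec.envelope:
        envelope |= prim.mask(ncoords)
    if filler_id is not None:
        labels[envelope & (labels == 0)] = filler_id
    return labels


def build_labelmap(spec: PhantomSpec) -> LabelMap:
    """Paint tissue primitives into a label volume; filler fills the rest.

    Raises if two tissue primitives collide, naming the colliding pair.
    """
    ncoords = spec.grid.normalized_coordinates()
    return LabelMap(spec.grid, labels_at_points(spec, ncoords, check_overlap=True))


@dataclass
class SyntheticSubject:
    """One phantom subject with full ground truth."""

    water: ScalarImage3D
    fat: ScalarImage3D
    pet: DynamicImage4D
    true_labelmap: LabelMap
    true_field: DeformationField  # reference -> subject
    truth: pd.DataFrame  # per VOI: n_voxels, volume_l, ff_true, ki_true
    plasma: PlasmaInput  # the generating plasma input (dense)
    spec: PhantomSpec


def _truth_from_labels(spec: PhantomSpec, labelmap: LabelMap) -> pd.DataFrame:
    table = spec.truth_table()
    counts = np.bincount(labelmap.labels.ravel(), minlength=len(spec.tissues) + 1)
    table["n_voxels"] = [int(counts[i]) for i in table["label_id"]]
    table["volume_l"] = table["n_voxels"] * spec.grid.voxel_volume / 1e6
    return table


def _mr_channels(
    spec: PhantomSpec, labelmap: LabelMap, rng: np.random.Generator
) -> tuple[ScalarImage3D, ScalarImage3D]:
    water = np.zeros(spec.grid.shape)
    fat = np.zeros(spec.grid.shape)
    for i, t in spec.tissue_by_label().items():
        m = labelmap.labels == i
        water[m] = (1.0 - t.ff) * t.signal
        fat[m] = t.ff * t.signal
    if spec.mr_sigma > 0:
        water = water + rng.normal(0.0, spec.mr_sigma, water.shape)
        fat = fat + rng.normal(0.0, spec.mr_sigma, fat.shape)
    # magnitude images are non-negative
    water = np.maximum(water, 0.0)
    fat = np.maximum(fat, 0.0)
    return ScalarImage3D(spec.grid, water), ScalarImage3D(spec.grid, fat)


def simulate_dynamic_pet(
    labelmap: LabelMap,
    spec: PhantomSpec,
    input_fn: PlasmaInput,
    frames: FrameSchedule | None = None,
    seed: int | None = None,
) -> DynamicImage4D:
    """Dynamic PET from irreversible 2TC kinetics per labelled tissue.

    Frame values are time-averages of the continuous tissue curve over each
    frame window.  Optional Gaussian noise has variance proportional to
    signal / frame duration (a reconstruction-domain approximation of
    count statistics).
    """
    frames = frames or spec.frames
    mids = frames.mids
    starts = np.asarray(frames.starts)
    ends = frames.ends
    blood = whole_blood_from_plasma(input_fn, spec.hematocrit, spec.rbc_partition)
    values = np.zeros((*labelmap.grid.shape, mids.size))
    for i, t in spec.tissue_by_label().items():
        m = labelmap.labels == i
        if not m.any():
            continue
        curve = simulate_tissue_curve(t.K1, t.k2, t.k3, t.Vb, input_fn, blood=blood)
        values[m] = frame_average(curve, starts, ends)
    if spec.pet_noise_scale > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        sd = spec.pet_noise_scale * np.sqrt(
            np.maximum(values, 0.0) / np.asarray(frames.durations)
        )
        values = values + rng.normal(0.0, 1.0, values.shape) * sd
    return DynamicImage4D(labelmap.grid, mids, np.asarray(frames.durations), values)


def make_reference(spec: PhantomSpec) -> SyntheticSubject:
    """Build the reference subject (identity ground-truth field)."""
    labelmap = build_labelmap(spec)
    rng = np.random.default_rng(spec.seed)
    water, fat = _mr_channels(spec, labelmap, rng)
    plasma = dense_plasma_input(spec.frames.ends[-1], scale=spec.input_scale)
    pet = simulate_dynamic_pet(
        labelmap, spec, plasma, spec.frames, seed=int(rng.integers(2**31))
    )
    from .deform import identity_field

    return SyntheticSubject(
        water=water,
        fat=fat,
        pet=pet,
        true_labelmap=labelmap,
        true_field=identity_field(spec.grid),
        truth=_truth_from_labels(spec, labelmap),
        plasma=plasma,
        spec=spec,
    )


# --------------------------------------------------------------------------
# deformed subjects


@dataclass(frozen=True)
class DeformParams:
    """A smooth invertible reference->subject deformation.

    Global anisotropic scaling about the grid centre plus translation plus
    a band-limited random displacement (white noise smoothed with a
    Gaussian of ``jiggle_sigma_mm`` and rescaled to a maximum magnitude of
    ``jiggle_amplitude_mm``), plus an independent Gaussian-windowed shift
    of the mobile abdominal organ analogue (``organ_shift_mm`` applied
    around ``organ_center_norm`` with window ``organ_sigma_mm``) — small
    abdominal organs move between subjects independently of global body
    habitus, which is what makes them hard for a single-atlas approach.
    """

    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jiggle_amplitude_mm: float = 0.0
    jiggle_sigma_mm: float = 24.0
    jiggle_seed: int = 0
    organ_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_center_norm: tuple[float, float, float] = (0.38, 0.42, 0.41)  # pancreas
    organ_sigma_mm: float = 20.0

    @property
    def is_identity(self) -> bool:
        return (
            tuple(self.scale) == (1.0, 1.0, 1.0)
            and tuple(self.translation_mm) == (0.0, 0.0, 0.0)
            and self.jiggle_amplitude_mm == 0.0
            and tuple(self.organ_shift_mm) == (0.0, 0.0, 0.0)
        )


def random_deform_params(
    rng: np.random.Generator,
    scale_range: tuple[float, float] = (0.93, 1.07),
    max_translation_mm: float = 6.0,
    jiggle_amplitude_mm: float = 4.0,
    jiggle_sigma_mm: float = 24.0,
    max_organ_shift_mm: float = 8.0,
) -> DeformParams:
    """Draw inter-subject variation the registration must recover."""
    return DeformParams(
        scale=tuple(rng.uniform(*scale_range, size=3)),
        translation_mm=tuple(rng.uniform(-max_translation_mm, max_translation_mm, size=3)),
        jiggle_amplitude_mm=jiggle_amplitude_mm,
        jiggle_sigma_mm=jiggle_sigma_mm,
        jiggle_seed=int(rng.integers(2**31)),
        organ_shift_mm=tuple(rng.uniform(-max_organ_shift_mm, max_organ_shift_mm, size=3)),
    )


def _jiggle_field(grid: ImageGrid, params: DeformParams) -> np.ndarray:
    """Non-affine displacement (mm) on the grid: band-limited random
    jiggle plus the localized mobile-organ shift."""
    u = np.zeros((*grid.shape, 3))
    if params.jiggle_amplitude_mm > 0:
        rng = np.random.default_rng(params.jiggle_seed)
        u = rng.normal(size=(*grid.shape, 3))
        sig = [params.jiggle_sigma_mm / s for s in grid.spacing]
        for c in range(3):
            u[..., c] = gaussian_filter(u[..., c], sigma=sig)
        mag = np.sqrt(np.sum(u * u, axis=-1))
        peak = mag.max()
        if peak > 0:
            u *= params.jiggle_amplitude_mm / peak
    shift = np.asarray(params.organ_shift_mm)
    if np.any(shift != 0):
        center = np.asarray(grid.origin) + np.asarray(params.organ_center_norm) * np.asarray(
            grid.extent_mm
        )
        rel = grid.identity_mapping() - center
        window = np.exp(-np.sum(rel * rel, axis=-1) / (2 * params.organ_sigma_mm**2))
        u = u + window[..., None] * shift
    return u


def build_true_field(grid: ImageGrid, params: DeformParams) -> DeformationField:
    """Construct T(x) = c + S(x - c) + t + u(x); rejects folding fields."""
    center = grid.physical_center()
    ident = grid.identity_mapping()
    scale = np.asarray(params.scale)
    mapped = center + (ident - center) * scale + np.asarray(params.translation_mm)
    mapped = mapped + _jiggle_field(grid, params)
    fld = DeformationField(grid, mapped)
    det = jacobian_determinant(fld).values
    if det.min() <= 0:
        raise ValueError(
            "deformation field folds (non-positive Jacobian determinant); "
            "reduce jiggle amplitude or increase its smoothness"
        )
    return fld


def _invert_true_field(
    grid: ImageGrid, params: DeformParams, n_iter: int = 25, tol_mm: float = 1e-3
) -> np.ndarray:
    """Numeric inverse W = T^{-1} on the grid by fixed-point iteration.

    Solves ``T(x) = y`` for every grid point y using
    ``x <- c + S^{-1}(y - c - t - u(x))``; converges because the jiggle
    gradient is small compared to the affine part.
    """
    center = grid.physical_center()
    scale = np.asarray(params.scale)
    trans = np.asarray(params.translation_mm)
    u = _jiggle_field(grid, params)
    y = grid.identity_mapping()
    x = (y - center - trans) / scale + center
    if not np.any(u):
        return x
    for _ in range(n_iter):
        idx = np.moveaxis(grid.physical_to_index(x), -1, 0)
        u_at_x = np.stack(
            [
                map_coordinates(u[..., c], idx, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )
        x_new = (y - center - trans - u_at_x) / scale + center
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol_mm:
            break
    return x


def make_subject(
    reference: SyntheticSubject, deform_params: DeformParams, seed: int
) -> SyntheticSubject:
    """Deform the reference through a known field into a new subject.

    Water/fat and the label map are the reference resampled through the
    inverse field (linear / nearest interpolation); the dynamic PET is
    re-simulated from the deformed label map with the same kinetics and a
    fresh seeded noise realisation, so tissue boundaries and the aorta
    blood pool stay sharp.  Identity parameters return a voxel-identical
    copy.
    """
    spec = reference.spec
    grid = spec.grid
    if deform_params.is_identity:
        from .deform import identity_field

        return SyntheticSubject(
            water=ScalarImage3D(grid, reference.water.values.copy()),
            fat=ScalarImage3D(grid, reference.fat.values.copy()),
            pet=DynamicImage4D(
                grid,
                reference.pet.frame_mids.copy(),
                reference.pet.frame_durations.copy(),
                reference.pet.values.copy(),
            ),
            true_labelmap=LabelMap(grid, reference.true_labelmap.labels.copy()),
            true_field=identity_field(grid),
            truth=reference.truth.copy(),
            plasma=reference.plasma,
            spec=spec,
        )
    true_field = build_true_field(grid, deform_params)
    inv = _invert_true_field(grid, deform_params)
    idx = np.moveaxis(grid.physical_to_index(inv), -1, 0)
    water = map_coordinates(reference.water.values, idx, order=1, mode="constant", cval=0.0)
    fat = map_coordinates(reference.fat.values, idx, order=1, mode="constant", cval=0.0)
    labels = map_coordinates(
        reference.true_labelmap.labels, idx, order=0, mode="constant", cval=0
    ).astype(np.int32)
    labelmap = LabelMap(grid, labels)
    pet = simulate_dynamic_pet(labelmap, spec, reference.plasma, spec.frames, seed=seed)
    return SyntheticSubject(
        water=ScalarImage3D(grid, water),
        fat=ScalarImage3D(grid, fat),
        pet=pet,
        true_labelmap=labelmap,
        true_field=true_field,
        truth=_truth_from_labels(spec, labelmap),
        plasma=reference.plasma,
        spec=spec,
    )
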