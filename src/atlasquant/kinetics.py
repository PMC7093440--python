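"""FDG kinetics: input functions, Patlak graphical analysis, M-value.

The irreversible two-tissue-compartment model drives both simulation and
interpretation here::

    dC1/dt = K1*Cp - (k2 + k3)*C1
    dC2/dt = k3*C1
    C_t    = C1 + C2 + Vb*Cb

with plasma input Cp, whole-blood Cb and net influx rate
``Ki = K1*k3 / (k2 + k3)``.  The Patlak plot linearises this for
t past the transient:  ``C_t(t)/Cp(t) = Ki * (int_0^t Cp / Cp(t)) + V0``,
so ordinary least squares on the late frames yields Ki as the slope.

Decay correction is assumed already applied to all activity data
(reconstruction-domain convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .core import DynamicImage4D, ScalarImage3D

__all__ = [
    "TimeActivityCurve",
    "PlasmaInput",
    "PatlakResult",
    "feng_input",
    "dense_plasma_input",
    "extract_idif",
    "correct_to_plasma",
    "whole_blood_from_plasma",
    "patlak_fit",
    "voxelwise_ki",
    "simulate_tissue_curve",
    "frame_average",
    "m_value",
    "steady_state_gir",
]

#: Feng model defaults: Cp(t) = (A1*t - A2 - A3)e^{l1 t} + A2 e^{l2 t} + A3 e^{l3 t}
FENG_A = (851.1225, 21.8798, 20.8113)  # kBq/ml/min, kBq/ml, kBq/ml
FENG_LAMBDA = (-4.1338598, -0.1190996, -0.0104344)  # 1/min


@dataclass
class TimeActivityCurve:
    """Activity concentration (kBq/ml) at increasing mid-frame times (min)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.times, self.values * factor)


@dataclass
class PlasmaInput:
    """Plasma tracer concentration curve feeding the Patlak fit."""

    tac: TimeActivityCurve
    provenance: str = "synthetic"  # or "idif_corrected"


@dataclass
class PatlakResult:
    ki: float  # slope, 1/min
    v0: float  # dimensionless intercept
    r_squared: float
    frames_used: np.ndarray  # mid-times of the frames in the fit

    def __post_init__(self) -> None:
        if self.frames_used.size < 2:
            raise ValueError("a Patlak fit requires at least 2 frames")
        if not np.isfinite(self.ki):
            raise ValueError("non-finite Patlak slope")


def feng_input(
    times: np.ndarray,
    A: tuple[float, float, float] = FENG_A,
    lam: tuple[float, float, float] = FENG_LAMBDA,
    scale: float = 1.0,
) -> np.ndarray:
    """Feng-type arterial input function evaluated at ``times`` (min)."""
    t = np.asarray(times, dtype=float)
    cp = (A[0] * t - A[1] - A[2]) * np.exp(lam[0] * t)
    cp += A[1] * np.exp(lam[1] * t) + A[2] * np.exp(lam[2] * t)
    cp = np.where(t > 0, cp, 0.0)
    return scale * np.maximum(cp, 0.0)


def dense_plasma_input(t_end: float, dt: float = 0.02, scale: float = 1.0) -> PlasmaInput:
    """Feng input sampled on a dense regular grid starting at t=0."""
    times = np.arange(0.0, t_end + dt, dt)
    return PlasmaInput(TimeActivityCurve(times, feng_input(times, scale=scale)), "synthetic")


def extract_idif(pet: DynamicImage4D, aorta_mask: np.ndarray) -> TimeActivityCurve:
    """Image-derived input function: per-frame mean activity over a VOI."""
    aorta_mask = np.asarray(aorta_mask, dtype=bool)
    if aorta_mask.shape != pet.grid.shape:
        raise ValueError("aorta VOI must be on the PET grid")
    if not aorta_mask.any():
        raise ValueError("empty aorta VOI")
    vals = pet.values[aorta_mask].mean(axis=0)
    return TimeActivityCurve(pet.frame_mids, vals)


def correct_to_plasma(
    whole_blood: TimeActivityCurve,
    hematocrit: float = 0.45,
    rbc_partition: float = 0.8,
) -> PlasmaInput:
    """Correct a whole-blood curve for blood-cell-bound radioactivity.

    ``Cp = C_wb / (1 - Hct*(1 - r))`` with r the erythrocyte-to-plasma
    concentration ratio; ``r = 1`` is the identity.
    """
    if not 0 <= hematocrit < 1:
        raise ValueError("hematocrit must lie in [0, 1)")
    if rbc_partition < 0:
        raise ValueError("rbc partition ratio must be >= 0")
    denom = 1.0 - hematocrit * (1.0 - rbc_partition)
    if denom <= 0:
        raise ValueError("non-positive plasma correction denominator")
    return PlasmaInput(whole_blood.scaled(1.0 / denom), "idif_corrected")


def whole_blood_from_plasma(
    plasma: PlasmaInput, hematocrit: float = 0.45, rbc_partition: float = 0.8
) -> TimeActivityCurve:
    """Inverse of :func:`correct_to_plasma` (used to synthesise blood signal)."""
    denom = 1.0 - hematocrit * (1.0 - rbc_partition)
    return plasma.tac.scaled(denom)


def _augment_from_zero(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prepend (0, 0) so the curve is integrable from t = 0."""
    if times[0] > 0:
        return np.concatenate([[0.0], times]), np.concatenate([[0.0], values])
    return times, values


def _plasma_at(plasma: PlasmaInput, t: np.ndarray) -> np.ndarray:
    times, values = _augment_from_zero(plasma.tac.times, plasma.tac.values)
    return np.interp(t, times, values)


def _integral_to(plasma: PlasmaInput, t: np.ndarray) -> np.ndarray:
    """Trapezoidal ``int_0^t Cp`` on the plasma sampling grid, Cp(0)=0."""
    times, values = _augment_from_zero(plasma.tac.times, plasma.tac.values)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(times) * (values[1:] + values[:-1]) / 2)])
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(times, t, side="right") - 1
    idx = np.clip(idx, 0, times.size - 2)
    cp_t = np.interp(t, times, values)
    partial = (t - times[idx]) * (values[idx] + cp_t) / 2
    return cum[idx] + partial


def patlak_regressors(
    tissue_times: np.ndarray, plasma: PlasmaInput, t_star: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame selection and (x, Cp) regressor values for a Patlak fit."""
    tissue_times = np.asarray(tissue_times, dtype=float)
    sel = tissue_times >= t_star - 1e-9
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 frames with mid-time >= t* = {t_star}")
    t = tissue_times[sel]
    cp = _plasma_at(plasma, t)
    if np.any(cp <= 0):
        raise ValueError("zero or negative plasma activity inside the Patlak window")
    x = _integral_to(plasma, t) / cp
    return sel, x, cp


def patlak_fit(tissue: TimeActivityCurve, plasma: PlasmaInput, t_star: float) -> PatlakResult:
    """Ordinary least squares Patlak fit over frames with mid-time >= t*."""
    sel, x, cp = patlak_regressors(tissue.times, plasma, t_star)
    y = tissue.values[sel] / cp
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate Patlak regressor (identical x values)")
    ki = float(np.sum((x - xm) * (y - ym)) / sxx)
    v0 = float(ym - ki * xm)
    ss_res = float(np.sum((y - (ki * x + v0)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PatlakResult(ki, v0, r2, tissue.times[sel])


def voxelwise_ki(
    pet: DynamicImage4D, plasma: PlasmaInput, t_star: float
) -> tuple[ScalarImage3D, np.ndarray]:
    """Patlak slope image over the whole volume.

    Shares the (x, Cp) regressors across voxels, so the slope reduces to a
    closed-form covariance ratio.  Voxels with non-finite input are set to
    0 and flagged False in the returned mask.
    """
    sel, x, cp = patlak_regressors(pet.frame_mids, plasma, t_star)
    frames = pet.values[..., sel]
    y = frames / cp  # broadcast over last axis
    finite = np.all(np.isfinite(y), axis=-1)
    y = np.where(finite[..., None], y, 0.0)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = np.tensordot(y - y.mean(axis=-1, keepdims=True), xc, axes=([-1], [0])) / sxx
    slope[~finite] = 0.0
    return ScalarImage3D(pet.grid, slope), finite


def simulate_tissue_curve(
    K1: float,
    k2: float,
    k3: float,
    Vb: float,
    plasma: PlasmaInput,
    blood: TimeActivityCurve | None = None,
) -> TimeActivityCurve:
    """Irreversible 2TC tissue concentration on the plasma sampling grid.

    Uses an exact exponential-integrator recursion assuming Cp is piecewise
    linear between samples (so a dense plasma grid gives a near-exact
    solution).  ``blood`` supplies the vascular term; defaults to plasma.
    """
    if min(K1, k2, k3, Vb) < 0:
        raise ValueError("kinetic parameters must be non-negative")
    t = plasma.tac.times
    cp = plasma.tac.values
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        cp = np.concatenate([[0.0], cp])
    cb = cp if blood is None else np.interp(t, *_augment_from_zero(blood.times, blood.values))
    beta = k2 + k3
    n = t.size
    c1 = np.zeros(n)
    h = np.diff(t)
    if beta > 0:
        eb = np.exp(-beta * h)
        slope = np.diff(cp) / h
        # int_0^h e^{-beta(h-s)} (a + b s) ds, a = cp[i], b = slope
        int_a = (1 - eb) / beta
        int_b = h / beta - (1 - eb) / beta**2
        for i in range(n - 1):
            c1[i + 1] = c1[i] * eb[i] + K1 * (cp[i] * int_a[i] + slope[i] * int_b[i])
    else:
        cum = np.concatenate([[0.0], np.cumsum(h * (cp[1:] + cp[:-1]) / 2)])
        c1 = K1 * cum
    c2 = k3 * np.concatenate([[0.0], np.cumsum(h * (c1[1:] + c1[:-1]) / 2)])
    ct = c1 + c2 + Vb * cb
    if plasma.tac.times[0] > 0:
        ct = ct[1:]
    return TimeActivityCurve(plasma.tac.times, ct)


def frame_average(curve: TimeActivityCurve, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Time-average a densely sampled curve over acquisition frames."""
    t, v = _augment_from_zero(curve.times, curve.values)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (v[1:] + v[:-1]) / 2)])

    def integral(q: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(t, q, side="right") - 1, 0, t.size - 2)
        vq = np.interp(q, t, v)
        return cum[idx] + (q - t[idx]) * (v[idx] + vq) / 2

    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if ends.max() > t[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond the simulated curve")
    return (integral(ends) - integral(starts)) / (ends - starts)


def m_value(glucose_infusion_rate: float, lean_body_mass: float) -> float:
    """Whole-body insulin sensitivity: steady-state GIR / lean body mass.

    ``glucose_infusion_rate`` in mg/min (already averaged over the clamp
    steady state), ``lean_body_mass`` in kg; returns mg/kg/min.
    """
    if glucose_infusion_rate < 0:
        raise ValueError("glucose infusion rate must be >= 0")
    if lean_body_mass <= 0:
        raise ValueError("lean body mass must be > 0")
    return glucose_infusion_rate / lean_body_mass


def steady_state_gir(
    times_min: np.ndarray, rates: np.ndarray, window: tuple[float, float] = (60.0, 120.0)
) -> float:
    """Mean glucose infusion rate over the clamp steady-state window.

    Samples outside ``window`` (minutes after clamp start, inclusive) are
    ignored.
    """
    times_min = np.asarray(times_min, dtype=float)
    rates = np.asarray(rates, dtype=float)
    sel = (times_min >= window[0]) & (times_min <= window[1])
    if not sel.any():
        raise ValueError(f"no infusion-rate samples inside the steady-state window {window}")
    return float(rates[sel].mean())
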