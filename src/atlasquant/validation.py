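"""Automated-vs-reference validation statistics.

Per tissue VOI: Dice overlap of the propagated and reference
segmentations, and for each measurement (volume, FF mean/median,
Ki mean/median, TTUR) the across-subject reference mean, automated mean,
coefficient of determination R^2, and a paired two-tailed t-test for
systematic differences.  p < 0.05 is flagged significant; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dice",
    "paired_t_test",
    "r_squared",
    "ValidationTable",
    "build_validation_table",
    "MEASURES",
]

MEASURES = ["volume_l", "ff_mean", "ff_median", "ki_mean", "ki_median", "ttur"]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` of two voxel masks.

    Two empty masks count as perfect agreement on absence (1.0, with a
    warning).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must live on a common grid")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        warnings.warn("Dice of two empty masks; defined as 1.0")
        return 1.0
    return 2.0 * int(np.sum(a & b)) / size


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Paired two-tailed t-test on per-subject value pairs.

    Returns ``(t, p, n)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` on
    ``d = x - y`` and p from the Student t distribution with n-1 degrees
    of freedom.  Identical vectors give (0, 1).  Zero-variance differences
    with a non-zero mean are reported as p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, n
        warnings.warn("zero-variance non-zero differences; p reported as 0")
        return float(np.sign(mean)) * np.inf, 0.0, n
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p, n


def r_squared(reference: np.ndarray, automated: np.ndarray) -> float:
    """Coefficient of determination as the squared Pearson correlation.

    For a simple linear fit this equals the OLS R^2, so the direction of
    the regression does not matter.  Exactly equal vectors return 1.0 by
    convention (perfect agreement even when variance is degenerate).
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(automated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if np.array_equal(x, y):
        return 1.0
    if x.size < 3:
        raise ValueError("R^2 requires at least 3 value pairs")
    if np.std(x) == 0:
        raise ValueError("degenerate variance in the reference values")
    if np.std(y) == 0:
        return 0.0  # a constant prediction explains no variance
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


@dataclass
class ValidationTable:
    """Per-VOI validation rows plus cohort-level summary numbers."""

    table: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def __str__(self) -> str:  # human-readable report
        lines = [self.table.to_string(float_format=lambda v: f"{v:.4g}")]
        mavd = self.summary.get("mean_abs_volume_diff_significant_pct")
        if mavd is not None and np.isfinite(mavd):
            lines.append(
                f"mean absolute volume difference over significant tissues: {mavd:.1f}%"
            )
        lines.append("TTUR units: Ki-unit (1/min) x L")
        return "\n".join(lines)


def _stats_block(ref: np.ndarray, auto: np.ndarray) -> dict:
    out = {
        "ref": float(np.mean(ref)),
        "auto": float(np.mean(auto)),
    }
    try:
        out["r2"] = r_squared(ref, auto)
    except ValueError:
        out["r2"] = np.nan
    if np.array_equal(ref, auto):
        # exact agreement: no evidence of a systematic difference
        out.update({"t": 0.0, "p": 1.0, "significant": False})
    elif ref.size >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p, _ = paired_t_test(auto, ref)
        out["t"] = t
        out["p"] = p
        out["significant"] = bool(p < 0.05)
    else:
        out.update({"t": np.nan, "p": np.nan, "significant": False})
    return out


def build_validation_table(
    quant_reports: list[pd.DataFrame],
    reference_measurements: list[pd.DataFrame],
    propagated_vois: list,
    reference_vois: dict[str, np.ndarray],
    voi_label_ids: dict[str, int] | None = None,
) -> ValidationTable:
    """Assemble the per-VOI automated-vs-reference comparison.

    Parameters
    ----------
    quant_reports, reference_measurements
        One DataFrame per subject (index VOI name, columns ``MEASURES``)
        from the automated and reference arms.
    propagated_vois
        Per subject, the subject VOIs propagated to reference space
        (:class:`~atlasquant.core.LabelMap`).
    reference_vois
        Reference-space VOI masks by name (the automated segmentations).
    voi_label_ids
        Label id per VOI name inside the propagated label maps; defaults
        to each mask's position order being irrelevant — required when
        propagated_vois are LabelMaps.
    """
    if not (len(quant_reports) == len(reference_measurements) == len(propagated_vois)):
        raise ValueError("per-subject inputs must have equal length")
    names = list(reference_vois.keys())
    for df in [*quant_reports, *reference_measurements]:
        missing = set(names) - set(df.index)
        if missing:
            raise ValueError(f"VOI missing from a per-subject report: {sorted(missing)}")
    rows = {}
    for name in names:
        ref_mask = reference_vois[name]
        dices = []
        for prop in propagated_vois:
            label_id = (voi_label_ids or {}).get(name)
            if label_id is None:
                raise ValueError("voi_label_ids mapping is required")
            dices.append(dice(prop.mask(label_id), ref_mask))
        row = {"dice": float(np.mean(dices))}
        for measure in MEASURES:
            ref = np.array([df.loc[name, measure] for df in reference_measurements])
            auto = np.array([df.loc[name, measure] for df in quant_reports])
            block = _stats_block(ref, auto)
            for key, val in block.items():
                row[f"{measure}_{key}"] = val
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "voi"

    sig = table[table["volume_l_significant"] == True]  # noqa: E712
    if len(sig):
        diffs = (sig["volume_l_auto"] - sig["volume_l_ref"]).abs() / sig["volume_l_ref"]
        mavd = float(diffs.mean() * 100)
    else:
        mavd = np.nan
    summary = {
        "n_subjects": len(quant_reports),
        "mean_abs_volume_diff_significant_pct": mavd,
        "n_significant_volume": int(len(sig)),
    }
    return ValidationTable(table, summary)
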