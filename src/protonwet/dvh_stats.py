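"""DVH metrics, worst-case robustness evaluation, and paired statistics.

Metrics follow the usual radiotherapy conventions: Vx = percent of structure
volume receiving at least x% of the prescription, Dx = dose (as percent of
prescription) received by at least x% of the volume, plus maximum dose, mean
dose, and the RTOG conformity index (prescription-isodose volume / target
volume, counted over the whole grid).  V/D/max/mean use exact voxel counts;
the binned cumulative DVH is for curves only.  The worst case over robustness
scenarios is the per-metric extremum (minimum for coverage metrics, maximum
for max dose).  Before/after override comparisons use the exact Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .ct_calibration import StructureMask
from .errors import UndefinedTestError, ValidationError
from .override_dose import DoseGrid

__all__ = [
    "DVHMetrics",
    "cumulative_dvh",
    "v_at",
    "d_at",
    "max_dose_pct",
    "mean_dose_pct",
    "conformity_index",
    "dvh_metrics",
    "worst_case_metrics",
    "beam_specific_metrics",
    "wilcoxon_signed_rank",
    "paired_metric_table",
]

#: sample size up to which the exact signed-rank null distribution is used
EXACT_WILCOXON_N = 25


@dataclass(frozen=True)
class DVHMetrics:
    """Standard target-coverage metrics, doses as percent of prescription."""

    v95_pct: float
    d95_pct: float
    max_dose_pct: float
    mean_dose_pct: float
    conformity_index: float

    def __post_init__(self):
        if not (0.0 <= self.v95_pct <= 100.0):
            raise ValidationError("v95 must be in [0, 100]")
        if self.mean_dose_pct > self.max_dose_pct + 1e-9:
            raise ValidationError("mean dose cannot exceed max dose")
        if self.conformity_index < 0:
            raise ValidationError("conformity index must be >= 0")


def _masked(dose: DoseGrid | np.ndarray, mask: StructureMask) -> np.ndarray:
    arr = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    if arr.shape != mask.data.shape:
        raise ValidationError(f"dose shape {arr.shape} != mask shape {mask.data.shape}")
    vals = arr[mask.data]
    if vals.size == 0:
        raise ValidationError(f"mask '{mask.name}' is empty")
    return vals


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, n_bins: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH curve: (dose bin edges, volume fraction receiving >= edge).

    Edges span 0 to max(110% of prescription, max structure dose); the curve
    starts at 1.0 at zero dose and is monotone non-increasing.
    """
    vals = _masked(dose, mask)
    top = max(1.1 * dose.prescription_dose, float(vals.max()))
    edges = np.linspace(0.0, top, n_bins + 1)
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    return edges, frac


def v_at(dose: DoseGrid, mask: StructureMask, threshold_pct_of_rx: float) -> float:
    """Percent of structure volume receiving >= threshold% of prescription."""
    vals = _masked(dose, mask)
    thr = threshold_pct_of_rx / 100.0 * dose.prescription_dose
    return 100.0 * float((vals >= thr).mean())


def d_at(dose: DoseGrid, mask: StructureMask, volume_pct: float) -> float:
    """Largest dose (as % of prescription) received by >= volume_pct of the mask.

    Exact order-statistic evaluation: with n voxels sorted descending, Dp is
    the ceil(p*n/100)-th largest voxel dose.
    """
    if not (0.0 < volume_pct <= 100.0):
        raise ValidationError("volume_pct must be in (0, 100]")
    vals = np.sort(_masked(dose, mask))[::-1]
    k = math.ceil(volume_pct / 100.0 * vals.size)
    return 100.0 * float(vals[k - 1]) / dose.prescription_dose


def max_dose_pct(dose: DoseGrid, mask: StructureMask) -> float:
    """Maximum voxel dose in the structure, % of prescription."""
    return 100.0 * float(_masked(dose, mask).max()) / dose.prescription_dose


def mean_dose_pct(dose: DoseGrid, mask: StructureMask) -> float:
    """Mean voxel dose in the structure, % of prescription."""
    return 100.0 * float(_masked(dose, mask).mean()) / dose.prescription_dose


def conformity_index(dose: DoseGrid, ctv_mask: StructureMask, rx: float | None = None) -> float:
    """RTOG conformity index: volume of the 100% isodose / CTV volume."""
    if ctv_mask.n_voxels == 0:
        raise ValidationError("CTV mask is empty")
    if rx is None:
        rx = dose.prescription_dose
    return float((dose.dose >= rx).sum()) / ctv_mask.n_voxels


def dvh_metrics(dose: DoseGrid, ctv_mask: StructureMask, rx: float | None = None) -> DVHMetrics:
    """The five coverage metrics for one structure (conformity vs this mask)."""
    if rx is not None and rx != dose.prescription_dose:
        dose = DoseGrid(
            dose=dose.dose, spacing_mm=dose.spacing_mm, origin_mm=dose.origin_mm,
            prescription_dose=rx, per_beam=dose.per_beam,
        )
    return DVHMetrics(
        v95_pct=v_at(dose, ctv_mask, 95.0),
        d95_pct=d_at(dose, ctv_mask, 95.0),
        max_dose_pct=max_dose_pct(dose, ctv_mask),
        mean_dose_pct=mean_dose_pct(dose, ctv_mask),
        conformity_index=conformity_index(dose, ctv_mask),
    )


def worst_case_metrics(scenario_metrics: list[DVHMetrics]) -> DVHMetrics:
    """Per-metric worst case over scenarios: min coverage, max of max dose."""
    if len(scenario_metrics) == 0:
        raise ValidationError("need at least one scenario")
    return DVHMetrics(
        v95_pct=min(m.v95_pct for m in scenario_metrics),
        d95_pct=min(m.d95_pct for m in scenario_metrics),
        max_dose_pct=max(m.max_dose_pct for m in scenario_metrics),
        mean_dose_pct=min(m.mean_dose_pct for m in scenario_metrics),
        conformity_index=min(m.conformity_index for m in scenario_metrics),
    )


def beam_specific_metrics(
    per_beam_doses: list[np.ndarray],
    ctv_mask: StructureMask,
    rx: float,
    spacing_mm=None,
    origin_mm=None,
) -> list[DVHMetrics]:
    """Each beam's CTV metrics against rx / n_beams as its per-beam prescription.

    ``per_beam_doses`` are the per-beam dose contributions under the
    equal-beam-weight assumption (each beam carries 1/n of the prescription).
    """
    n = len(per_beam_doses)
    if n == 0:
        raise ValidationError("need at least one beam dose")
    rx_beam = rx / n
    out = []
    for arr in per_beam_doses:
        dg = DoseGrid(
            dose=np.asarray(arr),
            spacing_mm=np.asarray(spacing_mm if spacing_mm is not None else [1, 1, 1], dtype=float),
            origin_mm=np.asarray(origin_mm if origin_mm is not None else [0, 0, 0], dtype=float),
            prescription_dose=rx_beam,
        )
        out.append(dvh_metrics(dg, ctv_mask))
    return out


def _exact_signed_rank_cdf_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per value of 2*W+ (subset-sum distribution)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    Zero differences are dropped (reduced-sample convention); tied absolute
    differences receive average ranks.  W = min(W+, W-).  For n <= 25 the
    p-value is exact — the full null distribution of W+ over the 2^n equally
    likely sign assignments is enumerated by dynamic programming — otherwise a
    normal approximation with continuity and tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero; test undefined")
    ranks = _sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= EXACT_WILCOXON_N:
        doubled = np.round(2.0 * ranks).astype(int)
        counts = _exact_signed_rank_cdf_counts(doubled)
        w2 = int(round(2.0 * w))
        p = 2.0 * counts[: w2 + 1].sum() / 2.0**n
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        z = (w - mean + 0.5) / math.sqrt(var)
        p = 2.0 * _sstats.norm.cdf(z)
    return w, float(min(p, 1.0))


def paired_metric_table(records: list[dict]) -> pd.DataFrame:
    """Before/after comparison table: one row per (case, structure, metric).

    Each record needs keys ``case``, ``structure``, ``metric``,
    ``value_without_override``, ``value_with_override``; delta (with - without)
    and percent delta are derived.
    """
    df = pd.DataFrame.from_records(records)
    required = {"case", "structure", "metric", "value_without_override", "value_with_override"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"paired records missing keys: {sorted(missing)}")
    df["delta"] = df["value_with_override"] - df["value_without_override"]
    base = df["value_without_override"]
    df["pct_delta"] = np.where(base != 0, 100.0 * df["delta"] / base, np.nan)
    return df
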