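"""Range and water-equivalent-thickness analysis of integrated depth-dose curves.

A multilayer ionization chamber (MLIC) records the integrated depth-dose (IDD)
of a monoenergetic proton pencil beam.  Placing a device upstream shortens the
proton range by the device's water-equivalent thickness (WET).  This module
extracts the distal R80/R90 depths of an IDD, measures WET as the mean shift of
those depths between a reference and a sample curve, and converts WET to a
relative stopping power (SPR = WET / physical thickness), aggregated per device
over the sampled measurement locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import RangeNotFoundError, ValidationError

__all__ = [
    "DepthDoseCurve",
    "RangeMetrics",
    "WETMeasurement",
    "DeviceSPRResult",
    "distal_threshold_depth",
    "range_metrics",
    "wet_from_curves",
    "spr_at_location",
    "device_spr",
]


@dataclass(frozen=True)
class DepthDoseCurve:
    """A sampled IDD: strictly increasing depths (mm) and non-negative signal.

    The signal scale is arbitrary; only ratios to the curve maximum matter.
    """

    depths_mm: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths_mm, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "depths_mm", depths)
        object.__setattr__(self, "signal", signal)
        if depths.ndim != 1 or signal.ndim != 1 or depths.size != signal.size:
            raise ValidationError("depths and signal must be 1-D arrays of equal length")
        if depths.size < 10:
            raise ValidationError(f"curve needs >= 10 samples, got {depths.size}")
        if not np.all(np.diff(depths) > 0):
            raise ValidationError("depths must be strictly increasing")
        if not np.all(np.isfinite(depths)) or not np.all(np.isfinite(signal)):
            raise ValidationError("curve contains non-finite values")
        if np.any(signal < 0):
            raise ValidationError("signal must be non-negative")
        if signal.max() <= 0:
            raise ValidationError("signal is identically zero")

    def smoothed(self, window: int) -> "DepthDoseCurve":
        """Centered moving average of odd width ``window`` (1 = no-op)."""
        if window <= 1:
            return self
        if window % 2 == 0:
            raise ValidationError("smoothing window must be odd")
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(self.signal, pad, mode="edge")
        return DepthDoseCurve(self.depths_mm, np.convolve(padded, kernel, mode="valid"))


@dataclass(frozen=True)
class RangeMetrics:
    """Distal depths (mm) where the signal falls to 80% / 90% of the maximum.

    On the distal edge the signal decreases with depth, so r90_mm <= r80_mm.
    """

    r80_mm: float
    r90_mm: float

    def __post_init__(self):
        if self.r90_mm > self.r80_mm + 1e-9:
            raise ValidationError("distal R90 cannot be deeper than R80")


@dataclass(frozen=True)
class WETMeasurement:
    """WET, physical thickness and SPR at one measurement location."""

    location_id: str
    wet_mm: float
    thickness_mm: float
    spr: float = field(init=False)

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValidationError(f"thickness must be > 0, got {self.thickness_mm}")
        object.__setattr__(self, "spr", self.wet_mm / self.thickness_mm)


@dataclass(frozen=True)
class DeviceSPRResult:
    """Per-device SPR: arithmetic mean (and sd for n >= 2) over locations."""

    device: str
    measurements: tuple[WETMeasurement, ...]
    mean_spr: float = field(init=False)
    spr_sd: float | None = field(init=False)

    def __post_init__(self):
        if len(self.measurements) == 0:
            raise ValidationError("device SPR requires at least one measurement")
        object.__setattr__(self, "measurements", tuple(self.measurements))
        sprs = np.array([m.spr for m in self.measurements])
        object.__setattr__(self, "mean_spr", float(sprs.mean()))
        sd = float(sprs.std(ddof=1)) if sprs.size >= 2 else None
        object.__setattr__(self, "spr_sd", sd)


def distal_threshold_depth(curve: DepthDoseCurve, fraction: float) -> float:
    """Most distal depth where the interpolated signal equals ``fraction * max``.

    The crossing is searched on decreasing segments only, scanning from the
    deep end of the curve, so a spurious shallow dip (noise) never changes the
    result.  Linear interpolation between the bracketing samples; an exact hit
    on a sample returns that sample's depth.

    Raises
    ------
    RangeNotFoundError
        If no decreasing segment crosses the level (truncated curve).
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    z, s = curve.depths_mm, curve.signal
    level = fraction * s.max()
    for i in range(z.size - 2, -1, -1):
        s0, s1 = s[i], s[i + 1]
        if s0 > s1 and s0 >= level >= s1:
            if s0 == level:
                return float(z[i])
            t = (s0 - level) / (s0 - s1)
            return float(z[i] + t * (z[i + 1] - z[i]))
    raise RangeNotFoundError(
        f"distal edge never crosses {fraction:.0%} of maximum; curve may be truncated"
    )


def range_metrics(curve: DepthDoseCurve) -> RangeMetrics:
    """Distal R80 and R90 of a curve (fractions of the curve maximum)."""
    return RangeMetrics(
        r80_mm=distal_threshold_depth(curve, 0.8),
        r90_mm=distal_threshold_depth(curve, 0.9),
    )


def wet_from_curves(reference: DepthDoseCurve, sample: DepthDoseCurve) -> float:
    """WET (mm) as the mean distal R80/R90 shift from reference to sample.

    wet = ((r80_ref - r80_sample) + (r90_ref - r90_sample)) / 2.  A negative
    result (sample ranges deeper than reference) is physically suspect and
    emits a warning, but is returned as-is to support QA misuse detection.
    """
    ref = range_metrics(reference)
    sam = range_metrics(sample)
    wet = 0.5 * ((ref.r80_mm - sam.r80_mm) + (ref.r90_mm - sam.r90_mm))
    if wet < 0:
        warnings.warn(
            f"negative WET ({wet:.2f} mm): sample curve ranges deeper than "
            "reference; inputs may be swapped",
            stacklevel=2,
        )
    return float(wet)


def spr_at_location(wet_mm: float, thickness_mm: float, location_id: str = "loc") -> WETMeasurement:
    """SPR at one location: measured WET divided by physical thickness."""
    return WETMeasurement(location_id=location_id, wet_mm=float(wet_mm), thickness_mm=float(thickness_mm))


def device_spr(measurements: list[WETMeasurement], device: str = "device") -> DeviceSPRResult:
    """Aggregate per-location SPRs into a device mean (and sd for n >= 2)."""
    return DeviceSPRResult(device=device, measurements=tuple(measurements))
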