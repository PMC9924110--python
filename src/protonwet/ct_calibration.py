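"""Treatment-planning-system side: CT calibration, ray tracing, SPR comparison.

A clinical TPS converts CT numbers (HU) to mass density and then to relative
stopping power (RSP) through piecewise-linear calibration tables, and measures
a device's water-equivalent thickness (WET) as the radiological path length of
a line through the device.  The TPS SPR at a marked location is WET divided by
the physical thickness along the same line.  Comparing TPS and measured SPRs
gives the percent error and the WET error in millimetres.

Grids use axis order (z, y, x); world position of voxel index ``i`` along an
axis is ``origin + (i + 0.5) * spacing``, i.e. voxel ``i`` spans
``[origin + i*spacing, origin + (i+1)*spacing)``.  All lengths are mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, GeometryError, ShapeMismatchError, ValidationError
from .idd_wet import DeviceSPRResult, WETMeasurement

__all__ = [
    "CalibrationCurve",
    "Phantom",
    "StructureMask",
    "Ray",
    "SPRComparison",
    "hu_to_density",
    "density_to_rsp",
    "hu_to_rsp",
    "ray_trace_wet",
    "device_thickness",
    "tps_spr_at_location",
    "compare_spr",
    "default_calibration",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Two-stage piecewise-linear calibration: HU -> density -> RSP.

    ``hu_nodes`` (strictly increasing) map to ``density_nodes`` (g/cm^3,
    non-decreasing); a second table keyed by ``rsp_density_nodes`` maps density
    to ``rsp_nodes`` (non-decreasing).  Out-of-domain inputs clamp to the end
    nodes, mirroring TPS behaviour.  A direct HU -> RSP table can be loaded via
    :meth:`from_hu_rsp`, which routes density through the RSP values.
    """

    hu_nodes: np.ndarray
    density_nodes: np.ndarray
    rsp_density_nodes: np.ndarray
    rsp_nodes: np.ndarray

    def __post_init__(self):
        hu = np.asarray(self.hu_nodes, dtype=float)
        den = np.asarray(self.density_nodes, dtype=float)
        rden = np.asarray(self.rsp_density_nodes, dtype=float)
        rsp = np.asarray(self.rsp_nodes, dtype=float)
        for name, arr in [("hu", hu), ("density", den), ("rsp_density", rden), ("rsp", rsp)]:
            if arr.ndim != 1 or arr.size < 2:
                raise CalibrationError(f"{name} table needs >= 2 nodes")
        if hu.size != den.size:
            raise CalibrationError("hu_nodes and density_nodes lengths differ")
        if rden.size != rsp.size:
            raise CalibrationError("rsp_density_nodes and rsp_nodes lengths differ")
        if not np.all(np.diff(hu) > 0):
            raise CalibrationError("hu_nodes must be strictly increasing")
        if np.any(np.diff(den) < 0) or np.any(np.diff(rden) < 0) or np.any(np.diff(rsp) < 0):
            raise CalibrationError("density and rsp tables must be non-decreasing")
        if np.any(den < 0) or np.any(rsp < 0):
            raise CalibrationError("density and rsp must be non-negative")
        object.__setattr__(self, "hu_nodes", hu)
        object.__setattr__(self, "density_nodes", den)
        object.__setattr__(self, "rsp_density_nodes", rden)
        object.__setattr__(self, "rsp_nodes", rsp)

    @classmethod
    def from_hu_rsp(cls, hu_nodes, rsp_nodes) -> "CalibrationCurve":
        """Build from a single direct HU -> RSP table."""
        rsp = np.asarray(rsp_nodes, dtype=float)
        return cls(hu_nodes=hu_nodes, density_nodes=rsp, rsp_density_nodes=rsp, rsp_nodes=rsp)

    def hu_to_density(self, hu):
        return np.interp(hu, self.hu_nodes, self.density_nodes)

    def density_to_rsp(self, density):
        return np.interp(density, self.rsp_density_nodes, self.rsp_nodes)

    def hu_to_rsp(self, hu):
        return self.density_to_rsp(self.hu_to_density(hu))

    def hu_for_rsp(self, rsp: float) -> float:
        """HU whose calibrated RSP is closest to ``rsp`` (inverse lookup).

        Used to design phantoms with a prescribed TPS-side RSP.  Flat segments
        of the composite curve return their shallowest HU.
        """
        hu_fine = np.linspace(self.hu_nodes[0], self.hu_nodes[-1], 20001)
        rsp_fine = self.hu_to_rsp(hu_fine)
        return float(np.interp(rsp, rsp_fine, hu_fine))


def hu_to_density(hu, curve: CalibrationCurve):
    """Piecewise-linear HU -> mass density (g/cm^3), clamped at the end nodes."""
    return curve.hu_to_density(hu)


def density_to_rsp(density, curve: CalibrationCurve):
    """Piecewise-linear density -> relative stopping power, clamped."""
    return curve.density_to_rsp(density)


def hu_to_rsp(hu, curve: CalibrationCurve):
    """Composite HU -> RSP conversion (HU -> density -> RSP)."""
    return curve.hu_to_rsp(hu)


def default_calibration() -> CalibrationCurve:
    """Clinical-style two-stage calibration with air/lung/adipose/water/bone nodes.

    These node values are package fixtures representative of a clinical
    biological-sample curve; they are not measured data.
    """
    hu = np.array([-1000.0, -800.0, -500.0, -100.0, 0.0, 60.0, 1000.0, 2000.0, 3000.0])
    density = np.array([0.00121, 0.200, 0.501, 0.930, 1.000, 1.060, 1.590, 2.120, 2.700])
    rsp_density = np.array([0.00121, 0.200, 0.501, 0.930, 1.000, 1.060, 1.590, 2.120, 2.700])
    rsp = np.array([0.00106, 0.203, 0.508, 0.944, 1.000, 1.052, 1.480, 1.920, 2.380])
    return CalibrationCurve(hu, density, rsp_density, rsp)


@dataclass
class Phantom:
    """Regular voxel grid of CT numbers, axis order (z, y, x)."""

    hu: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.hu.ndim != 3:
            raise ValidationError("phantom grid must be 3-D (z, y, x)")
        if self.spacing_mm.shape != (3,) or self.origin_mm.shape != (3,):
            raise ValidationError("spacing and origin must be length-3 vectors")
        if np.any(self.spacing_mm <= 0):
            raise ValidationError("spacing must be positive")
        if not np.all(np.isfinite(self.hu)):
            raise ValidationError("phantom contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def rsp_grid(self, curve: CalibrationCurve) -> np.ndarray:
        return curve.hu_to_rsp(self.hu)


@dataclass
class StructureMask:
    """Boolean voxel mask sharing a phantom's grid."""

    name: str
    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("mask must be 3-D (z, y, x)")

    @classmethod
    def like(cls, phantom: Phantom, data: np.ndarray, name: str) -> "StructureMask":
        if data.shape != phantom.shape:
            raise ShapeMismatchError(
                f"mask shape {data.shape} != phantom shape {phantom.shape}"
            )
        return cls(name=name, data=data, spacing_mm=phantom.spacing_mm, origin_mm=phantom.origin_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def check_same_grid(phantom: Phantom, mask: StructureMask) -> None:
    if mask.data.shape != phantom.shape:
        raise ShapeMismatchError(
            f"mask '{mask.name}' shape {mask.data.shape} != phantom shape {phantom.shape}"
        )
    if not np.allclose(mask.spacing_mm, phantom.spacing_mm) or not np.allclose(
        mask.origin_mm, phantom.origin_mm
    ):
        raise ShapeMismatchError(f"mask '{mask.name}' grid geometry differs from phantom")


@dataclass(frozen=True)
class Ray:
    """Directed line segment: origin, unit direction, length (mm)."""

    origin_mm: np.ndarray
    direction: np.ndarray
    length_mm: float

    def __post_init__(self):
        o = np.asarray(self.origin_mm, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if norm == 0:
            raise ValidationError("ray direction must be non-zero")
        object.__setattr__(self, "origin_mm", o)
        object.__setattr__(self, "direction", d / norm)
        if self.length_mm <= 0:
            raise ValidationError("ray length must be positive")

    @classmethod
    def through_points(cls, p0, p1) -> "Ray":
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        return cls(origin_mm=p0, direction=p1 - p0, length_mm=float(np.linalg.norm(p1 - p0)))


def _siddon_segments(shape, spacing, origin, ray: Ray):
    """Voxel indices and intersection lengths of a ray with a regular grid.

    Exact voxel-boundary traversal: parametric crossings with all grid planes
    are merged and each inter-crossing segment is attributed to the voxel
    containing its midpoint.  Returns (indices (N, 3) int array, lengths (N,)).
    """
    p0 = ray.origin_mm
    d = ray.direction
    lo = np.asarray(origin, dtype=float)
    hi = lo + np.asarray(shape) * np.asarray(spacing)

    t0, t1 = 0.0, float(ray.length_mm)
    for a in range(3):
        if d[a] == 0.0:
            if not (lo[a] <= p0[a] <= hi[a]):
                return np.empty((0, 3), dtype=int), np.empty(0)
        else:
            ta = (lo[a] - p0[a]) / d[a]
            tb = (hi[a] - p0[a]) / d[a]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        return np.empty((0, 3), dtype=int), np.empty(0)

    crossings = [np.array([t0, t1])]
    for a in range(3):
        if d[a] != 0.0:
            planes = lo[a] + np.arange(shape[a] + 1) * spacing[a]
            t = (planes - p0[a]) / d[a]
            crossings.append(t[(t > t0) & (t < t1)])
    t = np.unique(np.concatenate(crossings))
    mids = p0[None, :] + 0.5 * (t[:-1] + t[1:])[:, None] * d[None, :]
    idx = np.floor((mids - lo[None, :]) / np.asarray(spacing)[None, :]).astype(int)
    lengths = np.diff(t)
    keep = np.all((idx >= 0) & (idx < np.asarray(shape)[None, :]), axis=1) & (lengths > 1e-12)
    return idx[keep], lengths[keep]


def ray_trace_wet(
    phantom: Phantom,
    ray: Ray,
    curve: CalibrationCurve,
    restrict_mask: StructureMask | None = None,
    rsp_grid: np.ndarray | None = None,
) -> float:
    """Radiological path length (WEPL, mm) of a ray through the phantom.

    Sum over traversed voxel segments of segment length times voxel RSP.  With
    ``restrict_mask``, only segments inside the mask contribute (the TPS "WET
    of the device" measurement).  ``rsp_grid`` bypasses the HU conversion, e.g.
    for density-overridden grids.
    """
    if restrict_mask is not None:
        check_same_grid(phantom, restrict_mask)
    idx, lengths = _siddon_segments(phantom.shape, phantom.spacing_mm, phantom.origin_mm, ray)
    if idx.shape[0] == 0:
        warnings.warn("ray does not intersect the grid; WEPL = 0", stacklevel=2)
        return 0.0
    if rsp_grid is None:
        rsp_grid = phantom.rsp_grid(curve)
    vals = rsp_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    if restrict_mask is not None:
        vals = vals * restrict_mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.dot(lengths, vals))


def device_thickness(mask: StructureMask, ray: Ray) -> float:
    """Physical in-mask path length (mm) of a ray through a structure."""
    idx, lengths = _siddon_segments(mask.data.shape, mask.spacing_mm, mask.origin_mm, ray)
    if idx.shape[0] == 0:
        warnings.warn("ray does not intersect the grid; thickness = 0", stacklevel=2)
        return 0.0
    inside = mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    thickness = float(lengths[inside].sum())
    if thickness == 0.0:
        warnings.warn(f"ray misses mask '{mask.name}'; thickness = 0", stacklevel=2)
    return thickness


def tps_spr_at_location(
    phantom: Phantom,
    mask: StructureMask,
    ray: Ray,
    curve: CalibrationCurve,
    n_repeats: int = 3,
    jitter_sigma_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    location_id: str = "loc",
    rsp_grid: np.ndarray | None = None,
) -> WETMeasurement:
    """TPS-side SPR at one marked location: in-mask WET / physical thickness.

    ``n_repeats`` averages repeated evaluations; with ``jitter_sigma_mm > 0``
    each repeat offsets the ray perpendicular to its direction (emulating
    manual repeat measurements), otherwise repeats are identical.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    if jitter_sigma_mm > 0 and rng is None:
        rng = np.random.default_rng()
    wets, thicknesses = [], []
    for _ in range(n_repeats):
        r = ray
        if jitter_sigma_mm > 0:
            perp = rng.normal(0.0, jitter_sigma_mm, size=3)
            perp -= np.dot(perp, ray.direction) * ray.direction
            r = Ray(ray.origin_mm + perp, ray.direction, ray.length_mm)
        wets.append(ray_trace_wet(phantom, r, curve, restrict_mask=mask, rsp_grid=rsp_grid))
        thicknesses.append(device_thickness(mask, r))
    thickness = float(np.mean(thicknesses))
    if thickness <= 0:
        raise GeometryError(f"ray does not cross mask '{mask.name}' (zero thickness)")
    return WETMeasurement(location_id=location_id, wet_mm=float(np.mean(wets)), thickness_mm=thickness)


@dataclass(frozen=True)
class SPRComparison:
    """TPS vs measured SPR for one device.

    ``percent_diff`` = 100 * (tps - measured) / measured; ``wet_diff_mm`` =
    (tps - measured) * thickness.  Instances built from published per-location
    aggregates may carry those columns directly (see ``pipeline_io``).
    """

    device: str
    tps_spr: float
    measured_spr: float
    percent_diff: float
    wet_diff_mm: float
    tps_spr_sd: float | None = None
    measured_spr_sd: float | None = None
    percent_diff_sd: float | None = None
    wet_diff_sd_mm: float | None = None


def compare_spr(
    tps: DeviceSPRResult, measured: DeviceSPRResult, thickness_mm: float
) -> SPRComparison:
    """Percent SPR difference and WET error (mm) between TPS and measurement."""
    if tps.device != measured.device:
        raise ValidationError(f"device mismatch: {tps.device!r} vs {measured.device!r}")
    if measured.mean_spr <= 0:
        raise ValidationError("measured SPR must be positive")
    if thickness_mm <= 0:
        raise ValidationError("thickness must be positive")
    diff = tps.mean_spr - measured.mean_spr
    return SPRComparison(
        device=tps.device,
        tps_spr=tps.mean_spr,
        measured_spr=measured.mean_spr,
        percent_diff=100.0 * diff / measured.mean_spr,
        wet_diff_mm=diff * thickness_mm,
        tps_spr_sd=tps.spr_sd,
        measured_spr_sd=measured.spr_sd,
    )
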