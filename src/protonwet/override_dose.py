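"""Density override and broad-beam SOBP dose recalculation.

The measured device SPR is imposed on the planning grid by scaling the
relative stopping power (RSP) inside the device contour by the ratio
``measured_spr / tps_spr`` — SPR is approximately proportional to mass density
for a fixed material, so a ratio scaling in RSP space unifies the CT-number
and density override pathways of commercial systems.  Dose is then
recalculated with a deterministic broad-beam engine: for every voxel the
water-equivalent path length (WEPL) from the beam entrance is accumulated
along the beam direction and fed to an analytic spread-out-Bragg-peak (SOBP)
depth-dose; no lateral scatter or beam divergence is modelled.  Robustness
scenarios perturb the setup (rigid patient shifts) and the range (global RSP
scaling).

The axial grid must be square (ny == nx) so beam-frame rotation preserves the
array shape; 90-degree multiples rotate exactly, other angles use bilinear
resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct_calibration import (
    CalibrationCurve,
    Phantom,
    StructureMask,
    check_same_grid,
)
from .errors import GeometryError, ValidationError
from .idd_wet import DeviceSPRResult

__all__ = [
    "BeamSpec",
    "PlanSpec",
    "OverrideRecord",
    "Scenario",
    "ScenarioSet",
    "DoseGrid",
    "make_override",
    "apply_override",
    "sobp_depth_dose",
    "compute_dose",
    "scenario_doses",
    "build_scenarios",
]

AIR_HU = -1000.0

# total length of the raised-cosine distal ramp per unit 80%-20% falloff width:
# 0.5*(1+cos(pi*x)) crosses 0.8 at x=0.29517 and 0.2 at x=0.70483
_RAMP_LENGTH_PER_FALLOFF = 1.0 / (np.arccos(-0.6) / np.pi - np.arccos(0.6) / np.pi)


@dataclass(frozen=True)
class BeamSpec:
    """One beam: gantry angle in the axial plane, SOBP range/modulation (WEPL mm).

    Angle convention (axial (y, x) plane): 0 -> beam travels +y, 90 -> +x,
    180 -> -y, 270 -> -x.
    """

    gantry_angle_deg: float
    isocenter_mm: tuple[float, float, float]
    sobp_range_mm: float
    sobp_modulation_mm: float
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ValidationError("beam weight must be > 0")
        if not (0 < self.sobp_modulation_mm <= self.sobp_range_mm):
            raise ValidationError("need 0 < modulation <= range")


@dataclass(frozen=True)
class PlanSpec:
    """A multi-beam SOBP plan with robustness-evaluation parameters."""

    beams: tuple[BeamSpec, ...]
    prescription_dose: float
    setup_uncertainty_mm: float = 3.0
    range_uncertainty_fraction: float = 0.035

    def __post_init__(self):
        if not (2 <= len(self.beams) <= 4):
            raise ValidationError("plans must have between 2 and 4 beams")
        total = sum(b.weight for b in self.beams)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"beam weights must sum to 1, got {total}")
        if self.prescription_dose <= 0:
            raise ValidationError("prescription_dose must be > 0")
        if self.setup_uncertainty_mm < 0 or self.range_uncertainty_fraction < 0:
            raise ValidationError("uncertainties must be >= 0")


@dataclass(frozen=True)
class OverrideRecord:
    """Density-override factor for one device: measured SPR / TPS SPR."""

    device: str
    tps_spr: float
    measured_spr: float
    factor: float = field(init=False)

    def __post_init__(self):
        if self.tps_spr <= 0 or self.measured_spr <= 0:
            raise ValidationError("override requires positive TPS and measured SPR")
        object.__setattr__(self, "factor", self.measured_spr / self.tps_spr)


def make_override(tps: DeviceSPRResult, measured: DeviceSPRResult) -> OverrideRecord:
    """Override record from TPS-side and measured device SPR aggregates."""
    if tps.device != measured.device:
        raise ValidationError(f"device mismatch: {tps.device!r} vs {measured.device!r}")
    return OverrideRecord(device=tps.device, tps_spr=tps.mean_spr, measured_spr=measured.mean_spr)


def apply_override(rsp_grid: np.ndarray, mask: StructureMask, record: OverrideRecord) -> np.ndarray:
    """Scale RSP inside the mask by the override factor; outside unchanged.

    After this, a TPS SPR re-measurement through the mask returns the measured
    SPR exactly (the device voxels are homogeneous).
    """
    if mask.data.shape != rsp_grid.shape:
        raise ValidationError(
            f"mask shape {mask.data.shape} != rsp grid shape {rsp_grid.shape}"
        )
    out = rsp_grid.copy()
    if not mask.data.any():
        warnings.warn(f"override mask '{mask.name}' is empty; no-op", stacklevel=2)
        return out
    out[mask.data] *= record.factor
    return out


def sobp_depth_dose(
    wepl_mm,
    range_mm: float,
    modulation_mm: float,
    distal_falloff_mm: float = 4.0,
    proximal_ramp_mm: float = 10.0,
):
    """Relative SOBP dose at water-equivalent depth(s) ``wepl_mm``.

    Unit plateau on [range - modulation, range]; raised-cosine ramps on both
    sides.  The distal ramp is scaled so its 80%-to-20% distance equals
    ``distal_falloff_mm`` exactly (total ramp length ~2.44 x falloff, hence
    zero beyond range + 3 x falloff); the proximal ramp rises from zero over
    ``proximal_ramp_mm``.  Total function: any real input returns a value in
    [0, 1].
    """
    if distal_falloff_mm <= 0:
        raise ValidationError("distal_falloff_mm must be > 0")
    if proximal_ramp_mm <= 0:
        raise ValidationError("proximal_ramp_mm must be > 0")
    w = np.asarray(wepl_mm, dtype=float)
    plateau_start = range_mm - modulation_mm
    ramp_len = distal_falloff_mm * _RAMP_LENGTH_PER_FALLOFF
    dose = np.zeros_like(w)

    plateau = (w >= plateau_start) & (w <= range_mm)
    dose[plateau] = 1.0

    distal = (w > range_mm) & (w < range_mm + ramp_len)
    u = (w[distal] - range_mm) / ramp_len
    dose[distal] = 0.5 * (1.0 + np.cos(np.pi * u))

    proximal = (w < plateau_start) & (w > plateau_start - proximal_ramp_mm)
    v = (plateau_start - w[proximal]) / proximal_ramp_mm
    dose[proximal] = 0.5 * (1.0 + np.cos(np.pi * v))
    return dose if dose.ndim else float(dose)


# ---------------------------------------------------------------------------
# beam-frame resampling


def _beam_frame_coords(shape, angle_deg: float, inverse: bool):
    """Index coordinates mapping between patient frame and beam frame.

    Beam frame: axis 2 (v) is the beam travel direction, axis 1 (u) lateral.
    Requires a square axial grid.  For 90-degree multiples the sample points
    land exactly on grid indices, making the resampling exact.
    """
    nz, ny, nx = shape
    if ny != nx:
        raise ValidationError("dose engine requires a square axial grid (ny == nx)")
    n = ny
    c = (n - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # snap to exact values at 90-degree multiples
    if abs(angle_deg % 90.0) < 1e-9:
        cos_t, sin_t = round(cos_t), round(sin_t)
    a = np.arange(n) - c
    U, V = np.meshgrid(a, a, indexing="ij")
    if not inverse:
        # B[z, u, v] = A[z, y, x]: (y, x) offset = v*d + u*p, d=(cos,sin), p=(-sin,cos)
        Y = c + V * cos_t - U * sin_t
        X = c + V * sin_t + U * cos_t
    else:
        # A[z, y, x] = B[z, u, v]; here (U, V) grids play the role of (y, x)
        Yg, Xg = U, V
        Unew = -Yg * sin_t + Xg * cos_t
        Vnew = Yg * cos_t + Xg * sin_t
        Y, X = c + Unew, c + Vnew
    Z = np.broadcast_to(np.arange(nz)[:, None, None], (nz, n, n))
    Y = np.broadcast_to(Y[None], (nz, n, n))
    X = np.broadcast_to(X[None], (nz, n, n))
    return np.stack([Z, Y, X])


def _to_beam_frame(arr: np.ndarray, angle_deg: float, cval: float = 0.0) -> np.ndarray:
    coords = _beam_frame_coords(arr.shape, angle_deg, inverse=False)
    return ndimage.map_coordinates(arr.astype(float), coords, order=1, cval=cval)


def _from_beam_frame(arr: np.ndarray, angle_deg: float, cval: float = 0.0) -> np.ndarray:
    coords = _beam_frame_coords(arr.shape, angle_deg, inverse=True)
    return ndimage.map_coordinates(arr.astype(float), coords, order=1, cval=cval)


@dataclass
class DoseGrid:
    """Absolute dose on the phantom grid, with optional per-beam components."""

    dose: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    prescription_dose: float
    per_beam: dict[int, np.ndarray] | None = None


def compute_apertures(
    ctv_mask: StructureMask, plan: PlanSpec, aperture_margin_mm: float = 6.0
) -> dict[int, np.ndarray]:
    """Per-beam lateral apertures: CTV projected along the beam axis, dilated.

    Returned in beam-frame (z, u) coordinates; fixed relative to the beams, so
    setup-shift scenarios reuse the nominal apertures.
    """
    apertures = {}
    for i, beam in enumerate(plan.beams):
        ctv_b = _to_beam_frame(ctv_mask.data.astype(float), beam.gantry_angle_deg) > 0.5
        proj = ctv_b.any(axis=2)
        margin_vox = int(round(aperture_margin_mm / float(ctv_mask.spacing_mm[1])))
        if margin_vox > 0:
            proj = ndimage.binary_dilation(proj, iterations=margin_vox)
        apertures[i] = proj
    return apertures


def compute_dose(
    phantom: Phantom,
    masks: dict[str, StructureMask],
    plan: PlanSpec,
    calibration: CalibrationCurve,
    overrides: list[tuple[StructureMask, OverrideRecord]] | None = None,
    rsp_scale: float = 1.0,
    distal_falloff_mm: float = 4.0,
    proximal_ramp_mm: float = 10.0,
    aperture_margin_mm: float = 6.0,
    apertures: dict[int, np.ndarray] | None = None,
    keep_per_beam: bool = False,
) -> DoseGrid:
    """Broad-beam dose: per voxel and beam, SOBP dose at the voxel's WEPL.

    WEPL is accumulated from the grid boundary along the beam direction
    (cumulative RSP x step in the beam frame); each beam contributes
    ``weight * prescription * sobp_depth_dose(wepl)`` inside its aperture.
    ``rsp_scale`` multiplies the whole RSP grid (range-uncertainty scenarios);
    ``overrides`` rescale device RSP before dose calculation.  Deterministic.
    """
    if "ctv" not in masks and apertures is None:
        raise ValidationError("compute_dose needs a 'ctv' mask (or precomputed apertures)")
    for m in masks.values():
        check_same_grid(phantom, m)
    rsp = phantom.rsp_grid(calibration)
    for mask, record in overrides or []:
        rsp = apply_override(rsp, mask, record)
    rsp = rsp * rsp_scale
    if apertures is None:
        apertures = compute_apertures(masks["ctv"], plan, aperture_margin_mm)

    step = float(phantom.spacing_mm[2])
    if not np.allclose(phantom.spacing_mm[1], phantom.spacing_mm[2]):
        raise ValidationError("dose engine requires isotropic axial spacing (dy == dx)")
    total = np.zeros(phantom.shape)
    per_beam: dict[int, np.ndarray] = {}
    for i, beam in enumerate(plan.beams):
        rsp_b = _to_beam_frame(rsp, beam.gantry_angle_deg, cval=0.0)
        wepl = (np.cumsum(rsp_b, axis=2) - 0.5 * rsp_b) * step
        dose_b = sobp_depth_dose(
            wepl, beam.sobp_range_mm, beam.sobp_modulation_mm,
            distal_falloff_mm=distal_falloff_mm, proximal_ramp_mm=proximal_ramp_mm,
        )
        dose_b *= apertures[i][:, :, None]
        dose_p = _from_beam_frame(dose_b, beam.gantry_angle_deg, cval=0.0)
        contrib = beam.weight * plan.prescription_dose * dose_p
        total += contrib
        if keep_per_beam:
            per_beam[i] = contrib
    return DoseGrid(
        dose=total,
        spacing_mm=phantom.spacing_mm,
        origin_mm=phantom.origin_mm,
        prescription_dose=plan.prescription_dose,
        per_beam=per_beam if keep_per_beam else None,
    )


# ---------------------------------------------------------------------------
# robustness scenarios


@dataclass(frozen=True)
class Scenario:
    """One uncertainty scenario: rigid setup shift (mm) + global range scale."""

    name: str
    shift_mm: tuple[float, float, float]
    range_scale: float


@dataclass(frozen=True)
class ScenarioSet:
    """Nominal plus exactly 12 scenarios: 6 cardinal shifts x 2 range scales."""

    nominal: Scenario
    scenarios: tuple[Scenario, ...]

    def __post_init__(self):
        if len(self.scenarios) != 12:
            raise ValidationError(f"expected 12 non-nominal scenarios, got {len(self.scenarios)}")

    def all(self) -> tuple[Scenario, ...]:
        return (self.nominal, *self.scenarios)


def build_scenarios(setup_uncertainty_mm: float, range_uncertainty_fraction: float) -> ScenarioSet:
    """6 cardinal setup shifts (±z, ±y, ±x) x 2 range scales (1 ± fraction)."""
    axes = ["z", "y", "x"]
    scenarios = []
    for ax in range(3):
        for sign in (+1.0, -1.0):
            shift = [0.0, 0.0, 0.0]
            shift[ax] = sign * setup_uncertainty_mm
            for rsign, tag in ((+1.0, "up"), (-1.0, "down")):
                scenarios.append(
                    Scenario(
                        name=f"{axes[ax]}{'+' if sign > 0 else '-'}_range_{tag}",
                        shift_mm=tuple(shift),
                        range_scale=1.0 + rsign * range_uncertainty_fraction,
                    )
                )
    nominal = Scenario(name="nominal", shift_mm=(0.0, 0.0, 0.0), range_scale=1.0)
    return ScenarioSet(nominal=nominal, scenarios=tuple(scenarios))


def scenario_doses(
    phantom: Phantom,
    masks: dict[str, StructureMask],
    plan: PlanSpec,
    calibration: CalibrationCurve,
    overrides: list[tuple[StructureMask, OverrideRecord]] | None = None,
    **engine_kwargs,
) -> dict[str, DoseGrid]:
    """Nominal + 12 scenario doses, each resampled back onto the patient grid.

    A setup shift moves the patient rigidly in the room (HU grid and override
    masks resampled by +shift; apertures stay fixed to the beams); the
    resulting room-frame dose is resampled back by -shift so all scenario
    doses live on the patient anatomy.  The range scale multiplies RSP
    globally.  The inverse range scenario (scale 1 - f) shifts every distal
    edge distally; 1 + f shifts it proximally.
    """
    apertures = compute_apertures(
        masks["ctv"], plan, engine_kwargs.get("aperture_margin_mm", 6.0)
    )
    out: dict[str, DoseGrid] = {}
    sset = build_scenarios(plan.setup_uncertainty_mm, plan.range_uncertainty_fraction)
    for sc in sset.all():
        shift_vox = np.asarray(sc.shift_mm) / phantom.spacing_mm
        if np.any(np.abs(shift_vox) > 0):
            hu_s = ndimage.shift(phantom.hu, shift_vox, order=1, cval=AIR_HU)
            phantom_s = Phantom(hu=hu_s, spacing_mm=phantom.spacing_mm, origin_mm=phantom.origin_mm)
            masks_s = {
                name: StructureMask(
                    name=m.name,
                    data=ndimage.shift(m.data.astype(float), shift_vox, order=0, cval=0.0) > 0.5,
                    spacing_mm=m.spacing_mm,
                    origin_mm=m.origin_mm,
                )
                for name, m in masks.items()
            }
            overrides_s = [
                (masks_s.get(mask.name, mask), rec) for mask, rec in (overrides or [])
            ]
            if not any(m.data.any() for m in masks_s.values()):
                raise GeometryError(f"scenario {sc.name}: shifted anatomy exits the grid")
        else:
            phantom_s, overrides_s = phantom, overrides
        dg = compute_dose(
            phantom_s, masks, plan, calibration,
            overrides=overrides_s, rsp_scale=sc.range_scale, apertures=apertures,
            **{k: v for k, v in engine_kwargs.items() if k != "aperture_margin_mm"},
        )
        if np.any(np.abs(shift_vox) > 0):
            dg.dose = ndimage.shift(dg.dose, -shift_vox, order=1, cval=0.0)
        out[sc.name] = dg
    return out
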