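"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the physical study conditions:

* :func:`generate_idd` — a multilayer-ionization-chamber (MLIC) readout of a
  monoenergetic pencil-beam integrated depth-dose (IDD), with and without a
  device of known water-equivalent thickness (WET) upstream.  The pristine
  peak is an analytic power-law depth dose (exponents -0.435 / 0.565, the
  classic no-straggling Bragg form) convolved with a Gaussian of width
  ``straggling_sigma_mm``; a device upstream shifts the whole curve shallower
  by exactly its WET (a declared approximation valid for thin, low-density
  devices — scatter and straggling changes are neglected).
* :func:`generate_device_phantom` — a CT scan of a homogeneous device slab in
  air whose reported HU maps, through a chosen calibration curve, to a TPS RSP
  that deviates from the ground-truth RSP by a known, controlled fraction.
* :func:`generate_patient_phantom` — a patient-like cylinder (water body, CTV
  and organ-at-risk spheres, posterior cushion slab) together with a multi-beam
  spread-out-Bragg-peak plan whose range/modulation are set from ray-traced
  water-equivalent path lengths so the nominal plan covers the CTV.

Detector depth convention: chamber ``i`` is centred at ``(i + 0.5) * pitch``.
Identical seeds reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .ct_calibration import (
    CalibrationCurve,
    Phantom,
    Ray,
    StructureMask,
    default_calibration,
    ray_trace_wet,
)
from .errors import (
    GeometryError,
    RangeTruncationError,
    ResolutionError,
    ValidationError,
)
from .idd_wet import DepthDoseCurve

__all__ = [
    "BraggModelParams",
    "DeviceSpec",
    "OARSpec",
    "CaseSpec",
    "GridSpec",
    "LocationTruth",
    "DeviceGroundTruth",
    "PristineBraggModel",
    "generate_idd",
    "generate_idd_pair",
    "generate_device_phantom",
    "generate_patient_phantom",
]

AIR_HU = -1000.0
WATER_HU = 0.0

#: Default distal R80 (mm water) of a 200 MeV proton beam (ICRU-style water range).
RANGE_200MEV_MM = 259.0


@dataclass(frozen=True)
class BraggModelParams:
    """Parameters of the synthetic MLIC acquisition.

    ``nominal_range_mm`` is the distal R80 of the pristine (reference) peak in
    water; ``plateau_entrance_ratio`` sets entrance signal / peak signal;
    ``noise_cv`` is the coefficient of variation of independent multiplicative
    Gaussian noise per chamber.
    """

    nominal_range_mm: float = RANGE_200MEV_MM
    straggling_sigma_mm: float = 3.0
    plateau_entrance_ratio: float = 0.30
    chamber_pitch_mm: float = 2.0
    n_chambers: int = 180
    noise_cv: float = 0.005
    seed: int | None = None

    def __post_init__(self):
        if self.nominal_range_mm <= 0:
            raise ValidationError("nominal_range_mm must be > 0")
        if not (0 < self.straggling_sigma_mm < self.nominal_range_mm):
            raise ValidationError("straggling_sigma_mm must be in (0, nominal_range_mm)")
        if not (0 < self.plateau_entrance_ratio < 1):
            raise ValidationError("plateau_entrance_ratio must be in (0, 1)")
        if self.chamber_pitch_mm <= 0:
            raise ValidationError("chamber_pitch_mm must be > 0")
        if self.n_chambers < 10:
            raise ValidationError("n_chambers must be >= 10")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.n_chambers * self.chamber_pitch_mm <= self.nominal_range_mm:
            raise ValidationError("detector span must exceed nominal_range_mm")

    @property
    def chamber_depths_mm(self) -> np.ndarray:
        return (np.arange(self.n_chambers) + 0.5) * self.chamber_pitch_mm


class PristineBraggModel:
    """Analytic pristine Bragg curve, normalized to unit peak.

    Built once per (range, sigma, plateau ratio) on a 0.01 mm grid: the
    no-straggling power-law depth dose

        d(z) = (R - z)^(-0.435) + k * (R - z)^(0.565),   z < R

    is cell-averaged (the -0.435 singularity is integrable, so exact cell
    integrals are used) and convolved with the straggling Gaussian.  The
    plateau weight ``k`` is solved by bisection so the entrance/peak ratio
    matches the requested value, and the depth axis is shifted so the distal
    R80 sits exactly at ``nominal_range_mm``.
    """

    FINE_STEP_MM = 0.01
    _P_PEAK = 0.565  # 1 - 0.435, antiderivative exponent of the peak term

    def __init__(self, nominal_range_mm: float, straggling_sigma_mm: float,
                 plateau_entrance_ratio: float):
        self.nominal_range_mm = nominal_range_mm
        self.sigma = straggling_sigma_mm
        h = self.FINE_STEP_MM
        zmin = -8.0 * self.sigma
        zmax = nominal_range_mm + 10.0 * self.sigma
        edges = np.arange(zmin, zmax + h, h)
        self._z = 0.5 * (edges[:-1] + edges[1:])

        base = self._cell_means(edges, nominal_range_mm, -0.435)
        plateau = self._cell_means(edges, nominal_range_mm, 0.565)

        def build(k: float) -> np.ndarray:
            raw = base + k * plateau
            return gaussian_filter1d(raw, self.sigma / h, mode="nearest")

        def entrance_ratio(s: np.ndarray) -> float:
            i0 = int(np.searchsorted(self._z, 0.0))
            return float(s[i0] / s.max())

        lo, hi = 0.0, 1e-3
        target = plateau_entrance_ratio
        base_ratio = entrance_ratio(build(0.0))
        if target <= base_ratio:
            raise ValidationError(
                f"plateau_entrance_ratio {target:.3f} below the minimum "
                f"{base_ratio:.3f} attainable by this peak model"
            )
        while entrance_ratio(build(hi)) < target:
            hi *= 2.0
            if hi > 1e3:  # pragma: no cover - unreachable for ratio < 1
                raise ValidationError("cannot reach requested plateau_entrance_ratio")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if entrance_ratio(build(mid)) < target:
                lo = mid
            else:
                hi = mid
        s = build(0.5 * (lo + hi))
        self._signal = s / s.max()
        # pin the distal R80 of the fine curve exactly at nominal_range_mm
        self._depth_shift = self._fine_r80() - nominal_range_mm

    @staticmethod
    def _cell_means(edges: np.ndarray, r0: float, p: float) -> np.ndarray:
        """Exact cell averages of (r0 - z)^p over [edge_i, edge_{i+1}] ∩ (-inf, r0)."""
        q = p + 1.0
        a = np.minimum(edges[:-1], r0)
        b = np.minimum(edges[1:], r0)
        anti = ((r0 - a) ** q - (r0 - b) ** q) / q
        return anti / np.diff(edges)

    def _fine_r80(self) -> float:
        s, z = self._signal, self._z
        level = 0.8
        above = np.nonzero(s >= level)[0]
        i = above[-1]
        if i == s.size - 1 or s[i] == level:
            return float(z[i])
        t = (s[i] - level) / (s[i] - s[i + 1])
        return float(z[i] + t * (z[i + 1] - z[i]))

    def evaluate(self, depths_mm: np.ndarray) -> np.ndarray:
        """Signal at water-equivalent depths (mm); 0 beyond the distal tail."""
        z = np.asarray(depths_mm, dtype=float) + self._depth_shift
        return np.interp(z, self._z, self._signal, left=self._signal[0], right=0.0)


@lru_cache(maxsize=8)
def _bragg_model(nominal_range_mm: float, sigma_mm: float, ratio: float) -> PristineBraggModel:
    return PristineBraggModel(nominal_range_mm, sigma_mm, ratio)


def pristine_model(params: BraggModelParams) -> PristineBraggModel:
    """The (cached) analytic pristine-peak model for a parameter set."""
    return _bragg_model(params.nominal_range_mm, params.straggling_sigma_mm,
                        params.plateau_entrance_ratio)


def generate_idd(
    params: BraggModelParams,
    upstream_wet_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DepthDoseCurve:
    """MLIC readout of the pencil beam with ``upstream_wet_mm`` of material upstream.

    The noiseless signal is the pristine curve evaluated at
    ``chamber_depth + upstream_wet_mm`` (an exact depth shift), so every distal
    threshold depth moves shallower by exactly the upstream WET.  With
    ``noise_cv > 0`` each chamber is multiplied by an independent
    ``Normal(1, noise_cv)`` factor drawn from ``rng`` (or ``params.seed``).
    """
    if upstream_wet_mm < 0:
        raise ValidationError("upstream_wet_mm must be >= 0")
    depths = params.chamber_depths_mm
    shifted_r80 = params.nominal_range_mm - upstream_wet_mm
    if shifted_r80 + 2 * params.straggling_sigma_mm > depths[-1]:
        raise RangeTruncationError("distal falloff exits the deep end of the detector")
    if shifted_r80 < 5 * params.straggling_sigma_mm:
        raise RangeTruncationError("shifted peak pushed out of the shallow end of the detector")
    signal = pristine_model(params).evaluate(depths + upstream_wet_mm)
    if params.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        signal = np.clip(signal * (1.0 + params.noise_cv * rng.standard_normal(signal.size)), 0.0, None)
    return DepthDoseCurve(depths_mm=depths, signal=signal)


def generate_idd_pair(
    params: BraggModelParams, upstream_wet_mm: float
) -> tuple[DepthDoseCurve, DepthDoseCurve]:
    """(reference, sample) IDD pair sharing one RNG stream from ``params.seed``."""
    rng = np.random.default_rng(params.seed) if params.noise_cv > 0 else None
    reference = generate_idd(params, 0.0, rng=rng)
    sample = generate_idd(params, upstream_wet_mm, rng=rng)
    return reference, sample


# ---------------------------------------------------------------------------
# voxel phantoms


@dataclass(frozen=True)
class GridSpec:
    """Regular-grid geometry: shape (z, y, x), isotropic or per-axis spacing (mm)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValidationError("grid shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("grid spacing must be positive")


@dataclass(frozen=True)
class DeviceSpec:
    """A homogeneous device slab as seen by the virtual CT scanner.

    ``true_rsp`` is the physical ground truth; ``reported_hu`` is what the
    scanner writes into the image — choosing it off the calibration curve's
    value for ``true_rsp`` injects a controlled TPS SPR error.
    """

    name: str
    true_rsp: float
    thickness_mm: float
    reported_hu: float
    n_locations: int = 3
    location_jitter_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.true_rsp <= 0:
            raise ValidationError("true_rsp must be > 0")
        if self.thickness_mm <= 0:
            raise ValidationError("thickness_mm must be > 0")
        if self.n_locations < 1:
            raise ValidationError("n_locations must be >= 1")
        if self.location_jitter_cv < 0:
            raise ValidationError("location_jitter_cv must be >= 0")


@dataclass(frozen=True)
class LocationTruth:
    """Ground truth at one BB-marked location: where and what the device truly is."""

    location_id: str
    point_mm: tuple[float, float, float]
    ray: Ray
    true_rsp: float
    thickness_mm: float

    @property
    def true_wet_mm(self) -> float:
        return self.true_rsp * self.thickness_mm


@dataclass(frozen=True)
class DeviceGroundTruth:
    """Everything needed to score downstream estimates against injected truth."""

    device: str
    reported_hu: float
    thickness_mm: float
    locations: tuple[LocationTruth, ...]

    def mean_true_rsp(self) -> float:
        return float(np.mean([loc.true_rsp for loc in self.locations]))

    def injected_percent_error(self, curve: CalibrationCurve) -> float:
        """100 * (tps_rsp(reported_hu) - true_rsp) / true_rsp, per-location mean."""
        tps = float(curve.hu_to_rsp(self.reported_hu))
        errs = [100.0 * (tps - loc.true_rsp) / loc.true_rsp for loc in self.locations]
        return float(np.mean(errs))


def generate_device_phantom(
    spec: DeviceSpec,
    grid: GridSpec,
    calibration: CalibrationCurve | None = None,
) -> tuple[Phantom, StructureMask, DeviceGroundTruth]:
    """Voxelize a device slab in air, with BB-location metadata and ground truth.

    The slab is centred along y (its surface normal), spans the full x-z
    extent, and is measured by rays travelling in +y through each BB location.
    The recorded ground-truth thickness is the voxelized thickness, so all
    downstream arithmetic is exact on the grid.
    """
    dz, dy, dx = grid.spacing_mm
    n_thick = int(round(spec.thickness_mm / dy))
    if n_thick < 4:
        raise ResolutionError(
            f"slab of {spec.thickness_mm} mm spans {n_thick} voxels (< 4) at dy={dy} mm"
        )
    nz, ny, nx = grid.shape
    if n_thick > ny - 2:
        raise ResolutionError("grid too small to hold the slab plus air margin")
    if calibration is not None:
        hu_lo, hu_hi = calibration.hu_nodes[0], calibration.hu_nodes[-1]
        if not (hu_lo <= spec.reported_hu <= hu_hi):
            raise ValidationError(
                f"reported_hu {spec.reported_hu} outside calibration domain [{hu_lo}, {hu_hi}]"
            )

    hu = np.full(grid.shape, AIR_HU)
    iy0 = (ny - n_thick) // 2
    hu[:, iy0 : iy0 + n_thick, :] = spec.reported_hu
    phantom = Phantom(hu=hu, spacing_mm=np.array(grid.spacing_mm), origin_mm=np.array(grid.origin_mm))
    mask_data = np.zeros(grid.shape, dtype=bool)
    mask_data[:, iy0 : iy0 + n_thick, :] = True
    mask = StructureMask.like(phantom, mask_data, name=spec.name)

    rng = np.random.default_rng(spec.seed)
    xs = np.linspace(0.25, 0.75, spec.n_locations) * nx * dx + grid.origin_mm[2]
    z_mid = grid.origin_mm[0] + 0.5 * nz * dz
    y_surface = grid.origin_mm[1] + iy0 * dy
    actual_thickness = n_thick * dy
    locations = []
    for i, x in enumerate(xs):
        true_rsp = spec.true_rsp
        if spec.location_jitter_cv > 0:
            true_rsp = spec.true_rsp * (1.0 + spec.location_jitter_cv * rng.standard_normal())
        entry = np.array([z_mid, grid.origin_mm[1] - 10.0, x])
        ray = Ray(origin_mm=entry, direction=np.array([0.0, 1.0, 0.0]),
                  length_mm=ny * dy + 20.0)
        locations.append(
            LocationTruth(
                location_id=f"{spec.name}-bb{i}",
                point_mm=(z_mid, y_surface + 0.5 * actual_thickness, float(x)),
                ray=ray,
                true_rsp=float(true_rsp),
                thickness_mm=actual_thickness,
            )
        )
    truth = DeviceGroundTruth(
        device=spec.name,
        reported_hu=spec.reported_hu,
        thickness_mm=actual_thickness,
        locations=tuple(locations),
    )
    return phantom, mask, truth


# ---------------------------------------------------------------------------
# patient-like phantom and plan


@dataclass(frozen=True)
class OARSpec:
    """A spherical organ at risk; ``relation`` records its position along the
    device-traversing beam (proximal = entrance side, distal = beyond the CTV)."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    relation: str = "proximal"

    def __post_init__(self):
        if self.relation not in ("proximal", "distal"):
            raise ValidationError("relation must be 'proximal' or 'distal'")
        if self.radius_mm <= 0:
            raise ValidationError("OAR radius must be > 0")


@dataclass(frozen=True)
class CaseSpec:
    """Geometry + planning parameters of a patient-like case.

    The body is a water cylinder along z; the cushion slab sits posterior
    (+y side) of the body, so a 180-degree beam traverses it.  Beam gantry
    angles are in the axial (y, x) plane: 0 -> beam travels +y, 90 -> +x,
    180 -> -y, 270 -> -x.
    """

    grid: GridSpec = GridSpec(shape=(16, 96, 96), spacing_mm=(2.0, 2.0, 2.0))
    body_radius_mm: float = 70.0
    ctv_center_mm: tuple[float, float, float] | None = None
    ctv_radius_mm: float = 16.0
    oars: tuple[OARSpec, ...] = ()
    device: DeviceSpec | None = None
    device_gap_mm: float = 0.0
    beam_angles_deg: tuple[float, ...] = (180.0, 90.0)
    beam_weights: tuple[float, ...] | None = None
    prescription_dose: float = 2.0
    setup_uncertainty_mm: float = 3.0
    range_uncertainty_fraction: float = 0.035
    distal_margin_mm: float = 4.0
    proximal_margin_mm: float = 4.0

    def __post_init__(self):
        if not (2 <= len(self.beam_angles_deg) <= 4):
            raise ValidationError("plans must have between 2 and 4 beams")
        if self.prescription_dose <= 0:
            raise ValidationError("prescription_dose must be > 0")
        if self.beam_weights is not None and len(self.beam_weights) != len(self.beam_angles_deg):
            raise ValidationError("beam_weights length must match beam_angles_deg")


def _sphere_mask(grid: GridSpec, center, radius) -> np.ndarray:
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.spacing_mm
    oz, oy, ox = grid.origin_mm
    z = oz + (np.arange(nz) + 0.5) * dz
    y = oy + (np.arange(ny) + 0.5) * dy
    x = ox + (np.arange(nx) + 0.5) * dx
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    return (Z - center[0]) ** 2 + (Y - center[1]) ** 2 + (X - center[2]) ** 2 <= radius**2


def generate_patient_phantom(
    case: CaseSpec,
    calibration: CalibrationCurve | None = None,
) -> tuple[Phantom, dict[str, StructureMask], "PlanSpec"]:
    """Build the phantom, structure masks, and an SOBP plan that covers the CTV.

    Each beam's SOBP distal range is the ray-traced water-equivalent path
    length (WEPL) from outside the grid to the CTV's distal edge along the
    beam central axis plus ``distal_margin_mm``; the modulation extends the
    plateau back past the proximal edge by ``proximal_margin_mm``.
    """
    from .override_dose import BeamSpec, PlanSpec  # circularity: plan types live there

    if calibration is None:
        calibration = default_calibration()
    grid = case.grid
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.spacing_mm
    oz, oy, ox = grid.origin_mm
    center_y = oy + 0.5 * ny * dy
    center_x = ox + 0.5 * nx * dx
    center_z = oz + 0.5 * nz * dz

    # body cylinder along z, shifted anterior (-y) to leave room for the device
    body_shift = 0.0
    if case.device is not None:
        body_shift = -(case.device.thickness_mm + case.device_gap_mm + 2 * dy) / 2.0
    body_center = (center_z, center_y + body_shift, center_x)
    y = oy + (np.arange(ny) + 0.5) * dy
    x = ox + (np.arange(nx) + 0.5) * dx
    Y, X = np.meshgrid(y, x, indexing="ij")
    body2d = (Y - body_center[1]) ** 2 + (X - body_center[2]) ** 2 <= case.body_radius_mm**2
    body = np.broadcast_to(body2d, grid.shape).copy()
    if body2d[0, :].any() or body2d[-1, :].any() or body2d[:, 0].any() or body2d[:, -1].any():
        raise GeometryError("body cylinder extends outside the grid")

    hu = np.full(grid.shape, AIR_HU)
    hu[body] = WATER_HU

    masks_data: dict[str, np.ndarray] = {"body": body}
    device_mask = None
    if case.device is not None:
        n_thick = int(round(case.device.thickness_mm / dy))
        if n_thick < 4:
            raise ResolutionError("device slab must span >= 4 voxels")
        y_top = body_center[1] + case.body_radius_mm + case.device_gap_mm
        # first whole voxel row at or below the body surface (never overlapping)
        iy0 = int(np.ceil((y_top - oy) / dy - 1e-9))
        if iy0 + n_thick > ny:
            raise GeometryError("device slab extends outside the grid")
        dev = np.zeros(grid.shape, dtype=bool)
        dev[:, iy0 : iy0 + n_thick, :] = True
        if (dev & body).any():
            raise GeometryError("device overlaps the body")
        hu[dev] = case.device.reported_hu
        masks_data["device"] = dev
        device_mask = dev

    ctv_center = case.ctv_center_mm or body_center
    ctv = _sphere_mask(grid, ctv_center, case.ctv_radius_mm)
    if not (ctv <= body).all():
        raise GeometryError("CTV must lie fully inside the body")
    masks_data["ctv"] = ctv
    for oar in case.oars:
        m = _sphere_mask(grid, oar.center_mm, oar.radius_mm)
        if not m.any():
            raise GeometryError(f"OAR '{oar.name}' lies outside the grid")
        masks_data[oar.name] = m

    phantom = Phantom(hu=hu, spacing_mm=np.array(grid.spacing_mm), origin_mm=np.array(grid.origin_mm))
    masks = {name: StructureMask.like(phantom, data, name=name) for name, data in masks_data.items()}

    weights = case.beam_weights or tuple(1.0 / len(case.beam_angles_deg) for _ in case.beam_angles_deg)
    beams = []
    for angle, weight in zip(case.beam_angles_deg, weights):
        theta = np.deg2rad(angle)
        direction = np.array([0.0, np.cos(theta), np.sin(theta)])
        ctv_c = np.array(ctv_center)
        entry = ctv_c - direction * 1000.0
        distal_pt = ctv_c + direction * case.ctv_radius_mm
        proximal_pt = ctv_c - direction * case.ctv_radius_mm
        wepl_distal = ray_trace_wet(
            phantom, Ray.through_points(entry, distal_pt), calibration
        )
        wepl_proximal = ray_trace_wet(
            phantom, Ray.through_points(entry, proximal_pt), calibration
        )
        if wepl_distal <= 0:
            raise GeometryError(f"beam at {angle} deg misses the CTV")
        sobp_range = wepl_distal + case.distal_margin_mm
        modulation = sobp_range - max(wepl_proximal - case.proximal_margin_mm, 0.0)
        beams.append(
            BeamSpec(
                gantry_angle_deg=float(angle),
                isocenter_mm=tuple(float(c) for c in ctv_c),
                sobp_range_mm=float(sobp_range),
                sobp_modulation_mm=float(min(modulation, sobp_range)),
                weight=float(weight),
            )
        )
    plan = PlanSpec(
        beams=tuple(beams),
        prescription_dose=case.prescription_dose,
        setup_uncertainty_mm=case.setup_uncertainty_mm,
        range_uncertainty_fraction=case.range_uncertainty_fraction,
    )
    return phantom, masks, plan
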