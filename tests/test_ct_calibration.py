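"""HU calibration, Siddon ray tracing, and TPS-vs-measured SPR comparison."""

import numpy as np
import pytest

from protonwet.ct_calibration import (
    CalibrationCurve,
    Phantom,
    Ray,
    StructureMask,
    compare_spr,
    default_calibration,
    device_thickness,
    ray_trace_wet,
    tps_spr_at_location,
)
from protonwet.errors import CalibrationError, GeometryError, ValidationError
from protonwet.idd_wet import WETMeasurement, device_spr
from protonwet.synthetic_data import DeviceSpec, GridSpec, generate_device_phantom


@pytest.fixture
def two_node_curve():
    return CalibrationCurve(
        hu_nodes=[-1000.0, 0.0],
        density_nodes=[0.00121, 1.0],
        rsp_density_nodes=[0.0, 1.0],
        rsp_nodes=[0.0, 1.0],
    )


class TestCalibrationCurve:
    def test_node_values_exact(self, two_node_curve):
        assert two_node_curve.hu_to_density(-1000.0) == pytest.approx(0.00121)
        assert two_node_curve.hu_to_density(0.0) == pytest.approx(1.0)

    def test_linear_midpoint(self, two_node_curve):
        assert two_node_curve.hu_to_density(-500.0) == pytest.approx(0.500605)

    def test_out_of_domain_clamps(self, two_node_curve):
        assert two_node_curve.hu_to_density(-5000.0) == pytest.approx(0.00121)
        assert two_node_curve.hu_to_density(3000.0) == pytest.approx(1.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationCurve([0.0, -100.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(CalibrationError):
            CalibrationCurve([0.0, 100.0], [2.0, 1.0], [1.0, 2.0], [1.0, 2.0])

    def test_direct_hu_rsp_table(self):
        curve = CalibrationCurve.from_hu_rsp([-1000.0, 0.0], [0.0, 1.0])
        assert curve.hu_to_rsp(-250.0) == pytest.approx(0.75)

    def test_inverse_lookup_roundtrip(self, calibration):
        for rsp in (0.052, 0.080, 0.122, 0.5, 1.0):
            hu = calibration.hu_for_rsp(rsp)
            assert float(calibration.hu_to_rsp(hu)) == pytest.approx(rsp, abs=5e-4)


def _uniform_phantom(rsp_curve_hu, shape=(40, 40, 40), spacing=1.0):
    hu = np.full(shape, rsp_curve_hu)
    return Phantom(hu=hu, spacing_mm=np.full(3, float(spacing)), origin_mm=np.zeros(3))


class TestRayTracing:
    def test_water_identity(self, two_node_curve):
        """50 mm of unit-RSP material has WEPL exactly 50 mm."""
        ph = _uniform_phantom(0.0, shape=(60, 60, 60))  # HU 0 -> rsp 1.0
        ray = Ray(origin_mm=np.array([20.0, 20.0, 2.0]), direction=[0, 0, 1], length_mm=50.0)
        assert ray_trace_wet(ph, ray, two_node_curve) == pytest.approx(50.0, abs=1e-9)

    def test_low_density_slab_arithmetic(self):
        """30 mm slab of RSP 0.2 in vacuum -> WEPL 6.0 mm."""
        curve = CalibrationCurve.from_hu_rsp([-1000.0, 0.0], [0.0, 1.0])
        hu = np.full((10, 60, 10), -1000.0)
        hu[:, 15:45, :] = -800.0  # rsp 0.2
        ph = Phantom(hu=hu, spacing_mm=np.ones(3), origin_mm=np.zeros(3))
        ray = Ray(origin_mm=np.array([5.0, -10.0, 5.0]), direction=[0, 1, 0], length_mm=100.0)
        assert ray_trace_wet(ph, ray, curve) == pytest.approx(6.0, abs=1e-12)

    def test_additivity_over_subsegments(self, calibration):
        rng = np.random.default_rng(5)
        hu = rng.uniform(-1000, 1500, (20, 20, 20))
        ph = Phantom(hu=hu, spacing_mm=np.array([1.0, 1.5, 2.0]), origin_mm=np.zeros(3))
        rsp = ph.rsp_grid(calibration)
        for _ in range(10):
            o = rng.uniform(6, 12, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            full = Ray(o, d, 8.0)
            first = Ray(o, d, 3.0)
            second = Ray(o + 3.0 * d, d, 5.0)
            total = ray_trace_wet(ph, full, calibration, rsp_grid=rsp)
            parts = ray_trace_wet(ph, first, calibration, rsp_grid=rsp) + ray_trace_wet(
                ph, second, calibration, rsp_grid=rsp
            )
            assert total == pytest.approx(parts, abs=1e-9)

    def test_oblique_ray_matches_fine_step_oracle(self, hn_setup, calibration):
        """Siddon traversal vs brute-force 0.01-mm midpoint sampling.

        Measurement-style rays crossing the patient transversally: long
        radiological paths with transversal material boundaries, where the
        midpoint step oracle is itself accurate enough for a 1e-4 comparison.
        """
        _, ph, _, _ = hn_setup
        rsp = ph.rsp_grid(calibration)
        rng = np.random.default_rng(11)

        def brute(ray, step=0.01):
            ts = np.arange(step / 2, ray.length_mm, step)
            pts = ray.origin_mm[None, :] + ts[:, None] * ray.direction[None, :]
            idx = np.floor((pts - ph.origin_mm) / ph.spacing_mm).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(ph.shape)), axis=1)
            return rsp[idx[ok, 0], idx[ok, 1], idx[ok, 2]].sum() * step

        center = np.array([16.0, 96.0, 96.0])
        for _ in range(20):
            p_in = center + rng.uniform(-1, 1, 3) * np.array([4.0, 10.0, 10.0])
            phi = rng.uniform(0, 2 * np.pi)
            d = np.array([rng.uniform(-0.15, 0.15), np.cos(phi), np.sin(phi)])
            d /= np.linalg.norm(d)
            ray = Ray(p_in - 200.0 * d, d, 400.0)
            a = ray_trace_wet(ph, ray, calibration, rsp_grid=rsp)
            b = brute(ray)
            assert a == pytest.approx(b, rel=1e-4)

    def test_miss_returns_zero_with_warning(self, calibration):
        ph = _uniform_phantom(0.0, shape=(5, 5, 5))
        ray = Ray(origin_mm=np.array([100.0, 100.0, 100.0]), direction=[0, 0, 1], length_mm=10.0)
        with pytest.warns(UserWarning, match="does not intersect"):
            assert ray_trace_wet(ph, ray, calibration) == 0.0


class TestDeviceThickness:
    @pytest.fixture
    def slab_mask(self):
        data = np.zeros((10, 60, 60), dtype=bool)
        data[:, 15:45, :] = True  # 30 mm slab on 1 mm grid
        return StructureMask(name="slab", data=data, spacing_mm=np.ones(3), origin_mm=np.zeros(3))

    def test_perpendicular(self, slab_mask):
        ray = Ray(np.array([5.0, -5.0, 30.0]), [0, 1, 0], 100.0)
        assert device_thickness(slab_mask, ray) == pytest.approx(30.0, abs=1e-9)

    def test_45_degree_path(self, slab_mask):
        ray = Ray(np.array([5.0, -5.0, 5.0]), [0.0, 1.0, 1.0], 100.0)
        assert device_thickness(slab_mask, ray) == pytest.approx(30.0 * np.sqrt(2.0), abs=1e-9)

    def test_miss_is_zero(self, slab_mask):
        ray = Ray(np.array([5.0, 5.0, -50.0]), [0, 0, -1], 10.0)
        with pytest.warns(UserWarning):
            assert device_thickness(slab_mask, ray) == 0.0


class TestTPSSPR:
    def test_slab_spr_equals_calibrated_rsp(self, calibration):
        """TPS SPR through an injected-error phantom equals rsp(reported_hu) exactly."""
        hu = calibration.hu_for_rsp(0.080)
        spec = DeviceSpec(name="cushion", true_rsp=0.101, thickness_mm=30.0, reported_hu=hu)
        ph, mask, truth = generate_device_phantom(
            spec, GridSpec(shape=(6, 50, 40), spacing_mm=(2.0, 1.0, 1.0)), calibration
        )
        m = tps_spr_at_location(ph, mask, truth.locations[0].ray, calibration)
        assert m.spr == pytest.approx(float(calibration.hu_to_rsp(hu)), abs=1e-12)

    def test_repeats_deterministic_without_jitter(self, calibration):
        spec = DeviceSpec(name="s", true_rsp=0.2, thickness_mm=20.0, reported_hu=-800.0)
        ph, mask, truth = generate_device_phantom(spec, GridSpec(shape=(6, 40, 40)), calibration)
        ray = truth.locations[0].ray
        a = tps_spr_at_location(ph, mask, ray, calibration, n_repeats=3)
        b = tps_spr_at_location(ph, mask, ray, calibration, n_repeats=1)
        assert a.spr == b.spr and a.wet_mm == b.wet_mm

    def test_ray_missing_mask_raises(self, calibration):
        spec = DeviceSpec(name="s", true_rsp=0.2, thickness_mm=20.0, reported_hu=-800.0)
        ph, mask, _ = generate_device_phantom(spec, GridSpec(shape=(6, 40, 40)), calibration)
        miss = Ray(np.array([3.0, 1.0, -10.0]), [0, 0, 1], 60.0)  # skims the air rows
        with pytest.warns(UserWarning), pytest.raises(GeometryError):
            tps_spr_at_location(ph, mask, miss, calibration)


class TestCompareSPR:
    def _result(self, device, sprs):
        ms = [WETMeasurement(f"l{i}", s * 10.0, 10.0) for i, s in enumerate(sprs)]
        return device_spr(ms, device=device)

    def test_identity_zero_percent(self):
        c = compare_spr(self._result("d", [0.070]), self._result("d", [0.070]), 10.0)
        assert c.percent_diff == pytest.approx(0.0)

    def test_ratio_of_aggregates(self):
        """Aggregate SPRs 0.080 vs 0.101 give -20.8% (ratio of the two means)."""
        c = compare_spr(self._result("d", [0.080]), self._result("d", [0.101]), 30.0)
        assert c.percent_diff == pytest.approx(-20.8, abs=0.05)

    def test_wet_difference_scale(self):
        """(0.122 - 0.189) x 32.8 mm = -2.20 mm WET error."""
        c = compare_spr(self._result("d", [0.122]), self._result("d", [0.189]), 32.8)
        assert c.wet_diff_mm == pytest.approx(-2.20, abs=0.005)

    def test_device_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_spr(self._result("a", [0.1]), self._result("b", [0.1]), 10.0)
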