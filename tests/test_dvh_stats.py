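"""DVH metrics against brute-force oracles; exact Wilcoxon signed-rank test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from protonwet.ct_calibration import StructureMask
from protonwet.dvh_stats import (
    beam_specific_metrics,
    conformity_index,
    cumulative_dvh,
    d_at,
    dvh_metrics,
    max_dose_pct,
    mean_dose_pct,
    paired_metric_table,
    v_at,
    wilcoxon_signed_rank,
    worst_case_metrics,
    DVHMetrics,
)
from protonwet.errors import UndefinedTestError, ValidationError
from protonwet.override_dose import DoseGrid


def _grid(dose_array, rx=2.0):
    dose_array = np.asarray(dose_array, dtype=float)
    return DoseGrid(
        dose=dose_array, spacing_mm=np.ones(3), origin_mm=np.zeros(3), prescription_dose=rx
    )


def _mask(data):
    data = np.asarray(data, dtype=bool)
    return StructureMask(name="s", data=data, spacing_mm=np.ones(3), origin_mm=np.zeros(3))


class TestDVHCurve:
    def test_uniform_dose_step_function(self):
        dg = _grid(np.full((4, 4, 4), 1.2), rx=2.0)
        mask = _mask(np.ones((4, 4, 4)))
        edges, frac = cumulative_dvh(dg, mask, n_bins=100)
        assert frac[0] == 1.0
        assert np.all(np.diff(frac) <= 0)
        np.testing.assert_array_equal(frac[edges <= 1.2], 1.0)
        np.testing.assert_array_equal(frac[edges > 1.2], 0.0)

    def test_matches_per_voxel_counting(self):
        rng = np.random.default_rng(2)
        dose = rng.uniform(0, 2.5, (5, 5, 5))
        mask_data = rng.random((5, 5, 5)) > 0.4
        dg, mask = _grid(dose), _mask(mask_data)
        edges, frac = cumulative_dvh(dg, mask, n_bins=64)
        vals = dose[mask_data]
        for e, f in zip(edges, frac):
            assert f == pytest.approx((vals >= e).mean())


class TestPointMetrics:
    def test_uniform_rx_full_coverage(self):
        dg = _grid(np.full((3, 3, 3), 2.0))
        mask = _mask(np.ones((3, 3, 3)))
        assert v_at(dg, mask, 95.0) == 100.0

    def test_half_coverage(self):
        dose = np.zeros((2, 2, 2))
        dose[0] = 2.0
        assert v_at(_grid(dose), _mask(np.ones((2, 2, 2))), 95.0) == 50.0

    def test_v_at_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        dg = _grid(rng.uniform(0, 2.4, (6, 6, 6)))
        mask = _mask(np.ones((6, 6, 6)))
        vs = [v_at(dg, mask, t) for t in np.linspace(1.0, 120.0, 25)]
        assert all(a >= b for a, b in zip(vs, vs[1:]))

    def test_d_at_matches_sort_oracle(self):
        """Dp = largest dose d with >= p% of voxels at >= d (sorting brute force)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 100
            dose = rng.uniform(0, 3, (n, 1, 1))
            dg, mask = _grid(dose), _mask(np.ones((n, 1, 1)))
            for p in (5.0, 50.0, 95.0, 100.0):
                vals = dose.ravel()
                oracle = max(d for d in vals if (vals >= d).mean() >= p / 100.0)
                assert d_at(dg, mask, p) == pytest.approx(100.0 * oracle / 2.0)

    def test_d_at_non_increasing_in_volume(self):
        rng = np.random.default_rng(5)
        dg = _grid(rng.uniform(0, 2.4, (6, 6, 6)))
        mask = _mask(np.ones((6, 6, 6)))
        ds = [d_at(dg, mask, p) for p in np.linspace(1.0, 100.0, 25)]
        assert all(a >= b for a, b in zip(ds, ds[1:]))

    def test_volume_pct_domain(self):
        dg = _grid(np.ones((2, 2, 2)))
        with pytest.raises(ValidationError):
            d_at(dg, _mask(np.ones((2, 2, 2))), 0.0)

    def test_empty_mask_rejected(self):
        dg = _grid(np.ones((2, 2, 2)))
        with pytest.raises(ValidationError):
            v_at(dg, _mask(np.zeros((2, 2, 2))), 95.0)


class TestConformity:
    def test_isodose_over_target_ratio(self):
        dose = np.zeros((10, 10, 10))
        dose.ravel()[:120] = 2.0  # 120 voxels at rx
        ctv = np.zeros((10, 10, 10), dtype=bool)
        ctv.ravel()[:100] = True
        assert conformity_index(_grid(dose), _mask(ctv)) == pytest.approx(1.2)

    def test_no_voxel_at_rx(self):
        assert conformity_index(_grid(np.zeros((3, 3, 3))), _mask(np.ones((3, 3, 3)))) == 0.0

    def test_exact_rx_on_ctv_only(self):
        ctv = np.zeros((4, 4, 4), dtype=bool)
        ctv[1:3, 1:3, 1:3] = True
        dose = np.where(ctv, 2.0, 0.0)
        assert conformity_index(_grid(dose), _mask(ctv)) == pytest.approx(1.0)


class TestWorstCase:
    def _metrics(self, v95, dmax):
        return DVHMetrics(
            v95_pct=v95, d95_pct=v95, max_dose_pct=dmax, mean_dose_pct=v95 * 0.9,
            conformity_index=1.0,
        )

    def test_extrema_per_metric(self):
        ms = [self._metrics(99.1, 104.0), self._metrics(98.2, 107.0), self._metrics(99.5, 103.0)]
        worst = worst_case_metrics(ms)
        assert worst.v95_pct == 98.2
        assert worst.max_dose_pct == 107.0

    def test_single_scenario_is_itself(self):
        m = self._metrics(97.0, 105.0)
        assert worst_case_metrics([m]) == m

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            worst_case_metrics([])


class TestBeamSpecific:
    def test_uniform_half_rx_full_per_beam_coverage(self):
        ctv = np.zeros((4, 4, 4), dtype=bool)
        ctv[1:3, 1:3, 1:3] = True
        beam = np.where(ctv, 1.0, 0.0)  # rx/2 with rx=2, two beams
        ms = beam_specific_metrics([beam, beam], _mask(ctv), rx=2.0)
        assert all(m.v95_pct == 100.0 for m in ms)

    def test_matches_whole_plan_brute_force(self, hn_setup, calibration):
        """Per-beam metrics equal plan metrics computed on the rescaled beam dose."""
        from protonwet.override_dose import compute_dose

        _, phantom, masks, plan = hn_setup
        dg = compute_dose(phantom, masks, plan, calibration, keep_per_beam=True)
        per = beam_specific_metrics(
            [dg.per_beam[i] for i in sorted(dg.per_beam)], masks["ctv"],
            plan.prescription_dose,
        )
        for i, m in enumerate(per):
            beam_rx = plan.prescription_dose / len(plan.beams)
            ref = dvh_metrics(
                DoseGrid(dg.per_beam[i], dg.spacing_mm, dg.origin_mm, beam_rx), masks["ctv"]
            )
            assert m == ref
        # conservation: beams sum to the total plan dose
        np.testing.assert_allclose(sum(dg.per_beam.values()), dg.dose, atol=1e-12)


def _enumeration_pvalue(diffs):
    """Independent oracle: two-sided exact p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sstats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= w_obs + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / 2 ** len(d))


class TestWilcoxon:
    def test_all_positive_n5(self):
        w, p = wilcoxon_signed_rank([0.3, 1.2, 0.7, 2.0, 0.1])
        assert w == 0.0
        assert p == pytest.approx(2.0 / 32.0)

    def test_symmetric_differences_p_one(self):
        _, p = wilcoxon_signed_rank([1.5, -1.5, 0.4, -0.4])
        assert p == 1.0

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        diffs = np.round(rng.normal(0.2, 1.0, n), 1)  # rounding produces ties
        diffs[diffs == 0] = 0.05
        w, p = wilcoxon_signed_rank(diffs)
        assert p == pytest.approx(_enumeration_pvalue(diffs), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.5, 1.0, 14)
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(float(sstats.wilcoxon(d, method="exact").pvalue))

    def test_paired_signature_and_permutation_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(1, 0.3, 12), rng.normal(0.9, 0.3, 12)
        w1, p1 = wilcoxon_signed_rank(x, y)
        perm = rng.permutation(12)
        w2, p2 = wilcoxon_signed_rank(x[perm], y[perm])
        assert (w1, p1) == (w2, p2)
        assert 0.0 < p1 <= 1.0

    def test_normal_approximation_branch(self):
        rng = np.random.default_rng(10)
        d = rng.normal(0.4, 1.0, 60)
        _, p = wilcoxon_signed_rank(d)
        ref = float(sstats.wilcoxon(d, correction=True, method="approx").pvalue)
        assert p == pytest.approx(ref, rel=1e-6)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestPairedTable:
    def test_delta_columns(self):
        df = paired_metric_table(
            [
                {
                    "case": "c0", "structure": "ctv", "metric": "v95_pct",
                    "value_without_override": 99.0, "value_with_override": 98.5,
                }
            ]
        )
        assert df.loc[0, "delta"] == pytest.approx(-0.5)
        assert df.loc[0, "pct_delta"] == pytest.approx(-0.5 / 99.0 * 100.0)

    def test_missing_keys_rejected(self):
        with pytest.raises(ValidationError):
            paired_metric_table([{"case": "c0", "metric": "v95"}])


class TestEndToEndQualitative:
    def test_low_spr_cushion_override_barely_moves_ctv_coverage(
        self, hn_setup, calibration, cushion_override
    ):
        """|WET error| < 1 mm: worst-case CTV V95 changes by < 1 percentage point."""
        from protonwet.override_dose import scenario_doses

        _, phantom, masks, plan = hn_setup
        wet_error = 30.0 * abs(cushion_override.measured_spr - cushion_override.tps_spr)
        assert wet_error < 1.0
        worst = {}
        for label, ovr in (("without", []), ("with", [(masks["device"], cushion_override)])):
            doses = scenario_doses(phantom, masks, plan, calibration, ovr)
            worst[label] = worst_case_metrics(
                [dvh_metrics(dg, masks["ctv"]) for dg in doses.values()]
            )
        assert abs(worst["with"].v95_pct - worst["without"].v95_pct) < 1.0

    def test_proximal_oar_up_distal_oar_down(self, hn_setup, calibration, cushion_override):
        """Raising device SPR pulls the SOBP back: proximal OAR dose rises,
        distal OAR dose falls."""
        from protonwet.override_dose import compute_dose

        _, phantom, masks, plan = hn_setup
        d_no = compute_dose(phantom, masks, plan, calibration)
        d_ov = compute_dose(
            phantom, masks, plan, calibration,
            overrides=[(masks["device"], cushion_override)],
        )
        prox_delta = max_dose_pct(d_ov, masks["proximal_oar"]) - max_dose_pct(
            d_no, masks["proximal_oar"]
        )
        dist_delta = max_dose_pct(d_ov, masks["distal_oar"]) - max_dose_pct(
            d_no, masks["distal_oar"]
        )
        assert prox_delta > 0.0
        assert dist_delta < 0.0
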