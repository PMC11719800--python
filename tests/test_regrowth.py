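"""Bi-exponential regrowth kinetics: evaluation, fitting and derived times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfrtkit.regrowth import (
    GrowthMeasurement,
    InsufficientDataError,
    MouseRecord,
    RegrowthParams,
    ellipsoid_volume,
    eval_regrowth,
    fit_regrowth,
    fit_regrowth_pooled,
    global_min_time,
    regrowth_start,
    tripling_time,
)
from tests.conftest import CONTROL_ALPHA2, TREATED_ALPHA2


def make_record(params, schedule, v0=80.0, noise=None, rng=None,
                mouse_id="m1", arm="CRT", truncate=True):
    """Synthesize a MouseRecord from known kinetics on a schedule.

    ``truncate=False`` keeps the full schedule (no euthanasia at 3x V0),
    the design used for generate-then-recover fitting studies.
    """
    meas = []
    reached = False
    for day in schedule:
        v = v0 * eval_regrowth(params, day)
        if noise and rng is not None:
            sigma = math.sqrt(math.log1p(noise * noise))
            v *= rng.lognormal(-0.5 * sigma * sigma, sigma)
        meas.append(GrowthMeasurement(day=float(day), volume_mm3=v))
        if truncate and v >= 3.0 * v0:
            reached = True
            break
    return MouseRecord(mouse_id=mouse_id, arm=arm, v0=v0, measurements=meas,
                       reached_endpoint=reached,
                       last_followup_day=meas[-1].day if reached else 90.0)


class TestEllipsoidVolume:
    def test_sphere(self):
        d = 4.2
        assert ellipsoid_volume(d, d) == pytest.approx(math.pi / 6 * d**3)

    def test_analytic_inversion(self):
        assert ellipsoid_volume(6.0 / math.pi, 1.0) == pytest.approx(1.0)

    def test_random_pairs_match_formula(self, rng):
        for _ in range(100):
            b = rng.uniform(0.5, 10)
            l = b * rng.uniform(1.0, 3.0)
            assert ellipsoid_volume(l, b) == pytest.approx(
                math.pi / 6.0 * l * b * b, rel=1e-12
            )

    def test_swapped_axes_warn_and_correct(self):
        with pytest.warns(UserWarning, match="swap"):
            v = ellipsoid_volume(1.0, 2.0)
        assert v == pytest.approx(ellipsoid_volume(2.0, 1.0))


class TestParams:
    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            RegrowthParams(0.5, 0.6, 0.1, 0.05)
        with pytest.raises(ValueError):
            RegrowthParams(-0.1, 1.1, 0.1, 0.05)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a1=st.floats(0.0, 0.999), r1=st.floats(1e-3, 1.0),
           r2=st.floats(1e-3, 1.0))
    def test_unit_value_at_time_zero(self, a1, r1, r2):
        p = RegrowthParams.from_free(a1, r1, r2)
        assert eval_regrowth(p, 0.0) == pytest.approx(1.0, abs=1e-12)


class TestEvalRegrowth:
    def test_pure_exponential_triples_at_33_days(self):
        p = RegrowthParams.pure_exponential(math.log(3) / 33.0)
        assert eval_regrowth(p, 33.0) == pytest.approx(3.0, rel=1e-12)

    def test_biexponential_worked_value(self, crt_params):
        assert eval_regrowth(crt_params, 44.1) == pytest.approx(3.0, abs=1e-3)


class TestGlobalMinTime:
    def test_monotone_growth_has_nadir_at_zero(self):
        assert global_min_time(RegrowthParams.pure_exponential(0.05)) == 0.0

    def test_matches_grid_scan(self, crt_params):
        grid = np.arange(0.0, 60.0, 1e-4)
        t_scan = grid[np.argmin(eval_regrowth(crt_params, grid))]
        assert global_min_time(crt_params) == pytest.approx(t_scan, abs=2e-4)

    def test_random_params_match_numeric_argmin(self, rng):
        for _ in range(1000):
            p = RegrowthParams.from_free(
                float(rng.uniform(0.05, 0.95)),
                float(rng.uniform(0.02, 0.5)),
                float(rng.uniform(0.01, 0.2)),
            )
            t_min = global_min_time(p)
            grid = np.arange(0.0, max(4 * t_min, 1.0), 1e-3)
            t_scan = grid[np.argmin(eval_regrowth(p, grid))]
            assert abs(t_min - t_scan) < 1e-3 + 1e-3

    def test_stationary_at_nadir(self, crt_params):
        t_min = global_min_time(crt_params)
        h = 1e-6
        deriv = (eval_regrowth(crt_params, t_min + h)
                 - eval_regrowth(crt_params, t_min - h)) / (2 * h)
        assert abs(deriv) < 1e-8


class TestRegrowthStart:
    def test_next_scheduled_day(self):
        assert regrowth_start(12.4, [2, 4, 7, 9, 11, 12, 14, 16]) == 14

    def test_monotone_curve_starts_first_day(self):
        assert regrowth_start(0.0, [2, 4, 7]) == 2

    def test_nadir_beyond_schedule_is_censored(self):
        assert regrowth_start(99.0, [2, 4, 7]) is None


class TestTriplingTime:
    def test_pure_exponential_closed_form(self):
        p = RegrowthParams.pure_exponential(math.log(3) / 33.0)
        t3 = tripling_time(None, method="model", params=p)
        assert t3 == pytest.approx(33.0, abs=1e-6)

    @pytest.mark.parametrize("alpha2, expected",
                             [(0.045683, 44.10), (0.037873, 53.20),
                              (0.029674, 67.90)])
    def test_biexponential_matches_fine_grid(self, alpha2, expected):
        p = RegrowthParams.from_free(0.6, 0.15, alpha2)
        t3 = tripling_time(None, method="model", params=p)
        # independent fine-grid bracketing of the crossing
        grid = np.arange(0.0, 120.0, 1e-4)
        above = np.nonzero(eval_regrowth(p, grid) >= 3.0)[0]
        assert grid[above[0] - 1] <= t3 <= grid[above[0]]
        assert t3 == pytest.approx(expected, abs=0.01)

    def test_raw_interpolation_midpoint(self):
        rec = MouseRecord(
            "m", "CRT", 100.0,
            [GrowthMeasurement(day=10, volume_mm3=280.0),
             GrowthMeasurement(day=12, volume_mm3=320.0)],
        )
        assert tripling_time(rec, method="raw") == pytest.approx(11.0)

    def test_censored_when_threshold_unreached(self, schedule_90d):
        p = RegrowthParams.from_free(0.6, 0.15, 0.005)
        rec = make_record(p, schedule_90d)
        assert tripling_time(rec, method="raw") is None


class TestFitRegrowth:
    def test_noise_free_recovery(self, crt_params, schedule_90d):
        rec = make_record(crt_params, schedule_90d, truncate=False)
        fit = fit_regrowth(rec)
        assert fit.sse < 1e-10
        assert fit.params.a1 == pytest.approx(0.6, rel=1e-3)
        assert fit.params.alpha1 == pytest.approx(0.15, rel=1e-3)
        assert fit.params.alpha2 == pytest.approx(0.045683, rel=1e-3)

    def test_pure_exponential_boundary(self, schedule_90d):
        p = RegrowthParams.pure_exponential(CONTROL_ALPHA2)
        rec = make_record(p, schedule_90d, arm="control")
        fit = fit_regrowth(rec)
        assert fit.params.a1 <= 1e-3
        assert fit.params.alpha2 == pytest.approx(CONTROL_ALPHA2, rel=1e-3)

    def test_insufficient_points_rejected(self):
        rec = MouseRecord(
            "m", "CRT", 80.0,
            [GrowthMeasurement(day=d, volume_mm3=80.0) for d in (2, 4, 7)],
        )
        with pytest.raises(InsufficientDataError):
            fit_regrowth(rec)

    def test_fit_is_deterministic(self, crt_params, schedule_90d, rng):
        rec = make_record(crt_params, schedule_90d, noise=0.15,
                          rng=np.random.default_rng(11))
        f1, f2 = fit_regrowth(rec), fit_regrowth(rec)
        assert f1.params == f2.params
        assert f1.sse == f2.sse

    def test_noisy_alpha2_recovery(self, crt_params, schedule_90d):
        """15% caliper noise, 200 replicate 9-mouse cohorts fitted pooled:
        alpha2 median error below 10% of truth and bias below 2%."""
        truth = crt_params.alpha2
        estimates = []
        for i in range(200):
            r = np.random.default_rng(1000 + i)
            recs = [
                make_record(crt_params, schedule_90d,
                            v0=float(r.uniform(60, 100)), noise=0.15, rng=r,
                            truncate=False, mouse_id=f"m{j}")
                for j in range(9)
            ]
            estimates.append(fit_regrowth_pooled(recs).params.alpha2)
        estimates = np.array(estimates)
        rel_err = np.abs(estimates - truth) / truth
        assert np.median(rel_err) < 0.10
        assert abs(estimates.mean() - truth) / truth < 0.02

    def test_pooled_fit_recovers_shared_kinetics(self, crt_params,
                                                 schedule_90d):
        recs = [make_record(crt_params, schedule_90d, v0=v0,
                            mouse_id=f"m{i}", truncate=False)
                for i, v0 in enumerate((60.0, 80.0, 100.0))]
        fit = fit_regrowth_pooled(recs)
        assert fit.sse < 1e-9
        assert fit.params.alpha2 == pytest.approx(crt_params.alpha2, rel=1e-3)


class TestRecordValidation:
    def test_days_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            MouseRecord("m", "CRT", 80.0,
                        [GrowthMeasurement(day=4, volume_mm3=80.0),
                         GrowthMeasurement(day=2, volume_mm3=80.0)])

    def test_endpoint_flag_requires_threshold(self):
        with pytest.raises(ValueError, match="endpoint"):
            MouseRecord("m", "CRT", 80.0,
                        [GrowthMeasurement(day=2, volume_mm3=100.0)],
                        reached_endpoint=True)
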