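"""Stress response, root growth, and the three uptake models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootflow.root_uptake import (
    DEFAULT_R_COEFFS,
    UNIT_FACTOR,
    NoRootError,
    RootUptakeConfig,
    StressThresholds,
    alpha,
    compute_sink,
    h3_of_Tp,
    lnrd_wu,
    root_depth,
    sink_li_yadav,
    sink_prasad,
    sink_wu,
)
from rootflow.solver import Grid


def plateau_heads(grid, value=-2.0):
    """Heads inside the optimal range [h3, h2] so alpha = 1 everywhere."""
    return np.full(grid.nz, value)


class TestAlpha:
    def test_trapezoid_shape(self, thresholds):
        t = thresholds
        assert alpha((t.h2 + t.h3) / 2.0, t) == 1.0
        assert alpha(t.h1, t) == 0.0
        assert alpha(t.h4, t) == 0.0
        assert alpha(0.0, t) == 0.0  # saturated: anaerobiosis
        assert alpha((t.h3 + t.h4) / 2.0, t) == pytest.approx(0.5)
        assert alpha((t.h1 + t.h2) / 2.0, t) == pytest.approx(0.5)

    def test_continuous_and_bounded(self, thresholds):
        hs = np.linspace(-200.0, 0.5, 5000)
        a = alpha(hs, thresholds)
        assert np.all((a >= 0) & (a <= 1))
        # continuity: vanishing perturbations produce vanishing changes
        rng = np.random.default_rng(5)
        probes = rng.uniform(-200.0, 0.5, 200)
        da = np.abs(alpha(probes + 1e-8, thresholds) - alpha(probes, thresholds))
        assert np.max(da) < 1e-6


class TestH3Rule:
    @pytest.mark.parametrize(
        "ihth, tp, expected",
        [
            (1, 1.0, -11.0),
            (1, 5.0, -5.0),
            (1, 3.0, -8.0),
            (2, 1.0, -14.0),
            (2, 5.0, -8.0),
            (3, 1.0, -16.0),
            (3, 5.0, -10.0),
        ],
    )
    def test_linear_rule_and_endpoints(self, ihth, tp, expected):
        thr = StressThresholds(ihth=ihth)
        assert h3_of_Tp(tp, thr) == pytest.approx(expected)

    def test_clamped_outside_anchor_rates(self):
        thr = StressThresholds(ihth=1)
        assert h3_of_Tp(0.0, thr) == pytest.approx(-11.0)
        assert h3_of_Tp(50.0, thr) == pytest.approx(-5.0)

    def test_linearity_between_anchors(self):
        thr = StressThresholds(ihth=2)
        tps = np.linspace(1.0, 5.0, 11)
        h3s = np.array([h3_of_Tp(tp, thr) for tp in tps])
        assert np.allclose(np.diff(h3s, 2), 0.0, atol=1e-12)


class TestConfigValidation:
    def test_lambda_range_enforced(self):
        RootUptakeConfig(lam=0.01)
        RootUptakeConfig(lam=2.0)
        for bad in (0.0, 0.009, 2.01, -1.0):
            with pytest.raises(ValueError, match="lambda"):
                RootUptakeConfig(lam=bad)

    def test_icps_and_calendar_validation(self):
        with pytest.raises(ValueError, match="icps"):
            RootUptakeConfig(icps=4)
        with pytest.raises(ValueError, match="jthaw"):
            RootUptakeConfig(jthaw=200, jmatur=150)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            StressThresholds(h1=-1.0, h2=-0.5, h3=-5.0, h4=-150.0)
        with pytest.raises(ValueError, match="ihth"):
            StressThresholds(ihth=4)


class TestRootDepth:
    def test_piecewise_linear_growth(self, uptake_cfg):
        cfg = uptake_cfg
        assert root_depth(cfg.jthaw, cfg) == cfg.l0
        assert root_depth(cfg.jthaw - 30, cfg) == cfg.l0
        assert root_depth(cfg.jmatur, cfg) == cfg.zr_max
        assert root_depth(cfg.jmatur + 50, cfg) == cfg.zr_max
        mid = (cfg.jthaw + cfg.jmatur) / 2.0
        assert root_depth(mid, cfg) == pytest.approx((cfg.l0 + cfg.zr_max) / 2.0)

    def test_capped_at_profile_depth(self, uptake_cfg):
        assert root_depth(uptake_cfg.jmatur, uptake_cfg, z_max=0.6) == 0.6


class TestSinkPrasad:
    def test_zero_transpiration_zero_profile(self, grid_1m, uptake_cfg):
        prof = sink_prasad(plateau_heads(grid_1m), grid_1m, 0.0, 1.0, uptake_cfg)
        assert np.all(prof.S == 0.0)

    def test_beta_to_zero_limit_is_uniform(self, grid_1m):
        cfg = RootUptakeConfig(beta=1e-9, zr_max=1.0)
        prof = sink_prasad(plateau_heads(grid_1m), grid_1m, 5.0, 1.0, cfg)
        inroot = prof.S[grid_1m.z_centers <= 1.0]
        assert np.allclose(inroot, inroot[0], rtol=1e-6)

    def test_total_uptake_recovers_Tp(self, uptake_cfg):
        grid = Grid(nz=100, dz=0.01)  # dz = L/100
        prof = sink_prasad(plateau_heads(grid), grid, 5.0, 1.0, uptake_cfg)
        assert prof.actual_transpiration == pytest.approx(5.0, rel=0.01)

    def test_no_uptake_below_root_zone(self, grid_1m, uptake_cfg):
        prof = sink_prasad(plateau_heads(grid_1m), grid_1m, 5.0, 0.5, uptake_cfg)
        assert np.all(prof.S[grid_1m.z_centers > 0.5] == 0.0)

    def test_density_sum_refines_at_second_order(self):
        # midpoint quadrature of (beta+1)(1-z/L)^beta / L integrates to 1
        cfg = RootUptakeConfig(beta=2.0, zr_max=1.0)
        errs = []
        for nz in (20, 200):
            grid = Grid(nz=nz, dz=1.0 / nz)
            prof = sink_prasad(plateau_heads(grid), grid, 1.0, 1.0, cfg)
            errs.append(abs(prof.actual_transpiration - 1.0))
        assert errs[0] < 0.01
        assert errs[1] < 1e-4


class TestWuDensity:
    def test_polynomial_values(self):
        assert lnrd_wu(0.0) == pytest.approx(2.21)
        assert lnrd_wu(1.0) == pytest.approx(0.08)
        assert lnrd_wu(0.5) == pytest.approx(0.98125)

    def test_negative_coefficients_floored(self):
        assert lnrd_wu(1.0, (0.1, -1.0, 0.0, 0.0)) == 0.0

    def test_domain_check(self):
        with pytest.raises(ValueError):
            lnrd_wu(1.5)


class TestSinkWu:
    def test_exact_normalization_when_unstressed(self, grid_1m):
        cfg = RootUptakeConfig(icps=3, zr_max=1.0)
        prof = sink_wu(plateau_heads(grid_1m), grid_1m, 4.0, 1.0, cfg)
        assert prof.actual_transpiration == pytest.approx(4.0, rel=1e-12)

    def test_uniform_stress_scales_linearly(self, grid_1m):
        cfg = RootUptakeConfig(icps=3, zr_max=1.0)
        # heads on the falling limb at alpha = 0.5 exactly
        thr = cfg.thresholds
        h3 = h3_of_Tp(4.0, thr)
        h_mid = (h3 + thr.h4) / 2.0
        prof = sink_wu(np.full(grid_1m.nz, h_mid), grid_1m, 4.0, 1.0, cfg)
        assert prof.actual_transpiration == pytest.approx(2.0, rel=1e-9)

    def test_no_compensation_toward_wet_blocks(self, grid_1m):
        cfg = RootUptakeConfig(icps=3, zr_max=1.0)
        h = np.full(grid_1m.nz, -2.0)
        h[: grid_1m.nz // 2] = -300.0  # top half beyond wilting: alpha = 0
        prof = sink_wu(h, grid_1m, 4.0, 1.0, cfg)
        assert prof.actual_transpiration < 4.0
        assert np.all(prof.S[: grid_1m.nz // 2] == 0.0)

    def test_no_root_error(self, grid_1m):
        cfg = RootUptakeConfig(icps=3, zr_max=1.0)
        with pytest.raises(NoRootError):
            sink_wu(plateau_heads(grid_1m), grid_1m, 4.0, 0.001, cfg)


class TestSinkLiYadav:
    def test_unstressed_total_equals_Tp(self, grid_1m):
        cfg = RootUptakeConfig(icps=2, zr_max=1.0, lam=1.0)
        prof = sink_li_yadav(plateau_heads(grid_1m), grid_1m, 3.0, 1.0, cfg)
        assert prof.actual_transpiration == pytest.approx(3.0, rel=1e-12)

    def test_uniform_alpha_scales_total(self, grid_1m):
        cfg = RootUptakeConfig(icps=2, zr_max=1.0, lam=1.3)
        thr = cfg.thresholds
        h3 = h3_of_Tp(3.0, thr)
        h_mid = (h3 + thr.h4) / 2.0  # alpha = 0.5 everywhere
        prof = sink_li_yadav(np.full(grid_1m.nz, h_mid), grid_1m, 3.0, 1.0, cfg)
        assert prof.actual_transpiration == pytest.approx(1.5, rel=1e-9)

    def test_binary_stress_is_fully_compensated(self, grid_1m):
        cfg = RootUptakeConfig(icps=2, zr_max=1.0, lam=0.8)
        h = np.full(grid_1m.nz, -2.0)
        h[: grid_1m.nz // 3] = -300.0  # dry blocks: alpha = 0
        prof = sink_li_yadav(h, grid_1m, 3.0, 1.0, cfg)
        assert prof.actual_transpiration == pytest.approx(3.0, rel=1e-9)
        assert np.all(prof.S[: grid_1m.nz // 3] == 0.0)

    def test_fully_stressed_profile_flagged_not_raised(self, grid_1m):
        cfg = RootUptakeConfig(icps=2, zr_max=1.0)
        prof = sink_li_yadav(np.full(grid_1m.nz, -500.0), grid_1m, 3.0, 1.0, cfg)
        assert prof.fully_stressed
        assert np.all(prof.S == 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_compensation_identity_against_direct_sums(self, seed):
        # total uptake / Tp = sum(alpha^2 L^lam) / sum(alpha L^lam)
        grid = Grid(nz=10, dz=0.1)
        cfg = RootUptakeConfig(icps=2, zr_max=1.0, lam=1.2)
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.05, 1.0, grid.nz)
        # map alpha values onto the falling limb: h = h4 + a*(h3-h4)
        thr = cfg.thresholds
        h3 = h3_of_Tp(2.0, thr)
        h = thr.h4 + a * (h3 - thr.h4)
        prof = sink_li_yadav(h, grid, 2.0, 1.0, cfg)
        zr = grid.z_centers / 1.0
        lnrd = np.array([np.polyval(DEFAULT_R_COEFFS[::-1], z) for z in zr])
        expected = 2.0 * np.sum(a**2 * lnrd**1.2) / np.sum(a * lnrd**1.2)
        assert prof.actual_transpiration == pytest.approx(expected, rel=1e-9)
        assert min(a) - 1e-12 <= prof.actual_transpiration / 2.0 <= max(a) + 1e-12

    def test_total_monotone_in_single_alpha(self, grid_1m):
        cfg = RootUptakeConfig(icps=2, zr_max=1.0, lam=1.0)
        thr = cfg.thresholds
        h3 = h3_of_Tp(2.0, thr)
        base = np.full(grid_1m.nz, (h3 + thr.h4) / 2.0)
        prof0 = sink_li_yadav(base, grid_1m, 2.0, 1.0, cfg)
        bumped = base.copy()
        bumped[5] = h3  # alpha at block 5 raised from 0.5 to 1.0
        prof1 = sink_li_yadav(bumped, grid_1m, 2.0, 1.0, cfg)
        assert prof1.actual_transpiration >= prof0.actual_transpiration


class TestComputeSink:
    def test_dispatch_matches_direct_calls(self, grid_1m):
        h = plateau_heads(grid_1m)
        day = 200  # past maturity: L = zr_max
        for icps, fn in ((1, sink_prasad), (2, sink_li_yadav), (3, sink_wu)):
            cfg = RootUptakeConfig(icps=icps, zr_max=1.0, jthaw=134, jmatur=180)
            via_dispatch = compute_sink(h, grid_1m, 3.0, day, cfg)
            direct = fn(h, grid_1m, 3.0, 1.0, cfg)
            assert np.allclose(via_dispatch.S, direct.S)

    def test_zero_Tp_zero_profile_every_model(self, grid_1m):
        for icps in (1, 2, 3):
            cfg = RootUptakeConfig(icps=icps, zr_max=1.0)
            prof = compute_sink(plateau_heads(grid_1m), grid_1m, 0.0, 200, cfg)
            assert np.all(prof.S == 0.0)

    def test_compensation_totals_equal_Tp_for_any_lambda_when_wet(self, grid_1m):
        h = plateau_heads(grid_1m)
        for lam in (0.01, 1.0, 2.0):
            cfg = RootUptakeConfig(icps=2, zr_max=1.0, lam=lam)
            prof = compute_sink(h, grid_1m, 4.0, 200, cfg)
            assert prof.actual_transpiration == pytest.approx(4.0, rel=1e-9)

    def test_h3_refreshed_from_transpiration_rate(self, grid_1m):
        # at h = -9 m: optimal for slow Tp under set 1 (h3 = -11) but
        # stressed for fast Tp (h3 = -5)
        h = np.full(grid_1m.nz, -9.0)
        cfg = RootUptakeConfig(icps=1, zr_max=1.0)
        slow = compute_sink(h, grid_1m, 1.0, 200, cfg)
        fast = compute_sink(h, grid_1m, 5.0, 200, cfg)
        assert slow.actual_transpiration == pytest.approx(1.0, rel=0.02)
        # relative uptake drops once h3 rises above the ambient head
        assert fast.actual_transpiration / 5.0 < slow.actual_transpiration - 0.02

    def test_uptake_never_exceeds_potential(self, grid_1m):
        rng = np.random.default_rng(7)
        for icps in (1, 2, 3):
            cfg = RootUptakeConfig(icps=icps, zr_max=1.0)
            for _ in range(20):
                h = -(10.0 ** rng.uniform(-1, 2.2, grid_1m.nz))
                prof = compute_sink(h, grid_1m, 4.0, 200, cfg)
                assert prof.actual_transpiration <= 4.0 + 1e-9
                assert np.all(prof.S >= 0.0)
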