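"""Unit tests for the right-hand-side components."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sleepswitch as sw
from sleepswitch import model
from sleepswitch.params import (ModelParameters, ParameterError, SystemState,
                                SECONDS_PER_HOUR)


class TestFiringRate:
    def test_midpoint_is_half_max(self, nominal):
        assert sw.firing_rate(nominal.sigmoid.theta, nominal.sigmoid) == \
            pytest.approx(nominal.sigmoid.q_max / 2)

    def test_deep_saturation_below_threshold(self, nominal):
        s = nominal.sigmoid
        v = s.theta - 50 * s.sigma_prime
        assert sw.firing_rate(v, s) < 1e-15 * s.q_max

    def test_three_quarter_point(self, nominal):
        # closed-form inversion: Q = 0.75 q_max at v = theta + sigma' ln 3
        s = nominal.sigmoid
        v = s.theta + s.sigma_prime * math.log(3.0)
        assert sw.firing_rate(v, s) == pytest.approx(0.75 * s.q_max, rel=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(-100.0, 100.0), st.floats(-100.0, 100.0))
    def test_monotone_and_bounded(self, v1, v2):
        # strict bounds hold wherever float64 can resolve the sigmoid
        # tails (beyond ~theta + 37 sigma' the value rounds to q_max)
        s = ModelParameters.nominal().sigmoid
        q1, q2 = sw.firing_rate(v1, s), sw.firing_rate(v2, s)
        assert 0.0 < q1 < s.q_max
        if v1 < v2:
            assert q1 <= q2

    def test_rejects_non_finite(self, nominal):
        with pytest.raises(ValueError, match="non-finite"):
            sw.firing_rate(float("nan"), nominal.sigmoid)


class TestCircadianDrive:
    def test_acrophase_antiphase_quadrature(self, nominal):
        d = nominal.drives
        t0 = d.phase_ref
        assert sw.circadian_drive(t0, d) == pytest.approx(1.0)
        assert sw.circadian_drive(t0 + 12 * SECONDS_PER_HOUR, d) == \
            pytest.approx(-1.0)
        assert sw.circadian_drive(t0 + 6 * SECONDS_PER_HOUR, d) == \
            pytest.approx(0.0, abs=1e-12)

    def test_period_exactly_24_h(self, nominal):
        t = np.linspace(0, 86400, 7)
        c = sw.circadian_drive(t, nominal.drives)
        c_next = sw.circadian_drive(t + 86400.0, nominal.drives)
        np.testing.assert_allclose(c, c_next, atol=1e-12)
        assert np.all(np.abs(c) <= 1.0)


class TestNetDrives:
    def test_vlpo_constant_term(self, nominal):
        d = nominal.drives
        assert sw.net_drive_vlpo(0.0, 0.0, d) == pytest.approx(d.a_v)

    def test_vlpo_linearity_in_h(self, nominal):
        d = nominal.drives
        c, h = 0.7, 4.2
        base = d.a_v + d.nu_vc * c
        assert sw.net_drive_vlpo(c, 2 * h, d) - base == \
            pytest.approx(2 * (sw.net_drive_vlpo(c, h, d) - base))

    def test_vlpo_nominal_hand_sum(self, nominal):
        # -0.30 * 1 + 1.0 * 10 + (-8.5) = 1.2 mV
        assert sw.net_drive_vlpo(1.0, 10.0, nominal.drives) == \
            pytest.approx(1.2)

    def test_ma_suppressed_orexin(self, nominal):
        assert sw.net_drive_ma(0.0, nominal.coupling, nominal.drives) == \
            pytest.approx(nominal.drives.a_m)

    def test_ma_narcolepsy_limit_constant(self, nominal):
        p = nominal.with_overrides({"nu_mo": 0.0})
        for q_o in (0.0, 3.0, 50.0):
            assert sw.net_drive_ma(q_o, p.coupling, p.drives) == \
                pytest.approx(p.drives.a_m)

    def test_ma_nominal_hand_sum(self, nominal):
        # 0.52 + 5 * 0.30 = 2.02 mV
        assert sw.net_drive_ma(5.0, nominal.coupling, nominal.drives) == \
            pytest.approx(2.02)

    def test_ma_rejects_negative_rate(self, nominal):
        with pytest.raises(ValueError, match="negative"):
            sw.net_drive_ma(-1.0, nominal.coupling, nominal.drives)

    def test_orx_constant_and_linearity(self, nominal):
        d = nominal.drives
        assert sw.net_drive_orx(0.0, d) == pytest.approx(d.a_o)
        assert sw.net_drive_orx(1.0, d) - sw.net_drive_orx(-1.0, d) == \
            pytest.approx(2 * d.nu_oc)
        # 1.0 * 0.5 + 1.0 = 1.5 mV
        assert sw.net_drive_orx(0.5, d) == pytest.approx(1.5)


class TestHomeostat:
    def test_clearance_only_at_zero_rate(self, nominal):
        h = nominal.homeostat
        assert sw.homeostat_rate(1.0, 0.0, h) == pytest.approx(-1.0 / h.chi)

    def test_steady_state_equals_production(self, nominal):
        h = nominal.homeostat
        for q_m in (0.5, 2.3, 6.0):
            h_ss = model.homeostat_production(q_m, h)
            assert sw.homeostat_rate(h_ss, q_m, h) == pytest.approx(0.0, abs=1e-15)

    def test_production_bounded_and_at_qsat(self, nominal):
        h = nominal.homeostat
        sup = h.mu
        assert model.homeostat_production(1e6, h) == pytest.approx(sup)
        # at q_m = q_sat the production is (1 - 1/e) of its supremum
        assert model.homeostat_production(h.q_sat, h) == \
            pytest.approx((1 - math.exp(-1)) * sup, rel=1e-12)

    def test_production_nondecreasing(self, nominal):
        q = np.linspace(0, 30, 500)
        prod = model.homeostat_production(q, nominal.homeostat)
        assert np.all(np.diff(prod) >= 0)
        assert prod[0] == pytest.approx(0.0)


class TestRhsFull:
    def test_matches_manual_assembly(self, nominal):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = SystemState(*rng.uniform(-15, 15, size=3),
                            h=rng.uniform(0, 20), t=rng.uniform(0, 86400))
            got = sw.rhs_full(s, nominal)
            q_v = sw.firing_rate(s.v_v, nominal.sigmoid)
            q_m = sw.firing_rate(s.v_m, nominal.sigmoid)
            q_o = sw.firing_rate(s.v_o, nominal.sigmoid)
            c = sw.circadian_drive(s.t, nominal.drives)
            want = np.array([
                (nominal.coupling.nu_vm * q_m
                 + sw.net_drive_vlpo(c, s.h, nominal.drives) - s.v_v) / 10.0,
                (nominal.coupling.nu_mv * q_v
                 + sw.net_drive_ma(q_o, nominal.coupling, nominal.drives)
                 - s.v_m) / 10.0,
                (nominal.coupling.nu_ov * q_v
                 + sw.net_drive_orx(c, nominal.drives, s.h) - s.v_o) / 120.0,
                sw.homeostat_rate(s.h, q_m, nominal.homeostat),
            ])
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_finite_on_large_states(self, nominal):
        for v in (-1e3, 1e3):
            s = SystemState(v_v=v, v_m=-v, v_o=v, h=1e3, t=0.0)
            assert np.all(np.isfinite(sw.rhs_full(s, nominal)))

    def test_vanishes_at_phaseplane_fixed_points(self, nominal):
        # cross-module oracle: frozen-drive equilibria are equilibria of
        # the corresponding full-state assembly
        from sleepswitch.phaseplane import find_equilibria, reduced_rhs
        d_v, d_m = 2.3, 2.0
        for fp in find_equilibria(d_v, d_m, nominal):
            f = reduced_rhs(fp.v_v, fp.v_m, d_v, d_m, nominal)
            assert abs(f[0]) < 1e-10 and abs(f[1]) < 1e-10

    def test_dm_independent_of_orexin_without_coupling(self, nominal):
        p = nominal.with_overrides({"nu_mo": 0.0})
        vals = [sw.net_drive_ma(q, p.coupling, p.drives)
                for q in np.linspace(0, 80, 9)]
        assert np.ptp(vals) == 0.0


class TestNominalParameters:
    """Golden-value check of the nominal constructor (transcribed once)."""

    def test_nominal_table(self, nominal):
        assert nominal.sigmoid.q_max == 100.0
        assert nominal.sigmoid.theta == 10.0
        assert nominal.sigmoid.sigma_prime == 3.0
        assert nominal.coupling.nu_vm == -2.1
        assert nominal.coupling.nu_mv == -1.8
        assert nominal.coupling.nu_ov == -1.0
        assert nominal.coupling.nu_mo == 0.30
        assert nominal.coupling.nu_om == 0.0
        assert nominal.drives.nu_vc == -0.30
        assert nominal.drives.nu_vh == 1.0
        assert nominal.drives.nu_oc == 1.0
        assert nominal.drives.nu_oh == 0.0
        assert nominal.drives.a_v == -8.5
        assert nominal.drives.a_m == 0.52
        assert nominal.drives.a_o == 1.0
        assert nominal.homeostat.chi == 45.0 * 3600.0
        assert nominal.homeostat.mu == 17.0
        assert nominal.homeostat.q_sat == 2.3
        assert nominal.tau.tau_v == 10.0
        assert nominal.tau.tau_m == 10.0
        assert nominal.tau.tau_o == 120.0
        assert nominal.noise.sigma_v == 1.0
        assert nominal.noise.sigma_m == 1.0

    def test_invariant_violations_rejected(self):
        p = ModelParameters.nominal()
        p.coupling.nu_vm = +1.0
        with pytest.raises(ParameterError):
            p.validate()
        with pytest.raises(KeyError):
            ModelParameters.nominal().with_overrides({"nu_bogus": 1.0})

    def test_omega_locked_to_24h(self):
        p = ModelParameters.nominal()
        p.drives.omega *= 1.1
        with pytest.raises(ParameterError):
            p.validate()
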