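"""Tests of the frozen-drive phase-plane analysis."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import sleepswitch as sw
from sleepswitch import model
from sleepswitch.phaseplane import (BOUNDING_BOX, bistable_boundaries,
                                    classify_fixed_point, compute_nullclines,
                                    compute_separatrix, find_equilibria,
                                    portrait, reduced_jacobian, reduced_rhs,
                                    region_label, saddle_node_points)

BISTABLE = (2.3, 2.0)


def grid_scan_roots(d_v, d_m, p, n=400, box=BOUNDING_BOX):
    """Independent brute-force oracle for the reduced system's roots.

    Scans the 2-D vector field for cells where both components change
    sign, polishes each candidate with a 2-D Newton solve of the vector
    field itself (not the scalar composition used by the implementation
    under test), and de-duplicates the converged roots.
    """
    from scipy.optimize import fsolve
    lo, hi = box
    vv = np.linspace(lo, hi, n)
    vm = np.linspace(lo, hi, n)
    VV, VM = np.meshgrid(vv, vm, indexing="ij")
    F1, F2 = reduced_rhs(VV, VM, d_v, d_m, p)
    s1, s2 = np.sign(F1), np.sign(F2)
    roots = []
    for i in range(n - 1):
        for j in range(n - 1):
            c1 = s1[i:i + 2, j:j + 2]
            c2 = s2[i:i + 2, j:j + 2]
            if c1.max() > 0 > c1.min() and c2.max() > 0 > c2.min():
                guess = (0.5 * (vv[i] + vv[i + 1]),
                         0.5 * (vm[j] + vm[j + 1]))
                sol, info, ok, _ = fsolve(
                    lambda y: np.asarray(
                        reduced_rhs(y[0], y[1], d_v, d_m, p), float),
                    guess, full_output=True)
                if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
                    continue
                if not (lo <= sol[0] <= hi and lo <= sol[1] <= hi):
                    continue
                if not any(np.hypot(sol[0] - r[0], sol[1] - r[1]) < 1e-5
                           for r in roots):
                    roots.append(tuple(sol))
    return roots


class TestReducedRhs:
    def test_consistent_with_full_rhs(self, nominal):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v_v, v_m, v_o = rng.uniform(-12, 12, 3)
            h, t = rng.uniform(0, 15), rng.uniform(0, 86400)
            c = model.circadian_drive(t, nominal.drives)
            d_v = float(model.net_drive_vlpo(c, h, nominal.drives))
            q_o = model.firing_rate(v_o, nominal.sigmoid)
            d_m = float(model.net_drive_ma(q_o, nominal.coupling,
                                           nominal.drives))
            full = sw.rhs_full(sw.SystemState(v_v, v_m, v_o, h, t), nominal)
            red = reduced_rhs(v_v, v_m, d_v, d_m, nominal)
            assert full[0] == pytest.approx(float(red[0]), rel=1e-12)
            assert full[1] == pytest.approx(float(red[1]), rel=1e-12)

    def test_population_interchange_symmetry(self, nominal):
        """Swapping the populations with swapped parameters swaps the
        components of the vector field."""
        swapped = nominal.copy()
        swapped.coupling.nu_vm = nominal.coupling.nu_mv
        swapped.coupling.nu_mv = nominal.coupling.nu_vm
        swapped.tau.tau_v = nominal.tau.tau_m
        swapped.tau.tau_m = nominal.tau.tau_v
        rng = np.random.default_rng(1)
        for _ in range(20):
            v_v, v_m = rng.uniform(-12, 12, 2)
            d_v, d_m = rng.uniform(0, 3, 2)
            f = reduced_rhs(v_v, v_m, d_v, d_m, nominal)
            g = reduced_rhs(v_m, v_v, d_m, d_v, swapped)
            assert float(f[0]) == pytest.approx(float(g[1]), rel=1e-12)
            assert float(f[1]) == pytest.approx(float(g[0]), rel=1e-12)


class TestClassify:
    def test_canonical_matrices(self):
        assert classify_fixed_point(np.diag([-1.0, -1.0]))[0] == "stable"
        assert classify_fixed_point(np.diag([1.0, -1.0]))[0] == "saddle"
        assert classify_fixed_point(np.diag([1.0, 2.0]))[0] == "unstable"
        assert classify_fixed_point(np.diag([0.0, -1.0]))[0] == "marginal"

    def test_against_quadratic_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            j = rng.normal(size=(2, 2))
            cls, eigs = classify_fixed_point(j)
            tr, det = np.trace(j), np.linalg.det(j)
            disc = complex(tr * tr - 4 * det) ** 0.5
            roots = sorted([(tr - disc) / 2, (tr + disc) / 2],
                           key=lambda z: (z.real, z.imag))
            for got, want in zip(eigs, roots):
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)
            if det < 0:
                assert cls == "saddle"
            elif all(r.real < 0 for r in roots):
                assert cls == "stable"

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            classify_fixed_point(np.full((2, 2), np.nan))


class TestEquilibria:
    def test_deep_wake_regime(self, nominal):
        fps = find_equilibria(0.5, 3.0, nominal)
        assert len(fps) == 1
        fp = fps[0]
        assert fp.stability == "stable"
        q_v = model.firing_rate(fp.v_v, nominal.sigmoid)
        q_m = model.firing_rate(fp.v_m, nominal.sigmoid)
        assert q_m > q_v

    def test_bistable_inventory(self, nominal):
        fps = find_equilibria(*BISTABLE, nominal)
        kinds = [fp.stability for fp in fps]
        assert kinds == ["stable", "saddle", "stable"]  # V_m descending
        assert fps[0].is_wake and not fps[2].is_wake
        assert all(fp.residual < 1e-9 for fp in fps)

    def test_matches_grid_scan_oracle(self, nominal):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d_v = rng.uniform(0.0, 3.5)
            d_m = rng.uniform(0.0, 3.0)
            fps = find_equilibria(d_v, d_m, nominal)
            scan = grid_scan_roots(d_v, d_m, nominal)
            assert len(fps) == len(scan)
            for fp in fps:
                assert any(np.hypot(fp.v_v - r[0], fp.v_m - r[1]) < 1e-6
                           for r in scan)

    def test_count_always_odd(self, nominal):
        rng = np.random.default_rng(4)
        for _ in range(40):
            fps = find_equilibria(rng.uniform(0, 4), rng.uniform(0, 3),
                                  nominal)
            assert len(fps) in (1, 3)

    def test_wake_equilibrium_monotone_in_drives(self, nominal):
        """Inside the wake region Q_m rises with D_m and falls with D_v."""
        def wake_qm(d_v, d_m):
            fps = find_equilibria(d_v, d_m, nominal)
            wake = [fp for fp in fps
                    if fp.stability == "stable" and fp.is_wake]
            return model.firing_rate(wake[0].v_m, nominal.sigmoid)
        for d_v in (0.2, 0.6, 1.0):
            qs = [wake_qm(d_v, d_m) for d_m in (2.0, 2.5, 3.0)]
            assert qs[0] < qs[1] < qs[2]
        for d_m in (2.5, 3.0):
            qs = [wake_qm(d_v, d_m) for d_v in (0.2, 0.8, 1.4)]
            assert qs[0] > qs[1] > qs[2]


class TestNullclines:
    def test_defining_equations(self, nominal):
        curves = compute_nullclines(*BISTABLE, nominal, resolution=200)
        f1, _ = reduced_rhs(curves["v_v"][:, 0], curves["v_v"][:, 1],
                            *BISTABLE, nominal)
        _, f2 = reduced_rhs(curves["v_m"][:, 0], curves["v_m"][:, 1],
                            *BISTABLE, nominal)
        assert np.max(np.abs(f1)) < 1e-12
        assert np.max(np.abs(f2)) < 1e-12

    def test_fixed_points_on_intersections(self, nominal):
        curves = compute_nullclines(*BISTABLE, nominal, resolution=2000)
        for fp in find_equilibria(*BISTABLE, nominal):
            d1 = np.min(np.hypot(curves["v_v"][:, 0] - fp.v_v,
                                 curves["v_v"][:, 1] - fp.v_m))
            d2 = np.min(np.hypot(curves["v_m"][:, 0] - fp.v_v,
                                 curves["v_m"][:, 1] - fp.v_m))
            assert d1 < 0.05 and d2 < 0.05

    def test_resolution_floor(self, nominal):
        with pytest.raises(ValueError):
            compute_nullclines(*BISTABLE, nominal, resolution=10)


class TestSeparatrix:
    def test_basin_membership(self, nominal):
        """Points displaced either side of the separatrix flow to the two
        different stable states."""
        pt = portrait(*BISTABLE, nominal)
        stable = [fp for fp in pt.fixed_points if fp.stability == "stable"]
        sep = pt.separatrix
        mid = len(sep) // 2
        tangent = sep[mid + 3] - sep[mid - 3]
        normal = np.array([-tangent[1], tangent[0]])
        normal /= np.linalg.norm(normal)
        targets = set()
        for sign in (+1.0, -1.0):
            y0 = sep[mid] + sign * 0.05 * normal
            sol = solve_ivp(
                lambda t, y: np.asarray(
                    reduced_rhs(y[0], y[1], *BISTABLE, nominal), float),
                (0.0, 3000.0), y0, rtol=1e-8, atol=1e-10)
            end = sol.y[:, -1]
            dists = [np.hypot(end[0] - fp.v_v, end[1] - fp.v_m)
                     for fp in stable]
            assert min(dists) < 0.05
            targets.add(int(np.argmin(dists)))
        assert targets == {0, 1}

    def test_saddle_on_curve_and_endpoints_on_box(self, nominal):
        pt = portrait(*BISTABLE, nominal)
        saddle = pt.saddle()
        d = np.min(np.linalg.norm(
            pt.separatrix - [saddle.v_v, saddle.v_m], axis=1))
        assert d < 1e-6
        lo, hi = BOUNDING_BOX
        for end in (pt.separatrix[0], pt.separatrix[-1]):
            assert min(end[0] - lo, hi - end[0],
                       end[1] - lo, hi - end[1]) < 0.05

    def test_monostable_regime_raises(self, nominal):
        with pytest.raises(ValueError, match="saddle"):
            compute_separatrix(0.5, 3.0, nominal)


class TestBistableRegion:
    def test_fold_crossing_changes_count(self, nominal):
        bb = bistable_boundaries((1.2, 2.0), (0.4, 2.8), nominal,
                                 resolution=25)
        i = 0
        d_v = bb["d_v"][i]
        d_m_fold = bb["sleep_boundary_d_m"][i]
        assert np.isfinite(d_m_fold)
        inside = find_equilibria(d_v, d_m_fold + 0.01, nominal)
        outside = find_equilibria(d_v, d_m_fold - 0.01, nominal)
        assert len(inside) == 3 and len(outside) == 1

    def test_fold_determinant_vanishes(self, nominal):
        """At the refined saddle-node point the reduced Jacobian is
        singular to 1e-6."""
        for d_v in (1.4, 1.8, 2.4):
            folds = saddle_node_points(d_v, nominal)
            assert folds, f"no folds found at d_v={d_v}"
            for fold in folds:
                assert abs(fold["det_jacobian"]) < 1e-6

    def test_fold_consistent_with_bisection(self, nominal):
        bb = bistable_boundaries((1.6, 1.6), (0.4, 2.8), nominal,
                                 resolution=25, tol=1e-4)
        folds = saddle_node_points(1.6, nominal)
        d_ms = sorted(f["d_m"] for f in folds)
        assert bb["sleep_boundary_d_m"][0] == pytest.approx(d_ms[0], abs=5e-4)
        assert bb["wake_boundary_d_m"][0] == pytest.approx(d_ms[1], abs=5e-4)

    def test_region_map_qualitative_wedge(self, nominal):
        bb = bistable_boundaries((0.5, 3.0), (0.5, 2.75), nominal,
                                 resolution=10)
        rm = bb["region_map"]
        assert rm[0, -1] == "wake"       # low D_v, high D_m
        assert rm[-1, 0] == "sleep"      # high D_v, low D_m
        assert (rm == "bistable").sum() > 0

    def test_wedge_untouched_by_orexin_parameters(self, nominal):
        """The switch geometry only involves the VLPO-MA couplings and the
        sigmoid, so orexin-side changes leave the folds unchanged."""
        altered = nominal.with_overrides(
            {"nu_mo": 0.0, "tau_o": 600.0, "nu_ov": -2.0, "a_o": 0.1})
        for d_v in (1.4, 2.0):
            a = [f["d_m"] for f in saddle_node_points(d_v, nominal)]
            b = [f["d_m"] for f in saddle_node_points(d_v, altered)]
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)


class TestPortraitStructure:
    def test_region_iff_inventory(self, nominal):
        pt = portrait(*BISTABLE, nominal)
        assert pt.region == "bistable"
        assert pt.separatrix is not None
        mono = portrait(0.5, 3.0, nominal)
        assert mono.region == "wake"
        assert mono.separatrix is None

    def test_json_round_structure(self, nominal):
        import json
        doc = json.loads(portrait(*BISTABLE, nominal).to_json())
        assert doc["region"] == "bistable"
        assert len(doc["fixed_points"]) == 3
        assert doc["separatrix"] is not None
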