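"""Phase-plane analysis of the VLPO-MA switch at frozen net drives.

On timescales of seconds the drives (D_v, D_m) vary slowly and can be
treated as control parameters of the two-dimensional fast subsystem in
(V_v, V_m).  This module finds its equilibria, classifies them by the
eigenvalues of the reduced Jacobian, samples the nullclines and the
saddle's stable manifold (the separatrix between the wake and sleep
basins), and maps the saddle-node boundaries of the bistable wedge in
the (D_v, D_m) plane.

Both nullclines are explicit graphs:

    V_v-nullcline:  V_v = nu_vm Q(V_m) + D_v
    V_m-nullcline:  V_m = nu_mv Q(V_v) + D_m

so equilibria are roots of the scalar composition
F(V_m) = nu_mv Q(nu_vm Q(V_m) + D_v) + D_m - V_m, bracketed on a dense
grid and polished with Brent's method -- a deterministic procedure with
no random multistart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import model
from .params import ModelParameters

__all__ = [
    "FixedPoint", "PhasePortrait", "reduced_rhs", "find_equilibria",
    "classify_fixed_point", "compute_nullclines", "compute_separatrix",
    "bistable_boundaries", "region_label", "portrait", "saddle_node_points",
    "BOUNDING_BOX",
]

#: (V_v, V_m) search box, mV.  The lower edge must accommodate the
#: suppressed population's potential nu_xy * Q + D, which reaches about
#: -25 mV for drives up to ~4 mV; the upper edge comfortably brackets
#: sigmoid saturation (theta = 10, sigma' = 3).
BOUNDING_BOX = (-30.0, 15.0)

_GRID_N = 3001  # dense-bracketing resolution for root isolation


@dataclass
class FixedPoint:
    """Equilibrium of the reduced system with its linear stability."""

    v_v: float
    v_m: float
    stability: str            # "stable" | "saddle" | "unstable" | "marginal"
    eigenvalues: tuple[complex, complex]
    residual: float

    @property
    def is_wake(self) -> bool:
        return self.v_m > self.v_v


@dataclass
class PhasePortrait:
    """Equilibria, nullclines, separatrix and region label at fixed drives."""

    d_v: float
    d_m: float
    fixed_points: list[FixedPoint]
    nullclines: dict[str, np.ndarray]
    separatrix: np.ndarray | None
    region: str               # "wake" | "sleep" | "bistable"

    def saddle(self) -> FixedPoint:
        saddles = [fp for fp in self.fixed_points if fp.stability == "saddle"]
        if len(saddles) != 1:
            raise ValueError(f"expected exactly one saddle, found {len(saddles)}")
        return saddles[0]

    def to_json(self) -> str:
        doc = {
            "d_v": self.d_v, "d_m": self.d_m, "region": self.region,
            "fixed_points": [
                {"v_v": fp.v_v, "v_m": fp.v_m, "stability": fp.stability,
                 "eigenvalues": [[ev.real, ev.imag] for ev in fp.eigenvalues],
                 "residual": fp.residual}
                for fp in self.fixed_points
            ],
            "nullclines": {k: v.tolist() for k, v in self.nullclines.items()},
            "separatrix": (None if self.separatrix is None
                           else self.separatrix.tolist()),
        }
        return json.dumps(doc, indent=1)


def reduced_rhs(v_v, v_m, d_v: float, d_m: float, p: ModelParameters):
    """(dV_v/dt, dV_m/dt) of the fast subsystem at frozen drives, noise off."""
    q_v = model.firing_rate(v_v, p.sigmoid)
    q_m = model.firing_rate(v_m, p.sigmoid)
    return ((p.coupling.nu_vm * q_m + d_v - np.asarray(v_v, float)) / p.tau.tau_v,
            (p.coupling.nu_mv * q_v + d_m - np.asarray(v_m, float)) / p.tau.tau_m)


def _sigmoid_slope(v, p: ModelParameters):
    q = model.firing_rate(v, p.sigmoid)
    return q * (1.0 - q / p.sigmoid.q_max) / p.sigmoid.sigma_prime


def reduced_jacobian(v_v: float, v_m: float, p: ModelParameters) -> np.ndarray:
    """2x2 Jacobian of `reduced_rhs` at (v_v, v_m)."""
    return np.array([
        [-1.0 / p.tau.tau_v,
         p.coupling.nu_vm * _sigmoid_slope(v_m, p) / p.tau.tau_v],
        [p.coupling.nu_mv * _sigmoid_slope(v_v, p) / p.tau.tau_m,
         -1.0 / p.tau.tau_m],
    ])


def classify_fixed_point(jacobian: np.ndarray,
                         marginal_tol: float = 1e-9) -> tuple[str, tuple[complex, complex]]:
    """Stability class and eigenvalues from a 2x2 real Jacobian.

    Saddle iff det < 0; otherwise stable/unstable by the sign of the
    eigenvalue real parts.  A real part within ``marginal_tol`` of zero
    is flagged "marginal" rather than forced into a class.
    """
    jacobian = np.asarray(jacobian, dtype=float)
    if jacobian.shape != (2, 2) or not np.all(np.isfinite(jacobian)):
        raise ValueError("jacobian must be a finite 2x2 matrix")
    eigs = np.linalg.eigvals(jacobian)
    eigs = tuple(sorted((complex(e) for e in eigs),
                        key=lambda e: (e.real, e.imag)))
    det = float(np.linalg.det(jacobian))
    if det < 0:
        return "saddle", eigs
    re = [e.real for e in eigs]
    if any(abs(r) <= marginal_tol for r in re):
        return "marginal", eigs
    if all(r < 0 for r in re):
        return "stable", eigs
    return "unstable", eigs


def _composition_residual(v_m, d_v: float, d_m: float, p: ModelParameters):
    v_v = p.coupling.nu_vm * model.firing_rate(v_m, p.sigmoid) + d_v
    return p.coupling.nu_mv * model.firing_rate(v_v, p.sigmoid) + d_m - v_m


def find_equilibria(d_v: float, d_m: float, p: ModelParameters,
                    box: tuple[float, float] = BOUNDING_BOX,
                    ) -> list[FixedPoint]:
    """All isolated equilibria of the reduced system inside ``box``.

    Roots are isolated by sign changes of the scalar composition on a
    dense V_m grid and polished by Brent's method; each is classified by
    the reduced Jacobian.  Output is ordered by V_m descending (wake
    state first), deterministically.
    """
    lo, hi = box
    grid = np.linspace(lo, hi, _GRID_N)
    res = _composition_residual(grid, d_v, d_m, p)
    points: list[FixedPoint] = []
    sign = np.sign(res)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        root = brentq(_composition_residual, grid[i], grid[i + 1],
                      args=(d_v, d_m, p), xtol=1e-12, rtol=1e-14)
        v_m = float(root)
        v_v = float(p.coupling.nu_vm * model.firing_rate(v_m, p.sigmoid) + d_v)
        if not (lo <= v_v <= hi):
            continue
        f = reduced_rhs(v_v, v_m, d_v, d_m, p)
        residual = float(np.hypot(f[0], f[1]))
        stability, eigs = classify_fixed_point(reduced_jacobian(v_v, v_m, p))
        points.append(FixedPoint(v_v=v_v, v_m=v_m, stability=stability,
                                 eigenvalues=eigs, residual=residual))
    # grid points landing exactly on a root would be silently skipped by
    # the strict sign-change test; count them as unresolved candidates
    exact = np.flatnonzero(res == 0.0)
    for i in exact:
        v_m = float(grid[i])
        if not any(abs(fp.v_m - v_m) < 1e-9 for fp in points):
            v_v = float(p.coupling.nu_vm * model.firing_rate(v_m, p.sigmoid) + d_v)
            stability, eigs = classify_fixed_point(reduced_jacobian(v_v, v_m, p))
            points.append(FixedPoint(v_v=v_v, v_m=v_m, stability=stability,
                                     eigenvalues=eigs, residual=0.0))
    points.sort(key=lambda fp: -fp.v_m)
    return points


def compute_nullclines(d_v: float, d_m: float, p: ModelParameters,
                       resolution: int = 400,
                       box: tuple[float, float] = BOUNDING_BOX,
                       ) -> dict[str, np.ndarray]:
    """Sampled nullcline curves as (N, 2) arrays of (V_v, V_m) points.

    Both curves are single-valued graphs over the opposing potential, so
    the parameterization is trivially monotone in the scan variable.
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    lo, hi = box
    grid = np.linspace(lo, hi, resolution)
    vv_null = np.column_stack([
        p.coupling.nu_vm * model.firing_rate(grid, p.sigmoid) + d_v, grid])
    vm_null = np.column_stack([
        grid, p.coupling.nu_mv * model.firing_rate(grid, p.sigmoid) + d_m])
    return {"v_v": vv_null, "v_m": vm_null}


def compute_separatrix(d_v: float, d_m: float, p: ModelParameters,
                       fixed_points: list[FixedPoint] | None = None,
                       box: tuple[float, float] = BOUNDING_BOX,
                       eps: float = 1e-4, max_time: float = 2000.0,
                       ) -> np.ndarray:
    """Stable manifold of the saddle (the wake/sleep basin boundary).

    Integrates the reduced system backward in time from two points
    offset ``eps`` from the saddle along its stable eigenvector (both
    senses) until the trajectory leaves ``box``.  Returns an ordered
    (N, 2) array of (V_v, V_m) passing through the saddle.

    Raises ``ValueError`` when called in a monostable regime.
    """
    if fixed_points is None:
        fixed_points = find_equilibria(d_v, d_m, p, box)
    saddles = [fp for fp in fixed_points if fp.stability == "saddle"]
    if len(saddles) != 1:
        raise ValueError(
            "separatrix requires a bistable portrait with exactly one saddle; "
            f"found {len(saddles)}")
    saddle = saddles[0]
    jac = reduced_jacobian(saddle.v_v, saddle.v_m, p)
    eigvals, eigvecs = np.linalg.eig(jac)
    stable_idx = int(np.argmin(eigvals.real))
    if eigvals[stable_idx].real >= 0:
        raise ValueError("saddle has no stable eigendirection")
    direction = np.real(eigvecs[:, stable_idx])
    direction = direction / np.linalg.norm(direction)
    lo, hi = box

    def backward(t, y):
        f = reduced_rhs(y[0], y[1], d_v, d_m, p)
        return [-f[0], -f[1]]

    def leave_box(t, y):
        return min(y[0] - lo, hi - y[0], y[1] - lo, hi - y[1])
    leave_box.terminal = True
    leave_box.direction = -1

    branches = []
    for sense in (+1.0, -1.0):
        y0 = np.array([saddle.v_v, saddle.v_m]) + sense * eps * direction
        sol = solve_ivp(backward, (0.0, max_time), y0, events=leave_box,
                        rtol=1e-9, atol=1e-11, max_step=5.0, dense_output=True)
        ts = np.linspace(0.0, sol.t[-1], 400)
        branches.append(sol.sol(ts).T)
    curve = np.vstack([branches[0][::-1],
                       [[saddle.v_v, saddle.v_m]],
                       branches[1]])
    return curve


def region_label(fixed_points: list[FixedPoint]) -> str:
    """Region class from the equilibrium inventory at fixed drives."""
    stable = [fp for fp in fixed_points if fp.stability == "stable"]
    saddles = [fp for fp in fixed_points if fp.stability == "saddle"]
    if len(stable) == 2 and len(saddles) == 1:
        return "bistable"
    if len(stable) == 1 and not saddles:
        return "wake" if stable[0].is_wake else "sleep"
    raise ValueError(
        f"unexpected equilibrium structure: {len(stable)} stable, "
        f"{len(saddles)} saddle")


def portrait(d_v: float, d_m: float, p: ModelParameters,
             resolution: int = 400, with_separatrix: bool = True,
             box: tuple[float, float] = BOUNDING_BOX) -> PhasePortrait:
    """Complete phase portrait at frozen drives (D_v, D_m)."""
    fps = find_equilibria(d_v, d_m, p, box)
    region = region_label(fps)
    sep = None
    if region == "bistable" and with_separatrix:
        sep = compute_separatrix(d_v, d_m, p, fixed_points=fps, box=box)
    return PhasePortrait(
        d_v=d_v, d_m=d_m, fixed_points=fps,
        nullclines=compute_nullclines(d_v, d_m, p, resolution, box),
        separatrix=sep, region=region)


def saddle_node_points(d_v: float, p: ModelParameters,
                       box: tuple[float, float] = BOUNDING_BOX,
                       ) -> list[dict]:
    """Exact fold (saddle-node) points along a fixed-D_v scan line.

    At a fold the composition residual G(V_m; d_m) and its V_m
    derivative vanish together.  The tangency condition

        nu_vm nu_mv Q'(V_m) Q'(V_v(V_m)) = 1

    does not involve d_m, so each of its roots V_m* yields a fold with
    d_m* = V_m* - nu_mv Q(V_v(V_m*)).  The reduced Jacobian determinant
    is zero at these points up to root-finder precision.  Returns a list
    of dicts with keys v_m, v_v, d_m, det_jacobian, ordered by d_m.
    """
    lo, hi = box

    def tangency(v_m):
        v_v = p.coupling.nu_vm * model.firing_rate(v_m, p.sigmoid) + d_v
        return (p.coupling.nu_vm * p.coupling.nu_mv
                * _sigmoid_slope(v_m, p) * _sigmoid_slope(v_v, p)) - 1.0

    grid = np.linspace(lo, hi, _GRID_N)
    vals = np.array([tangency(v) for v in grid])
    sign = np.sign(vals)
    folds = []
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        v_m = brentq(tangency, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-15)
        v_v = float(p.coupling.nu_vm * model.firing_rate(v_m, p.sigmoid) + d_v)
        d_m = float(v_m - p.coupling.nu_mv * model.firing_rate(v_v, p.sigmoid))
        folds.append({
            "v_m": float(v_m), "v_v": v_v, "d_m": d_m,
            "det_jacobian": float(np.linalg.det(
                reduced_jacobian(v_v, v_m, p))),
        })
    folds.sort(key=lambda f: f["d_m"])
    return folds


def _count_equilibria(d_v: float, d_m: float, p: ModelParameters,
                      box: tuple[float, float],
                      with_label: bool = False):
    lo, hi = box
    grid = np.linspace(lo, hi, _GRID_N)
    res = _composition_residual(grid, d_v, d_m, p)
    sign = np.sign(res)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    count = len(crossings)
    if not with_label:
        return count
    if count >= 3:
        label = "bistable"
    else:
        # single equilibrium: classify by which population dominates at
        # the (grid-resolution) root
        v_m = grid[crossings[0]] if count else np.nan
        v_v = p.coupling.nu_vm * model.firing_rate(v_m, p.sigmoid) + d_v
        label = "wake" if v_m > v_v else "sleep"
    return count, label


def bistable_boundaries(d_v_range: tuple[float, float],
                        d_m_range: tuple[float, float],
                        p: ModelParameters, resolution: int = 41,
                        tol: float = 1e-3,
                        box: tuple[float, float] = BOUNDING_BOX) -> dict:
    """Saddle-node boundaries of the bistable wedge in the (D_v, D_m) plane.

    For each D_v on the scan grid, D_m values where the equilibrium
    count changes 1 <-> 3 are refined by bisection to ``tol`` (mV).  The
    upper fold is the *wake bifurcation boundary* (beyond it only wake
    is stable) and the lower fold the *sleep bifurcation boundary*.
    Scan lines with no bistable interval carry NaN; scan lines where the
    count profile is not a single 1-3-1 plateau are reported in
    ``anomalies`` rather than smoothed over.

    Returns a dict with ``d_v`` (grid), ``wake_boundary_d_m``,
    ``sleep_boundary_d_m``, ``region_map`` (resolution x resolution of
    {"wake","sleep","bistable"} codes along ``d_m_grid``), and
    ``anomalies``.
    """
    dv_lo, dv_hi = d_v_range
    dm_lo, dm_hi = d_m_range
    d_v_grid = np.linspace(dv_lo, dv_hi, resolution)
    d_m_grid = np.linspace(dm_lo, dm_hi, resolution)
    wake_b = np.full(resolution, np.nan)
    sleep_b = np.full(resolution, np.nan)
    region_map = np.empty((resolution, resolution), dtype=object)
    anomalies: list[str] = []

    def refine(d_v, lo_dm, hi_dm):
        # bisect a fold: count differs between lo_dm and hi_dm
        c_lo = _count_equilibria(d_v, lo_dm, p, box)
        while hi_dm - lo_dm > tol:
            mid = 0.5 * (lo_dm + hi_dm)
            if _count_equilibria(d_v, mid, p, box) == c_lo:
                lo_dm = mid
            else:
                hi_dm = mid
        return 0.5 * (lo_dm + hi_dm)

    for i, d_v in enumerate(d_v_grid):
        pairs = [_count_equilibria(d_v, d_m, p, box, with_label=True)
                 for d_m in d_m_grid]
        counts = np.array([c for c, _ in pairs])
        for j, (_, label) in enumerate(pairs):
            region_map[i, j] = label
        changes = np.flatnonzero(np.diff(counts) != 0)
        if len(changes) == 0:
            continue
        bad_counts = not set(np.unique(counts)) <= {1, 3}
        if bad_counts or len(changes) > 2 or counts[changes[0]] != 1:
            # non-monotone or unexpected count structure along the scan
            # line: reported as data, never smoothed over
            anomalies.append(
                f"d_v={d_v:.4f}: equilibrium count profile "
                f"{counts.tolist()} is not a single 1->3(->1) plateau")
            continue
        sleep_b[i] = refine(d_v, d_m_grid[changes[0]],
                            d_m_grid[changes[0] + 1])
        if len(changes) == 2:
            # wake fold inside the scanned range (otherwise the wedge
            # extends beyond the d_m ceiling and the entry stays NaN)
            wake_b[i] = refine(d_v, d_m_grid[changes[1]],
                               d_m_grid[changes[1] + 1])

    return {"d_v": d_v_grid, "d_m_grid": d_m_grid,
            "wake_boundary_d_m": wake_b, "sleep_boundary_d_m": sleep_b,
            "region_map": region_map, "anomalies": anomalies}
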