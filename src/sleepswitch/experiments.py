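"""Scripted in-silico experiments.

Reproductions of the model's standard protocols: normal (nominal)
dynamics, orexin-removal narcolepsy, the orexin-coupling sweep with
hypnogram statistics, the sleep-inertia study over the orexin time
constant, drive-plane trajectory traces, and a minimal forced-wake
(sleep-deprivation) demonstration.

Every experiment takes an explicit master seed; per-run seeds are
derived deterministically from it via `numpy.random.SeedSequence`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypnogram import (Hypnogram, SleepStats, label_states,
                        sleep_statistics, transition_aligned_average)
from .integrate import (Trajectory, initial_state, integrate_deterministic,
                        integrate_em)
from .params import SECONDS_PER_DAY, SECONDS_PER_HOUR, ModelParameters

__all__ = [
    "ScenarioSpec", "ScenarioResult", "SweepResult", "run_scenario",
    "orexin_sweep", "chronotype_phase", "sleep_inertia_experiment",
    "drive_plane_trace", "sleep_deprivation_demo", "derive_seed",
]

logger = logging.getLogger(__name__)

NOMINAL_NU_MO = ModelParameters.nominal().coupling.nu_mo

#: Preset for the clinical condition (about 90% orexin loss); total
#: removal (nu_mo = 0) is the default narcolepsy experiment.
NARCOLEPSY_90_PERCENT = {"nu_mo": 0.1 * NOMINAL_NU_MO}


def derive_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit child seed from a master seed and index key."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ScenarioSpec:
    """A reproducible simulation scenario.

    ``overrides`` maps bare parameter symbols (e.g. ``"nu_mo"``) to
    values; unknown symbols are rejected before any simulation starts.
    The equilibration segment is simulated and discarded; all derived
    artifacts come from the retained segment.
    """

    overrides: dict[str, float] = field(default_factory=dict)
    duration_days: float = 25.0
    equilibration_days: float = 3.0
    seed: int = 0
    noise: bool = True
    init: str = "awake"
    dt: float = 0.1
    record_dt: float = 1.0

    def validate(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.equilibration_days < 0:
            raise ValueError("equilibration_days must be >= 0")

    def build_params(self, base: ModelParameters | None = None) -> ModelParameters:
        base = base if base is not None else ModelParameters.nominal()
        return base.with_overrides(self.overrides)


@dataclass
class ScenarioResult:
    trajectory: Trajectory            # retained segment only
    hypnogram: Hypnogram
    stats: SleepStats
    params: ModelParameters
    spec: ScenarioSpec


def _simulate(spec: ScenarioSpec, params: ModelParameters,
              forced_dm: tuple[float, float, float] | None = None) -> Trajectory:
    t_eq = spec.equilibration_days * SECONDS_PER_DAY
    t_end = t_eq + spec.duration_days * SECONDS_PER_DAY
    init = initial_state(params, spec.init)
    if spec.noise:
        rec = max(1, int(round(spec.record_dt / spec.dt)))
        traj = integrate_em(params, init, (0.0, t_end), dt=spec.dt,
                            seed=spec.seed, record_every=rec,
                            forced_dm=forced_dm)
    else:
        if forced_dm is not None:
            raise ValueError("forced-wake protocols require the stochastic "
                             "integrator (noise on)")
        traj = integrate_deterministic(params, init, (0.0, t_end),
                                       grid_dt=spec.record_dt)
    return traj.window(t_eq, t_end + 1e-9)


def run_scenario(spec: ScenarioSpec,
                 base_params: ModelParameters | None = None) -> ScenarioResult:
    """Simulate a scenario and derive hypnogram + statistics.

    Fully reproducible: identical specs give identical outputs.
    """
    spec.validate()
    params = spec.build_params(base_params)   # rejects unknown symbols
    traj = _simulate(spec, params)
    hyp = label_states(traj)
    stats = sleep_statistics(hyp, traj)
    return ScenarioResult(trajectory=traj, hypnogram=hyp, stats=stats,
                          params=params, spec=spec)


@dataclass
class SweepResult:
    """Per-point hypnogram statistics across an orexin-coupling sweep."""

    nu_mo: np.ndarray
    stats: list[SleepStats]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nu, st in zip(self.nu_mo, self.stats):
            row = {"nu_mo": nu}
            row.update(st.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def orexin_sweep(base: ScenarioSpec, n_points: int = 51,
                 nu_mo_max: float = 2.0 * NOMINAL_NU_MO,
                 nu_mo_min: float = 0.0) -> SweepResult:
    """Hypnogram statistics at equally spaced orexin->MA couplings.

    Each grid point reruns the base scenario with only ``nu_mo``
    overridden (seed varied deterministically per point).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(nu_mo_min, nu_mo_max, n_points)
    stats = []
    for i, nu in enumerate(grid):
        spec = ScenarioSpec(
            overrides={**base.overrides, "nu_mo": float(nu)},
            duration_days=base.duration_days,
            equilibration_days=base.equilibration_days,
            seed=derive_seed(base.seed, i), noise=base.noise,
            init=base.init, dt=base.dt, record_dt=base.record_dt)
        result = run_scenario(spec)
        stats.append(result.stats)
        logger.info("sweep point %d/%d: nu_mo=%.4f, %.1f transitions/day",
                    i + 1, n_points, nu,
                    result.stats.transitions_per_day[0])
    return SweepResult(nu_mo=grid, stats=stats)


def _circular_mean_hours(hours: list[float]) -> float:
    ang = np.asarray(hours) * (2 * np.pi / 24.0)
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * 24.0 / (2 * np.pi)) % 24.0)


def chronotype_phase(sweep: SweepResult) -> pd.DataFrame:
    """Mean sleep-onset clock time per sweep point, consolidated points only.

    A point is consolidated when its median transitions/day equals 2 (a
    single daily sleep episode).  Onset times are averaged circularly.
    Returns an empty table (with a warning) if no point qualifies.
    """
    rows = []
    for nu, st in zip(sweep.nu_mo, sweep.stats):
        if st.transitions_per_day_median == 2 and st.sleep_onset_clock_times_h:
            rows.append({
                "nu_mo": nu,
                "sleep_onset_clock_h": _circular_mean_hours(
                    st.sleep_onset_clock_times_h),
                "n_onsets": len(st.sleep_onset_clock_times_h),
            })
    if not rows:
        logger.warning("chronotype_phase: no consolidated sweep points")
        return pd.DataFrame(columns=["nu_mo", "sleep_onset_clock_h", "n_onsets"])
    return pd.DataFrame(rows)


def sleep_inertia_experiment(tau_o_values: list[float] | None = None,
                             n_runs: int = 50, window: float = 1800.0,
                             seed: int = 0,
                             base_params: ModelParameters | None = None,
                             dt: float = 0.1) -> dict[float, dict]:
    """Transition-aligned firing-rate traces as a function of tau_o.

    For each orexin time constant, ``n_runs`` replicate noisy runs are
    simulated from a common deterministic 3-day equilibration, aligned
    at the first morning sleep-to-wake transition (and, separately, the
    evening wake-to-sleep transition), and averaged.  The result maps
    tau_o to a dict with ``sleep_to_wake`` / ``wake_to_sleep`` aligned
    traces and ``qo_saturation_time_s``, the time after waking at which
    the mean orexin firing rate first reaches 95% of its steady
    post-waking level (30-s window-averaged).
    """
    if tau_o_values is None:
        tau_o_values = [10.0, 120.0, 600.0]
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    base = base_params if base_params is not None else ModelParameters.nominal()
    out: dict[float, dict] = {}
    for k, tau_o in enumerate(tau_o_values):
        params = base.with_overrides({"tau_o": float(tau_o)})
        t_eq = 3.0 * SECONDS_PER_DAY
        eq = integrate_deterministic(params, initial_state(params),
                                     (0.0, t_eq), grid_dt=60.0)
        init = eq.final_state()
        runs = []
        horizon = 26.0 * SECONDS_PER_HOUR
        rec = max(1, int(round(1.0 / dt)))
        for r in range(n_runs):
            traj = integrate_em(params, init, (t_eq, t_eq + horizon), dt=dt,
                                seed=derive_seed(seed, k, r),
                                record_every=rec)
            runs.append(traj)
        s2w = transition_aligned_average(runs, "sleep_to_wake", window)
        w2s = transition_aligned_average(runs, "wake_to_sleep", window)
        out[tau_o] = {
            "sleep_to_wake": s2w,
            "wake_to_sleep": w2s,
            "qo_saturation_time_s": (
                np.nan if s2w is None
                else qo_saturation_time(s2w["t"], s2w["mean_q_o"],
                                        steady_at_s=5.0 * tau_o)),
        }
    return out


def qo_saturation_time(t: np.ndarray, mean_q_o: np.ndarray,
                       smooth_s: float = 30.0, level: float = 0.95,
                       steady_tail_s: float = 300.0,
                       steady_at_s: float | None = None) -> float:
    """First post-transition time at which Q_o reaches ``level`` of steady.

    The trace is smoothed with a ``smooth_s`` moving average.  The
    steady post-waking level is estimated either as a 60-s average
    centred at ``steady_at_s`` (use ~5 relaxation time constants, so the
    relaxation is complete but the slow circadian creep of the waking
    level is excluded) or, when ``steady_at_s`` is None, as the smoothed
    mean over the final ``steady_tail_s`` of the window.  Returns NaN
    when the level is not reached inside the window.
    """
    step = float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_s / step)))
    kernel = np.ones(w) / w
    sm = np.convolve(mean_q_o, kernel, mode="same")
    post = t >= 0
    t_post, q_post = t[post], sm[post]
    if steady_at_s is not None:
        t_ref = min(steady_at_s, t_post[-1] - 30.0)
        near = np.abs(t_post - t_ref) <= 30.0
        steady = float(np.mean(q_post[near]))
    else:
        tail = q_post[t_post >= t_post[-1] - steady_tail_s]
        steady = float(np.mean(tail))
    target = level * steady
    above = np.flatnonzero(q_post >= target)
    if len(above) == 0:
        return float("nan")
    return float(t_post[above[0]])


def drive_plane_trace(traj: Trajectory, debounce_s: float = 60.0) -> pd.DataFrame:
    """Trajectory expressed in the (D_v, D_m) drive plane, state-tagged.

    With the orexin->MA coupling at zero the trace is a horizontal
    segment at constant D_m; nominally it is a daily loop through the
    wake, bistable, and sleep regions.
    """
    hyp = label_states(traj, debounce_s=debounce_s)
    d = traj.derived
    state = np.empty(len(traj), dtype=object)
    for a, b, s in hyp.intervals:
        state[(traj.times >= a) & (traj.times < b)] = s
    state[state == None] = hyp.intervals[-1][2]  # noqa: E711 (trailing sample)
    return pd.DataFrame({"t_s": traj.times, "d_v": d["d_v"],
                         "d_m": d["d_m"], "state": state})


def sleep_deprivation_demo(spec: ScenarioSpec,
                           forced_wake_interval: tuple[float, float],
                           forced_drive_mV: float = 2.0,
                           base_params: ModelParameters | None = None) -> dict:
    """Minimal total-sleep-deprivation protocol via a wake-effort drive.

    A constant externally imposed drive (mV) is added to D_m during
    ``forced_wake_interval`` (seconds, relative to the start of the
    retained segment).  Returns the forced and unforced results plus the
    homeostatic build-up at the end of the forced interval and the first
    recovery sleep bout length against the unforced baseline.
    """
    spec.validate()
    if not spec.noise:
        raise ValueError("deprivation demo uses the stochastic protocol")
    params = spec.build_params(base_params)
    t_eq = spec.equilibration_days * SECONDS_PER_DAY
    f0, f1 = forced_wake_interval
    if not (0 <= f0 < f1 <= spec.duration_days * SECONDS_PER_DAY):
        raise ValueError("forced interval must lie within the retained record")
    forced = (t_eq + f0, t_eq + f1, forced_drive_mV)

    base_traj = _simulate(spec, params)
    forced_traj = _simulate(spec, params, forced_dm=forced)
    base_hyp = label_states(base_traj)
    forced_hyp = label_states(forced_traj)

    t_end_forced = t_eq + f1
    h_forced = float(np.interp(t_end_forced, forced_traj.times, forced_traj.h))
    h_base = float(np.interp(t_end_forced, base_traj.times, base_traj.h))
    rec_sleeps = [(a, b) for a, b in forced_hyp.bouts("sleep")
                  if a >= t_end_forced]
    base_sleeps = [b - a for a, b in base_hyp.bouts("sleep")]
    return {
        "baseline": base_traj, "forced": forced_traj,
        "baseline_hypnogram": base_hyp, "forced_hypnogram": forced_hyp,
        "h_end_forced": h_forced, "h_end_baseline": h_base,
        "recovery_sleep_s": (rec_sleeps[0][1] - rec_sleeps[0][0]
                             if rec_sleeps else float("nan")),
        "baseline_mean_sleep_s": float(np.mean(base_sleeps))
        if base_sleeps else float("nan"),
    }
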