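"""Hypnograms and sleep-wake statistics.

A trajectory is scored into wake/sleep by an instantaneous criterion
(default: wake iff V_m > V_v, ties resolved to the previous state), and
transient fluctuations shorter than a debounce window (nominal 60 s)
are merged into their surrounding state.  Statistics follow the
conventions of the model experiments: whole simulated days only,
state-conditioned firing-rate means obtained by masking the trajectory
with the hypnogram intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integrate import Trajectory
from .params import SECONDS_PER_DAY, SECONDS_PER_HOUR

__all__ = ["Hypnogram", "SleepStats", "label_states", "sleep_statistics",
           "transition_aligned_average"]

WAKE, SLEEP = "wake", "sleep"

#: Selectable instantaneous scoring criteria.
CRITERIA = ("vm_gt_vv", "qm_threshold")


@dataclass
class Hypnogram:
    """Ordered, contiguous, alternating wake/sleep intervals.

    ``intervals`` is a list of (start_s, end_s, state).  After
    debouncing, every interval is at least ``debounce_s`` long except
    possibly the first and last (edge truncation).
    """

    intervals: list[tuple[float, float, str]]
    debounce_s: float = 60.0
    source: str = ""

    def __post_init__(self):
        for (a, b, s), (a2, b2, s2) in zip(self.intervals, self.intervals[1:]):
            if not (b == a2 and s != s2):
                raise ValueError("intervals must be contiguous and alternating")

    @property
    def n_transitions(self) -> int:
        return len(self.intervals) - 1

    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def end(self) -> float:
        return self.intervals[-1][1]

    def bouts(self, state: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, s in self.intervals if s == state]

    def state_at(self, t: float) -> str:
        for a, b, s in self.intervals:
            if a <= t < b:
                return s
        raise ValueError(f"time {t} outside hypnogram range")

    def transition_times(self, kind: str) -> list[float]:
        """Times of transitions; kind is 'sleep_to_wake' or 'wake_to_sleep'."""
        target = WAKE if kind == "sleep_to_wake" else SLEEP
        return [b[0] for a, b in zip(self.intervals, self.intervals[1:])
                if b[2] == target]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals,
                            columns=["start_s", "end_s", "state"])


@dataclass
class SleepStats:
    """Per-day sleep-wake summary statistics (means and SDs)."""

    n_days: int
    transitions_per_day: tuple[float, float]
    transitions_per_day_median: float
    total_sleep_per_day_h: tuple[float, float]
    sleep_bout_durations_s: tuple[float, float]
    wake_bout_durations_s: tuple[float, float]
    mean_q_m_wake: float
    mean_q_v_sleep: float
    mean_h: float
    sleep_onset_clock_times_h: list[float] = field(default_factory=list)

    def to_dict(self) -> dict[str, float]:
        return {
            "n_days": self.n_days,
            "transitions_per_day_mean": self.transitions_per_day[0],
            "transitions_per_day_sd": self.transitions_per_day[1],
            "transitions_per_day_median": self.transitions_per_day_median,
            "total_sleep_per_day_h_mean": self.total_sleep_per_day_h[0],
            "total_sleep_per_day_h_sd": self.total_sleep_per_day_h[1],
            "sleep_bout_durations_s_mean": self.sleep_bout_durations_s[0],
            "sleep_bout_durations_s_sd": self.sleep_bout_durations_s[1],
            "wake_bout_durations_s_mean": self.wake_bout_durations_s[0],
            "wake_bout_durations_s_sd": self.wake_bout_durations_s[1],
            "mean_q_m_wake": self.mean_q_m_wake,
            "mean_q_v_sleep": self.mean_q_v_sleep,
            "mean_h": self.mean_h,
        }


def _raw_labels(traj: Trajectory, criterion: str, threshold: float) -> np.ndarray:
    if criterion == "vm_gt_vv":
        diff = traj.v_m - traj.v_v
    elif criterion == "qm_threshold":
        diff = traj.derived["q_m"] - threshold
    else:
        raise ValueError(f"unknown criterion {criterion!r}; one of {CRITERIA}")
    wake = diff > 0
    ties = np.flatnonzero(diff == 0)
    for i in ties:  # hysteresis-consistent: a tie keeps the previous state
        wake[i] = wake[i - 1] if i > 0 else wake[i + 1] if len(wake) > 1 else True
    return wake


def _runs(wake: np.ndarray) -> tuple[list[bool], list[int]]:
    idx = np.flatnonzero(np.diff(wake.view(np.int8))) + 1
    starts = np.concatenate(([0], idx))
    ends = np.concatenate((idx, [len(wake)]))
    return [bool(wake[s]) for s in starts], list(ends - starts)


def _merge_short_runs(labels: list[bool], lengths: list[float],
                      min_len: float) -> tuple[list[bool], list[float]]:
    """Iteratively absorb the shortest interior run below ``min_len``.

    Shortest-first makes the merge order-independent.  Edge runs are
    kept even when short (they have no neighbour on one side).
    """
    labels, lengths = list(labels), list(lengths)
    while len(labels) > 2:
        interior = range(1, len(labels) - 1)
        short = [i for i in interior if lengths[i] < min_len]
        if not short:
            break
        i = min(short, key=lambda j: (lengths[j], j))
        labels[i] = labels[i - 1]
        merged_lab, merged_len = [labels[0]], [lengths[0]]
        for lab, ln in zip(labels[1:], lengths[1:]):
            if lab == merged_lab[-1]:
                merged_len[-1] += ln
            else:
                merged_lab.append(lab)
                merged_len.append(ln)
        labels, lengths = merged_lab, merged_len
    return labels, lengths


def label_states(traj: Trajectory, debounce_s: float = 60.0,
                 criterion: str = "vm_gt_vv",
                 threshold: float = 1.0) -> Hypnogram:
    """Score a trajectory into a debounced wake/sleep hypnogram.

    Raw per-sample labels come from the instantaneous criterion; any run
    of samples shorter than ``debounce_s`` is then merged into its
    surrounding state (shortest run first), so the output alternates and
    every interior interval is at least ``debounce_s`` long.
    """
    if len(traj) == 0:
        raise ValueError("cannot label an empty trajectory")
    step = traj.sample_interval
    if debounce_s > 0 and step > debounce_s / 10.0:
        raise ValueError(
            f"trajectory sampling interval {step:.3g} s too coarse for a "
            f"{debounce_s:.3g} s debounce (need <= debounce/10)")
    wake = _raw_labels(traj, criterion, threshold)
    labels, counts = _runs(wake)
    lengths = [c * step for c in counts]
    labels, lengths = _merge_short_runs(labels, lengths, debounce_s)
    t0 = float(traj.times[0])
    edges = t0 + np.concatenate(([0.0], np.cumsum(lengths)))
    edges[-1] = float(traj.times[-1]) + step  # cover the final sample
    intervals = [(float(a), float(b), WAKE if lab else SLEEP)
                 for a, b, lab in zip(edges[:-1], edges[1:], labels)]
    return Hypnogram(intervals=intervals, debounce_s=debounce_s,
                     source=traj.fingerprint())


def sleep_statistics(hyp: Hypnogram, traj: Trajectory) -> SleepStats:
    """Per-day statistics of a hypnogram over whole days only.

    The record is truncated to an integer number of days from its start.
    State-conditioned firing-rate means mask the trajectory with the
    hypnogram intervals; sleep-onset clock times are the wake->sleep
    transition times modulo 24 h.
    """
    record_len = hyp.end - hyp.start
    n_days = int(record_len // SECONDS_PER_DAY)
    if n_days < 1:
        raise ValueError("record must cover at least one whole day")
    t_stop = hyp.start + n_days * SECONDS_PER_DAY

    day_edges = hyp.start + SECONDS_PER_DAY * np.arange(n_days + 1)
    trans = np.array([b[0] for a, b in zip(hyp.intervals, hyp.intervals[1:])])
    trans = trans[trans < t_stop]
    per_day_trans = np.histogram(trans, bins=day_edges)[0]
    if hyp.intervals[0][2] != hyp.state_at(t_stop - 1e-6):
        # cyclic closure: a record that ends in the opposite state wraps
        # through one more transition (keeps 2 x sleep-bouts/day exact
        # for periodic records)
        per_day_trans[-1] += 1

    sleep_per_day = np.zeros(n_days)
    sleep_bouts, wake_bouts = [], []
    onsets = []
    for (a, b, s), prev in zip(hyp.intervals,
                               [None] + hyp.intervals[:-1]):
        a_c, b_c = max(a, hyp.start), min(b, t_stop)
        if b_c <= a_c:
            continue
        if s == SLEEP:
            d0 = int((a_c - hyp.start) // SECONDS_PER_DAY)
            d1 = int((b_c - hyp.start - 1e-9) // SECONDS_PER_DAY)
            for d in range(d0, d1 + 1):
                lo = hyp.start + d * SECONDS_PER_DAY
                hi = lo + SECONDS_PER_DAY
                sleep_per_day[d] += max(0.0, min(b_c, hi) - max(a_c, lo))
            sleep_bouts.append(b - a)
            if prev is not None and a < t_stop:
                onsets.append((a / SECONDS_PER_HOUR) % 24.0)
        else:
            wake_bouts.append(b - a)

    times, states = traj.times, traj.states
    mask_keep = times < t_stop
    wake_mask = np.zeros(len(times), dtype=bool)
    for a, b, s in hyp.intervals:
        if s == WAKE:
            wake_mask |= (times >= a) & (times < b)
    d = traj.derived
    in_wake = wake_mask & mask_keep
    in_sleep = (~wake_mask) & mask_keep
    mean_q_m_wake = float(np.mean(d["q_m"][in_wake])) if in_wake.any() else np.nan
    mean_q_v_sleep = float(np.mean(d["q_v"][in_sleep])) if in_sleep.any() else np.nan

    def ms(x):
        x = np.asarray(x, dtype=float)
        if len(x) == 0:
            return (np.nan, np.nan)
        return (float(np.mean(x)), float(np.std(x)))

    return SleepStats(
        n_days=n_days,
        transitions_per_day=ms(per_day_trans),
        transitions_per_day_median=float(np.median(per_day_trans)),
        total_sleep_per_day_h=ms(sleep_per_day / SECONDS_PER_HOUR),
        sleep_bout_durations_s=ms(sleep_bouts),
        wake_bout_durations_s=ms(wake_bouts),
        mean_q_m_wake=mean_q_m_wake,
        mean_q_v_sleep=mean_q_v_sleep,
        mean_h=float(np.mean(states[mask_keep, 3])),
        sleep_onset_clock_times_h=onsets,
    )


def transition_aligned_average(runs: list[Trajectory], kind: str,
                               window: float, debounce_s: float = 60.0,
                               min_prior_bout: float = 1800.0,
                               ) -> dict[str, np.ndarray] | None:
    """Mean and SD traces of Q_v, Q_m, Q_o aligned at a state transition.

    Each run is re-timed so that its first qualifying transition of
    ``kind`` ("sleep_to_wake" or "wake_to_sleep") preceded by a bout of
    at least ``min_prior_bout`` seconds sits at t = 0, then all runs are
    sampled on a common grid spanning ``window`` seconds either side and
    averaged pointwise.  Runs with no qualifying transition are excluded
    (and reported in the result) rather than silently averaged.

    Returns a dict with ``t`` (relative time), ``mean_q_v/m/o``,
    ``sd_q_v/m/o``, ``n_runs``, and ``n_excluded``.
    """
    if kind not in ("sleep_to_wake", "wake_to_sleep"):
        raise ValueError(f"unknown transition kind {kind!r}")
    aligned = []
    excluded = 0
    grid = None
    for traj in runs:
        hyp = label_states(traj, debounce_s=debounce_s)
        t_align = None
        for (a, b, s), nxt in zip(hyp.intervals, hyp.intervals[1:]):
            is_kind = (nxt[2] == WAKE) == (kind == "sleep_to_wake")
            if is_kind and (b - a) >= min_prior_bout:
                t_align = b
                break
        if t_align is None:
            excluded += 1
            continue
        if grid is None:
            step = traj.sample_interval
            grid = np.arange(-window, window + 0.5 * step, step)
        rel = traj.times - t_align
        if rel[0] > -window or rel[-1] < window:
            excluded += 1
            continue
        d = traj.derived
        aligned.append([np.interp(grid, rel, d[k])
                        for k in ("q_v", "q_m", "q_o")])
    if not aligned:
        return None
    arr = np.array(aligned)  # (runs, 3, n_grid)
    return {
        "t": grid,
        "mean_q_v": arr[:, 0].mean(axis=0), "sd_q_v": arr[:, 0].std(axis=0),
        "mean_q_m": arr[:, 1].mean(axis=0), "sd_q_m": arr[:, 1].std(axis=0),
        "mean_q_o": arr[:, 2].mean(axis=0), "sd_q_o": arr[:, 2].std(axis=0),
        "n_runs": len(aligned), "n_excluded": excluded,
    }
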