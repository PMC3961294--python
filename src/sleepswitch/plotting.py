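"""Optional figure-mirroring plot helpers (matplotlib).

Small conveniences for the standard views: a phase portrait with
nullclines (solid/dashed), equilibria (filled/open circles) and the
separatrix (dotted); a sleep/wake raster strip; and transition-aligned
firing-rate traces with +-1 SD bands.
"""

from __future__ import annotations

import numpy as np

from .hypnogram import Hypnogram
from .phaseplane import PhasePortrait


def plot_portrait(p: PhasePortrait, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(*p.nullclines["v_v"].T, "-", color="tab:red", lw=1.2,
            label="$V_v$ nullcline")
    ax.plot(*p.nullclines["v_m"].T, "--", color="tab:blue", lw=1.2,
            label="$V_m$ nullcline")
    if p.separatrix is not None:
        ax.plot(*p.separatrix.T, ":", color="k", lw=1.0, label="separatrix")
    for fp in p.fixed_points:
        filled = fp.stability == "stable"
        ax.plot(fp.v_v, fp.v_m, "o", ms=7, mec="k",
                mfc="k" if filled else "none")
    ax.set_xlabel("$V_v$ (mV)")
    ax.set_ylabel("$V_m$ (mV)")
    ax.set_title(f"$D_v$={p.d_v:.2f}, $D_m$={p.d_m:.2f} mV ({p.region})")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_raster(hyp: Hypnogram, ax=None, day_length: float = 86400.0):
    """Sleep (black) / wake (white) strip, one row per simulated day."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2))
    t0 = hyp.start
    for a, b, s in hyp.intervals:
        if s != "sleep":
            continue
        d0 = int((a - t0) // day_length)
        d1 = int((b - t0) // day_length)
        for d in range(d0, d1 + 1):
            lo = max(a, t0 + d * day_length) - t0 - d * day_length
            hi = min(b, t0 + (d + 1) * day_length) - t0 - d * day_length
            if hi > lo:
                ax.broken_barh([(lo / 3600.0, (hi - lo) / 3600.0)],
                               (d, 0.9), color="k")
    n_days = int((hyp.end - t0) // day_length) + 1
    ax.set_xlim(0, 24)
    ax.set_ylim(n_days, 0)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("day")
    return ax


def plot_aligned_traces(aligned: dict, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    t_min = aligned["t"] / 60.0
    for key, color, label in (("q_m", "tab:blue", "$Q_m$"),
                              ("q_v", "k", "$Q_v$"),
                              ("q_o", "tab:green", "$Q_o$")):
        m, s = aligned[f"mean_{key}"], aligned[f"sd_{key}"]
        ax.plot(t_min, m, color=color, label=label)
        ax.plot(t_min, m + s, ":", color=color, lw=0.8)
        ax.plot(t_min, np.clip(m - s, 0, None), ":", color=color, lw=0.8)
    ax.axvline(0.0, color="gray", lw=0.6)
    ax.set_xlabel("time from transition (min)")
    ax.set_ylabel("firing rate (s$^{-1}$)")
    ax.legend(fontsize=8)
    return ax
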