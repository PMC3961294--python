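# Methods

## Model

`sleepswitch` implements a neural-mass model of the sleep–wake switch.
Three populations are tracked by their mean cell-body potential relative
to rest, `V_j` (mV): the sleep-active ventrolateral preoptic nucleus
(VLPO, `j = v`), the wake-active monoaminergic brainstem/hypothalamic
group (MA, `j = m`; TMN, LC, DR, VTA lumped), and the orexinergic
neurons of the lateral hypothalamus (Orx, `j = o`).  Each population
fires at the sigmoidal rate

    Q(V) = Q_max / (1 + exp(-(V - theta) / sigma'))

with `Q_max = 100 s^-1`, `theta = 10 mV`, `sigma' = 3 mV` shared by all
three populations.  The coupled dynamics are

    tau_v dV_v/dt = nu_vm Q(V_m) + D_v - V_v + xi_v(t)
    tau_m dV_m/dt = nu_mv Q(V_v) + D_m - V_m + xi_m(t)
    tau_o dV_o/dt = nu_ov Q(V_v) + nu_om Q(V_m) + D_o - V_o
    chi  dH/dt    = mu (1 - exp(-Q(V_m)/q_sat)) - H

with net drives

    D_v = nu_vc C(t) + nu_vh H + a_v
    D_m = nu_mo Q(V_o) + a_m
    D_o = nu_oc C(t) + nu_oh H + a_o
    C(t) = cos(omega (t - t_acro)),   omega = 2*pi / 24 h.

`nu_vm, nu_mv < 0` implement the VLPO–MA mutual inhibition (the
flip-flop), `nu_ov < 0` the inhibition of Orx by the VLPO, and
`nu_mo >= 0` the excitation of the MA by Orx — the only route by which
Orx affects the switch, so orexin loss is modelled by reducing the
single parameter `nu_mo`.  The MA→Orx weight `nu_om` and the
homeostatic input to Orx `nu_oh` are fixed at 0 by default (settable,
since small nonzero values are physiologically conceivable).  `H` is
the homeostatic sleep drive: it accumulates while the MA fire and
clears with time constant `chi = 45 h` during sleep.  Its production
saturates at `mu` for large `Q_m` so that waking states of very
different arousal levels build sleep pressure comparably; the specific
saturating form above (exponential approach, scale `q_sat`) is this
package's formulation of that requirement, chosen because among
bounded two-constant forms it is the one that simultaneously yields an
entrained 24-h cycle with roughly 8 h of sleep at nominal parameters
and a near-constant daily sleep total when `nu_mo` is swept to zero.

Nominal parameter values (the `ModelParameters.nominal()` constructor
is the single source of truth; every value is transcribed exactly once):

| group | values |
|---|---|
| couplings (mV s) | `nu_vm = -2.1`, `nu_mv = -1.8`, `nu_ov = -1.0`, `nu_mo = 0.30`, `nu_om = 0` |
| drives (mV) | `nu_vc = -0.30`, `nu_vh = 1.0` (per H unit), `nu_oc = 1.0`, `nu_oh = 0`, `a_v = -8.5`, `a_m = 0.52`, `a_o = 1.0` |
| time constants (s) | `tau_v = tau_m = 10`, `tau_o = 120` |
| homeostat | `chi = 45 h`, `mu = 17`, `q_sat = 2.3 s^-1` |
| noise (mV) | `sigma_v = sigma_m = 1` |

`H` is stored dimensionless; `nu_vh` carries its conversion to mV of
drive.  The circadian acrophase `t_acro` defaults to 15:00 so that the
emergent entrained schedule sleeps about 23:10–07:50 — a typical human
schedule with the circadian maximum in the mid-afternoon of the waking
day.  The acrophase only anchors clock labels; all phase *differences*
(e.g. chronotype shifts) are independent of it.

## Stochastic integration

The noise terms `xi_v, xi_m` are independent zero-mean Gaussian white
noises with standard-deviation parameter `sigma_j`, entering the VLPO
and MA equations only.  The stochastic system is integrated with a
fixed-step Euler–Maruyama scheme (default `dt = 0.1 s`, compiled with
numba).  Applying Euler–Maruyama to the equations as written gives the
per-step increment `(sigma_j / tau_j) * sqrt(dt) * z`, which is the
default discretization; a `per-step` convention (`sigma` read as the
standard deviation of a sample held over one step) is selectable via
`NoiseParams.scaling_convention`.  Under the default convention the
stationary potential fluctuation in a pinned state is
`sigma / sqrt(2 tau) ≈ 0.22 mV`, small against the ~10 mV separation
of the wake and sleep branches, so transitions happen only where the
bistable thresholds are low.  The noise-free system is integrated with
scipy's LSODA (stiff-capable, adaptive) and resampled from dense
output onto a uniform grid.

`(parameters, initial state, dt, seed)` determine every trajectory
bit-for-bit; per-run seeds in experiments derive deterministically from
a master seed via `numpy.random.SeedSequence`.  `convergence_report`
tabulates summary-statistic discrepancies over a `dt` refinement ladder
so users can verify the default step for their scenario; transition
counts at `dt = 0.2…0.02 s` agree within day-to-day noise.

Long stochastic runs are recorded on a 1-s grid (the integration step
stays `dt`); that is 60x finer than the 60-s labeling debounce and
keeps a 28-day record ~80 MB instead of ~8 GB at full `dt` resolution.

## Phase-plane analysis

On timescales of seconds the drives `(D_v, D_m)` vary slowly and act
as control parameters of the fast `(V_v, V_m)` subsystem.  Both
nullclines are explicit graphs, so equilibria are isolated as sign
changes of the scalar composition `nu_mv Q(nu_vm Q(V_m) + D_v) + D_m -
V_m` on a 3001-point grid and polished by Brent's method — a
deterministic procedure (no random multistart); they are classified by
the eigenvalues of the analytic 2x2 Jacobian (saddle iff det < 0;
marginal eigenvalues flagged, never forced into a class).  The search
box is `V_v, V_m ∈ [-30, 15] mV`: the suppressed population sits near
`nu Q + D ≈ -25 mV` at drives of ~4 mV, so a tighter box would discard
genuine equilibria.  The separatrix is the saddle's stable manifold,
obtained by integrating the reduced flow backward in time from ±1e-4
offsets along the stable eigenvector until the box is left.  The
bistable wedge in the `(D_v, D_m)` plane is mapped two ways: bisection
of the equilibrium count along scan lines (tolerance 1e-3 mV), and
exactly, via the tangency condition `nu_vm nu_mv Q'(V_m) Q'(V_v) = 1`,
whose roots give fold points with singular Jacobian to solver
precision.  Scan lines whose equilibrium-count profile is not a single
1→3(→1) plateau are reported as anomalies, never smoothed.  The wedge
depends only on the VLPO–MA couplings and the sigmoid, not on any
orexin-side parameter (asserted in tests).

## Hypnograms and statistics

Wake is scored instantaneously as `V_m > V_v` (equivalently
`Q_m > Q_v`, the sigmoid being shared and monotone); ties keep the
previous state.  The criterion is configurable (`qm_threshold` scores
wake as `Q_m` above a fixed rate).  Runs of samples shorter than the
60-s debounce are merged into their surrounding state, shortest run
first, which makes the merge order-independent; edge runs are kept
even when short.  Labeling requires the trajectory sampling interval
to be at most one tenth of the debounce.  In the consolidated regime
the scored hypnogram is insensitive to these choices; in the strongly
fragmented regime (orexin removed) the transition *count* retains a
factor-~1.5 sensitivity to the exact heuristic — e.g. sampling the
state on a 60-s grid instead of merging sub-60-s runs raises the count
by roughly that factor — so fragmentation rates should be compared
across conditions scored with one fixed heuristic, not across
heuristics.

Statistics are computed over whole days only: per-day transition
counts (with cyclic closure when a record ends in the opposite state
to its start, so a periodic 16 h/8 h record scores exactly 2/day),
daily sleep totals, bout-duration moments, state-conditioned firing
means by masking the trajectory with the hypnogram, and sleep-onset
clock times (averaged circularly).

Transition-aligned averaging re-times each run so its first qualifying
transition (preceded by a bout of at least 30 min) sits at t = 0, then
averages pointwise on a common grid; runs without a qualifying
transition are excluded and counted, never silently averaged.  The
post-waking saturation time of `Q_o` is the first time its smoothed
(30-s) aligned mean reaches 95% of the steady post-waking level.  The
steady level is estimated 5 relaxation time constants after the
transition: by then the exponential approach is complete to <1%, while
the slow circadian creep of the waking level (which would inflate a
tail-of-window estimate and bias the crossing late) is excluded.  For
an exponential relaxation this measure sits at ~3 tau_o, i.e. ~6 min
at the nominal `tau_o = 120 s`.

## Experiments

All scenario experiments share one protocol: simulate
`equilibration_days` (default 3) from a preset initial state, discard
it, and derive every artifact from the retained segment.  The
narcolepsy default is total orexin removal (`nu_mo = 0`); the ~90%
clinical loss is provided as a preset.  The orexin sweep re-runs the
base scenario on an equally spaced `nu_mo` grid (default 51 points,
0–0.6 mV s, i.e. up to twice nominal, since higher orexin levels are
predicted to delay the sleep episode); the chronotype table restricts
to consolidated points (median 2 transitions/day).  The sleep-inertia
study aligns 50 replicate runs per `tau_o` at the morning awakening
and the evening sleep onset.  The sleep-deprivation demonstration adds
a constant wake-effort drive to `D_m` during a forced interval; the
magnitude is a free parameter (default 2 mV) — it is not calibrated to
any external protocol.

## What the simulations do and do not emulate

All data in this package are generated by the model itself; there is
no fitting to recorded hypnograms.  The simulated records emulate:
consolidated ~16 h/8 h human sleep–wake cycles entrained to a 24-h
day; severe state fragmentation with preserved daily sleep amount when
orexin signalling is removed; phase advance of sleep onset with
reduced orexin coupling; and a gradual, orexin-paced morning rise of
arousal (sleep inertia).  They do not emulate REM/NREM architecture,
cataplexy, naps driven by behaviour, light-dependent circadian
entrainment (the circadian drive is a fixed sinusoid), or
inter-individual variability beyond explicit parameter overrides.
Passing tests therefore certify the dynamical mechanism, not clinical
calibration.

## Numerical choices and degenerate inputs

- Default `dt = 0.1 s`; ship `convergence_report` rather than assert a
  universal step.  Reporting grid 1 s (stochastic) / 1 s resampled
  (deterministic).
- Sigmoid evaluated in overflow-safe form; beyond ~37 sigma' from
  threshold it saturates to exactly 0 or `Q_max` in float64.
- A non-finite state aborts integration with the offending time; a
  negative `H` is an error, never silently clamped.
- Equilibration presets relax the potentials onto the requested branch
  by fixed-point iteration at frozen drives; `H` starts at 10.5
  (mid-cycle) and the 3-day equilibration absorbs the residual.
- Bisection tolerance for fold boundaries: 1e-3 mV; root residuals
  below 1e-9; marginal-eigenvalue tolerance 1e-9.
- Config round-trips use `repr` floats; trajectory CSV uses 17
  significant digits and `float_precision="round_trip"` parsing, so
  file round-trips are bit-exact.

## Known limitations

- The fragmented-regime transition count depends on the labeling
  heuristic (see above); the package fixes one heuristic and exposes
  the alternatives.
- The Euler–Maruyama scheme is strong order 0.5; no Milstein or
  adaptive stochastic stepping (additive noise makes EM = Milstein
  here, but step-size control is still fixed).
- The circadian drive is a pure sinusoid; no dynamic oscillator, no
  light input, no jet-lag/shift-work re-entrainment dynamics.
- Sleep is binary; no staging.
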