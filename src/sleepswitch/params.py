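"""Model parameters for the orexin-extended sleep-wake switch.

The model couples three neural-mass populations -- the sleep-active
ventrolateral preoptic nucleus (VLPO), the wake-active monoaminergic
nuclei (MA), and the orexinergic neurons of the lateral hypothalamus
(Orx) -- with a 24-h sinusoidal circadian drive and a homeostatic sleep
drive H.  Every symbol of the governing equations lives here, grouped the
way the nominal parameter table groups them, and the nominal constructor
is the single source of truth for the nominal values.

Units are SI seconds/millivolts internally (the homeostatic clearance
time ``chi`` is stored in seconds, displayed in hours by the config
layer).  H is dimensionless; the weight ``nu_vh`` carries its conversion
into millivolts of drive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0

#: Scaling conventions for discretizing the white-noise terms of the
#: VLPO/MA equations (see NoiseParams.scaling_convention).
NOISE_CONVENTIONS = ("white-noise-density", "per-step")


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass
class SigmoidParams:
    """Population firing-rate sigmoid Q(V) = q_max / (1 + exp(-(V - theta)/sigma_prime)).

    All three populations share the same sigmoid.

    Attributes
    ----------
    q_max : float
        Maximal firing rate (s^-1).
    theta : float
        Mean firing threshold relative to rest (mV).
    sigma_prime : float
        Spread of firing thresholds across the population (mV).
    """

    q_max: float = 100.0
    theta: float = 10.0
    sigma_prime: float = 3.0

    def validate(self) -> None:
        if not (self.q_max > 0):
            raise ParameterError(f"q_max must be positive, got {self.q_max}")
        if not (self.sigma_prime > 0):
            raise ParameterError(
                f"sigma_prime must be positive, got {self.sigma_prime}"
            )


@dataclass
class CouplingParams:
    """Synaptic connection strengths between the populations (mV s).

    ``nu_xy`` weighs the input from population *y* to population *x*.
    The VLPO-MA pair is mutually inhibitory (both weights negative); Orx
    excites the MA through ``nu_mo`` and is inhibited by the VLPO through
    ``nu_ov``.  The MA->Orx weight ``nu_om`` is taken to be negligible
    and fixed at zero by default, though a small value can be set
    explicitly.
    """

    nu_vm: float = -2.1
    nu_mv: float = -1.8
    nu_ov: float = -1.0
    nu_mo: float = 0.30
    nu_om: float = 0.0

    def validate(self) -> None:
        if not (self.nu_vm < 0):
            raise ParameterError(f"nu_vm must be negative, got {self.nu_vm}")
        if not (self.nu_mv < 0):
            raise ParameterError(f"nu_mv must be negative, got {self.nu_mv}")
        if not (self.nu_ov < 0):
            raise ParameterError(f"nu_ov must be negative, got {self.nu_ov}")
        if not (self.nu_mo >= 0):
            raise ParameterError(f"nu_mo must be >= 0, got {self.nu_mo}")


@dataclass
class DriveParams:
    """External drives: circadian weights, homeostatic weight, constants.

    The circadian drive C(t) is a unit-amplitude sinusoid with a 24-h
    period whose maximum falls at clock time ``phase_ref``.  It inhibits
    the VLPO (``nu_vc`` < 0, the projection is disinhibitory-inverted via
    the dorsomedial hypothalamus) and excites Orx (``nu_oc`` > 0).  The
    homeostatic drive disinhibits the VLPO with weight ``nu_vh``; its
    input to Orx (``nu_oh``) is neglected by default.  ``a_v``, ``a_m``,
    ``a_o`` are time-averaged drives from sources not modelled
    explicitly.
    """

    nu_vc: float = -0.30
    nu_vh: float = 1.0
    nu_oc: float = 1.0
    nu_oh: float = 0.0
    a_v: float = -8.5
    a_m: float = 0.52
    a_o: float = 1.0
    omega: float = 2.0 * math.pi / SECONDS_PER_DAY
    phase_ref: float = 15.0 * SECONDS_PER_HOUR

    def validate(self) -> None:
        if not (self.nu_vc < 0):
            raise ParameterError(f"nu_vc must be negative, got {self.nu_vc}")
        if not (self.nu_vh > 0):
            raise ParameterError(f"nu_vh must be positive, got {self.nu_vh}")
        if not (self.nu_oc > 0):
            raise ParameterError(f"nu_oc must be positive, got {self.nu_oc}")
        if not math.isclose(self.omega, 2.0 * math.pi / SECONDS_PER_DAY,
                            rel_tol=1e-12):
            raise ParameterError(
                "omega must equal 2*pi/86400 s^-1 (24-h period), got "
                f"{self.omega}"
            )


@dataclass
class HomeostatParams:
    """Homeostatic sleep drive: chi dH/dt = -H + mu * (1 - exp(-Q_m / q_sat)).

    H accumulates while the MA fire (wake) and clears with time constant
    ``chi`` while they are silent (sleep).  Production saturates at
    ``mu`` for large Q_m so that waking states of very different arousal
    produce comparable sleep pressure.

    Attributes
    ----------
    chi : float
        Clearance time constant (s; nominal 45 h).
    mu : float
        Production scale = supremum of the production term (H units).
    q_sat : float
        MA firing rate scale of the production saturation (s^-1).
    """

    chi: float = 45.0 * SECONDS_PER_HOUR
    mu: float = 17.0
    q_sat: float = 2.3

    def validate(self) -> None:
        for name in ("chi", "mu", "q_sat"):
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterError(f"{name} must be positive, got {v}")


@dataclass
class TimeConstants:
    """Relaxation time constants of the mean cell-body potentials (s).

    ``tau_o`` (nominal 120 s, an order of magnitude slower than the
    VLPO/MA constants) sets the timescale of the gradual orexin-mediated
    sleep-to-wake transition.
    """

    tau_v: float = 10.0
    tau_m: float = 10.0
    tau_o: float = 120.0

    def validate(self) -> None:
        for name in ("tau_v", "tau_m", "tau_o"):
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterError(f"{name} must be positive, got {v}")


@dataclass
class NoiseParams:
    """White-noise inputs to the VLPO and MA potential equations.

    ``sigma_v`` and ``sigma_m`` are the noise standard-deviation
    parameters (mV); they are equal under nominal settings.  The
    ``scaling_convention`` tag selects how the continuous-time noise term
    is discretized by the Euler-Maruyama stepper:

    ``"white-noise-density"`` (default)
        The noise term in ``tau dV/dt = ... + xi(t)`` is treated as white
        noise of intensity sigma, giving the increment
        ``(sigma/tau) * sqrt(dt) * z``.
    ``"per-step"``
        sigma is read as the standard deviation of the discrete noise
        sample held over one step, giving ``(sigma/tau) * dt * z``.
    """

    sigma_v: float = 1.0
    sigma_m: float = 1.0
    scaling_convention: str = "white-noise-density"

    def validate(self) -> None:
        if self.sigma_v < 0 or self.sigma_m < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.scaling_convention not in NOISE_CONVENTIONS:
            raise ParameterError(
                f"unknown scaling_convention {self.scaling_convention!r}; "
                f"expected one of {NOISE_CONVENTIONS}"
            )


@dataclass
class ModelParameters:
    """Complete parameter set of the coupled VLPO-MA-Orx-H system."""

    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    drives: DriveParams = field(default_factory=DriveParams)
    homeostat: HomeostatParams = field(default_factory=HomeostatParams)
    tau: TimeConstants = field(default_factory=TimeConstants)
    noise: NoiseParams = field(default_factory=NoiseParams)

    @classmethod
    def nominal(cls) -> "ModelParameters":
        """The nominal parameter set (all defaults; single source of truth)."""
        p = cls()
        p.validate()
        return p

    def validate(self) -> None:
        for group in (self.sigmoid, self.coupling, self.drives,
                      self.homeostat, self.tau, self.noise):
            group.validate()

    def copy(self) -> "ModelParameters":
        return dataclasses.replace(
            self,
            sigmoid=dataclasses.replace(self.sigmoid),
            coupling=dataclasses.replace(self.coupling),
            drives=dataclasses.replace(self.drives),
            homeostat=dataclasses.replace(self.homeostat),
            tau=dataclasses.replace(self.tau),
            noise=dataclasses.replace(self.noise),
        )

    # -- symbol access ---------------------------------------------------

    def _groups(self) -> Iterator[tuple[str, object]]:
        yield from (("sigmoid", self.sigmoid), ("coupling", self.coupling),
                    ("drives", self.drives), ("homeostat", self.homeostat),
                    ("tau", self.tau), ("noise", self.noise))

    def symbols(self) -> dict[str, float | str]:
        """Flat symbol -> value mapping (internal SI units)."""
        out: dict[str, float | str] = {}
        for _, group in self._groups():
            for f in dataclasses.fields(group):
                out[f.name] = getattr(group, f.name)
        return out

    def set_symbol(self, name: str, value: float) -> None:
        """Set a parameter by its bare symbol name (e.g. ``"nu_mo"``)."""
        for _, group in self._groups():
            if any(f.name == name for f in dataclasses.fields(group)):
                setattr(group, name, value)
                return
        raise KeyError(f"unknown model parameter symbol: {name!r}")

    def with_overrides(self, overrides: dict[str, float]) -> "ModelParameters":
        """Return a validated copy with the given symbol overrides applied."""
        p = self.copy()
        for name, value in overrides.items():
            p.set_symbol(name, value)
        p.validate()
        return p

    def fingerprint(self) -> str:
        """Short stable hash of the parameter values (for run manifests)."""
        payload = json.dumps(self.symbols(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- packing for the compiled integrator ------------------------------

    def pack(self) -> np.ndarray:
        """Pack the numeric parameters into a flat float64 array.

        Layout is consumed by the Euler-Maruyama kernel; keep in sync
        with :mod:`sleepswitch._kernels`.
        """
        s, c, d, h, t, n = (self.sigmoid, self.coupling, self.drives,
                            self.homeostat, self.tau, self.noise)
        return np.array([
            s.q_max, s.theta, s.sigma_prime,
            c.nu_vm, c.nu_mv, c.nu_ov, c.nu_mo, c.nu_om,
            d.nu_vc, d.nu_vh, d.nu_oc, d.nu_oh,
            d.a_v, d.a_m, d.a_o, d.omega, d.phase_ref,
            h.chi, h.mu, h.q_sat,
            t.tau_v, t.tau_m, t.tau_o,
            n.sigma_v, n.sigma_m,
            0.0 if n.scaling_convention == "white-noise-density" else 1.0,
        ], dtype=np.float64)


@dataclass
class SystemState:
    """Instantaneous state: mean potentials (mV), homeostat level, time (s)."""

    v_v: float
    v_m: float
    v_o: float
    h: float
    t: float = 0.0

    def validate(self) -> None:
        vals = (self.v_v, self.v_m, self.v_o, self.h, self.t)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite system state: {self}")
        if self.h < 0:
            raise ParameterError(f"homeostat level must be >= 0, got {self.h}")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_v, self.v_m, self.v_o, self.h])
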