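"""Lujan-style closed-form breathing motion and its instantaneous velocity.

The Lujan model describes one-dimensional (superior-inferior) respiratory
motion as

    z(t) = z0 - b * cos^{2n}(pi*t/tau - phi0)

with exhale position ``z0``, breathing displacement ``b`` (mm), period
``tau`` (s), steepness exponent ``n`` and starting phase ``phi0``.  The
even power keeps the trajectory in ``[z0 - b, z0]`` and flattens the
exhale plateau as ``n`` grows.

Two velocity conventions are provided (:class:`VelocityMode`):

``literal``
    The textbook derivative of z(t):
    ``dz/dt = (2*n*pi*b/tau) * cos^{2n-1}(x) * sin(x)``, ``x = pi*t/tau - phi0``.

``replication``
    The same prefactor with exponent ``2n+1`` instead of ``2n-1``:
    ``v(t) = (2*n*pi*b/tau) * cos^{2n+1}(x) * sin(x)``.  This is the exact
    derivative of the damped trajectory
    ``A_rep(t) = z0 - (b*n/(n+1)) * cos^{2n+2}(x)``
    (:func:`replication_displacement`).  For n = 1 its maximum is
    ``(2*pi*b/tau) * 3*sqrt(3)/16`` at t = tau/6, rather than the literal
    ``pi*b/tau`` at tau/4.  Published simulated velocity tables in this
    problem area follow the replication convention; both are kept so either
    family of numbers can be reproduced or compared.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InputError
from .waveform import DEFAULT_SAMPLING_INTERVAL, RespiratoryWaveform

#: Relative grid step (fraction of tau) of the numeric velocity-maximum scan.
_SCAN_STEP_FRACTION = 1e-4


class VelocityMode(str, enum.Enum):
    """Which instantaneous-velocity convention to use."""

    LITERAL = "literal"
    REPLICATION = "replication"


@dataclass(frozen=True)
class LujanParams:
    """Parameters of the cos^2n breathing model.

    Attributes
    ----------
    b : float
        Displacement of motion (peak-to-trough amplitude), mm.
    tau : float
        Period of the breathing cycle, s.
    z0 : float
        Position at exhale, mm (default 0).
    n : int
        Steepness exponent; the displacement is cos^{2n} (default 1).
    phi0 : float
        Starting phase, radians (default 0).
    """

    b: float
    tau: float
    z0: float = 0.0
    n: int = 1
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.b < 0:
            raise InputError("displacement b must be >= 0")
        if self.tau <= 0:
            raise InputError("period tau must be positive")
        if self.n < 1 or int(self.n) != self.n:
            raise InputError("steepness n must be a positive integer")


def params_from_bpm(b: float, bpm: float, **kwargs) -> LujanParams:
    """Build :class:`LujanParams` from a breathing rate in breaths/minute (tau = 60/bpm)."""
    if bpm <= 0:
        raise InputError("breathing rate must be positive")
    return LujanParams(b=b, tau=60.0 / bpm, **kwargs)


def _phase(params: LujanParams, t):
    return np.pi * np.asarray(t, dtype=float) / params.tau - params.phi0


def lujan_displacement(params: LujanParams, t):
    """Literal trajectory z(t) = z0 - b*cos^{2n}(pi*t/tau - phi0), mm."""
    return params.z0 - params.b * np.cos(_phase(params, t)) ** (2 * params.n)


def replication_displacement(params: LujanParams, t):
    """Trajectory whose derivative is the replication-mode velocity.

    ``A_rep(t) = z0 - (b*n/(n+1)) * cos^{2n+2}(pi*t/tau - phi0)``; for n = 1
    this is ``z0 - (b/2)*cos^4``.
    """
    n = params.n
    scale = params.b * n / (n + 1)
    return params.z0 - scale * np.cos(_phase(params, t)) ** (2 * n + 2)


def displacement(params: LujanParams, t, mode: VelocityMode = VelocityMode.LITERAL):
    """Trajectory in the convention matching ``mode`` (mm)."""
    if VelocityMode(mode) is VelocityMode.LITERAL:
        return lujan_displacement(params, t)
    return replication_displacement(params, t)


def lujan_velocity(params: LujanParams, t, mode: VelocityMode = VelocityMode.LITERAL):
    """Instantaneous velocity dz/dt in mm/s under the chosen convention."""
    x = _phase(params, t)
    prefactor = 2.0 * params.n * np.pi * params.b / params.tau
    exponent = 2 * params.n - 1 if VelocityMode(mode) is VelocityMode.LITERAL else 2 * params.n + 1
    return prefactor * np.cos(x) ** exponent * np.sin(x)


def max_instantaneous_velocity(
    params: LujanParams, mode: VelocityMode = VelocityMode.LITERAL
) -> tuple[float, float]:
    """Maximum of |velocity| over one cycle and the earliest time attaining it.

    Closed forms are used for n = 1 with zero starting phase:

    * literal: v_max = pi*b/tau at t = tau/4
    * replication: v_max = (2*pi*b/tau)*(3*sqrt(3)/16) at t = tau/6

    Otherwise the maximum is located by a dense scan (step 1e-4*tau)
    refined with bounded scalar minimisation; the refinement brings the
    numeric value within 1e-9 relative of the closed form where one exists.

    Returns
    -------
    (v_max, t_max) : tuple of float
        Peak speed in mm/s and its time in seconds within [0, tau).
    """
    mode = VelocityMode(mode)
    if params.b == 0:
        return 0.0, 0.0
    if params.n == 1 and params.phi0 == 0.0:
        if mode is VelocityMode.LITERAL:
            return math.pi * params.b / params.tau, params.tau / 4.0
        v = (2.0 * math.pi * params.b / params.tau) * (3.0 * math.sqrt(3.0) / 16.0)
        return v, params.tau / 6.0

    tau = params.tau
    grid = np.arange(0.0, tau, _SCAN_STEP_FRACTION * tau)
    speeds = np.abs(lujan_velocity(params, grid, mode))
    k = int(np.argmax(speeds))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: -abs(float(lujan_velocity(params, t, mode))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12 * tau},
    )
    return -float(res.fun), float(res.x)


def generate_lujan_waveform(
    params: LujanParams,
    duration: float,
    dt: float = DEFAULT_SAMPLING_INTERVAL,
    mode: VelocityMode = VelocityMode.LITERAL,
) -> RespiratoryWaveform:
    """Sample the model trajectory onto a uniform grid.

    ``mode`` selects the trajectory convention: the literal cos^{2n} path,
    or the replication-mode antiderivative ``A_rep`` used when downstream
    averaged-velocity analysis should match replication-mode peak speeds.
    Sample count is ``floor(duration/dt) + 1``.
    """
    if duration <= 0:
        raise InputError("duration must be positive")
    if dt <= 0:
        raise InputError("sampling interval must be positive")
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    d = displacement(params, t, mode)
    return RespiratoryWaveform(
        times=t, displacements=np.asarray(d, dtype=float), source_label=f"lujan-{VelocityMode(mode).value}"
    )
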