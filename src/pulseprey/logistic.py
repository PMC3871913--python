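"""Closed-form treatment of the scalar pulsed-logistic subsystems.

With the predator absent the two bamboo equations decouple into scalar
impulsive logistic systems

.. math::

    \\dot x = x (a - b x), \\qquad x(t_k^+) = (1 - \\theta)\\, x(t_k),

with pulses every ``T`` time units.  Everything here is exact: the flow
between pulses is the closed-form logistic solution, one period of
flow-then-pulse is the stroboscopic map, and its unique positive fixed
point (when it exists) generates the periodic solution ``x*(t)``.

The positive periodic orbit exists iff ``ln(1-theta) + a*T > 0``, i.e. the
per-cycle exponential growth outweighs the pulse removal; otherwise every
positive solution decays to zero.  The mean of the orbit obeys the exact
identity ``\\int_0^T x*(t) dt = (ln(1-theta) + a T) / b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeriodicOrbit",
    "logistic_flow",
    "stroboscopic_map",
    "existence_margin",
    "periodic_fixed_point",
    "orbit_integral",
    "sample_orbit",
]


def logistic_flow(x0: float, a: float, b: float, dt: float) -> float:
    """Exact solution of ``dx/dt = x(a - b x)`` after time ``dt``.

    Returns ``a x0 e^{a dt} / (a + b x0 (e^{a dt} - 1))``.  Zero and the
    carrying capacity ``a/b`` are fixed points; the formula is finite for
    all ``x0 >= 0``.
    """
    if x0 == 0.0:
        return 0.0
    # expm1 keeps precision for small a*dt
    em1 = math.expm1(a * dt)
    return a * x0 * (em1 + 1.0) / (a + b * x0 * em1)


def stroboscopic_map(x0plus: float, a: float, b: float, theta: float, T: float) -> float:
    """One full cycle of the pulsed logistic system: flow for ``T``, then pulse.

    Maps the post-pulse density to the next post-pulse density.  The map is
    increasing and concave on ``[0, inf)``, so it has at most one positive
    fixed point.
    """
    return (1.0 - theta) * logistic_flow(x0plus, a, b, T)


def existence_margin(a: float, theta: float, T: float) -> float:
    """Per-cycle net log-growth ``ln(1-theta) + a T``.

    Positive iff the positive periodic orbit exists.
    """
    return math.log1p(-theta) + a * T


@dataclass(frozen=True)
class PeriodicOrbit:
    """T-periodic solution of a pulsed logistic subsystem.

    ``x0plus`` is the density immediately *after* a pulse; one period runs
    pulse-to-pulse.  ``phase`` records where in the full model's cycle the
    pulse falls (time in ``(0, T]``), so the two bamboo orbits can be
    aligned on a common window.
    """

    a: float
    b: float
    theta: float
    T: float
    x0plus: float
    phase: float = 0.0

    def value(self, s: float) -> float:
        """Orbit value a time ``s`` after the pulse, ``0 <= s <= T`` (left
        limit at ``s = T``, i.e. pre-pulse)."""
        return logistic_flow(self.x0plus, self.a, self.b, s)

    def at_phase(self, t: float) -> float:
        """Orbit value at absolute cycle time ``t`` (mod T), respecting
        ``phase``; right-continuous at the pulse instant."""
        s = (t - self.phase) % self.T
        return logistic_flow(self.x0plus, self.a, self.b, s)


def periodic_fixed_point(
    a: float, b: float, theta: float, T: float, phase: float = 0.0
) -> PeriodicOrbit | None:
    """Positive fixed point of the stroboscopic map, or ``None`` if absent.

    Solving ``(1-theta) * flow(x, T) = x`` gives

    .. math::

        x_0^+ = \\frac{a\\,((1-\\theta) e^{aT} - 1)}{b\\,(e^{aT} - 1)},

    which is positive exactly when ``ln(1-theta) + a T > 0``.  When the
    existence condition fails the zero solution is globally attracting and
    ``None`` is returned (an explicit result, not an exception, so regime
    scans can tabulate nonexistence).
    """
    if b <= 0 or T <= 0 or not 0.0 <= theta < 1.0:
        raise ValueError("require b>0, T>0, 0<=theta<1")
    if existence_margin(a, theta, T) <= 0.0:
        return None
    eaT = math.exp(a * T)
    x0plus = a * ((1.0 - theta) * eaT - 1.0) / (b * (eaT - 1.0))
    return PeriodicOrbit(a=a, b=b, theta=theta, T=T, x0plus=x0plus, phase=phase)


def orbit_integral(orbit: PeriodicOrbit) -> float:
    """Exact one-period integral ``int_0^T x*(t) dt = (ln(1-theta) + a T)/b``."""
    return existence_margin(orbit.a, orbit.theta, orbit.T) / orbit.b


def sample_orbit(orbit: PeriodicOrbit, n: int) -> tuple[np.ndarray, np.ndarray]:
    """``n`` samples ``(t, x*(t))`` of one period on ``(0, T]``.

    Times are measured from the pulse; the first sample sits just after the
    pulse (at ``t -> 0+`` the orbit value is ``x0plus``) and the last at
    ``t = T`` holds the pre-pulse left limit, so
    ``(1 - theta) * x[-1] == x0plus`` up to rounding.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    t = np.linspace(0.0, orbit.T, n)
    x = np.array([orbit.value(s) for s in t])
    return t, x
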