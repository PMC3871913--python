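"""Event-driven integration of the full three-species impulsive system.

Pulse times are known a priori from the schedule, so no event detection is
needed: the smooth vector field is integrated between consecutive pulses
with an adaptive stiff-capable method (LSODA) and the proportional-removal
map is applied at each pulse instant.  Trajectories keep both the left
limit (pre-pulse) and right limit (post-pulse) at every event.

Also provides the boundedness machinery: the weighted-population Lyapunov
value ``V = (a31/a13) x1 + (a32/a23) x2 + x3`` satisfies
``dV/dt + a30 V <= D`` between pulses and does not increase at pulses,
which yields the explicit envelope
``V(t) <= V(0+) e^{-a30 t} + D (1 - e^{-a30 t}) / a30`` and the ultimate
bound ``D / a30``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ModelParameters, State, apply_pulse, pulse_schedule, vector_field

__all__ = [
    "PulseEvent",
    "Trajectory",
    "UltimateBound",
    "simulate",
    "lyapunov_value",
    "ultimate_bound",
    "tail_extrema",
    "SimulationError",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12


class SimulationError(RuntimeError):
    """Integration failure, reported with the failing time interval."""


@dataclass(frozen=True)
class PulseEvent:
    time: float
    component: str
    pre: np.ndarray
    post: np.ndarray


@dataclass
class Trajectory:
    """Piecewise-continuous solution with pulse-event bookkeeping.

    ``t``/``x`` are strictly increasing samples; at a pulse instant the
    sample stores the left limit, while the post-pulse (right-limit) value
    lives in the corresponding :class:`PulseEvent`.
    """

    t: np.ndarray
    x: np.ndarray  # shape (len(t), 3)
    events: list[PulseEvent] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def final_state(self) -> State:
        return State.from_array(self.x[-1], t=float(self.t[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x1": self.x[:, 0], "x2": self.x[:, 1], "x3": self.x[:, 2]}
        )

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write samples as CSV; events and diagnostics go to ``<path>.events.json``."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "events": [
                    {
                        "time": e.time,
                        "component": e.component,
                        "pre": list(map(float, e.pre)),
                        "post": list(map(float, e.post)),
                    }
                    for e in self.events
                ],
                "diagnostics": self.diagnostics,
            }
            path.with_suffix(path.suffix + ".events.json").write_text(
                json.dumps(meta, indent=2) + "\n"
            )

    def stroboscopic_values(self, component: str) -> np.ndarray:
        """Post-pulse values of the pulsed component at its own events."""
        idx = {"bamboo1": 0, "bamboo2": 1}[component]
        return np.array([e.post[idx] for e in self.events if e.component == component])


def simulate(
    p: ModelParameters,
    x0,
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    max_samples_per_segment: int | None = None,
) -> Trajectory:
    """Integrate the impulsive system from ``t = 0`` to ``t_end``.

    ``x0`` is the initial (post-pulse, t=0+) state, componentwise >= 0.
    No positivity floor is imposed on the state: positivity must emerge
    from the dynamics, and tests check that it does.
    """
    if isinstance(x0, State):
        x0 = x0.as_array()
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (3,):
        raise ValueError("x0 must have three components")
    if np.any(x0 < 0):
        raise ValueError(f"initial state must be nonnegative, got {x0}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    fractions = {"bamboo1": p.alpha, "bamboo2": p.beta}
    events = pulse_schedule(p, 0.0, t_end)
    breakpoints = [t for t, _ in events]
    if not breakpoints or breakpoints[-1] < t_end:
        breakpoints.append(t_end)

    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    log: list[PulseEvent] = []
    nfev = 0
    nseg = 0

    t_cur, x_cur = 0.0, x0.copy()
    ts.append(np.array([0.0]))
    xs.append(x_cur.reshape(1, 3))
    ev_iter = iter(events)
    next_ev = next(ev_iter, None)

    for t_stop in breakpoints:
        if t_stop > t_cur:
            sol = solve_ivp(
                lambda t, x: vector_field(x, p),
                (t_cur, t_stop),
                x_cur,
                method=method,
                rtol=rtol,
                atol=atol,
                dense_output=False,
            )
            nfev += sol.nfev
            nseg += 1
            if not sol.success:
                raise SimulationError(
                    f"integration failed on [{t_cur}, {t_stop}]: {sol.message}"
                )
            seg_t, seg_x = sol.t, sol.y.T
            if max_samples_per_segment and len(seg_t) > max_samples_per_segment:
                keep = np.linspace(0, len(seg_t) - 1, max_samples_per_segment).astype(int)
                seg_t, seg_x = seg_t[keep], seg_x[keep]
            # drop the duplicate segment-start sample (already recorded)
            ts.append(seg_t[1:])
            xs.append(seg_x[1:])
            t_cur, x_cur = t_stop, seg_x[-1].copy()
        if next_ev is not None and math.isclose(t_stop, next_ev[0], rel_tol=0, abs_tol=1e-9):
            _, comp = next_ev
            pre = x_cur.copy()
            x_cur = apply_pulse(x_cur, comp, fractions[comp])
            log.append(PulseEvent(time=t_stop, component=comp, pre=pre, post=x_cur.copy()))
            next_ev = next(ev_iter, None)

    t_arr = np.concatenate(ts)
    x_arr = np.vstack(xs)
    return Trajectory(
        t=t_arr,
        x=x_arr,
        events=log,
        diagnostics={
            "rtol": rtol,
            "atol": atol,
            "method": method,
            "segments": nseg,
            "nfev": nfev,
            "t_end": t_end,
        },
    )


def lyapunov_value(s, p: ModelParameters) -> float:
    """Weighted total population ``V = (a31/a13) x1 + (a32/a23) x2 + x3``.

    Linear and positive-definite on the nonnegative orthant: zero iff the
    state is the origin.
    """
    if isinstance(s, State):
        s = s.as_array()
    x1, x2, x3 = s
    return (p.a31 / p.a13) * x1 + (p.a32 / p.a23) * x2 + x3


@dataclass(frozen=True)
class UltimateBound:
    """Closed-form ultimate bound on the weighted population.

    ``D`` bounds ``dV/dt + a30 V`` from above (the negative predator
    self-limitation term is dropped), so ``limsup V <= V_bound = D/a30``
    and each component is ultimately below its ``M`` entry.
    """

    D: float
    V_bound: float
    M1: float
    M2: float
    M3: float

    @property
    def M(self) -> float:
        return max(self.M1, self.M2, self.M3)


def ultimate_bound(p: ModelParameters) -> UltimateBound:
    """Maximize the two concave quadratics bounding ``dV/dt + a30 V``.

    Substituting the vector field into ``dV/dt + a30 V`` and dropping the
    nonpositive ``-a33 x3^2`` term leaves
    ``(a31/a13) x1 (a10 + a30 - a11 x1) + (a32/a23) x2 (a20 + a30 - a22 x2)``,
    i.e. ``c1 = (a10 + a30) a31/a13``, ``d1 = a31 a11 / a13`` (and the
    prey-2 analogues), so ``D = c1^2/(4 d1) + c2^2/(4 d2)`` and
    ``V_bound = D/a30``.  Componentwise: ``x1 <= (a13/a31) V_bound`` etc.
    The ``a31/a13`` weight multiplies the whole prey-1 bracket, including
    the ``a30`` contribution from ``a30 V`` — without it the quadratic is
    not an upper bound once ``a31 > a13``.
    """
    c1 = (p.a10 + p.a30) * p.a31 / p.a13
    d1 = p.a31 * p.a11 / p.a13
    c2 = (p.a20 + p.a30) * p.a32 / p.a23
    d2 = p.a32 * p.a22 / p.a23
    D = c1 * c1 / (4.0 * d1) + c2 * c2 / (4.0 * d2)
    V_bound = D / p.a30
    return UltimateBound(
        D=D,
        V_bound=V_bound,
        M1=(p.a13 / p.a31) * V_bound,
        M2=(p.a23 / p.a32) * V_bound,
        M3=V_bound,
    )


def lyapunov_envelope(V0: float, p: ModelParameters, t) -> np.ndarray:
    """Exact decay envelope ``V0 e^{-a30 t} + D (1 - e^{-a30 t})/a30``."""
    ub = ultimate_bound(p)
    decay = np.exp(-p.a30 * np.asarray(t, dtype=float))
    return V0 * decay + ub.V_bound * (1.0 - decay)


def tail_extrema(traj: Trajectory, window_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Componentwise (min, max) over the trailing fraction of the trajectory.

    Used to certify numerical permanence (tail min bounded away from zero)
    or extinction (tail max below a threshold).
    """
    if not 0.0 < window_fraction < 1.0:
        raise ValueError("window_fraction must lie in (0, 1)")
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    cut = t1 - window_fraction * (t1 - t0)
    mask = traj.t >= cut
    if not mask.any():
        raise ValueError("tail window contains no samples")
    tail = traj.x[mask]
    return tail.min(axis=0), tail.max(axis=0)
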