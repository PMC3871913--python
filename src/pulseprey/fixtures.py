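"""Seeded generation of parameter sets placed deliberately in each regime.

Regime fixtures are drawn by rejection sampling from regime-specific
proposal boxes until :func:`~pulseprey.stability.classify_regime` returns
the requested label *and* the defining condition values clear a margin
(default 0.1 on the per-period exponents).  The margin keeps fixtures in
the interior of their regime so that finite-horizon simulations resolve
the predicted asymptotics: e.g. a stability exponent <= -0.1 contracts the
predator by at least e^{-0.1} per period, reaching 1e-6 well within 200
periods.  Draws are deterministic given ``(regime, seed)``.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParameters, validate_parameters
from .stability import REGIME_LABELS, classify_regime

__all__ = ["generate_fixture", "FixtureExhausted"]


class FixtureExhausted(RuntimeError):
    """Rejection sampling failed to hit the requested regime."""

    def __init__(self, regime: str, attempts: int):
        self.regime = regime
        self.attempts = attempts
        super().__init__(
            f"no parameter set classified as {regime!r} after {attempts} attempts"
        )


# stable per-regime stream index so streams never collide across regimes
_REGIME_INDEX = {name: i for i, name in enumerate(REGIME_LABELS)}
_REGIME_INDEX["random_positive"] = len(REGIME_LABELS)

# proposal boxes: {field: (low, high)}, log-uniform for rates
_BROAD = {
    "a10": (0.5, 2.0), "a11": (0.2, 1.0), "a13": (0.05, 0.5),
    "a20": (0.5, 2.0), "a22": (0.2, 1.0), "a23": (0.05, 0.5),
    "a30": (0.1, 1.0), "a31": (0.05, 0.5), "a32": (0.05, 0.5),
    "a33": (0.01, 0.2),
    "alpha": (0.05, 0.7), "beta": (0.05, 0.7),
    "T": (0.5, 4.0), "l": (0.2, 0.8),
}

_PROPOSALS: dict[str, dict] = {
    "random_positive": _BROAD,
    "panda_free_stable": {
        **_BROAD,
        # modest conversion gains and firm mortality keep the predator subcritical
        "a30": (0.3, 1.0), "a31": (0.02, 0.15), "a32": (0.02, 0.15),
        "T": (0.8, 2.5), "alpha": (0.05, 0.5), "beta": (0.05, 0.5),
    },
    "permanent_certified": {
        # weak predation pressure (small a13, a23) keeps the ultimate bound's
        # side conditions satisfiable while strong conversion sustains invasion
        "a10": (0.8, 1.5), "a11": (0.8, 1.5), "a13": (0.05, 0.12),
        "a20": (0.8, 1.5), "a22": (0.8, 1.5), "a23": (0.05, 0.12),
        "a30": (0.3, 0.6), "a31": (0.3, 0.6), "a32": (0.3, 0.6),
        "a33": (0.01, 0.05),
        "alpha": (0.05, 0.3), "beta": (0.05, 0.3),
        "T": (1.5, 3.5), "l": (0.3, 0.7),
    },
    "subsystem1_permanent": {
        **_BROAD,
        # prey-1 alone sustains the predator; heavy predation defeats the
        # M-dependent side certificate
        "a13": (0.5, 1.5), "a23": (0.5, 1.5),
        "a31": (0.4, 1.0), "a32": (0.02, 0.08),
        "a11": (0.3, 0.8), "a30": (0.05, 0.25), "T": (1.0, 3.0),
        "alpha": (0.05, 0.4), "beta": (0.05, 0.4),
    },
    "subsystem2_permanent": {
        **_BROAD,
        "a13": (0.5, 1.5), "a23": (0.5, 1.5),
        "a31": (0.02, 0.08), "a32": (0.4, 1.0),
        "a22": (0.3, 0.8), "a30": (0.05, 0.25), "T": (1.0, 3.0),
        "alpha": (0.05, 0.4), "beta": (0.05, 0.4),
    },
    "no_bamboo_orbit": {
        **_BROAD,
        "alpha": (0.7, 0.95), "T": (0.05, 0.25), "a10": (0.5, 1.0),
    },
    "unstable_uncertified": None,  # not constructible on demand (no certificate)
}


def _draw(rng: np.random.Generator, box: dict) -> ModelParameters:
    vals = {}
    for name, (lo, hi) in box.items():
        if name in ("alpha", "beta", "l"):
            vals[name] = rng.uniform(lo, hi)
        else:  # positive rates: log-uniform
            vals[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return validate_parameters(ModelParameters(**vals))


def _deliberate(regime: str, report, margin: float) -> bool:
    """Interior-of-regime checks beyond the bare label."""
    if regime in ("random_positive", "no_bamboo_orbit"):
        return True
    # robust orbit existence so stroboscopic convergence is geometric
    if report.existence_margin1 < 2 * margin or report.existence_margin2 < 2 * margin:
        return False
    if regime == "panda_free_stable":
        return report.stability_exponent <= -margin
    if regime == "permanent_certified":
        return (
            report.stability_exponent >= margin
            and report.side_alpha >= margin
            and report.side_beta >= margin
        )
    if regime == "subsystem1_permanent":
        return report.cond_sub1 >= margin
    if regime == "subsystem2_permanent":
        return report.cond_sub2 >= margin
    return True


def generate_fixture(
    regime: str,
    seed: int,
    margin: float = 0.1,
    max_attempts: int = 10_000,
) -> ModelParameters:
    """Deterministic parameter set whose classification is ``regime``.

    ``regime`` may be any classifier label except ``unstable_uncertified``
    (which has no constructive certificate), or ``"random_positive"`` for
    an unconstrained valid draw.  Raises :class:`FixtureExhausted` after
    ``max_attempts`` rejections.
    """
    if regime not in _PROPOSALS or _PROPOSALS[regime] is None:
        raise ValueError(
            f"cannot generate fixtures for regime {regime!r}; choose from "
            f"{sorted(k for k, v in _PROPOSALS.items() if v is not None)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _REGIME_INDEX[regime]]))
    box = _PROPOSALS[regime]
    for _ in range(max_attempts):
        p = _draw(rng, box)
        if regime == "random_positive":
            return p
        report = classify_regime(p)
        if report.label == regime and _deliberate(regime, report, margin):
            return p
    raise FixtureExhausted(regime, max_attempts)
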