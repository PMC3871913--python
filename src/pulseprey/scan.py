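"""Parameter sweeps over the analytic regime structure.

The principal sweep is over the pulse period ``T``: as ``T`` crosses the
extinction threshold ``T*`` the predator's Floquet multiplier crosses 1
and the classification flips from predator extinction to invasion.  Rows
carry the multiplier, threshold, and label per grid value; optionally a
full simulation confirms each row with tail extrema of the predator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .model import ModelParameters, validate_parameters
from .simulate import simulate, tail_extrema
from .stability import classify_regime

__all__ = ["ScanResult", "scan_period", "scan_parameter"]

SCAN_RTOL = 1e-6
SCAN_ATOL = 1e-9


@dataclass
class ScanResult:
    """One row per grid cell, plus full provenance for reproducibility."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write_csv(self, path: str | Path) -> None:
        """CSV with the resolved configuration embedded as '#' header lines."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# pulseprey scan\n")
            fh.write("# provenance: " + json.dumps(self.provenance, sort_keys=True) + "\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ScanResult":
        path = Path(path)
        prov = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("# provenance: "):
                    prov = json.loads(line[len("# provenance: "):])
                if not line.startswith("#"):
                    break
        table = pd.read_csv(path, comment="#")
        return cls(table=table, provenance=prov)


def scan_parameter(
    p: ModelParameters,
    param: str,
    values: Sequence[float],
    with_simulation: bool = False,
    x0=(1.0, 1.0, 0.5),
    window_fraction: float = 0.25,
    rtol: float = SCAN_RTOL,
    atol: float = SCAN_ATOL,
) -> ScanResult:
    """Classify the regime along a grid of values for one parameter.

    With ``with_simulation`` each row additionally integrates the full
    system for ``200 * max(1, T)`` time units (at least 200 pulse periods
    for ``T <= 1``) and records the predator's tail extrema.  Per-cell
    failures are recorded in the row's ``error`` column rather than
    aborting the scan.
    """
    rows = []
    for v in values:
        row: dict = {param: v}
        try:
            pv = validate_parameters(p.replace(**{param: float(v)}))
            rep = classify_regime(pv)
            row.update(
                exists1=rep.exists1,
                exists2=rep.exists2,
                lambda3=rep.lambda3,
                stability_exponent=rep.stability_exponent,
                t_star=rep.T_star,
                label=rep.label,
                error="",
            )
            if with_simulation:
                t_end = 200.0 * max(1.0, pv.T)
                traj = simulate(pv, x0, t_end, rtol=rtol, atol=atol,
                                max_samples_per_segment=8)
                lo, hi = tail_extrema(traj, window_fraction)
                row.update(
                    x1_tail_min=lo[0], x1_tail_max=hi[0],
                    x2_tail_min=lo[1], x2_tail_max=hi[1],
                    x3_tail_min=lo[2], x3_tail_max=hi[2],
                )
        except Exception as exc:  # per-cell failure -> recorded, scan continues
            row.setdefault("label", "")
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    prov = {
        "base_parameters": p.to_dict(),
        "param": param,
        "values": [float(v) for v in values],
        "with_simulation": with_simulation,
        "x0": list(map(float, x0)) if with_simulation else None,
        "rtol": rtol,
        "atol": atol,
        "window_fraction": window_fraction,
        "version": __version__,
    }
    return ScanResult(table=table, provenance=prov)


def scan_period(
    p: ModelParameters,
    T_values: Sequence[float],
    with_simulation: bool = False,
    **kwargs,
) -> ScanResult:
    """Sweep the pulse period ``T`` (values must be positive, increasing)."""
    vals = list(T_values)
    if any(v <= 0 for v in vals):
        raise ValueError("T values must be positive")
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError("T values must be strictly increasing")
    return scan_parameter(p, "T", vals, with_simulation=with_simulation, **kwargs)
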