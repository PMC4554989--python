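"""One-at-a-time sensitivity sweeps and the K × C interplay grid.

Each sweep varies a single parameter (K, C or F_pert) with the other two held
fixed and summarizes every run by the robustness quantities x_max (response
peak at the end of the challenge), x_inf (asymptote of an indefinite
perturbation) and T (recovery decay constant).  The expected qualitative
behavior, which the test suite asserts over fine sweeps:

* K — hyperbolic decline of x_inf (= perc*F_pert/K) and of T (= C/K);
* C — no effect on x_inf; T grows linearly; x_max falls when the challenge
  window is too short to reach the asymptote;
* F_pert — linear increase of x_max and x_inf; no effect on recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .model import (
    ModelParams,
    Trajectory,
    derive_quantities,
    simulate_closed_form,
    standard_grid,
)

__all__ = ["SweepSpec", "run_sweep", "run_interplay_grid", "paper_default_sweeps"]

SWEEPABLE = ("K", "C", "F_pert")


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time sweep: which parameter varies, over which values.

    ``fixed`` supplies the held-fixed configuration; its entry for the swept
    parameter is ignored.  ``values`` must be strictly increasing.
    """

    swept_parameter: str
    values: NDArray[np.float64]
    fixed: ModelParams
    grid: NDArray[np.float64] = field(default_factory=standard_grid)

    def __post_init__(self) -> None:
        if self.swept_parameter not in SWEEPABLE:
            raise ValueError(
                f"swept_parameter must be one of {SWEEPABLE}, "
                f"got {self.swept_parameter!r}"
            )
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("values must be strictly increasing")
        if (v <= 0).any():
            raise ValueError("swept values must be positive")
        object.__setattr__(self, "values", v)


def log_spaced(lo: float, hi: float, num: int = 50) -> NDArray[np.float64]:
    """Default sweep density: log-spaced values between ``lo`` and ``hi``."""
    return np.geomspace(lo, hi, num)


def run_sweep(spec: SweepSpec, keep_trajectories: bool = False):
    """Run one simulation per swept value and tabulate (value, x_max, x_inf, T).

    Returns the summary DataFrame, or ``(DataFrame, list[Trajectory])`` when
    ``keep_trajectories`` is set.
    """
    rows = []
    trajectories: list[Trajectory] = []
    for v in spec.values:
        params = replace(spec.fixed, **{spec.swept_parameter: float(v)})
        dq = derive_quantities(params)
        rows.append({
            "swept_parameter": spec.swept_parameter,
            "value": float(v),
            "x_max": dq.x_max,
            "x_inf": dq.x_inf,
            "T": dq.T,
        })
        if keep_trajectories:
            trajectories.append(simulate_closed_form(params, spec.grid))
    table = pd.DataFrame(rows)
    return (table, trajectories) if keep_trajectories else table


def run_interplay_grid(
    K_values, C_values, fixed: ModelParams, grid: NDArray[np.float64] | None = None
) -> dict[tuple[float, float], Trajectory]:
    """Full trajectories for every (K, C) combination (low/mid/high crossed).

    Returns a mapping ``(K, C) -> Trajectory`` on the standard grid; with the
    canonical 3 x 3 inputs this is the 9-panel interplay analysis showing that
    K sets the attainable amplitude while C shapes the approach to it.
    """
    if grid is None:
        grid = standard_grid()
    out: dict[tuple[float, float], Trajectory] = {}
    for K in K_values:
        for C in C_values:
            params = replace(fixed, K=float(K), C=float(C))
            out[(float(K), float(C))] = simulate_closed_form(params, grid)
    return out


def paper_default_sweeps(num: int = 50) -> list[SweepSpec]:
    """The three canonical one-at-a-time sweeps.

    K in [0.1, 1] with C = 2, F_pert = 1; C in [0.5, 20] with K = 0.1,
    F_pert = 1; F_pert in [1, 10] with K = 0.1, C = 2 — all with perc = 1 and
    the challenge between 20 and 60.
    """
    return [
        SweepSpec("K", log_spaced(0.1, 1.0, num),
                  ModelParams(K=0.1, C=2.0, F_pert=1.0, perc=1.0)),
        SweepSpec("C", log_spaced(0.5, 20.0, num),
                  ModelParams(K=0.1, C=2.0, F_pert=1.0, perc=1.0)),
        SweepSpec("F_pert", log_spaced(1.0, 10.0, num),
                  ModelParams(K=0.1, C=2.0, F_pert=1.0, perc=1.0)),
    ]
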