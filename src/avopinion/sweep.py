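"""Ensemble execution over parameter grids and success-curve fitting.

The anti-vaccination dominance transition is stochastic: for a given
activism threshold AT, the fraction of runs that end in AV success rises
sigmoidally with the writing probability PW.  This module runs seeded
ensembles over (AT, PW, ...) grids, collects success ratios and
transition times, and fits logistic or Gompertz sigmoids to the
success-vs-PW curve.

Seeding is auditable: cell ``i``, replicate ``j`` uses
``base_seed + i * n_reps + j``, so any single run can be reproduced in
isolation and ensemble results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .burst_analysis import DistributionFit
from .engine import run_simulation
from .model_core import ModelParams

__all__ = ["EnsembleSpec", "EnsembleResult", "run_ensemble", "fit_success_sigmoid"]


@dataclass(frozen=True)
class EnsembleSpec:
    """A grid of parameter overrides with replication and seeding."""

    base_params: ModelParams
    grid: Tuple[Dict[str, object], ...]
    n_reps: int
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if not self.grid:
            raise ValueError("grid must contain at least one cell")
        object.__setattr__(self, "grid", tuple(dict(g) for g in self.grid))

    def cell_params(self, i: int) -> ModelParams:
        return self.base_params.with_overrides(**self.grid[i])

    def cell_seed(self, i: int, j: int) -> int:
        return self.base_seed + i * self.n_reps + j


@dataclass
class EnsembleResult:
    spec: EnsembleSpec
    summary: pd.DataFrame  # one row per cell: overrides, success_count, n_reps, success_ratio
    transition_times: List[np.ndarray]  # per cell, one entry per successful run
    transition_durations: List[np.ndarray]
    seeds: List[List[int]]


def run_ensemble(spec: EnsembleSpec, progress: bool = False) -> EnsembleResult:
    """Run every (cell, replicate) serially with deterministic seeds.

    Results are a pure function of the spec; re-running reproduces the
    identical summary and transition-time collections.
    """
    rows = []
    times: List[np.ndarray] = []
    durations: List[np.ndarray] = []
    seeds: List[List[int]] = []
    for i, overrides in enumerate(spec.grid):
        try:
            params = spec.cell_params(i)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"grid cell {i} ({overrides!r}): {exc}") from exc
        cell_seeds = [spec.cell_seed(i, j) for j in range(spec.n_reps)]
        cell_times = []
        cell_durs = []
        n_success = 0
        for s in cell_seeds:
            res = run_simulation(params, s)
            if res.av_success:
                n_success += 1
                cell_times.append(res.transition_time)
                cell_durs.append(res.transition_duration)
            if progress:
                print(f"cell {i} seed {s}: success={res.av_success}", flush=True)
        row = dict(overrides)
        row.update(
            cell=i,
            success_count=n_success,
            n_reps=spec.n_reps,
            success_ratio=n_success / spec.n_reps,
        )
        rows.append(row)
        times.append(np.array(cell_times, dtype=float))
        durations.append(np.array(cell_durs, dtype=float))
        seeds.append(cell_seeds)
    summary = pd.DataFrame(rows)
    return EnsembleResult(spec, summary, times, durations, seeds)


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray, loc: float, slope: float, cap: float) -> np.ndarray:
    return cap / (1.0 + np.exp(-slope * (x - loc)))


def _gompertz(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * np.exp(-c * x))


def fit_success_sigmoid(
    points: Sequence[Tuple[float, float]],
    family: str = "logistic",
) -> DistributionFit:
    """Least-squares sigmoid fit to (PW, success_ratio) points.

    ``logistic``: L / (1 + exp(-s (PW - x0))) with L capped at 1, where
    x0 is the transition location (PW at half maximum).  ``gompertz``:
    a exp(-b exp(-c PW)), a capped at 1, whose half-maximum location is
    reported as ``location``.  Degenerate input (all ratios equal, or a
    curve that never rises) yields an explicit no-fit result rather than
    an exception.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (PW, ratio) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(y, y[0]):
        return DistributionFit(
            family=family, params={}, n_samples=int(x.size),
            ok=False, degenerate=True, note="all success ratios equal; no transition to fit")
    span = x.max() - x.min()
    x0_guess = float(x[np.argmin(np.abs(y - 0.5 * y.max()))])
    try:
        if family == "logistic":
            popt, _ = optimize.curve_fit(
                _logistic, x, y,
                p0=[x0_guess, 10.0 / max(span, 1e-9), min(1.0, max(y.max(), 0.5))],
                bounds=([x.min() - span, 0.0, 0.0], [x.max() + span, np.inf, 1.0]),
                maxfev=20000,
            )
            loc, slope, cap = map(float, popt)
            params = {"location": loc, "slope": slope, "cap": cap}
            resid = y - _logistic(x, *popt)
        elif family == "gompertz":
            popt, _ = optimize.curve_fit(
                _gompertz, x, y,
                p0=[min(1.0, max(y.max(), 0.5)), 5.0, 10.0 / max(span, 1e-9)],
                bounds=([0.0, 1e-9, 0.0], [1.0, np.inf, np.inf]),
                maxfev=20000,
            )
            a, b, c = map(float, popt)
            # PW at half of the upper plateau a: a e^{-b e^{-c x}} = a/2
            loc = float(np.log(b / np.log(2.0)) / c) if c > 0 else float("nan")
            params = {"a": a, "b": b, "c": c, "location": loc}
            resid = y - _gompertz(x, *popt)
        else:
            raise ValueError(f"unknown sigmoid family '{family}'")
    except RuntimeError as exc:  # optimizer failed to converge
        return DistributionFit(
            family=family, params={}, n_samples=int(x.size),
            ok=False, note=f"fit failed: {exc}")
    return DistributionFit(
        family=family,
        params=params,
        n_samples=int(x.size),
        ks_distance=float(np.max(np.abs(resid))),
        log_likelihood=-float(resid @ resid),
    )
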