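"""Outcome classification and regulation-strength scans.

A trajectory is classified by its end state over a steady tail window:

``coexistence``
    every cell type persists above the extinction threshold and the
    composition is time-invariant (each type's growth balances death);
``exclusion``
    a steady subset persists while the rest are extinct;
``collapse``
    all cell types extinct by the horizon;
``unstable``
    still transient at the horizon.

Independently of the label, the *instability time* records when a
normal (social) cell type first dwindles below the floor (0.1 billion),
the event the therapy scenarios monitor.

The scans sweep an elasticity over a grid, simulate each value under
the reference conditions, and report the smallest value achieving the
scan's target outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bounds import RegulationSpec
from .engine import SimConfig, Trajectory, simulate

__all__ = [
    "OutcomeClass",
    "ScanResult",
    "growth_bias_series",
    "classify",
    "required_specific_capacity",
    "scan_min_epsilon",
    "scan_min_gamma",
    "epsilon_scan_config",
    "gamma_scan_config",
]

#: social cell types (1-based) whose decline defines instability
SOCIAL_TYPES = (1, 2)

FLOOR = 0.1  # billions; a social type below this marks instability
EXTINCT = 0.01  # billions; below this a type is considered gone
TAIL_WINDOW = 20.0  # months of steady tail required for a settled label
REL_TOL = 1e-6  # per-step relative biomass change allowed in the tail


@dataclass
class OutcomeClass:
    label: str  # coexistence | exclusion | collapse | unstable
    instability_time: float | None
    final_B: np.ndarray
    survivors: tuple[int, ...] = ()  # 1-based indices above the extinction threshold


@dataclass
class ScanResult:
    parameter: str
    grid: np.ndarray
    outcomes: list[OutcomeClass]
    threshold: float | None
    monotonic: bool = True  #: once achieved, achieved for all larger grid values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.grid,
                "outcome": [o.label for o in self.outcomes],
                "instability_time": [o.instability_time for o in self.outcomes],
            }
        )


def growth_bias_series(traj: Trajectory) -> np.ndarray:
    """Realized growth bias beta(t) = (b2 - b1)/2 along a two-cell run."""
    if traj.realized.shape[1] < 2:
        raise ValueError("trajectory lacks two cell types")
    return (traj.realized[:, 1] - traj.realized[:, 0]) / 2.0


def required_specific_capacity(traj: Trajectory) -> np.ndarray:
    """X-synthesis flux per unit of cell type 1, per step.

    For the two-cell community the X demand of step k is throughput/4,
    all supplied by type 1; the series diverges (reported as ``inf``)
    when B1 vanishes while demand persists.
    """
    demand = traj.throughput / 4.0
    B1 = traj.B[:-1, 0]
    out = np.full_like(demand, np.nan)
    pos = B1 > 0
    out[pos] = demand[pos] / B1[pos]
    out[(~pos) & (demand > 0)] = np.inf
    out[(~pos) & (demand <= 0)] = 0.0
    return out


def classify(
    traj: Trajectory,
    floor: float = FLOOR,
    extinct: float = EXTINCT,
    tail_window: float = TAIL_WINDOW,
    rel_tol: float = REL_TOL,
) -> OutcomeClass:
    """Assign an outcome label to a finished trajectory."""
    ts = traj.ts
    tail = round(tail_window / ts)
    if tail + 1 > traj.B.shape[0]:
        raise ValueError("horizon shorter than the classification tail window")
    B = traj.B
    final = B[-1]
    social = [i - 1 for i in SOCIAL_TYPES if i - 1 < B.shape[1]]
    below = np.flatnonzero((B[:, social] < floor).any(axis=1))
    instability = float(traj.t[below[0]]) if below.size else None
    tail_B = B[-(tail + 1):]
    alive = final > extinct
    survivors = tuple(int(i + 1) for i in np.flatnonzero(alive))
    if alive.any():
        # steadiness concerns the persisting types; an exponentially
        # dying type never settles in relative terms but is simply gone
        rel = np.abs(np.diff(tail_B[:, alive], axis=0)) / np.maximum(
            tail_B[:-1, alive], 1e-300
        )
        steady = bool(rel.max() <= rel_tol)
    else:
        steady = False
    if alive.all() and steady:
        label = "coexistence"
    elif alive.any() and steady:
        label = "exclusion"
    elif not alive.any():
        label = "collapse"
    else:
        label = "unstable"
    return OutcomeClass(label, instability, final, survivors)


# -- scan configurations ---------------------------------------------------


def epsilon_scan_config(beta: float, epsilon: float, horizon: float = 200.0) -> SimConfig:
    """Two-cell regulated run at growth bias beta.

    mu = (0.25 - beta, 0.25 + beta); the initial composition is the
    balanced-state composition 2*mu (e.g. (0.4, 0.6) at beta = 0.05), as
    in the reference scans.
    """
    mu = [0.25 - beta, 0.25 + beta]
    return SimConfig(
        horizon=horizon,
        mu=mu,
        initial_B=[2 * m for m in mu],
        regulation=RegulationSpec(mode="two_cell_regulated", epsilon=epsilon),
    )


def gamma_scan_config(
    mode: str, gamma: float, epsilon: float = 1.0, horizon: float = 200.0
) -> SimConfig:
    """Three-cell run for the gamma scans: mu = (0.2, 0.3, 0.2),
    B(0) = (0.39, 0.59, 0.02)."""
    reg_mode = "three_cell_mutual" if mode == "mutual" else "three_cell_oneway"
    return SimConfig(
        horizon=horizon,
        mu=[0.2, 0.3, 0.2],
        initial_B=[0.39, 0.59, 0.02],
        regulation=RegulationSpec(mode=reg_mode, epsilon=epsilon, gamma=gamma),
    )


def _scan(
    grid: np.ndarray,
    make_config,
    achieved,
    full: bool,
    parameter: str,
) -> ScanResult:
    outcomes: list[OutcomeClass] = []
    threshold = None
    values = []
    for v in grid:
        values.append(v)
        outcomes.append(classify(simulate(make_config(float(v)))))
        if achieved(outcomes[-1]) and threshold is None:
            threshold = float(v)
            if not full:
                break
    flags = [achieved(o) for o in outcomes]
    monotonic = True
    if threshold is not None and full:
        start = flags.index(True)
        monotonic = all(flags[start:])
    return ScanResult(parameter, np.asarray(values), outcomes, threshold, monotonic)


def scan_min_epsilon(
    beta: float,
    grid_step: float = 0.01,
    grid_max: float = 1.5,
    horizon: float = 200.0,
    full: bool = False,
) -> ScanResult:
    """Smallest elasticity (on the grid) giving stable two-cell
    coexistence at growth bias beta."""
    grid = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 10)
    return _scan(
        grid,
        lambda e: epsilon_scan_config(beta, e, horizon),
        lambda o: o.label == "coexistence",
        full,
        "epsilon",
    )


def scan_min_gamma(
    mode: str = "mutual",
    grid_step: float = 0.05,
    grid_max: float = 1.0,
    horizon: float = 200.0,
    full: bool = False,
) -> ScanResult:
    """Smallest cross-regulation strength gamma achieving the scan target.

    ``mutual``: all three types persist (stability).  ``oneway``: the
    normal pair outgrows the transformed type (types 1 and 2 persist,
    type 3 excluded).
    """
    if mode == "mutual":
        achieved = lambda o: o.label == "coexistence"
    elif mode == "oneway":
        achieved = lambda o: o.label == "exclusion" and o.survivors == (1, 2)
    else:
        raise ValueError(f"unknown gamma-scan mode {mode!r}")
    grid = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 10)
    return _scan(
        grid,
        lambda g: gamma_scan_config(mode, g, horizon=horizon),
        achieved,
        full,
        "gamma",
    )
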