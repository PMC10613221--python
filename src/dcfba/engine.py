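"""The stepwise-growth dcFBA loop.

Each time step of length ``ts`` (months) performs:

1. compute per-type biomass-synthesis upper bounds from the cell numbers
   (module :mod:`dcfba.bounds`), according to the configured regulation;
2. apply metabolic capacity caps: each common-good synthesis flux is
   limited to ``vmax_coeff`` times the producing type's cell number;
3. solve the flux balance LP (maximal total biomass synthesis) under
   those bounds; when no cap binds the realized biomass fluxes equal
   their upper bounds, and when a cap binds the shortfall scales all
   bounds by a common factor (1 - omega), exactly the by-product
   replacement rule of the capacity-limited two-cell scenario;
4. update the cell numbers with first-order death:
   ``B_i(t+ts) = B_i(t) * (1 - d) + ts * b_i,FBA``.

Indexing follows the model equations literally: the bounds (and the
capacity term) carrying time stamp ``t + ts`` are functions of the
biomasses at ``t``, while the biomass update at ``t + ts`` consumes the
fluxes stamped ``t``.  The flux applied over a step therefore derives
from the state one step earlier (a one-step pipeline); the very first
step uses the initial state.  This literal scheme reproduces the
reference trajectories (e.g. the 9.5-month critical crossing of the
untreated three-cell run); the no-lag variant shifts them earlier.

For the built-in networks the per-step LP has a closed form: the maximal
throughput is ``T = min(influx, 4*Vmax*B_X, 4*Vmax*B_Y)`` over the X- and
Y-producer pools, the optimal total biomass synthesis is
``min(sum(b_ub), T/2)``, and the realized fluxes are the bounds scaled
proportionally.  The default ``lp_mode='auto'`` uses this closed form;
``lp_mode='always'`` solves the LP with scipy at every step (the two are
verified identical in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import lp as _lp
from .bounds import (
    BoundsSet,
    RegulationSpec,
    bounds_three_cell_asocial,
    bounds_three_cell_mutual,
    bounds_three_cell_oneway,
    bounds_two_cell,
    bounds_two_cell_regulated,
    regulation_factor,
    _pow,
)
from .networks import build_three_cell_network, build_two_cell_network

__all__ = [
    "SimConfig",
    "Trajectory",
    "StepRecord",
    "capacity_caps",
    "effective_omega",
    "compute_bounds",
    "step",
    "simulate",
]

#: biomass below this many billions of cells is treated as extinct
EXTINCTION_FLOOR = 1e-12

#: indices (0-based) of X-producing cell types; type 2 (index 1) makes Y
X_PRODUCERS = (0, 2, 3)
Y_PRODUCERS = (1,)


class SimConfig(BaseModel):
    """Complete, explicit description of one dcFBA run.

    Times are months, biomasses billions of cells (1-liter vessel),
    fluxes C-mol per time step.  ``death_step`` is the per-step death
    fraction d = ts * k_D (0.05 per 0.1-month step, i.e. 0.5 per month).
    """

    model_config = ConfigDict(extra="forbid")

    ts: float = 0.1
    horizon: float = 200.0
    death_step: float = 0.05
    death_step_per_type: list[float] | None = None
    vmax_coeff: float = 3.0
    influx: float = 1.0
    initial_B: list[float] = [0.4, 0.6]
    mu: list[float] = [0.2, 0.3]
    regulation: RegulationSpec = RegulationSpec()
    capacity_enabled: bool = True
    omega_mode: Literal["zero", "eq10"] = "zero"
    lp_mode: Literal["auto", "always"] = "auto"
    xy_stoich: int = 4
    objective_weights: dict[str, float] | None = None
    epsilon1_per_type: list[float] | None = None  # per asocial type (3, 4)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.ts <= 0:
            raise ValueError("ts must be positive")
        if not 0.0 <= self.death_step < 1.0:
            raise ValueError("death_step must be in [0, 1)")
        if self.vmax_coeff <= 0 or self.influx <= 0:
            raise ValueError("vmax_coeff and influx must be positive")
        n = len(self.initial_B)
        if len(self.mu) != n:
            raise ValueError("mu and initial_B must have equal length")
        if not 2 <= n <= 4:
            raise ValueError("between 2 and 4 cell types are supported")
        if any(b < 0 for b in self.initial_B):
            raise ValueError("initial biomasses must be non-negative")
        if any(m <= 0 for m in self.mu):
            raise ValueError("inherent growth rates must be positive")
        steps = self.horizon / self.ts
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("horizon must be an integral number of steps")
        mode = self.regulation.mode
        if mode in ("none", "two_cell_regulated") and n != 2:
            raise ValueError(f"mode {mode!r} requires 2 cell types")
        if mode in ("three_cell_mutual", "three_cell_oneway") and n != 3:
            raise ValueError(f"mode {mode!r} requires 3 cell types")
        if mode == "three_cell_asocial" and n not in (3, 4):
            raise ValueError("asocial mode requires 3 or 4 cell types")
        if self.omega_mode == "eq10" and mode != "none":
            raise ValueError("eq10 omega handling applies to the unregulated run")
        if self.death_step_per_type is not None and len(self.death_step_per_type) != n:
            raise ValueError("death_step_per_type length mismatch")
        if self.epsilon1_per_type is not None and len(self.epsilon1_per_type) != max(n - 2, 0):
            raise ValueError("epsilon1_per_type needs one entry per asocial type")
        if self.lp_mode == "auto" and self.objective_weights is not None:
            w = set(self.objective_weights.values())
            if w != {1.0}:
                raise ValueError("custom objective weights require lp_mode='always'")
        return self

    @property
    def n_steps(self) -> int:
        return round(self.horizon / self.ts)

    @property
    def n_types(self) -> int:
        return len(self.initial_B)

    def death_vector(self) -> np.ndarray:
        if self.death_step_per_type is not None:
            return np.asarray(self.death_step_per_type, dtype=float)
        return np.full(self.n_types, self.death_step)

    def epsilon1_vector(self) -> np.ndarray:
        """Responsiveness of each asocial type (3, 4) to type 2."""
        if self.epsilon1_per_type is not None:
            return np.asarray(self.epsilon1_per_type, dtype=float)
        return np.full(max(self.n_types - 2, 0), self.regulation.epsilon1)


@dataclass
class StepRecord:
    B_next: np.ndarray
    bounds: np.ndarray
    realized: np.ndarray
    omega_eff: float
    throughput: float
    cap_binding: bool


@dataclass
class Trajectory:
    """States plus per-step fluxes and bound diagnostics of one run.

    ``B[k]`` is the state at ``t[k]``; ``bounds[k]``/``realized[k]`` are
    the biomass bounds and realized fluxes applied during the step from
    ``t[k]`` to ``t[k+1]`` (one row fewer than states).
    """

    t: np.ndarray
    B: np.ndarray
    bounds: np.ndarray
    realized: np.ndarray
    omega: np.ndarray
    throughput: np.ndarray
    cap_binding: np.ndarray
    config: SimConfig = field(repr=False)

    @property
    def ts(self) -> float:
        return self.config.ts

    @property
    def n_types(self) -> int:
        return self.B.shape[1]

    def final_B(self) -> np.ndarray:
        return self.B[-1]

    def first_cap_binding_time(self) -> float | None:
        idx = np.flatnonzero(self.cap_binding)
        if idx.size == 0:
            return None
        # the flux of step k applies over (t[k], t[k+1]]
        return float(self.t[idx[0] + 1])

    def to_frame(self) -> pd.DataFrame:
        n, m = self.B.shape
        pad = np.full((1, self.bounds.shape[1]), np.nan)
        data = {"t": self.t}
        for i in range(m):
            data[f"B{i + 1}"] = self.B[:, i]
        flux = np.vstack([self.realized, pad[:, : m]])
        bnd = np.vstack([self.bounds, pad[:, : m]])
        for i in range(m):
            data[f"b{i + 1}"] = flux[:, i]
        for i in range(m):
            data[f"bound{i + 1}"] = bnd[:, i]
        data["omega"] = np.append(self.omega, np.nan)
        data["cap_binding"] = np.append(self.cap_binding, False)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def capacity_caps(B, vmax_coeff: float) -> dict[str, float]:
    """Upper bounds on the common-good synthesis reactions.

    Each producer's conversion flux (DI1X, DI2Y, DI3X) is capped at
    ``vmax_coeff`` times its current cell number; the X output per flux
    unit is the xy stoichiometry factor.
    """
    if vmax_coeff <= 0:
        raise ValueError("vmax_coeff must be positive")
    B = np.asarray(B, dtype=float)
    caps = {"DI1X": vmax_coeff * B[0], "DI2Y": vmax_coeff * B[1]}
    if B.size >= 3:
        caps["DI3X"] = vmax_coeff * B[2:].sum()
    return caps


def _max_throughput(B, cfg: SimConfig) -> float:
    """Largest feasible glucose throughput given the capacity caps."""
    if not cfg.capacity_enabled:
        return cfg.influx
    B = np.asarray(B, dtype=float)
    s = float(cfg.xy_stoich)
    bx = sum(B[i] for i in X_PRODUCERS if i < B.size)
    by = sum(B[i] for i in Y_PRODUCERS)
    return min(cfg.influx, s * cfg.vmax_coeff * bx, s * cfg.vmax_coeff * by)


def effective_omega(B, vmax_coeff: float, xy_stoich: int = 4, influx: float = 1.0) -> float:
    """By-product fraction implied by the capacity limits:
    1 - omega = min(1, 4*Vmax*B_X, 4*Vmax*B_Y) at unit influx."""
    B = np.asarray(B, dtype=float)
    s = float(xy_stoich)
    bx = sum(B[i] for i in X_PRODUCERS if i < B.size)
    by = sum(B[i] for i in Y_PRODUCERS)
    return 1.0 - min(1.0, s * vmax_coeff * bx / influx, s * vmax_coeff * by / influx)


def compute_bounds(B, cfg: SimConfig, omega: float = 0.0) -> BoundsSet:
    """Dispatch to the regulation variant configured in ``cfg``."""
    B = np.asarray(B, dtype=float)
    mu = np.asarray(cfg.mu, dtype=float)
    spec = cfg.regulation
    mode = spec.mode
    if mode == "none":
        return bounds_two_cell(B, mu, omega=omega)
    if mode == "two_cell_regulated":
        return bounds_two_cell_regulated(B, mu, spec)
    if mode == "three_cell_mutual":
        return bounds_three_cell_mutual(B, mu, spec)
    if mode == "three_cell_oneway":
        return bounds_three_cell_oneway(B, mu, spec)
    # asocial: 3 types, or 4 with a resistant clone sharing type 3's biology
    e1 = cfg.epsilon1_vector()
    if B.size == 3:
        s = spec.model_copy(update={"epsilon1": float(e1[0])})
        return bounds_three_cell_asocial(B, mu, s)
    r = np.array([regulation_factor(b, spec) for b in B])
    numerators = [
        mu[0] * B[0] * _pow(r[1], spec.epsilon),
        mu[1] * B[1] * _pow(r[0] + spec.partial * r[2:].sum(), spec.epsilon),
    ] + [mu[i] * B[i] * _pow(r[1], e1[i - 2]) for i in range(2, B.size)]
    from .bounds import _normalize

    return _normalize(numerators)


def _build_network(cfg: SimConfig):
    if cfg.n_types == 2:
        return build_two_cell_network(b=1.0, xy_stoich=cfg.xy_stoich, influx=cfg.influx)
    if cfg.n_types == 3:
        return build_three_cell_network(influx=cfg.influx)
    raise ValueError("explicit LP stepping supports 2 or 3 cell types")


def step(B, cfg: SimConfig, pipeline_B=None, death: np.ndarray | None = None) -> StepRecord:
    """Advance one time step from state ``B``.

    ``pipeline_B`` is the state from which the step's bounds and caps
    derive (defaults to ``B`` itself; :func:`simulate` passes the state
    one step back, per the literal equation indexing).
    """
    B = np.asarray(B, dtype=float)
    P = B if pipeline_B is None else np.asarray(pipeline_B, dtype=float)
    d = cfg.death_vector() if death is None else death
    T = _max_throughput(P, cfg)
    if cfg.omega_mode == "eq10":
        omega = 1.0 - T / cfg.influx
        bs = compute_bounds(P, cfg, omega=omega)
        bounds_arr = bs.b_ub
        realized = bounds_arr.copy()
        total = bs.total
        binding = omega > 1e-12
    else:
        bs = compute_bounds(P, cfg)
        bounds_arr = bs.b_ub
        total = bs.total
        z = min(total, 0.5 * T) if total > 0 else 0.0
        if cfg.lp_mode == "always" and total > 0:
            z = _lp_objective(P, cfg, bounds_arr)
        realized = bounds_arr * (z / total) if total > 0 else np.zeros_like(bounds_arr)
        binding = z < total - 1e-12
        omega = 1.0 - 2.0 * z / cfg.influx if binding else 0.0
    B_next = B * (1.0 - d) + cfg.ts * realized
    B_next[B_next < EXTINCTION_FLOOR] = 0.0
    return StepRecord(B_next, bounds_arr, realized, omega, T, bool(binding))


def _lp_objective(P, cfg: SimConfig, bounds_arr) -> float:
    """Optimal total biomass synthesis from the explicit per-step LP."""
    net = _build_network(cfg)
    overrides = {f"BM{i + 1}": float(bounds_arr[i]) for i in range(cfg.n_types)}
    if cfg.capacity_enabled:
        overrides.update(capacity_caps(P, cfg.vmax_coeff))
    weights = cfg.objective_weights or net.objective_weights
    sol = _lp.solve_fba(net, weights, upper_overrides=overrides, lexicographic=False)
    if sol.status != "optimal":
        raise _lp.LPError(f"per-step LP {sol.status}")
    return sol.objective_value


def simulate(cfg: SimConfig) -> Trajectory:
    """Run the stepwise-growth loop over the configured horizon.

    Deterministic: identical configurations produce bit-identical
    trajectories.
    """
    n = cfg.n_steps
    m = cfg.n_types
    d = cfg.death_vector()
    B = np.asarray(cfg.initial_B, dtype=float)
    P = B.copy()
    t = np.round(np.arange(n + 1) * cfg.ts, 10)
    states = np.empty((n + 1, m))
    bounds_hist = np.empty((n, m))
    realized_hist = np.empty((n, m))
    omega_hist = np.empty(n)
    throughput_hist = np.empty(n)
    binding_hist = np.zeros(n, dtype=bool)
    states[0] = B
    for k in range(n):
        rec = step(B, cfg, pipeline_B=P, death=d)
        bounds_hist[k] = rec.bounds
        realized_hist[k] = rec.realized
        omega_hist[k] = rec.omega_eff
        throughput_hist[k] = rec.throughput
        binding_hist[k] = rec.cap_binding
        P = B
        B = rec.B_next
        states[k + 1] = B
    return Trajectory(
        t=t,
        B=states,
        bounds=bounds_hist,
        realized=realized_hist,
        omega=omega_hist,
        throughput=throughput_hist,
        cap_binding=binding_hist,
        config=cfg,
    )
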