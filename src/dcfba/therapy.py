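"""Trigger-based therapy on the three-cell (tumor) community.

Interventions fire when the asocial cell type's number crosses a
critical level (0.4 billion by default) or at fixed times:

``kill_fraction``
    instantaneous removal of a fraction of the tumor cells;
``death_multiplier``
    persistent increase of the tumor death-rate constant (an immune
    adjuvant effect);
``restore_regulation``
    a drug restoring the tumor's responsiveness to regulation by cell
    type 2 (raises its elasticity epsilon1, persistently);
``spawn_resistant``
    emergence of a drug-resistant clone: a fourth cell type copying the
    tumor's pre-therapy biology (epsilon1 = 0), seeded at a small
    biomass.

Trigger conditions are evaluated once per step on the updated state (the
initial state included); several interventions firing in the same step
execute in plan order.  After any intervention the next step's bounds
are recomputed from the post-intervention state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .engine import SimConfig, Trajectory, step

__all__ = [
    "Trigger",
    "Intervention",
    "TherapyPlan",
    "Event",
    "detect_trigger",
    "apply_intervention",
    "simulate_with_therapy",
]


class Trigger(BaseModel):
    model_config = ConfigDict(extra="forbid")

    type: Literal["threshold", "time"] = "threshold"
    level: float = 0.4  # billions; fires when the watched type reaches it
    cell_type: int = 3  # 1-based index of the watched type
    time: float | None = None  # months, for type="time"

    @model_validator(mode="after")
    def _check(self) -> "Trigger":
        if self.type == "time" and self.time is None:
            raise ValueError("time trigger requires a time")
        if self.level <= 0:
            raise ValueError("threshold level must be positive")
        return self

    def fires(self, t: float, B: np.ndarray, ts: float) -> bool:
        if self.type == "time":
            return abs(t - self.time) < ts / 2
        i = self.cell_type - 1
        return i < B.size and B[i] >= self.level


class Intervention(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal[
        "kill_fraction", "death_multiplier", "restore_regulation", "spawn_resistant"
    ]
    trigger: Trigger = Trigger()
    fraction: float = 0.8  # kill_fraction: fraction removed
    multiplier: float = 3.0  # death_multiplier
    new_epsilon1: float = 1.1  # restore_regulation
    seed_biomass: float = 0.01  # spawn_resistant, billions
    target: int = 3  # 1-based cell type acted upon
    max_applications: int = 1
    skip_first: int = 0  # ignore this many trigger firings before acting

    @model_validator(mode="after")
    def _check(self) -> "Intervention":
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("kill fraction must be in (0, 1]")
        if self.multiplier < 1.0:
            raise ValueError("death multiplier must be >= 1")
        if self.seed_biomass <= 0:
            raise ValueError("seed biomass must be positive")
        if self.max_applications < 1:
            raise ValueError("max_applications must be >= 1")
        if self.skip_first < 0:
            raise ValueError("skip_first must be >= 0")
        return self


class TherapyPlan(BaseModel):
    model_config = ConfigDict(extra="forbid")

    interventions: list[Intervention] = []


@dataclass
class Event:
    t: float
    kind: str
    params: dict
    state: np.ndarray = field(repr=False)


def detect_trigger(traj: Trajectory, trigger: Trigger) -> float | None:
    """First grid time at which the trigger condition holds, or None.

    Threshold crossings use the discrete convention: the first state
    (after its biomass update) at or above the level.
    """
    for k, t in enumerate(traj.t):
        if trigger.fires(float(t), traj.B[k], traj.ts):
            return float(t)
    return None


def apply_intervention(
    B: np.ndarray, cfg: SimConfig, iv: Intervention
) -> tuple[np.ndarray, SimConfig]:
    """Return the mutated state and configuration (inputs untouched)."""
    B = B.copy()
    i = iv.target - 1
    if iv.kind == "kill_fraction":
        B[i] *= 1.0 - iv.fraction
        return B, cfg
    if iv.kind == "death_multiplier":
        d = cfg.death_vector()
        d[i] *= iv.multiplier
        return B, cfg.model_copy(update={"death_step_per_type": d.tolist()})
    if iv.kind == "restore_regulation":
        e1 = cfg.epsilon1_vector()
        e1[i - 2] = iv.new_epsilon1
        return B, cfg.model_copy(update={"epsilon1_per_type": e1.tolist()})
    if iv.kind == "spawn_resistant":
        # clone of the tumor with pre-therapy parameters (unresponsive)
        if cfg.n_types != 3 or cfg.regulation.mode != "three_cell_asocial":
            raise ValueError("resistant clones require the three-cell asocial mode")
        B = np.append(B, iv.seed_biomass)
        e1 = cfg.epsilon1_vector()
        cfg = cfg.model_copy(
            update={
                "initial_B": cfg.initial_B + [iv.seed_biomass],
                "mu": cfg.mu + [cfg.mu[2]],
                "death_step_per_type": np.append(cfg.death_vector(), cfg.death_step).tolist(),
                "epsilon1_per_type": np.append(e1, 0.0).tolist(),
            }
        )
        return B, cfg
    raise ValueError(f"unknown intervention kind {iv.kind!r}")  # pragma: no cover


def simulate_with_therapy(
    cfg: SimConfig, plan: TherapyPlan
) -> tuple[Trajectory, list[Event]]:
    """Run the engine loop with trigger monitoring and an event log.

    With an empty plan the trajectory is identical to
    :func:`dcfba.engine.simulate`.  A spawned resistant clone widens the
    biomass arrays from its event onward (earlier rows carry 0 for the
    clone).
    """
    n = cfg.n_steps
    max_types = 4 if any(
        iv.kind == "spawn_resistant" for iv in plan.interventions
    ) else cfg.n_types
    remaining = [iv.max_applications for iv in plan.interventions]
    skips = [iv.skip_first for iv in plan.interventions]
    events: list[Event] = []

    B = np.asarray(cfg.initial_B, dtype=float)
    P = B.copy()
    t_grid = np.round(np.arange(n + 1) * cfg.ts, 10)
    states = np.zeros((n + 1, max_types))
    bounds_hist = np.zeros((n, max_types))
    realized_hist = np.zeros((n, max_types))
    omega_hist = np.empty(n)
    throughput_hist = np.empty(n)
    binding_hist = np.zeros(n, dtype=bool)

    def check_events(t: float, B: np.ndarray, P: np.ndarray, cfg: SimConfig):
        changed = False
        for idx, iv in enumerate(plan.interventions):
            if remaining[idx] <= 0:
                continue
            if iv.trigger.fires(t, B, cfg.ts):
                if skips[idx] > 0:
                    skips[idx] -= 1
                    continue
                B, cfg = apply_intervention(B, cfg, iv)
                remaining[idx] -= 1
                changed = True
                events.append(
                    Event(t, iv.kind, iv.model_dump(exclude={"trigger"}), B.copy())
                )
        if changed:
            P = B.copy()  # bounds pipeline restarts from the new state
        return B, P, cfg

    B, P, cfg = check_events(0.0, B, P, cfg)
    states[0, : B.size] = B
    for k in range(n):
        rec = step(B, cfg, pipeline_B=P)
        m = B.size
        bounds_hist[k, :m] = rec.bounds
        realized_hist[k, :m] = rec.realized
        omega_hist[k] = rec.omega_eff
        throughput_hist[k] = rec.throughput
        binding_hist[k] = rec.cap_binding
        P = B
        B = rec.B_next
        B, P, cfg = check_events(float(t_grid[k + 1]), B, P, cfg)
        states[k + 1, : B.size] = B
    traj = Trajectory(
        t=t_grid,
        B=states,
        bounds=bounds_hist,
        realized=realized_hist,
        omega=omega_hist,
        throughput=throughput_hist,
        cap_binding=binding_hist,
        config=cfg,
    )
    return traj, events


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {"t": ev.t, "kind": ev.kind}
        row.update({k: v for k, v in ev.params.items() if np.isscalar(v)})
        for i, b in enumerate(ev.state):
            row[f"B{i + 1}"] = b
        rows.append(row)
    return pd.DataFrame(rows)
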