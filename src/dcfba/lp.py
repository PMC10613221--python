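"""Flux balance analysis and flux variability on the community networks.

Standard FBA: maximize a linear objective over fluxes subject to
steady-state mass balance of the balanced metabolites (S v = 0) and the
flux bounds.  Because the optimum of these toy networks is degenerate,
solutions are made deterministic by a lexicographic refinement (minimize
the by-product flux omega, then total CO2 efflux, at the fixed optimal
objective), and flux variability analysis (FVA) characterizes the full
set of alternative optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .networks import StoichNetwork

__all__ = [
    "FluxSolution",
    "FluxRange",
    "LPError",
    "solve_fba",
    "flux_variability",
    "beta_range",
    "co2_efflux",
    "biomass_cmol",
]

#: tolerance for mass-balance and bound checks on LP solutions
BALANCE_TOL = 1e-9


class LPError(RuntimeError):
    """Raised when the linear program is infeasible or unbounded."""


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux at a fixed optimal objective value."""

    ranges: dict[str, tuple[float, float]]
    objective_value: float
    network: StoichNetwork = field(repr=False)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, lo, hi) for r, (lo, hi) in self.ranges.items()],
            columns=["reaction", "min", "max"],
        )


def _solve(
    net: StoichNetwork,
    c: np.ndarray,
    extra_eq: list[tuple[np.ndarray, float]] | None = None,
    upper_overrides: dict[str, float] | None = None,
):
    """Minimize c.v subject to S v = 0, bounds, and extra equality rows."""
    S = net.stoich_matrix()
    lb, ub = net.bounds_array()
    if upper_overrides:
        ids = net.reaction_ids
        ub = ub.copy()
        for rid, val in upper_overrides.items():
            ub[ids.index(rid)] = min(ub[ids.index(rid)], val)
    A = S
    b = np.zeros(S.shape[0])
    if extra_eq:
        A = np.vstack([S] + [row for row, _ in extra_eq])
        b = np.concatenate([b, [rhs for _, rhs in extra_eq]])
    res = linprog(c, A_eq=A, b_eq=b, bounds=list(zip(lb, ub)), method="highs")
    return res


def solve_fba(
    net: StoichNetwork,
    objective_weights: dict[str, float] | None = None,
    upper_overrides: dict[str, float] | None = None,
    lexicographic: bool = True,
) -> FluxSolution:
    """Maximize the (weighted) objective over feasible steady fluxes.

    ``upper_overrides`` tightens reaction upper bounds (used by the
    dynamic engine for per-step biomass bounds and capacity caps).  With
    ``lexicographic`` the reported flux vector additionally minimizes
    omega, then total CO2 efflux, so results are identical across LP
    backends despite degenerate optima.
    """
    weights = objective_weights if objective_weights is not None else net.objective_weights
    if not any(weights.values()):
        raise LPError("objective has no nonzero weight")
    ids = net.reaction_ids
    c_obj = np.zeros(len(ids))
    for rid, w in weights.items():
        c_obj[ids.index(rid)] = w
    res = _solve(net, -c_obj, upper_overrides=upper_overrides)
    if res.status == 2:
        return FluxSolution({}, np.nan, "infeasible")
    if res.status == 3:
        return FluxSolution({}, np.nan, "unbounded")
    if not res.success:  # pragma: no cover - solver failure
        raise LPError(f"LP solver failed: {res.message}")
    z = -res.fun
    x = res.x
    if lexicographic:
        fix = [(c_obj, z)]
        for crit in ("OMEGA", "CO2"):
            c2 = np.zeros(len(ids))
            if crit == "OMEGA":
                if "OMEGA" not in ids:
                    continue
                c2[ids.index("OMEGA")] = 1.0
            else:
                for j, rxn in enumerate(net.reactions):
                    c2[j] = max(rxn.stoich.get("CO2", 0.0), 0.0)
            r2 = _solve(net, c2, extra_eq=fix, upper_overrides=upper_overrides)
            if r2.success:
                x = r2.x
                fix = fix + [(c2, r2.fun)]
    sol = FluxSolution(dict(zip(ids, x)), z, "optimal")
    _check_solution(net, sol, upper_overrides)
    return sol


def _check_solution(
    net: StoichNetwork, sol: FluxSolution, upper_overrides: dict[str, float] | None
) -> None:
    S = net.stoich_matrix()
    v = np.array([sol.fluxes[r] for r in net.reaction_ids])
    resid = np.abs(S @ v).max()
    if resid > BALANCE_TOL:
        raise LPError(f"mass-balance residual {resid:.2e} exceeds tolerance")
    for rxn in net.reactions:
        ub = rxn.upper_bound
        if upper_overrides and rxn.id in upper_overrides:
            ub = min(ub, upper_overrides[rxn.id])
        f = sol.fluxes[rxn.id]
        if f < rxn.lower_bound - BALANCE_TOL or f > ub + BALANCE_TOL:
            raise LPError(f"flux {rxn.id}={f} violates bounds")


def flux_variability(
    net: StoichNetwork,
    at_objective: float | None = None,
    objective_weights: dict[str, float] | None = None,
    reactions: list[str] | None = None,
) -> FluxRange:
    """Min/max of each flux with the objective fixed at its optimum.

    ``at_objective`` defaults to the FBA optimum; an unattainable value
    raises :class:`LPError`.
    """
    weights = objective_weights if objective_weights is not None else net.objective_weights
    if at_objective is None:
        at_objective = solve_fba(net, weights, lexicographic=False).objective_value
    ids = net.reaction_ids
    c_obj = np.zeros(len(ids))
    for rid, w in weights.items():
        c_obj[ids.index(rid)] = w
    fix = [(c_obj, float(at_objective))]
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reactions or ids:
        j = ids.index(rid)
        lo_hi = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(ids))
            c[j] = sign
            res = _solve(net, c, extra_eq=fix)
            if not res.success:
                raise LPError(
                    f"objective value {at_objective} not attainable (FVA on {rid})"
                )
            lo_hi.append(sign * res.fun + 0.0)  # +0.0 normalizes -0.0
        ranges[rid] = (lo_hi[0], lo_hi[1])
    return FluxRange(ranges, float(at_objective), net)


def beta_range(fr: FluxRange) -> tuple[float, float]:
    """Attainable range of the growth bias at the fixed optimal objective.

    The growth bias is half the difference of the biomass synthesis rates
    in C-mol terms, beta = (BM2 - b*BM1)/2 (for biomass cost b = 1 this
    is simply half the difference of the two biomass fluxes, and it always
    equals the glucose-consumption bias (v2g - v1g)/2).  The range is
    computed by optimizing the linear functional directly, not from the
    independent per-reaction intervals.
    """
    net = fr.network
    ids = net.reaction_ids
    for rid in ("BM1", "BM2"):
        if rid not in ids:
            raise LPError(f"network lacks biomass reaction {rid}")
    weights = net.objective_weights
    c_obj = np.zeros(len(ids))
    for rid, w in weights.items():
        c_obj[ids.index(rid)] = w
    fix = [(c_obj, fr.objective_value)]
    c_beta = np.zeros(len(ids))
    c_beta[ids.index("BM2")] = 0.5
    c_beta[ids.index("BM1")] = -0.5 * net.biomass_cost
    out = []
    for sign in (1.0, -1.0):
        res = _solve(net, sign * c_beta, extra_eq=fix)
        if not res.success:
            raise LPError("objective value not attainable (beta range)")
        out.append(sign * res.fun)
    return out[0], out[1]


def co2_efflux(net: StoichNetwork, sol: FluxSolution) -> float:
    """Total CO2 production of a flux solution (C-mol per step)."""
    return sum(
        rxn.stoich.get("CO2", 0.0) * sol.fluxes[rxn.id]
        for rxn in net.reactions
        if rxn.stoich.get("CO2", 0.0) > 0
    )


def biomass_cmol(net: StoichNetwork, sol: FluxSolution) -> float:
    """Total biomass synthesis in C-mol (b * flux for biomass 1)."""
    total = 0.0
    for rid in ("BM1", "BM2", "BM3"):
        if rid in net.reaction_ids:
            cost = net.biomass_cost if rid == "BM1" else 1.0
            total += cost * sol.fluxes[rid]
    return total
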