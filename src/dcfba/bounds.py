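"""Per-step biomass-synthesis upper bounds for every regulation variant.

At each time step the community may synthesize at most (1 - omega)/2
C-mol of biomass in total (half of the glucose not lost to by-product).
How that allowance is split between the cell types is set by bound
ratios: each type's share is proportional to its inherent specific
growth rate mu_i times its cell number, optionally multiplied by
regulation factors -- powers of the *other* types' cell numbers with
elasticities epsilon (between the social pair), epsilon1 (type 3's
responsiveness to type 2) and gamma (cross-regulation with type 3).

Biomasses are expressed in billions of cells (1-liter vessel) so the
identity regulation factor stays in (0, 1] for the regimes of interest;
values above 1 are allowed and the power is applied unchanged.  The
convention 0**0 = 1 makes a zero elasticity degenerate cleanly to the
unregulated ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "RegulationSpec",
    "BoundsSet",
    "regulation_factor",
    "bounds_growth_tendency",
    "bounds_two_cell",
    "bounds_two_cell_regulated",
    "bounds_three_cell_asocial",
    "bounds_three_cell_mutual",
    "bounds_three_cell_oneway",
]

RegulationMode = Literal[
    "none",
    "two_cell_regulated",
    "three_cell_asocial",
    "three_cell_mutual",
    "three_cell_oneway",
]


class RegulationSpec(BaseModel):
    """Regulation mode and its elasticity parameters.

    ``factor_form`` selects how a regulator's cell number B enters the
    bound ratios: ``identity`` uses B itself; ``hyperbolic`` uses the
    receptor-occupancy form B/(B + Kd/alpha) of a growth factor whose
    concentration is proportional to B.
    """

    model_config = ConfigDict(extra="forbid")

    mode: RegulationMode = "none"
    epsilon: float = 0.0
    epsilon1: float = 0.0
    partial: int = 0  # 0 or 1: does type 3 stimulate type 2?
    gamma: float = 0.0
    factor_form: Literal["identity", "hyperbolic"] = "identity"
    kd_over_alpha: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "RegulationSpec":
        if self.epsilon < 0 or self.epsilon1 < 0 or self.gamma < 0:
            raise ValueError("elasticities must be non-negative")
        if self.partial not in (0, 1):
            raise ValueError("partial must be 0 or 1")
        if self.kd_over_alpha <= 0:
            raise ValueError("kd_over_alpha must be positive")
        if self.mode == "none" and (self.epsilon or self.epsilon1 or self.gamma):
            raise ValueError("mode 'none' admits no elasticity parameters")
        if self.mode == "two_cell_regulated" and (self.epsilon1 or self.gamma):
            raise ValueError("two-cell regulation uses only epsilon")
        if self.mode == "three_cell_asocial" and self.gamma:
            raise ValueError("asocial mode has no gamma; use mutual/oneway")
        return self


@dataclass
class BoundsSet:
    """Per-type biomass-flux upper bounds plus diagnostics."""

    b_ub: np.ndarray  #: per cell type, C-mol biomass per step
    omega: float = 0.0
    denominator: float = 0.0  #: the shared normalization (FR1/FR2 analogue)
    extinct: bool = False  #: community extinct (all numerators zero)
    v_g: np.ndarray | None = field(default=None)  #: glucose->intermediate fluxes

    @property
    def total(self) -> float:
        return float(self.b_ub.sum())


def regulation_factor(B: float, spec: RegulationSpec) -> float:
    """Activity of a regulator with B billion cells, in [0, 1] for B <= 1."""
    if B < 0:
        raise ValueError(f"negative biomass {B}")
    if spec.factor_form == "hyperbolic":
        return B / (B + spec.kd_over_alpha)
    return B


def _pow(base: float, exponent: float) -> float:
    # 0**0 := 1 so that zero elasticity reduces to the unregulated ratio
    if exponent == 0.0:
        return 1.0
    return base ** exponent


def _normalize(numerators: Sequence[float], scale: float = 0.5) -> BoundsSet:
    n = np.asarray(numerators, dtype=float)
    total = n.sum()
    if total <= 0.0:
        return BoundsSet(np.zeros_like(n), denominator=0.0, extinct=True)
    return BoundsSet(scale * n / total, denominator=float(total))


def bounds_growth_tendency(
    mu: Sequence[float], f1: float, f2: float
) -> BoundsSet:
    """Bounds from arbitrary growth tendencies f_i(t): 0.5*mu_i*f_i/sum."""
    if f1 < 0 or f2 < 0:
        raise ValueError("growth tendencies must be non-negative")
    if f1 == 0 and f2 == 0:
        raise ValueError("both growth tendencies are zero")
    return _normalize([mu[0] * f1, mu[1] * f2])


def bounds_two_cell(
    B: Sequence[float], mu: Sequence[float], omega: float = 0.0
) -> BoundsSet:
    """Unregulated stepwise bounds: shares proportional to mu_i * B_i.

    Also reports the glucose-to-intermediate fluxes
    v_{i,g} = (1 - omega)/4 + b_ub,i implied by the common-goods balance.
    """
    if not 0.0 <= omega < 1.0:
        raise ValueError(f"omega must be in [0, 1), got {omega}")
    bs = _normalize([mu[0] * B[0], mu[1] * B[1]], scale=0.5 * (1.0 - omega))
    bs.omega = omega
    if not bs.extinct:
        bs.v_g = (1.0 - omega) / 4.0 + bs.b_ub
    return bs


def bounds_two_cell_regulated(
    B: Sequence[float], mu: Sequence[float], spec: RegulationSpec
) -> BoundsSet:
    """Mutually regulated pair: each type's share carries the partner's
    regulation factor to the power epsilon."""
    e = spec.epsilon
    r1 = regulation_factor(B[0], spec)
    r2 = regulation_factor(B[1], spec)
    return _normalize(
        [
            mu[0] * B[0] * _pow(r2, e),
            mu[1] * _pow(r1, e) * B[1],
        ]
    )


def bounds_three_cell_asocial(
    B: Sequence[float], mu: Sequence[float], spec: RegulationSpec
) -> BoundsSet:
    """Social pair (elasticity epsilon) plus a mutant cell type 3.

    ``spec.partial`` sets whether type 3 stimulates type 2 (its biomass
    adds to type 1's in type 2's regulation factor) and ``spec.epsilon1``
    is type 3's responsiveness to type 2.  The four corners are:
    the asocial mutant (partial=0, epsilon1=0), non-responsive only
    (partial=1, epsilon1=0), non-communicating only (partial=0,
    epsilon1=epsilon) and the social control (partial=1,
    epsilon1=epsilon), which behaves exactly like a third social cell.
    """
    e, e1, part = spec.epsilon, spec.epsilon1, spec.partial
    r1 = regulation_factor(B[0], spec)
    r2 = regulation_factor(B[1], spec)
    r3 = regulation_factor(B[2], spec)
    return _normalize(
        [
            mu[0] * B[0] * _pow(r2, e),
            mu[1] * B[1] * _pow(r1 + part * r3, e),
            mu[2] * B[2] * _pow(r2, e1),
        ]
    )


def bounds_three_cell_mutual(
    B: Sequence[float], mu: Sequence[float], spec: RegulationSpec
) -> BoundsSet:
    """All three types regulate each other: the social pair with
    elasticity epsilon, and pair <-> type 3 with elasticity gamma in both
    directions."""
    e, g = spec.epsilon, spec.gamma
    r1 = regulation_factor(B[0], spec)
    r2 = regulation_factor(B[1], spec)
    r3 = regulation_factor(B[2], spec)
    return _normalize(
        [
            mu[0] * B[0] * _pow(r2, e) * _pow(r3, g),
            mu[1] * _pow(r1, e) * B[1] * _pow(r3, g),
            mu[2] * _pow(r1, g) * _pow(r2, g) * B[2],
        ]
    )


def bounds_three_cell_oneway(
    B: Sequence[float], mu: Sequence[float], spec: RegulationSpec
) -> BoundsSet:
    """Only type 3 is regulated (by both normal types, elasticity gamma);
    the normal pair keeps its mutual epsilon regulation."""
    e, g = spec.epsilon, spec.gamma
    r1 = regulation_factor(B[0], spec)
    r2 = regulation_factor(B[1], spec)
    return _normalize(
        [
            mu[0] * B[0] * _pow(r2, e),
            mu[1] * _pow(r1, e) * B[1],
            mu[2] * _pow(r1, g) * _pow(r2, g) * B[2],
        ]
    )
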