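"""Toy community stoichiometric networks.

Two (or three) cell types share a single carbon/free-energy substrate
(glucose) and depend on each other through the "common goods" X and Y:
cell type 1 converts glucose to its private intermediate I1 and makes X,
cell type 2 makes Y from I2, and every glucose-to-intermediate step
consumes one unit of each common good.  Each intermediate is spent either
on the cell type's own biomass or on common-good synthesis (releasing one
CO2 per conversion).  A by-product drain from glucose (flux ``omega``)
closes the carbon balance when the community runs below its optimum.

The two-cell network has 8 reactions and 5 balanced metabolites
(glucose, I1, I2, X, Y); biomass, CO2 and the by-product are boundary
(sink) species, so biomass bookkeeping lives in the dynamic engine rather
than in the LP.  The three-cell network adds a mutant cell type 3 that
mirrors cell type 1 (an X producer with intermediate I3).

Reaction identifiers are fixed (``GLCIN``, ``GTI1``, ``GTI2``, ``GTI3``,
``DI1X``, ``DI2Y``, ``DI3X``, ``BM1``, ``BM2``, ``BM3``, ``OMEGA``) so
configurations and trajectory files remain stable across versions.

Units: fluxes are C-mol per time step; the culture vessel is 1 liter, so
cell numbers (billions) and concentrations coincide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Reaction",
    "StoichNetwork",
    "NetworkError",
    "build_two_cell_network",
    "build_three_cell_network",
    "write_network",
    "read_network",
]

#: balanced metabolites of the two-cell community
BALANCED_TWO = ("glucose", "I1", "I2", "X", "Y")
#: boundary (sink) species of the two-cell community
BOUNDARY_TWO = ("CO2", "byproduct", "biomass1", "biomass2")


class NetworkError(ValueError):
    """Raised for invalid network definitions or malformed documents."""


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry and flux bounds (C-mol/step)."""

    id: str
    stoich: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoich", dict(self.stoich))


@dataclass
class StoichNetwork:
    """A species-by-reactions stoichiometric system with an LP objective.

    ``species`` are the balanced (steady-state) metabolites; every other
    species referenced by a reaction must appear in ``boundary_species``
    and is excluded from the mass-balance constraints.
    """

    species: list[str]
    boundary_species: list[str]
    reactions: list[Reaction]
    objective_weights: dict[str, float] = field(default_factory=dict)
    biomass_cost: float = 1.0  #: C-mol of intermediate per C-mol biomass 1

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        declared = set(self.species) | set(self.boundary_species)
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise NetworkError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for sp in rxn.stoich:
                if sp not in declared:
                    raise NetworkError(
                        f"reaction {rxn.id} references undeclared species {sp!r}"
                    )
        for rid in self.objective_weights:
            if rid not in seen:
                raise NetworkError(f"objective references unknown reaction {rid!r}")

    def reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoich_matrix(self) -> np.ndarray:
        """Balanced-species x reactions matrix (rows follow ``species``)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoich.items():
                if sp in self.species:
                    S[self.species.index(sp), j] = coeff
        return S

    def bounds_array(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StoichNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.boundary_species == other.boundary_species
            and self.objective_weights == other.objective_weights
            and self.biomass_cost == other.biomass_cost
            and len(self.reactions) == len(other.reactions)
            and all(
                a.id == b.id
                and dict(a.stoich) == dict(b.stoich)
                and a.lower_bound == b.lower_bound
                and a.upper_bound == b.upper_bound
                for a, b in zip(self.reactions, other.reactions)
            )
        )


# -- builders --------------------------------------------------------------


def build_two_cell_network(
    b: float = 1.0, xy_stoich: int = 4, influx: float = 1.0
) -> StoichNetwork:
    """Two cell types competing for glucose and coupled through X and Y.

    Parameters
    ----------
    b:
        Biomass cost of cell type 1: C-mol of I1 consumed per C-mol of
        biomass 1 (growth yield 1/b).  Cell type 2 always has cost 1.
    xy_stoich:
        Units of common good produced per intermediate converted (the
        DI1X/DI2Y stoichiometry; 4 in the reference community).
    influx:
        Upper bound of the glucose influx (C-mol per time step).  The
        influx is modeled as ``0 <= GLCIN <= influx`` so that capacity-
        limited states remain feasible; at the unconstrained optimum the
        bound is tight.
    """
    if b <= 0:
        raise NetworkError(f"biomass cost b must be positive, got {b}")
    if influx <= 0:
        raise NetworkError(f"glucose influx must be positive, got {influx}")
    if xy_stoich < 1 or int(xy_stoich) != xy_stoich:
        raise NetworkError(f"xy_stoich must be an integer >= 1, got {xy_stoich}")
    s = float(xy_stoich)
    reactions = [
        Reaction("GLCIN", {"glucose": 1.0}, 0.0, float(influx)),
        Reaction("GTI1", {"glucose": -1.0, "X": -1.0, "Y": -1.0, "I1": 1.0}),
        Reaction("GTI2", {"glucose": -1.0, "X": -1.0, "Y": -1.0, "I2": 1.0}),
        Reaction("DI1X", {"I1": -1.0, "X": s, "CO2": 1.0}),
        Reaction("DI2Y", {"I2": -1.0, "Y": s, "CO2": 1.0}),
        Reaction("BM1", {"I1": -float(b), "biomass1": 1.0}),
        Reaction("BM2", {"I2": -1.0, "biomass2": 1.0}),
        Reaction("OMEGA", {"glucose": -1.0, "byproduct": 1.0}),
    ]
    return StoichNetwork(
        species=list(BALANCED_TWO),
        boundary_species=list(BOUNDARY_TWO),
        reactions=reactions,
        objective_weights={"BM1": 1.0, "BM2": 1.0},
        biomass_cost=float(b),
    )


def build_three_cell_network(influx: float = 1.0) -> StoichNetwork:
    """Extend the two-cell community with a mutant X producer (type 3).

    Cell type 3 mirrors cell type 1: it converts glucose to its own
    intermediate I3 (consuming X and Y) and spends I3 on biomass 3 or on
    X synthesis.  Biomass costs are 1 for all three types.
    """
    net = build_two_cell_network(b=1.0, xy_stoich=4, influx=influx)
    net.species.append("I3")
    net.boundary_species.append("biomass3")
    net.reactions.extend(
        [
            Reaction("GTI3", {"glucose": -1.0, "X": -1.0, "Y": -1.0, "I3": 1.0}),
            Reaction("DI3X", {"I3": -1.0, "X": 4.0, "CO2": 1.0}),
            Reaction("BM3", {"I3": -1.0, "biomass3": 1.0}),
        ]
    )
    net.objective_weights["BM3"] = 1.0
    net.validate()
    return net


# -- serialization ---------------------------------------------------------


def write_network(net: StoichNetwork, format: str = "json") -> str:
    """Serialize a network to a JSON or SBML Level 3 document (string)."""
    if format == "json":
        return _to_json(net)
    if format == "sbml":
        return _to_sbml(net)
    raise NetworkError(f"unknown format {format!r}")


def read_network(document: str, format: str = "json") -> StoichNetwork:
    """Inverse of :func:`write_network`; round-trips exactly."""
    if format == "json":
        return _from_json(document)
    if format == "sbml":
        return _from_sbml(document)
    raise NetworkError(f"unknown format {format!r}")


def _to_json(net: StoichNetwork) -> str:
    doc = {
        "species": net.species,
        "boundary_species": net.boundary_species,
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lower_bound,
                "ub": "inf" if math.isinf(r.upper_bound) else r.upper_bound,
            }
            for r in net.reactions
        ],
        "objective": net.objective_weights,
        "biomass_cost": net.biomass_cost,
    }
    return json.dumps(doc, indent=1)


def _from_json(document: str) -> StoichNetwork:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise NetworkError(f"malformed JSON network document: {exc}") from exc
    try:
        reactions = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoich"].items()},
                float(r["lb"]),
                math.inf if r["ub"] == "inf" else float(r["ub"]),
            )
            for r in doc["reactions"]
        ]
        return StoichNetwork(
            species=list(doc["species"]),
            boundary_species=list(doc["boundary_species"]),
            reactions=reactions,
            objective_weights={k: float(v) for k, v in doc["objective"].items()},
            biomass_cost=float(doc.get("biomass_cost", 1.0)),
        )
    except KeyError as exc:
        raise NetworkError(f"network document missing field {exc}") from exc


# SBML L3 core with the classic flux-bound convention: per-reaction kinetic-law
# local parameters LOWER_BOUND / UPPER_BOUND / OBJECTIVE_COEFFICIENT, boundary
# species flagged with boundaryCondition, one 1-liter compartment.


def _to_sbml(net: StoichNetwork) -> str:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("dcfba_community")
    comp = model.createCompartment()
    comp.setId("vessel")
    comp.setSize(1.0)  # 1 liter culture vessel
    comp.setConstant(True)
    for sp, boundary in [(s, False) for s in net.species] + [
        (s, True) for s in net.boundary_species
    ]:
        s = model.createSpecies()
        s.setId(sp)
        s.setCompartment("vessel")
        s.setBoundaryCondition(boundary)
        s.setHasOnlySubstanceUnits(True)
        s.setConstant(False)
    p = model.createParameter()
    p.setId("biomass_cost")
    p.setValue(net.biomass_cost)
    p.setConstant(True)
    for rxn in net.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        for sp, coeff in sorted(rxn.stoich.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(sp)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("FLUX_VALUE"))
        for name, value in [
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("OBJECTIVE_COEFFICIENT", net.objective_weights.get(rxn.id, 0.0)),
            ("FLUX_VALUE", 0.0),
        ]:
            lp = kl.createLocalParameter()
            lp.setId(name)
            lp.setValue(value)
    return libsbml.writeSBMLToString(doc)


def _from_sbml(document: str) -> StoichNetwork:
    import libsbml

    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise NetworkError(
            "malformed SBML document: "
            + doc.getError(0).getMessage().strip()
        )
    model = doc.getModel()
    if model is None:
        raise NetworkError("SBML document contains no model")
    species, boundary = [], []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        (boundary if s.getBoundaryCondition() else species).append(s.getId())
    declared = set(species) | set(boundary)
    objective: dict[str, float] = {}
    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        stoich: dict[str, float] = {}
        for refs, sign in [(r.getListOfReactants(), -1.0), (r.getListOfProducts(), 1.0)]:
            for ref in refs:
                sp = ref.getSpecies()
                if sp not in declared:
                    raise NetworkError(
                        f"reaction {r.getId()} references undeclared species {sp!r}"
                    )
                stoich[sp] = stoich.get(sp, 0.0) + sign * ref.getStoichiometry()
        kl = r.getKineticLaw()
        lb, ub = 0.0, math.inf
        if kl is not None:
            if kl.getLocalParameter("LOWER_BOUND") is not None:
                lb = kl.getLocalParameter("LOWER_BOUND").getValue()
            if kl.getLocalParameter("UPPER_BOUND") is not None:
                ub = kl.getLocalParameter("UPPER_BOUND").getValue()
            oc = kl.getLocalParameter("OBJECTIVE_COEFFICIENT")
            if oc is not None and oc.getValue() != 0.0:
                objective[r.getId()] = oc.getValue()
        reactions.append(Reaction(r.getId(), stoich, lb, ub))
    cost = model.getParameter("biomass_cost")
    return StoichNetwork(
        species=species,
        boundary_species=boundary,
        reactions=reactions,
        objective_weights=objective,
        biomass_cost=cost.getValue() if cost is not None else 1.0,
    )
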