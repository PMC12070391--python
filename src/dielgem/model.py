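"""In-memory constraint-based model containers.

These are deliberately plain dataclasses rather than a wrapper around a
solver object: the diel transformation is a structural rewrite (duplicate,
add, re-bound), and keeping the model as inert data makes every step a pure
function that is trivial to diff, serialize, and property-test. Conversion
to a solver-backed :class:`cobra.Model` happens only at simulation time
(see :mod:`dielgem.interop`).

Sign convention for stoichiometry: negative coefficient = consumed,
positive = produced. Flux bounds are in the conventional GEM units of
mmol·gDW⁻¹·h⁻¹.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional


@dataclass
class Compartment:
    id: str
    name: str = ""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment_id: str = ""
    formula: Optional[str] = None


@dataclass
class Reaction:
    """A reaction: stoichiometry map plus flux bounds.

    ``gpr`` is an opaque boolean gene rule (never interpreted here);
    ``pathway`` is the subsystem label consumed by pathway enrichment.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: Optional[str] = None
    pathway: Optional[str] = None

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            pathway=self.pathway,
        )


@dataclass
class LinearConstraint:
    """An extra linear coupling constraint over reaction fluxes.

    ``lower <= sum(coefficients[r] * v_r) <= upper``. Used by the diel
    pipeline to pin the day:night nitrate-uptake proportion p:q as
    ``q·v_day − p·v_night = 0`` without fixing the absolute uptake.
    """

    id: str
    coefficients: Dict[str, float] = field(default_factory=dict)
    lower: float = 0.0
    upper: float = 0.0


@dataclass
class MetabolicModel:
    id: str
    compartments: List[Compartment] = field(default_factory=list)
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)
    constraints: List[LinearConstraint] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def compartment_ids(self) -> List[str]:
        return [c.id for c in self.compartments]

    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r} in model {self.id!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite with id {mid!r} in model {self.id!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=[Compartment(c.id, c.name) for c in self.compartments],
            metabolites=[
                Metabolite(m.id, m.name, m.compartment_id, m.formula)
                for m in self.metabolites
            ],
            reactions=[r.copy() for r in self.reactions],
            objective=dict(self.objective),
            constraints=[
                LinearConstraint(c.id, dict(c.coefficients), c.lower, c.upper)
                for c in self.constraints
            ],
        )


def validate_model(model: MetabolicModel) -> List[str]:
    """Check every structural invariant; return human-readable violations.

    Total function: never raises on well-typed input. An empty list means
    the model is internally consistent (unique ids, no dangling references,
    ordered bounds, non-empty stoichiometries).
    """
    violations: List[str] = []

    def _dups(ids: List[str], kind: str) -> None:
        seen = set()
        for i in ids:
            if i in seen:
                violations.append(f"duplicate {kind} id {i!r}")
            seen.add(i)

    comp_ids = model.compartment_ids()
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    _dups(comp_ids, "compartment")
    _dups(met_ids, "metabolite")
    _dups(rxn_ids, "reaction")
    comp_set, met_set, rxn_set = set(comp_ids), set(met_ids), set(rxn_ids)

    for m in model.metabolites:
        if m.compartment_id not in comp_set:
            violations.append(
                f"metabolite {m.id!r} references unknown compartment "
                f"{m.compartment_id!r}"
            )

    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            violations.append(
                f"reaction {r.id!r} has lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        if not r.stoichiometry:
            violations.append(f"reaction {r.id!r} has empty stoichiometry")
        for mid in r.stoichiometry:
            if mid not in met_set:
                violations.append(
                    f"reaction {r.id!r} references unknown metabolite {mid!r}"
                )

    for rid in model.objective:
        if rid not in rxn_set:
            violations.append(f"objective references unknown reaction {rid!r}")

    for c in model.constraints:
        if c.lower > c.upper:
            violations.append(
                f"constraint {c.id!r} has lower {c.lower} > upper {c.upper}"
            )
        for rid in c.coefficients:
            if rid not in rxn_set:
                violations.append(
                    f"constraint {c.id!r} references unknown reaction {rid!r}"
                )

    return violations


# -- JSON debugging export -------------------------------------------------

def model_to_json(model: MetabolicModel) -> str:
    return json.dumps(asdict(model), indent=1, sort_keys=True)


def model_from_json(text: str) -> MetabolicModel:
    d = json.loads(text)
    return MetabolicModel(
        id=d["id"],
        compartments=[Compartment(**c) for c in d["compartments"]],
        metabolites=[Metabolite(**m) for m in d["metabolites"]],
        reactions=[Reaction(**r) for r in d["reactions"]],
        objective={k: float(v) for k, v in d["objective"].items()},
        constraints=[LinearConstraint(**c) for c in d["constraints"]],
    )
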