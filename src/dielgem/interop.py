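"""Conversion between :class:`dielgem.model.MetabolicModel` and cobra.

All LP machinery (FBA, pFBA, flux sampling) runs on a solver-backed
``cobra.Model`` built here; extra linear coupling constraints are attached
to the optlang problem so every downstream solve and sampler respects them.
"""

from __future__ import annotations

from typing import Optional

import cobra

from .errors import ModelValidationError
from .model import (
    Compartment,
    LinearConstraint,
    MetabolicModel,
    Metabolite,
    Reaction,
    validate_model,
)

PATHWAY_NOTE_KEY = "SUBSYSTEM"


def to_cobra(model: MetabolicModel, validate: bool = True) -> cobra.Model:
    """Build a solver-backed cobra model, including coupling constraints."""
    if validate:
        violations = validate_model(model)
        if violations:
            raise ModelValidationError(violations)

    cm = cobra.Model(model.id)
    cm.compartments = {c.id: c.name for c in model.compartments}

    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment_id, formula=m.formula
        )
        mets[m.id] = cmet

    rxns = []
    for r in model.reactions:
        crxn = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        rxns.append(crxn)
    cm.add_reactions(rxns)
    for r, crxn in zip(model.reactions, rxns):
        crxn.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gpr:
            crxn.gene_reaction_rule = r.gpr
        if r.pathway is not None:
            crxn.notes[PATHWAY_NOTE_KEY] = r.pathway

    for rid, weight in model.objective.items():
        cm.reactions.get_by_id(rid).objective_coefficient = weight
    cm.objective_direction = "max"

    for con in model.constraints:
        expr = sum(
            coef * cm.reactions.get_by_id(rid).flux_expression
            for rid, coef in con.coefficients.items()
        )
        cm.add_cons_vars(
            cm.problem.Constraint(expr, lb=con.lower, ub=con.upper, name=con.id)
        )

    return cm


def from_cobra(cm: cobra.Model, model_id: Optional[str] = None) -> MetabolicModel:
    """Extract the structural content of a cobra model.

    Pathway labels are taken from the reaction notes key ``SUBSYSTEM`` (the
    convention this package writes), falling back to ``reaction.subsystem``
    when set by another reader. Extra optlang constraints are *not*
    recovered here — SBML persistence of those goes through the annotation
    block handled in :mod:`dielgem.sbml`.
    """
    model = MetabolicModel(id=model_id or cm.id or "model")
    comp_items = list(cm.compartments.items())
    # metabolites may live in compartments cobra never registered explicitly
    known = {cid for cid, _ in comp_items}
    for met in cm.metabolites:
        if met.compartment and met.compartment not in known:
            comp_items.append((met.compartment, ""))
            known.add(met.compartment)
    model.compartments = [Compartment(cid, name or "") for cid, name in comp_items]

    for met in cm.metabolites:
        model.metabolites.append(
            Metabolite(
                id=met.id,
                name=met.name or "",
                compartment_id=met.compartment or "",
                formula=met.formula or None,
            )
        )

    objective = {}
    for rxn in cm.reactions:
        pathway = rxn.notes.get(PATHWAY_NOTE_KEY)
        if pathway is None and getattr(rxn, "subsystem", None):
            pathway = rxn.subsystem or None
        model.reactions.append(
            Reaction(
                id=rxn.id,
                name=rxn.name or "",
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=rxn.gene_reaction_rule or None,
                pathway=pathway,
            )
        )
        if rxn.objective_coefficient:
            objective[rxn.id] = float(rxn.objective_coefficient)
    model.objective = objective
    return model
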