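"""SBML Level 3 + FBC v2 read/write.

cobra's battle-tested SBML writer/reader is the backbone. Two things are
layered on top:

* pathway labels ride in reaction notes under the key ``SUBSYSTEM:`` (a
  convention many published pGEMs use), falling back to SBML groups when a
  third-party file provides them via cobra;
* SBML FBC has no native cross-reaction linear constraint, so the coupling
  constraints (e.g. the day:night nitrate ratio) are serialized into a
  namespaced model-level annotation block and re-hydrated on read. This
  keeps a diel model a single self-describing file.

Annotation schema (namespace ``https://dielgem.dev/constraints/v1``)::

    <dg:linearConstraints xmlns:dg="...">
      <dg:constraint id="..." lower="0" upper="0">
        <dg:term reaction="EX_NO3_Day" coefficient="2"/>
        ...
      </dg:constraint>
    </dg:linearConstraints>

Reaction ids inside the annotation are package-level ids (without the SBML
``R_`` prefix cobra adds on write).
"""

from __future__ import annotations

from typing import List

import libsbml
import cobra
import cobra.io

from .errors import ModelValidationError, SBMLError
from .interop import from_cobra, to_cobra
from .model import LinearConstraint, MetabolicModel, validate_model

CONSTRAINT_NS = "https://dielgem.dev/constraints/v1"
CONSTRAINT_PREFIX = "dg"


# ---------------------------------------------------------------------------
# annotation block
# ---------------------------------------------------------------------------

def _constraints_to_annotation(constraints: List[LinearConstraint]) -> str:
    parts = [
        f'<{CONSTRAINT_PREFIX}:linearConstraints '
        f'xmlns:{CONSTRAINT_PREFIX}="{CONSTRAINT_NS}">'
    ]
    for c in constraints:
        parts.append(
            f'<{CONSTRAINT_PREFIX}:constraint id="{c.id}" '
            f'lower="{c.lower!r}" upper="{c.upper!r}">'
        )
        for rid, coef in c.coefficients.items():
            parts.append(
                f'<{CONSTRAINT_PREFIX}:term reaction="{rid}" '
                f'coefficient="{coef!r}"/>'
            )
        parts.append(f"</{CONSTRAINT_PREFIX}:constraint>")
    parts.append(f"</{CONSTRAINT_PREFIX}:linearConstraints>")
    return "".join(parts)


def _annotation_to_constraints(sbml_model: libsbml.Model) -> List[LinearConstraint]:
    node = sbml_model.getAnnotation()
    if node is None:
        return []
    constraints: List[LinearConstraint] = []
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getName() != "linearConstraints" or child.getURI() != CONSTRAINT_NS:
            continue
        for j in range(child.getNumChildren()):
            cnode = child.getChild(j)
            if cnode.getName() != "constraint":
                continue
            attrs = cnode.getAttributes()
            con = LinearConstraint(
                id=attrs.getValue("id"),
                lower=float(attrs.getValue("lower")),
                upper=float(attrs.getValue("upper")),
            )
            for k in range(cnode.getNumChildren()):
                term = cnode.getChild(k)
                if term.getName() != "term":
                    continue
                tattrs = term.getAttributes()
                con.coefficients[tattrs.getValue("reaction")] = float(
                    tattrs.getValue("coefficient")
                )
            constraints.append(con)
    return constraints


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize as SBML L3V1 + FBC v2; raises on invariant violations."""
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    cm = to_cobra(model, validate=False)
    try:
        cobra.io.write_sbml_model(cm, path)
    except OSError as exc:
        raise SBMLError(f"cannot write SBML to {path!r}: {exc}") from exc

    if model.constraints:
        doc = libsbml.readSBMLFromFile(path)
        smodel = doc.getModel()
        status = smodel.appendAnnotation(
            _constraints_to_annotation(model.constraints)
        )
        if status != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise SBMLError(
                f"failed to attach constraint annotation (libsbml code {status})"
            )
        libsbml.writeSBMLToFile(doc, path)


def read_sbml(path: str) -> MetabolicModel:
    """Parse an SBML L3 FBC file into a :class:`MetabolicModel`.

    Raises :class:`SBMLError` on malformed SBML (naming the offending
    element), on files lacking FBC flux bounds, and on structurally broken
    models (e.g. a reaction referencing an undeclared species).
    """
    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLError(
                f"malformed SBML in {path!r} (line {err.getLine()}): "
                f"{err.getMessage().strip()}"
            )
    smodel = doc.getModel()
    if smodel is None:
        raise SBMLError(f"{path!r} contains no SBML model element")
    if smodel.getPlugin("fbc") is None:
        raise SBMLError(
            f"{path!r} has no FBC package: flux bounds and an objective are "
            "required (SBML Level 3 with fbc v2)"
        )
    # undeclared species references are not an XML error; catch them here so
    # the message names the offending reaction instead of a reader traceback
    declared = {smodel.getSpecies(i).getId() for i in range(smodel.getNumSpecies())}
    for i in range(smodel.getNumReactions()):
        rxn = smodel.getReaction(i)
        refs = [rxn.getReactant(j) for j in range(rxn.getNumReactants())]
        refs += [rxn.getProduct(j) for j in range(rxn.getNumProducts())]
        for ref in refs:
            if ref.getSpecies() not in declared:
                raise SBMLError(
                    f"reaction {rxn.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
    constraints = _annotation_to_constraints(smodel)

    try:
        cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises CobraSBMLError or plain errors
        raise SBMLError(f"failed to parse {path!r}: {exc}") from exc

    model = from_cobra(cm)
    model.constraints = constraints
    violations = validate_model(model)
    if violations:
        raise SBMLError(
            f"{path!r} parsed but is inconsistent:\n  " + "\n  ".join(violations)
        )
    return model
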