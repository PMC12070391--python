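"""FBA solving and the diel validation quantities.

Flux balance analysis maximizes the model objective over
{v : S·v = 0, lb ≤ v ≤ ub, coupling constraints}. By default a parsimonious
second stage minimizes total absolute flux at the fixed optimum so reported
flux directions are not an artefact of LP degeneracy.

Validation quantities:

* quantum yield — RuBisCO carboxylation flux divided by photon uptake flux
  (mol CO₂ fixed per mol photons absorbed);
* storage-pool report — signed day↔pool and pool↔night exchange fluxes per
  stored metabolite, classified day_to_night / night_to_day / inactive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import cobra.flux_analysis

from .errors import SimulationError
from .interop import to_cobra
from .model import MetabolicModel

FLUX_TOL = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxDistribution:
    """Reaction-id → flux map from one LP solve (mmol·gDW⁻¹·h⁻¹)."""

    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: float = math.nan
    status: str = INFEASIBLE

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


def solve_fba(
    model: MetabolicModel, minimize_total_flux: bool = True
) -> FluxDistribution:
    """Solve FBA (parsimonious by default) and report status faithfully."""
    if not model.objective:
        raise SimulationError("model has an empty objective; nothing to maximize")
    cm = to_cobra(model)
    solution = cm.optimize(raise_error=False)
    if solution.status != "optimal":
        status = UNBOUNDED if "unbounded" in str(solution.status) else INFEASIBLE
        return FluxDistribution(status=status)

    if minimize_total_flux:
        solution = cobra.flux_analysis.pfba(cm)
    fluxes = {rid: float(solution.fluxes[rid]) for rid in model.reaction_ids()}
    objective_value = sum(w * fluxes[rid] for rid, w in model.objective.items())
    return FluxDistribution(fluxes=fluxes, objective_value=objective_value,
                            status=OPTIMAL)


def quantum_yield(
    flux: FluxDistribution,
    rubisco_carboxylation_id: str,
    photon_uptake_id: str,
) -> float:
    """Mol CO₂ fixed per mol photons: v_rubisco / |v_photon|.

    The photon flux enters by magnitude so the result is orientation-
    independent (an export-positive photon exchange carries uptake as
    negative flux). For diel models pass the day-phase reaction ids.
    """
    if flux.status != OPTIMAL:
        raise SimulationError(
            f"quantum yield needs an optimal flux distribution (status={flux.status})"
        )
    try:
        v_rubisco = flux[rubisco_carboxylation_id]
        v_photon = flux[photon_uptake_id]
    except KeyError as exc:
        raise SimulationError(f"reaction {exc.args[0]!r} not in flux distribution")
    if abs(v_photon) <= FLUX_TOL:
        raise SimulationError(
            f"photon uptake flux is ~0 ({v_photon:g}); quantum yield undefined"
        )
    return v_rubisco / abs(v_photon)


# ---------------------------------------------------------------------------
# storage pool report
# ---------------------------------------------------------------------------

DAY_TO_NIGHT = "day_to_night"
NIGHT_TO_DAY = "night_to_day"
INACTIVE = "inactive"


@dataclass
class StorageEntry:
    metabolite_id: str
    day_to_pool_flux: float
    pool_to_night_flux: float
    net_direction: str


@dataclass
class StoragePoolReport:
    entries: Dict[str, StorageEntry] = field(default_factory=dict)

    def direction(self, met_id: str) -> str:
        return self.entries[met_id].net_direction


def storage_pool_report(
    model: MetabolicModel,
    flux: FluxDistribution,
    day_suffix: str = "_Day",
    night_suffix: str = "_Night",
    tol: float = FLUX_TOL,
) -> StoragePoolReport:
    """Classify the direction each stored metabolite crosses the pool.

    Relies on the pipeline's naming scheme: pool compartments start with
    ``sp``, pool species end in ``_sp``, and each pool species is touched
    by exactly two exchange reactions (``SP_<met>_Day``, ``SP_<met>_Night``).
    Positive day flux deposits into the pool; positive night flux withdraws
    into the night phase; at steady state the two are equal, so the common
    sign gives the net direction.
    """
    if flux.status != OPTIMAL:
        raise SimulationError("storage report needs an optimal flux distribution")

    pool_compartments = {
        c.id for c in model.compartments if c.id == "sp" or c.id.startswith("sp_")
    }
    if not pool_compartments:
        raise SimulationError(
            "model has no storage pool compartment; run the diel pipeline first"
        )
    pool_mets = {
        m.id for m in model.metabolites if m.compartment_id in pool_compartments
    }

    report = StoragePoolReport()
    for pm_id in sorted(pool_mets):
        met_id = pm_id[:-3] if pm_id.endswith("_sp") else pm_id
        touching = [r for r in model.reactions if pm_id in r.stoichiometry]
        day_rxn = night_rxn = None
        for r in touching:
            others = [mid for mid in r.stoichiometry if mid != pm_id]
            if any(o.endswith(day_suffix) for o in others):
                day_rxn = r
            elif any(o.endswith(night_suffix) for o in others):
                night_rxn = r
        if day_rxn is None or night_rxn is None:
            raise SimulationError(
                f"pool species {pm_id!r} lacks a day or night exchange reaction"
            )
        # deposit-positive: flux times the pool species' coefficient
        day_to_pool = flux[day_rxn.id] * day_rxn.stoichiometry[pm_id]
        pool_to_night = flux[night_rxn.id] * (-night_rxn.stoichiometry[pm_id])
        if abs(day_to_pool) <= tol and abs(pool_to_night) <= tol:
            direction = INACTIVE
        elif day_to_pool > tol:
            direction = DAY_TO_NIGHT
        else:
            direction = NIGHT_TO_DAY
        report.entries[met_id] = StorageEntry(
            metabolite_id=met_id,
            day_to_pool_flux=day_to_pool,
            pool_to_night_flux=pool_to_night,
            net_direction=direction,
        )
    return report
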