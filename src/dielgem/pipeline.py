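"""The five-step diel transformation.

A non-diel plant GEM is rewritten into a day/night model in a fixed order:

1. duplicate every compartment, metabolite and reaction into a day copy and
   a night copy (suffixing ids and display names);
2. build a storage-pool compartment (one per tissue for multi-tissue
   models) with reversible exchange reactions that let the listed
   metabolites cross between phases;
3. block photon uptake at night (both bounds to zero);
4. optionally pin the day:night nitrate-uptake proportion p:q via a linear
   coupling constraint q·v_day − p·v_night = 0 (default 3:2);
5. optionally merge the phase biomass reactions into a single total-biomass
   objective, zeroing the individual phase copies.

Every step is a pure function: it copies its input model, never mutates it,
and never deletes an entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import ModelValidationError, PipelineError
from .model import (
    Compartment,
    LinearConstraint,
    MetabolicModel,
    Metabolite,
    Reaction,
    validate_model,
)

logger = logging.getLogger(__name__)

DEFAULT_RATIO: Tuple[float, float] = (3.0, 2.0)


@dataclass
class PipelineConfig:
    """Every user choice the pipeline consumes.

    ``ratio`` is the (p, q) day:night nitrate-uptake proportion; ``None``
    skips step 4 entirely. ``tissue_names`` empty means a generic
    (single-tissue) model. ``tissue_storage`` may map a tissue name to an
    explicit metabolite-id list, overriding substring matching.
    ``biomass_weights`` are the (day, night) shares of one unit of total
    biomass and must sum to 1.
    """

    photon_reaction_ids: List[str] = field(default_factory=list)
    nitrate_reaction_ids: List[str] = field(default_factory=list)
    biomass_reaction_ids: List[str] = field(default_factory=list)
    storage_metabolite_ids: List[str] = field(default_factory=list)
    tissue_names: List[str] = field(default_factory=list)
    tissue_storage: Dict[str, List[str]] = field(default_factory=dict)
    day_suffix: str = "_Day"
    night_suffix: str = "_Night"
    ratio: Optional[Tuple[float, float]] = DEFAULT_RATIO
    merge_biomass: bool = True
    biomass_weights: Tuple[float, float] = (0.5, 0.5)
    storage_bound: float = 1000.0

    def validate(self) -> None:
        if not self.day_suffix or not self.night_suffix:
            raise PipelineError("phase suffixes must be non-empty")
        if self.day_suffix == self.night_suffix:
            raise PipelineError("day and night suffixes must differ")
        if not self.photon_reaction_ids:
            raise PipelineError(
                "at least one photon uptake reaction id is required "
                "(a plant GEM must photosynthesize)"
            )
        if self.ratio is not None:
            p, q = self.ratio
            if p <= 0 or q <= 0:
                raise PipelineError(
                    f"nitrate ratio components must be positive, got {self.ratio}"
                )
        wd, wn = self.biomass_weights
        if abs(wd + wn - 1.0) > 1e-9:
            raise PipelineError(
                f"biomass weights must sum to 1, got {self.biomass_weights}"
            )


@dataclass
class PhaseMap:
    """Correspondence between original ids and their day/night copies.

    Keys span all three id spaces (compartments, metabolites, reactions);
    per-kind views are kept so downstream consumers (DFA pairing, storage
    pool construction) need not guess what an id denotes.
    """

    original_to_day: Dict[str, str] = field(default_factory=dict)
    original_to_night: Dict[str, str] = field(default_factory=dict)
    compartment_ids: List[str] = field(default_factory=list)
    metabolite_ids: List[str] = field(default_factory=list)
    reaction_ids: List[str] = field(default_factory=list)

    def reaction_pairs(self) -> List[Tuple[str, str, str]]:
        """(original, day copy, night copy) for every original reaction."""
        return [
            (rid, self.original_to_day[rid], self.original_to_night[rid])
            for rid in self.reaction_ids
        ]


# ---------------------------------------------------------------------------
# step 1 — phase duplication
# ---------------------------------------------------------------------------

def duplicate_phases(
    model: MetabolicModel, config: PipelineConfig
) -> Tuple[MetabolicModel, PhaseMap]:
    """Duplicate every compartment, metabolite and reaction into two phases.

    Ids and display names both receive the phase suffix; stoichiometry,
    bounds, gene rules and pathway labels are copied verbatim with internal
    references rewritten to the same phase. The objective becomes the two
    phase copies of the original objective reactions at the original
    weights. Running this on an already-duplicated model raises (suffix
    collision) rather than silently quadrupling.
    """
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    if not model.reactions:
        raise PipelineError("cannot duplicate an empty model")

    suffixes = (config.day_suffix, config.night_suffix)
    all_ids = (
        model.compartment_ids() + model.metabolite_ids() + model.reaction_ids()
    )
    for entity_id in all_ids:
        for suf in suffixes:
            if entity_id.endswith(suf):
                raise PipelineError(
                    f"id {entity_id!r} already carries the phase suffix "
                    f"{suf!r}; the model appears to be diel already"
                )

    out = MetabolicModel(id=model.id + "_diel")
    pm = PhaseMap(
        compartment_ids=model.compartment_ids(),
        metabolite_ids=model.metabolite_ids(),
        reaction_ids=model.reaction_ids(),
    )

    def _suffix_name(name: str, suf: str) -> str:
        return (name + suf) if name else name

    for suf, mapping in (
        (config.day_suffix, pm.original_to_day),
        (config.night_suffix, pm.original_to_night),
    ):
        for c in model.compartments:
            out.compartments.append(Compartment(c.id + suf, _suffix_name(c.name, suf)))
            mapping[c.id] = c.id + suf
        for m in model.metabolites:
            out.metabolites.append(
                Metabolite(
                    id=m.id + suf,
                    name=_suffix_name(m.name, suf),
                    compartment_id=m.compartment_id + suf,
                    formula=m.formula,
                )
            )
            mapping[m.id] = m.id + suf
        for r in model.reactions:
            out.reactions.append(
                Reaction(
                    id=r.id + suf,
                    name=_suffix_name(r.name, suf),
                    stoichiometry={
                        mid + suf: coef for mid, coef in r.stoichiometry.items()
                    },
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    gpr=r.gpr,
                    pathway=r.pathway,
                )
            )
            mapping[r.id] = r.id + suf

    for rid, weight in model.objective.items():
        out.objective[pm.original_to_day[rid]] = weight
        out.objective[pm.original_to_night[rid]] = weight

    return out, pm


def infer_phase_map(
    model: MetabolicModel,
    day_suffix: str = "_Day",
    night_suffix: str = "_Night",
) -> PhaseMap:
    """Reconstruct the phase correspondence of an already-diel model.

    Pairs every id ``X<day_suffix>`` with ``X<night_suffix>`` across the
    three id spaces. Lets DFA and reporting run on a diel model loaded from
    file, where the original :class:`PhaseMap` is no longer in memory.
    Storage-pool exchange reactions (``SP_…``) carry the phase suffixes but
    are pool crossings, not phase copies of an original reaction, and are
    skipped.
    """
    pm = PhaseMap()
    spaces = (
        (model.compartment_ids(), pm.compartment_ids),
        (model.metabolite_ids(), pm.metabolite_ids),
        (model.reaction_ids(), pm.reaction_ids),
    )
    for ids, record in spaces:
        idset = set(ids)
        for i in ids:
            if record is pm.reaction_ids and i.startswith("SP_"):
                continue
            if i.endswith(day_suffix):
                orig = i[: -len(day_suffix)]
                night = orig + night_suffix
                if night in idset:
                    record.append(orig)
                    pm.original_to_day[orig] = i
                    pm.original_to_night[orig] = night
    if not pm.reaction_ids:
        raise PipelineError(
            f"no reaction pairs found with suffixes {day_suffix!r}/"
            f"{night_suffix!r}; is this a diel model?"
        )
    return pm


# ---------------------------------------------------------------------------
# step 2 — storage pool
# ---------------------------------------------------------------------------

def _pool_metabolite_id(met_id: str) -> str:
    return f"{met_id}_sp"


def storage_exchange_ids(met_id: str) -> Tuple[str, str]:
    """Deterministic ids of the two phase↔pool exchange reactions."""
    return f"SP_{met_id}_Day", f"SP_{met_id}_Night"


def _match_tissue(tissue: str, met: Metabolite) -> bool:
    t = tissue.lower()
    return t in met.id.lower() or t in met.compartment_id.lower()


def create_storage_pool(
    model: MetabolicModel, phase_map: PhaseMap, config: PipelineConfig
) -> MetabolicModel:
    """Add the storage-pool compartment(s) and phase↔pool exchanges.

    For each stored metabolite X a pool species ``X_sp`` is created with
    two reversible reactions: ``SP_X_Day`` (positive flux deposits the day
    copy into the pool) and ``SP_X_Night`` (positive flux withdraws from
    the pool into the night copy). Multi-tissue models get one pool
    compartment per tissue; metabolites are assigned to tissues by
    case-insensitive substring of their id or compartment id unless
    ``config.tissue_storage`` lists them explicitly.
    """
    unknown = [
        mid for mid in config.storage_metabolite_ids
        if mid not in phase_map.original_to_day
        or mid not in set(phase_map.metabolite_ids)
    ]
    if unknown:
        raise PipelineError(
            "storage metabolite ids not present in the original model: "
            + ", ".join(sorted(unknown))
        )

    out = model.copy()
    bound = config.storage_bound

    if config.tissue_names:
        assignment: Dict[str, List[str]] = {}
        originals = {m.id: m for m in _original_metabolites(model, phase_map, config)}
        for tissue in config.tissue_names:
            if tissue in config.tissue_storage:
                mets = list(config.tissue_storage[tissue])
                missing = [m for m in mets if m not in originals]
                if missing:
                    raise PipelineError(
                        f"tissue {tissue!r} storage list names unknown "
                        f"metabolites: {', '.join(missing)}"
                    )
            else:
                mets = [
                    mid for mid in config.storage_metabolite_ids
                    if _match_tissue(tissue, originals[mid])
                ]
            if not mets:
                raise PipelineError(
                    f"tissue {tissue!r} matches no storage metabolite; "
                    "check tissue names or provide an explicit list"
                )
            assignment[tissue] = mets
        groups = [
            (f"sp_{tissue.lower()}", f"Storage pool ({tissue})", mets)
            for tissue, mets in assignment.items()
        ]
    else:
        groups = [("sp", "Storage pool", list(config.storage_metabolite_ids))]

    for comp_id, comp_name, met_ids in groups:
        out.compartments.append(Compartment(comp_id, comp_name))
        for mid in met_ids:
            pool_id = _pool_metabolite_id(mid)
            day_id = phase_map.original_to_day[mid]
            night_id = phase_map.original_to_night[mid]
            out.metabolites.append(
                Metabolite(
                    id=pool_id,
                    name=f"{mid} (storage pool)",
                    compartment_id=comp_id,
                )
            )
            sp_day, sp_night = storage_exchange_ids(mid)
            out.reactions.append(
                Reaction(
                    id=sp_day,
                    name=f"Storage exchange {mid} day",
                    stoichiometry={day_id: -1.0, pool_id: 1.0},
                    lower_bound=-bound,
                    upper_bound=bound,
                )
            )
            out.reactions.append(
                Reaction(
                    id=sp_night,
                    name=f"Storage exchange {mid} night",
                    stoichiometry={pool_id: -1.0, night_id: 1.0},
                    lower_bound=-bound,
                    upper_bound=bound,
                )
            )
    return out


def _original_metabolites(model, phase_map, config):
    """Reconstruct pre-duplication metabolite records (id + compartment)."""
    day_suffix = config.day_suffix
    mets = []
    day_ids = {phase_map.original_to_day[m]: m for m in phase_map.metabolite_ids}
    for m in model.metabolites:
        if m.id in day_ids:
            orig = day_ids[m.id]
            comp = m.compartment_id
            if comp.endswith(day_suffix):
                comp = comp[: -len(day_suffix)]
            mets.append(Metabolite(id=orig, compartment_id=comp))
    return mets


# ---------------------------------------------------------------------------
# step 3 — night photon blocking
# ---------------------------------------------------------------------------

def block_night_photon_uptake(
    model: MetabolicModel, phase_map: PhaseMap, config: PipelineConfig
) -> MetabolicModel:
    """Set both bounds of every night-phase photon uptake reaction to zero."""
    out = model.copy()
    for pid in config.photon_reaction_ids:
        night_id = phase_map.original_to_night.get(pid)
        if night_id is None or not out.has_reaction(night_id):
            raise PipelineError(
                f"photon reaction {pid!r} has no night-phase copy in the model"
            )
        rxn = out.get_reaction(night_id)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# step 4 — nitrate day:night ratio (optional)
# ---------------------------------------------------------------------------

def apply_nitrate_ratio(
    model: MetabolicModel, phase_map: PhaseMap, config: PipelineConfig
) -> MetabolicModel:
    """Couple day and night nitrate uptake as v_day : v_night = p : q.

    Encoded as the equality q·v_day − p·v_night = 0, which pins only the
    proportion and leaves the absolute uptake free. Skipped when
    ``config.ratio`` is None. Each nitrate reaction must be oriented
    uptake-positive (upper bound > 0); export-oriented reactions raise.
    """
    if config.ratio is None:
        return model
    p, q = config.ratio
    if p <= 0 or q <= 0:
        raise PipelineError(f"ratio components must be positive, got {config.ratio}")

    out = model.copy()
    for nid in config.nitrate_reaction_ids:
        day_id = phase_map.original_to_day.get(nid)
        night_id = phase_map.original_to_night.get(nid)
        if day_id is None or night_id is None:
            raise PipelineError(
                f"nitrate reaction {nid!r} has no phase copies in the model"
            )
        for rid in (day_id, night_id):
            if not out.has_reaction(rid):
                raise PipelineError(f"nitrate phase copy {rid!r} missing from model")
        if out.get_reaction(day_id).upper_bound <= 0:
            raise PipelineError(
                f"nitrate reaction {nid!r} is oriented as export "
                "(upper bound <= 0); re-orient it so positive flux is uptake"
            )
        out.constraints.append(
            LinearConstraint(
                id=f"nitrate_ratio_{nid}",
                coefficients={day_id: q, night_id: -p},
                lower=0.0,
                upper=0.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# step 5 — biomass merging (optional)
# ---------------------------------------------------------------------------

def total_biomass_id(biomass_id: str) -> str:
    return f"{biomass_id}_total"


def merge_biomass(
    model: MetabolicModel, phase_map: PhaseMap, config: PipelineConfig
) -> MetabolicModel:
    """Create total-biomass reaction(s) and zero the phase copies.

    The total reaction consumes w_day of the day copy's precursors plus
    w_night of the night copy's (coefficient-wise weighted sum); both
    individual phase biomass reactions get bounds (0, 0); the objective is
    reset to weight 1 on the total reaction(s) only.
    """
    if not config.biomass_reaction_ids:
        raise PipelineError("biomass merge requested but no biomass ids given")
    wd, wn = config.biomass_weights

    out = model.copy()
    out.objective = {}
    for bid in config.biomass_reaction_ids:
        day_id = phase_map.original_to_day.get(bid)
        night_id = phase_map.original_to_night.get(bid)
        if day_id is None or night_id is None:
            raise PipelineError(
                f"biomass reaction {bid!r} has no phase copies in the model"
            )
        day_rxn = out.get_reaction(day_id)
        night_rxn = out.get_reaction(night_id)

        stoich: Dict[str, float] = {}
        for mid, coef in day_rxn.stoichiometry.items():
            stoich[mid] = stoich.get(mid, 0.0) + wd * coef
        for mid, coef in night_rxn.stoichiometry.items():
            stoich[mid] = stoich.get(mid, 0.0) + wn * coef

        total_id = total_biomass_id(bid)
        if out.has_reaction(total_id):
            raise PipelineError(f"total biomass id {total_id!r} already exists")
        out.reactions.append(
            Reaction(
                id=total_id,
                name=f"Total biomass ({bid})",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=max(day_rxn.upper_bound, night_rxn.upper_bound),
            )
        )
        day_rxn.lower_bound = day_rxn.upper_bound = 0.0
        night_rxn.lower_bound = night_rxn.upper_bound = 0.0
        out.objective[total_id] = 1.0
    return out


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def run_pipeline(
    model: MetabolicModel, config: PipelineConfig
) -> Tuple[MetabolicModel, PhaseMap, Dict[str, Dict[str, int]]]:
    """Run steps 1→2→3→(4)→(5) and return (model, phase map, report).

    Step 4 runs only when a ratio is configured; step 5 only when
    ``merge_biomass`` is set and biomass ids are given (a model without a
    biomass reaction needs only four steps). The report maps step name to
    entity-count deltas.
    """
    config.validate()
    report: Dict[str, Dict[str, int]] = {}

    def _counts(m: MetabolicModel) -> Dict[str, int]:
        return {
            "compartments": len(m.compartments),
            "metabolites": len(m.metabolites),
            "reactions": len(m.reactions),
            "constraints": len(m.constraints),
        }

    def _log(step: str, before: Dict[str, int], m: MetabolicModel) -> None:
        after = _counts(m)
        delta = {k: after[k] - before[k] for k in after}
        report[step] = delta
        logger.info("step %s: %s", step, delta)

    def _run(step: str, fn, current: MetabolicModel, *args) -> MetabolicModel:
        before = _counts(current)
        try:
            result = fn(current, *args)
        except PipelineError as exc:
            raise PipelineError(f"[{step}] {exc}") from exc
        _log(step, before, result)
        return result

    before = _counts(model)
    try:
        diel, pm = duplicate_phases(model, config)
    except PipelineError as exc:
        raise PipelineError(f"[duplicate_phases] {exc}") from exc
    _log("duplicate_phases", before, diel)

    diel = _run("create_storage_pool", create_storage_pool, diel, pm, config)
    diel = _run(
        "block_night_photon_uptake", block_night_photon_uptake, diel, pm, config
    )
    if config.ratio is not None and config.nitrate_reaction_ids:
        diel = _run("apply_nitrate_ratio", apply_nitrate_ratio, diel, pm, config)
    if config.merge_biomass and config.biomass_reaction_ids:
        diel = _run("merge_biomass", merge_biomass, diel, pm, config)
    return diel, pm, report
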