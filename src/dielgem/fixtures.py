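"""Synthetic photoautotroph models for desk-scale testing and demos.

The generic toy GEM is a minimal but complete plant-like network: photon
uptake drives a light reaction producing NADPH, ATP and reduced ferredoxin;
carbon fixation (the RuBisCO carboxylation proxy) turns CO₂ into a sugar
unit; sucrose/starch interconversion, ferredoxin-dependent amino-acid
synthesis from nitrate, respiration, ATP maintenance and a biomass drain
close the network. Stoichiometry is chosen so that:

* the analytic quantum yield equals ``qy_target`` (one fixation event per
  ``1/qy_target`` photons, with nothing else competing for NADPH);
* after the diel transformation, night growth is only possible through the
  storage pool (no light → no NADPH → no fixation, and no reduced
  ferredoxin → no amino-acid synthesis at night), so storage-pool flux
  directions are forced by construction, not by solver luck;
* under the day:night nitrate ratio, night nitrate uptake exceeds night
  consumption (zero) and must cross the pool to the day phase.

The ferredoxin pool mimics light-dependent nitrogen assimilation without
competing with the Calvin cycle for NADPH; surplus reduced ferredoxin is
re-oxidized by a dedicated sink.

Fixture generation is deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isclose
from typing import Dict, List, Tuple

import numpy as np

from .dfa import SampleMatrix
from .errors import DielgemError
from .model import Compartment, MetabolicModel, Metabolite, Reaction
from .pipeline import PhaseMap, PipelineConfig

FILLER_PATHWAYS = (
    "glycolysis / gluconeogenesis",
    "steroid biosynthesis",
    "flavonoid biosynthesis",
)


@dataclass
class FixtureSpec:
    n_filler_reactions: int = 6
    include_starch_cycle: bool = True
    include_two_tissues: bool = False
    qy_target: float = 0.125
    seed: int = 7

    def validate(self) -> None:
        if not 0 < self.qy_target <= 1:
            raise DielgemError(f"qy_target must be in (0, 1], got {self.qy_target}")
        photons = 1.0 / self.qy_target
        if not isclose(photons, round(photons), abs_tol=1e-9):
            raise DielgemError(
                f"qy_target {self.qy_target} is unreachable: the light reaction "
                "uses an integer photon coefficient, so 1/qy_target must be an "
                "integer"
            )
        if self.n_filler_reactions < 0:
            raise DielgemError("n_filler_reactions must be non-negative")


def _tissue_network(
    model: MetabolicModel,
    suffix: str,
    photons_per_fix: int,
    photosynthetic: bool,
    include_starch_cycle: bool,
    n_filler: int,
) -> None:
    """Append one tissue's reactions/metabolites to ``model`` in place.

    ``suffix`` is "" for the generic model. Non-photosynthetic tissues get
    the same core but no light/fixation machinery and a photon uptake
    bounded to zero.
    """
    c, p = f"c{suffix}", f"p{suffix}"
    model.compartments += [
        Compartment(c, f"cytosol{suffix}"),
        Compartment(p, f"plastid{suffix}"),
    ]

    def met(mid, comp, name=""):
        model.metabolites.append(Metabolite(mid, name or mid, comp))
        return mid

    photon = met(f"Photon_c{suffix}", c, "photon")
    co2 = met(f"CO2_c{suffix}", c, "carbon dioxide")
    no3 = met(f"NO3_c{suffix}", c, "nitrate")
    h2o = met(f"H2O_c{suffix}", c, "water")
    pi = met(f"Pi_c{suffix}", c, "phosphate")
    atp = met(f"ATP_c{suffix}", c, "ATP")
    sugar = met(f"Sugar_c{suffix}", c, "sugar unit")
    sucrose = met(f"Sucrose_c{suffix}", c, "sucrose")
    aa = met(f"AA_c{suffix}", c, "amino acid")

    def rxn(rid, stoich, lb=0.0, ub=1000.0, pathway=None, name=""):
        model.reactions.append(
            Reaction(rid, name or rid, stoich, lb, ub, pathway=pathway)
        )

    rxn(f"EX_Photon{suffix}", {photon: 1.0},
        ub=1000.0 if photosynthetic else 0.0, name="photon uptake")
    rxn(f"EX_CO2{suffix}", {co2: 1.0}, lb=-1000.0, name="CO2 exchange")
    rxn(f"EX_NO3{suffix}", {no3: 1.0}, name="nitrate uptake")
    rxn(f"EX_Pi{suffix}", {pi: 1.0}, name="phosphate uptake")
    rxn(f"EX_H2O{suffix}", {h2o: -1.0}, name="water export")

    if photosynthetic:
        nadph = met(f"NADPH_c{suffix}", p, "NADPH")
        fdred = met(f"Fdred_c{suffix}", p, "reduced ferredoxin")
        rxn(
            f"Light{suffix}",
            {photon: -float(photons_per_fix), nadph: 2.0, atp: 3.0, fdred: 1.0},
            pathway="photosynthesis - light reactions",
            name="light reactions",
        )
        rxn(
            f"Fix{suffix}",
            {co2: -1.0, nadph: -2.0, atp: -3.0, sugar: 1.0, h2o: 1.0},
            pathway="carbon fixation",
            name="RuBisCO carboxylation",
        )
        rxn(f"FdOx{suffix}", {fdred: -1.0}, name="ferredoxin re-oxidation")
        rxn(
            f"AASynth{suffix}",
            {sugar: -1.0, no3: -1.0, atp: -1.0, fdred: -1.0, aa: 1.0},
            pathway="amino acid biosynthesis",
            name="ferredoxin-dependent amino acid synthesis",
        )
        if include_starch_cycle:
            starch = met(f"Starch_p{suffix}", p, "starch")
            rxn(
                f"StarchSynth{suffix}",
                {sugar: -1.0, atp: -1.0, starch: 1.0},
                pathway="starch and sucrose metabolism",
                name="starch synthesis",
            )
            rxn(
                f"StarchDeg{suffix}",
                {starch: -1.0, sugar: 1.0},
                pathway="starch and sucrose metabolism",
                name="starch degradation",
            )

    rxn(
        f"SucroseSynth{suffix}",
        {sugar: -1.0, sucrose: 1.0},
        lb=-1000.0,
        pathway="starch and sucrose metabolism",
        name="sucrose interconversion",
    )
    rxn(
        f"Resp{suffix}",
        {sugar: -1.0, atp: 4.0, co2: 1.0},
        pathway="glycolysis / gluconeogenesis",
        name="respiration",
    )
    rxn(f"ATPM{suffix}", {atp: -1.0}, lb=0.1, name="ATP maintenance")
    rxn(
        f"BIO{suffix}",
        {sugar: -1.0, aa: -0.5, atp: -2.0, pi: -0.1},
        name="biomass",
    )

    for i in range(n_filler):
        fm = met(f"Fm{i}_c{suffix}", c, f"filler metabolite {i}")
        rxn(
            f"Filler{i}{suffix}",
            {sugar: -1.0, fm: 1.0},
            lb=-1000.0,
            pathway=FILLER_PATHWAYS[i % len(FILLER_PATHWAYS)],
            name=f"filler reaction {i}",
        )


def make_toy_plant_gem(
    spec: FixtureSpec = FixtureSpec(),
) -> Tuple[MetabolicModel, PipelineConfig]:
    """Build the synthetic photoautotroph GEM plus its matched config."""
    spec.validate()
    photons_per_fix = round(1.0 / spec.qy_target)

    model = MetabolicModel(id="toy_plant_gem")
    if spec.include_two_tissues:
        _tissue_network(model, "_Leaf", photons_per_fix, True,
                        spec.include_starch_cycle, spec.n_filler_reactions)
        _tissue_network(model, "_Root", photons_per_fix, False,
                        False, 0)
        # inter-tissue transporters: leaf exports sucrose and amino acids,
        # root exports nitrate
        model.reactions += [
            Reaction("T_Sucrose", "sucrose transport leaf->root",
                     {"Sucrose_c_Leaf": -1.0, "Sucrose_c_Root": 1.0},
                     -1000.0, 1000.0),
            Reaction("T_AA", "amino acid transport leaf->root",
                     {"AA_c_Leaf": -1.0, "AA_c_Root": 1.0}, -1000.0, 1000.0),
            Reaction("T_NO3", "nitrate transport root->leaf",
                     {"NO3_c_Root": -1.0, "NO3_c_Leaf": 1.0}, -1000.0, 1000.0),
        ]
        model.objective = {"BIO_Leaf": 1.0, "BIO_Root": 1.0}
        storage = ["Sucrose_c_Leaf", "AA_c_Leaf", "NO3_c_Leaf",
                   "Sucrose_c_Root", "AA_c_Root", "NO3_c_Root"]
        if spec.include_starch_cycle:
            storage.insert(1, "Starch_p_Leaf")
        config = PipelineConfig(
            photon_reaction_ids=["EX_Photon_Leaf", "EX_Photon_Root"],
            nitrate_reaction_ids=["EX_NO3_Leaf", "EX_NO3_Root"],
            biomass_reaction_ids=["BIO_Leaf", "BIO_Root"],
            storage_metabolite_ids=storage,
            tissue_names=["Leaf", "Root"],
        )
    else:
        _tissue_network(model, "", photons_per_fix, True,
                        spec.include_starch_cycle, spec.n_filler_reactions)
        model.objective = {"BIO": 1.0}
        storage = ["Sucrose_c", "AA_c", "NO3_c"]
        if spec.include_starch_cycle:
            storage.insert(1, "Starch_p")
        config = PipelineConfig(
            photon_reaction_ids=["EX_Photon"],
            nitrate_reaction_ids=["EX_NO3"],
            biomass_reaction_ids=["BIO"],
            storage_metabolite_ids=storage,
        )
    return model, config


def make_null_sample_pairs(
    n_pairs: int,
    n_samples: int,
    seed: int,
    effect_size: float = 0.0,
    baseline: float = 10.0,
    sd: float = 1.0,
) -> Tuple[SampleMatrix, PhaseMap]:
    """Synthetic paired day/night sample rows for test calibration.

    Under the null (``effect_size = 0``) both rows of a pair are drawn from
    the same normal distribution N(baseline, sd²); otherwise the night row
    is shifted by ``effect_size`` standard deviations. Returns the matrix
    plus a synthetic phase map pairing ``R<i>_Day`` with ``R<i>_Night``.
    """
    if n_pairs < 1 or n_samples < 2:
        raise DielgemError("need n_pairs >= 1 and n_samples >= 2")
    rng = np.random.default_rng(seed)
    ids: List[str] = []
    rows = np.empty((2 * n_pairs, n_samples))
    pm = PhaseMap()
    for i in range(n_pairs):
        day_id, night_id = f"R{i}_Day", f"R{i}_Night"
        ids += [day_id, night_id]
        rows[2 * i] = rng.normal(baseline, sd, n_samples)
        rows[2 * i + 1] = rng.normal(baseline + effect_size * sd, sd, n_samples)
        pm.reaction_ids.append(f"R{i}")
        pm.original_to_day[f"R{i}"] = day_id
        pm.original_to_night[f"R{i}"] = night_id
    return SampleMatrix(reaction_ids=ids, samples=rows, seed=seed), pm
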