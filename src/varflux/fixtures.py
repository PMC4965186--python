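"""Deterministic synthetic inputs for the whole pipeline.

Everything the analyses consume can be generated here: a toy
erythrocyte-style genome-scale model (glycolysis split around a
GAPDH-like step, a pentose-phosphate branch with a G6PD-like step,
NADPH- and ATP-consuming sinks, and a catechol-methylation pair so the
reduced-methylated-export phenotype is testable end to end), a "mini-RBC"
mass-action kinetic core with an exactly consistent reference steady
state, randomized structure-metadata tables, and the three variant
scenarios studied throughout (a COMT-like class I enzyme with weakened
ligand binding, a G6PD-like class I enzyme with tightened substrate
binding and reduced turnover, and a GAPDH-like class II enzyme with a
lethality threshold).

All generators are pure functions of their arguments; tables are seeded.
The mini-RBC surrogate is a fixture: its rate constants and reference
state are fixed package constants at desk scale, not estimates of any
published erythrocyte model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .datamodel import MetabolicModel, Metabolite, Reaction, VariantRecord
from .kinetics import (
    KineticModel,
    KineticReaction,
    MoietyPool,
    RateLaw,
    calibrate_percs,
    insert_enzyme_module,
)
from .structure_qc import StructureRecord
from .thermo import BindingPerturbation, MichaelisParameters


class ExpectedDirection(Enum):
    FLUX_DOWN = "flux_down"
    AFFINITY_UP = "affinity_up"
    LETHAL_ABOVE_THRESHOLD = "lethal_above_threshold"


@dataclass
class Scenario:
    """A named variant scenario: binding perturbations plus expectations."""

    name: str
    gene: str
    perturbations: list[BindingPerturbation]
    kinetic_overrides: dict[str, float] | None = None
    expected_direction: ExpectedDirection = ExpectedDirection.FLUX_DOWN
    #: toy-GEM reaction carrying the variant enzyme (constraint-based side)
    target_reaction: str | None = None
    #: downstream exchange whose secretion the variant should depress
    readout_exchange: str | None = None
    #: mini-RBC enzyme-module id (kinetic side); None when no mapping exists
    kinetic_enzyme: str | None = None


# ---------------------------------------------------------------------------
# Toy genome-scale model
# ---------------------------------------------------------------------------

def make_toy_gem() -> MetabolicModel:
    """A fixed ~20-reaction erythrocyte-style toy network (no RNG).

    Gene rules cover the interesting GPR cases: a single-gene step
    (gGAPDH), an isozyme pair (``gPFK1 or gPFK2``), a complex-or-isoform
    rule on the glucose transporter, and shared transporter genes. The
    methylation pair (dopamine-like and norepinephrine-like substrates
    imported, methylated counterparts exported, both gated by gCOMT) makes
    reduced methylated-product export observable in FVA.
    """
    mets = [
        Metabolite("glc_e", "glucose (external)", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("g6p_c", "glucose 6-phosphate", "c"),
        Metabolite("g3p_c", "glyceraldehyde 3-phosphate", "c"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("lac_c", "lactate", "c"),
        Metabolite("lac_e", "lactate (external)", "e"),
        Metabolite("r5p_c", "ribose 5-phosphate", "c"),
        Metabolite("r5p_e", "ribose 5-phosphate (external)", "e"),
        Metabolite("atp_c", "ATP", "c"),
        Metabolite("adp_c", "ADP", "c"),
        Metabolite("nad_c", "NAD+", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("nadp_c", "NADP+", "c"),
        Metabolite("nadph_c", "NADPH", "c"),
        Metabolite("oxid_e", "oxidant (external)", "e"),
        Metabolite("oxid_c", "oxidant", "c"),
        Metabolite("dopa_e", "catechol substrate A (external)", "e"),
        Metabolite("dopa_c", "catechol substrate A", "c"),
        Metabolite("mdopa_c", "methylated catechol A", "c"),
        Metabolite("mdopa_e", "methylated catechol A (external)", "e"),
        Metabolite("nore_e", "catechol substrate B (external)", "e"),
        Metabolite("nore_c", "catechol substrate B", "c"),
        Metabolite("mnore_c", "methylated catechol B", "c"),
        Metabolite("mnore_e", "methylated catechol B (external)", "e"),
    ]
    BIG = 1000.0
    rxns = [
        Reaction("EX_glc", {"glc_e": -1}, -10.0, 0.0, "", True),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0.0, BIG,
                 "(gGLUT1 and gGLUT1b) or gGLUT2"),
        Reaction("HK", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
                 0.0, BIG, "gHK"),
        Reaction("PFK_lump", {"g6p_c": -1, "atp_c": -1, "g3p_c": 2, "adp_c": 1},
                 0.0, BIG, "gPFK1 or gPFK2"),
        Reaction("GAPD_lump",
                 {"g3p_c": -1, "nad_c": -1, "adp_c": -2,
                  "pyr_c": 1, "nadh_c": 1, "atp_c": 2},
                 0.0, BIG, "gGAPDH"),
        Reaction("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
                 -BIG, BIG, "gLDH"),
        Reaction("LACt", {"lac_c": -1, "lac_e": 1}, 0.0, BIG, "gMCT"),
        Reaction("EX_lac", {"lac_e": -1}, 0.0, BIG, "", True),
        Reaction("G6PD_lump", {"g6p_c": -1, "nadp_c": -2, "r5p_c": 1, "nadph_c": 2},
                 0.0, BIG, "gG6PD"),
        Reaction("R5Pt", {"r5p_c": -1, "r5p_e": 1}, 0.0, BIG, "gR5Pt"),
        Reaction("EX_r5p", {"r5p_e": -1}, 0.0, BIG, "", True),
        Reaction("OXIDt", {"oxid_e": -1, "oxid_c": 1}, 0.0, BIG, "gOXIDt"),
        Reaction("EX_oxid", {"oxid_e": -1}, -8.0, 0.0, "", True),
        Reaction("GSHOX", {"nadph_c": -1, "oxid_c": -1, "nadp_c": 1},
                 0.0, BIG, "gGSR"),
        Reaction("ATPASE", {"atp_c": -1, "adp_c": 1}, 0.0, BIG, "gATPase"),
        Reaction("EX_dopa", {"dopa_e": -1}, -5.0, 0.0, "", True),
        Reaction("DOPAt", {"dopa_e": -1, "dopa_c": 1}, 0.0, BIG, "gAMT"),
        Reaction("COMT_A", {"dopa_c": -1, "mdopa_c": 1}, 0.0, BIG, "gCOMT"),
        Reaction("MDOPAt", {"mdopa_c": -1, "mdopa_e": 1}, 0.0, BIG, "gAMT"),
        Reaction("EX_mdopa", {"mdopa_e": -1}, 0.0, BIG, "", True),
        Reaction("EX_nore", {"nore_e": -1}, -5.0, 0.0, "", True),
        Reaction("NOREt", {"nore_e": -1, "nore_c": 1}, 0.0, BIG, "gAMT"),
        Reaction("COMT_B", {"nore_c": -1, "mnore_c": 1}, 0.0, BIG, "gCOMT"),
        Reaction("MNOREt", {"mnore_c": -1, "mnore_e": 1}, 0.0, BIG, "gAMT"),
        Reaction("EX_mnore", {"mnore_e": -1}, 0.0, BIG, "", True),
    ]
    return MetabolicModel(model_id="toy_rbc_gem", metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Mini-RBC kinetic core
# ---------------------------------------------------------------------------

#: Reference concentrations (mM) of the mini-RBC core.
MINI_RBC_CONCENTRATIONS: dict[str, float] = {
    "glc": 5.0,
    "g6p": 0.05,
    "g3p": 0.01,
    "pyr": 0.1,
    "lac": 1.5,
    "r5p": 0.02,
    "atp": 1.6,
    "adp": 0.4,
    "nad": 0.06,
    "nadh": 0.03,
    "nadp": 0.002,
    "nadph": 0.06,
}

#: Reference fluxes (mM per time unit); satisfy S v = 0 exactly by design.
MINI_RBC_FLUXES: dict[str, float] = {
    "GLC_IN": 1.0,
    "HK": 1.0,
    "PFK": 0.8,
    "G6PD": 0.2,
    "R5P_RECYCLE": 0.15,
    "R5P_DRAIN": 0.05,
    "GAPDH": 1.8,
    "G3P_LEAK": 0.05,
    "LDH": 1.8,
    "LAC_OUT": 1.8,
    "LOAD_NADPH": 0.4,
    "LOAD_ATP": 1.8,
}

#: Michaelis parameters used when housing the two variant enzymes in
#: explicit modules. Km values are in mM (the G6PD value mirrors the
#: experimental wild-type Km of 52 uM); kcat is per time unit.
MINI_RBC_MODULE_PARAMS: dict[str, tuple[str, str, MichaelisParameters]] = {
    "G6PD": ("G6PD", "g6p", MichaelisParameters(Km=0.052, kcat=10.0)),
    "GAPDH": ("GAPDH", "g3p", MichaelisParameters(Km=0.005, kcat=10.0)),
}


def _mini_rbc_reactions() -> list[KineticReaction]:
    MA, CF = RateLaw.MASS_ACTION, RateLaw.CONSTANT_FLUX
    return [
        # constant glucose supply (zero-order source)
        KineticReaction("GLC_IN", {"glc": 1.0}, rate_law=CF),
        KineticReaction("HK", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1},
                        reversible=False, rate_law=MA),
        KineticReaction("PFK", {"g6p": -1, "atp": -1, "g3p": 2, "adp": 1},
                        reversible=False, rate_law=MA),
        KineticReaction("G6PD", {"g6p": -1, "nadp": -2, "r5p": 1, "nadph": 2},
                        reversible=False, rate_law=MA),
        # partial pentose-phosphate recycle: 3 R5P -> 5 G3P carbon return
        KineticReaction("R5P_RECYCLE", {"r5p": -1, "g3p": 5.0 / 3.0},
                        reversible=False, rate_law=MA),
        KineticReaction("R5P_DRAIN", {"r5p": -1}, reversible=False, rate_law=MA),
        KineticReaction("GAPDH",
                        {"g3p": -1, "nad": -1, "adp": -2,
                         "pyr": 1, "nadh": 1, "atp": 2},
                        reversible=False, rate_law=MA),
        # small methylglyoxal-like shunt keeping G3P bounded
        KineticReaction("G3P_LEAK", {"g3p": -1}, reversible=False, rate_law=MA),
        KineticReaction("LDH", {"pyr": -1, "nadh": -1, "lac": 1, "nad": 1},
                        reversible=True, Keq=1000.0, rate_law=MA),
        KineticReaction("LAC_OUT", {"lac": -1}, reversible=False, rate_law=MA),
        # oxidative load: an imposed (zero-order) NADPH demand — oxidant
        # influx does not slow down because NADPH is scarce
        KineticReaction("LOAD_NADPH", {"nadph": -1, "nadp": 1}, rate_law=CF),
        # energy load: first-order ATPase demand (scales with ATP), which
        # also damps the glycolytic investment-payback instability
        KineticReaction("LOAD_ATP", {"atp": -1, "adp": 1},
                        reversible=False, rate_law=MA),
    ]


def _mini_rbc_pools() -> list[MoietyPool]:
    c = MINI_RBC_CONCENTRATIONS
    return [
        MoietyPool("adenylate", ("atp", "adp"), c["atp"] + c["adp"]),
        MoietyPool("nad_pool", ("nad", "nadh"), c["nad"] + c["nadh"]),
        MoietyPool("nadp_pool", ("nadp", "nadph"), c["nadp"] + c["nadph"]),
    ]


def make_mini_rbc() -> KineticModel:
    """The calibrated lumped mini-RBC model, stationary at its reference."""
    return calibrate_percs(
        model_id="mini_rbc",
        species=dict(MINI_RBC_CONCENTRATIONS),
        reactions=_mini_rbc_reactions(),
        ss_flux=dict(MINI_RBC_FLUXES),
        pools=_mini_rbc_pools(),
    )


def make_mini_rbc_with_modules() -> KineticModel:
    """Mini-RBC with G6PD and GAPDH housed in explicit enzyme modules."""
    model = make_mini_rbc()
    for enzyme, (reaction, substrate, params) in MINI_RBC_MODULE_PARAMS.items():
        model = insert_enzyme_module(model, reaction, params, substrate, enzyme=enzyme)
    return model


# ---------------------------------------------------------------------------
# Structure metadata tables
# ---------------------------------------------------------------------------

def make_structure_table(
    n: int,
    seed: int,
    fractions: tuple[float, float, float] = (0.3, 0.4, 0.3),
) -> list[StructureRecord]:
    """Reproducible structure records spanning all three QC groups.

    ``fractions`` gives the (perfect, partial, model-only) mixture; counts
    are exact (largest-remainder allocation), so requested proportions are
    met up to integer rounding.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    raw = np.array(fractions, dtype=float)
    raw = raw / raw.sum()
    counts = np.floor(raw * n).astype(int)
    for _ in range(n - counts.sum()):
        counts[np.argmax(raw * n - counts)] += 1
    records: list[StructureRecord] = []
    k = 0
    for group, count in zip(("perfect", "partial", "model"), counts):
        for _ in range(count):
            gene = f"gene{k:03d}"
            sid = f"S{k:04d}"
            if group == "perfect":
                rec = StructureRecord(
                    gene=gene, structure_id=sid, is_experimental=True,
                    seq_identity=1.0,
                    seq_coverage=float(rng.uniform(0.85, 1.0)),
                    resolution=float(rng.uniform(1.0, 2.2)),
                    missing_interior_residues=0,
                )
            elif group == "partial":
                rec = StructureRecord(
                    gene=gene, structure_id=sid, is_experimental=True,
                    seq_identity=float(rng.uniform(0.95, 0.999)),
                    seq_coverage=float(rng.uniform(0.80, 0.98)),
                    resolution=float(rng.uniform(1.5, 3.2)),
                    missing_interior_residues=int(rng.integers(0, 4)),
                )
            else:
                rec = StructureRecord(
                    gene=gene, structure_id=sid, is_experimental=False,
                    seq_identity=float(rng.uniform(0.3, 0.9)),
                    seq_coverage=float(rng.uniform(0.2, 0.75)),
                    resolution=None,
                    missing_interior_residues=int(rng.integers(0, 30)),
                )
            records.append(rec)
            k += 1
    return records


def structure_table_to_frame(records: list[StructureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "structure_id": r.structure_id,
                "experimental": r.is_experimental,
                "identity": r.seq_identity,
                "coverage": r.seq_coverage,
                "resolution": r.resolution if r.resolution is not None else float("nan"),
                "missing_interior": r.missing_interior_residues,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Variant scenarios
# ---------------------------------------------------------------------------

def make_variant_table() -> list[VariantRecord]:
    """The three study variants (class bookkeeping only)."""
    return [
        VariantRecord("gCOMT", "Val108Met", "rs4680", "benign",
                      ["tolcapone", "entacapone"]),
        VariantRecord("gG6PD", "Arg454His", "rs137852324", "disease", []),
        VariantRecord("gGAPDH", "Lys309Asn", "rs11549334", "unknown", []),
    ]


def make_paper_scenarios() -> list[Scenario]:
    """The three study scenarios with their binding free-energy differences.

    The G6PD and GAPDH ΔΔG values are the published central estimates for
    the respective ligands (uncertainties are metadata, not propagated).
    COMT per-ligand values were published only in supplementary material;
    the values here are synthetic stand-ins with the reported sign
    (weakened binding, ΔΔG < 0). The G6PD scenario carries a kcat
    reduction mirroring the experimentally observed loss of turnover; its
    magnitude is a fixture constant.
    """
    comt = Scenario(
        name="COMT_LIKE",
        gene="gCOMT",
        perturbations=[
            BindingPerturbation("gCOMT", "dopamine_like", ddg=-1.5),
            BindingPerturbation("gCOMT", "norepinephrine_like", ddg=-1.0),
            BindingPerturbation("gCOMT", "inhibitor_like", ddg=-2.0),
        ],
        expected_direction=ExpectedDirection.FLUX_DOWN,
        target_reaction="COMT_A",
        readout_exchange="EX_mdopa",
        kinetic_enzyme=None,  # absent from the kinetic core
    )
    g6pd = Scenario(
        name="G6PD_LIKE",
        gene="gG6PD",
        perturbations=[
            BindingPerturbation("gG6PD", "g6p", ddg=3.00),
            BindingPerturbation("gG6PD", "6pg", ddg=5.81),
            BindingPerturbation("gG6PD", "nadp", ddg=-13.057),
        ],
        kinetic_overrides={"kcat_factor": 0.15},
        expected_direction=ExpectedDirection.AFFINITY_UP,
        target_reaction="G6PD_lump",
        readout_exchange="EX_oxid",
        kinetic_enzyme="G6PD",
    )
    gapdh = Scenario(
        name="GAPDH_LIKE",
        gene="gGAPDH",
        perturbations=[
            BindingPerturbation("gGAPDH", "g3p", ddg=-3.55),
            BindingPerturbation("gGAPDH", "nad", ddg=-0.5504),
        ],
        expected_direction=ExpectedDirection.LETHAL_ABOVE_THRESHOLD,
        target_reaction="GAPD_lump",
        readout_exchange="EX_lac",
        kinetic_enzyme="GAPDH",
    )
    return [comt, g6pd, gapdh]


def get_scenario(name: str) -> Scenario:
    for sc in make_paper_scenarios():
        if sc.name.lower() == name.lower():
            return sc
    raise KeyError(f"unknown scenario {name!r}")


def make_dossier_table() -> pd.DataFrame:
    """Triage dossiers for the toy gene set (all flag combinations hit)."""
    rows = [
        # class I: structure + variant-drug association + drug binding
        dict(gene="gCOMT", has_structure=True, has_drug_binding_info=True,
             has_snp_drug_association=True, has_variant_with_effect_data=True,
             is_network_important=True),
        dict(gene="gG6PD", has_structure=True, has_drug_binding_info=True,
             has_snp_drug_association=True, has_variant_with_effect_data=True,
             is_network_important=True),
        # class II: structure + variant-effect data, no drug association
        dict(gene="gGAPDH", has_structure=True, has_drug_binding_info=False,
             has_snp_drug_association=False, has_variant_with_effect_data=True,
             is_network_important=True),
        # class III: network-important with structure only
        dict(gene="gHK", has_structure=True, has_drug_binding_info=False,
             has_snp_drug_association=False, has_variant_with_effect_data=False,
             is_network_important=True),
        # class IV: network-important only
        dict(gene="gLDH", has_structure=False, has_drug_binding_info=False,
             has_snp_drug_association=False, has_variant_with_effect_data=False,
             is_network_important=True),
        # unclassified: nothing
        dict(gene="gMCT", has_structure=False, has_drug_binding_info=False,
             has_snp_drug_association=False, has_variant_with_effect_data=False,
             is_network_important=False),
    ]
    return pd.DataFrame(rows)
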