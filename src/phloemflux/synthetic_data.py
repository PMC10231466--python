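"""Synthetic core metabolic model and transcript profiles.

The toy core model is a compact but structurally faithful plant central
metabolism network: split photosystems with cyclic electron flow, a lumped
Calvin cycle fixing exactly one CO2 per unit flux, glycolysis with both
ATP- and PPi-dependent phosphofructokinase, an oxidative pentose phosphate
branch, mitochondrial respiration, plasma-membrane and vacuolar proton
pumps, sucrose synthesis plus two degradation routes (invertase and the
PPi-consuming sucrose-synthase route), protein/RNA turnover pseudo-reactions
that consume ATP and release AMP and pyrophosphate, adenylate kinase in all
three energised compartments, and three amino-acid pathways with contrasting
energy by-products (histidine: releases PPi and NADH; glutamate: cheap;
lysine: consumes ATP and NADPH).  It is small enough for exhaustive
structural audits yet rich enough that every scenario of the analysis suite
is expressible on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .metnet_core import MetabolicModel, Metabolite, Reaction, UNBOUNDED

DEFAULT_LIGHT_INTENSITY = 200.0  # µmol photons m-2 s-1 incident on mesophyll


class SpecError(ValueError):
    """Contradictory or invalid generator specification."""


@dataclass
class ToyModelSpec:
    seed: int = 0
    light_intensity: float = DEFAULT_LIGHT_INTENSITY
    protons_per_symport: float = 1.0
    include: Dict[str, bool] = field(
        default_factory=lambda: {
            "photosystems": True,
            "mito_atp_synthase": True,
            "oppp": True,
            "glycolysis": True,
            "proton_pumps": True,
            "turnover_ppi": True,
            "vacuole": True,
            "sucrose_metabolism": True,
            "amino_acids": True,
        }
    )
    amino_acid_set: Sequence[str] = ("glu", "his", "lys")
    isoform_examples: bool = False

    def validate(self) -> None:
        if self.light_intensity <= 0:
            raise SpecError("light intensity must be positive")
        if self.include.get("amino_acids") and not self.amino_acid_set:
            raise SpecError("amino_acids enabled but amino_acid_set empty")
        if self.include.get("turnover_ppi") and not self.include.get("amino_acids"):
            raise SpecError("turnover requires amino acid pathways")


@dataclass
class SyntheticTranscriptSpec:
    seed: int = 0
    ground_truth_flux: Optional[Dict[str, float]] = None
    sigma: float = 0.0
    dropout: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise SpecError("dropout must be in [0, 1)")
        if self.sigma < 0:
            raise SpecError("sigma must be nonnegative")


# ---------------------------------------------------------------------------
# Core model
# ---------------------------------------------------------------------------

_METABOLITES = [
    # (base, compartments, formula)
    ("photon", "ep", None),
    ("co2", "ecpm", "CO2"),
    ("o2", "ecpm", "O2"),
    ("no3", "ecv", "NO3"),
    ("nh4", "c", "H4N"),
    ("h", "cev", "H"),
    ("pi", "cpm", "HO4P"),
    ("ppi", "cp", "H4O7P2"),
    ("atp", "cpm", "C10H12N5O13P3"),
    ("adp", "cpm", "C10H12N5O10P2"),
    ("amp", "cpm", "C10H12N5O7P"),
    ("nad", "cm", None),
    ("nadh", "cm", None),
    ("nadp", "cp", None),
    ("nadph", "cp", None),
    ("pq", "p", None),
    ("pqh2", "p", None),
    ("pcox", "p", None),
    ("pcred", "p", None),
    ("fdox", "p", None),
    ("fdred", "p", None),
    ("pmf", "p", None),
    ("gap", "cp", "C3H5O6P"),
    ("pga", "cp", "C3H4O7P"),
    ("fbp", "c", "C6H10O12P2"),
    ("fru6p", "c", "C6H11O9P"),
    ("glc6p", "c", "C6H11O9P"),
    ("ru5p", "c", "C5H9O8P"),
    ("r5p", "c", "C5H9O8P"),
    ("pyr", "cm", "C3H3O3"),
    ("mal", "cv", "C4H4O5"),
    ("suc", "cve", "C12H22O11"),
    ("glc", "cpe", "C6H12O6"),
    ("fru", "cve", "C6H12O6"),
    ("starch", "p", "C6H10O5"),
    ("glu", "cve", "C5H8NO4"),
    ("his", "cve", "C6H9N3O2"),
    ("lys", "cve", "C6H14N2O2"),
]

_COMPARTMENT_NAMES = {
    "c": "cytosol",
    "p": "plastid",
    "m": "mitochondrion",
    "v": "vacuole",
    "e": "extracellular",
}


def _reactions(spec: ToyModelSpec) -> List[Reaction]:
    nH = spec.protons_per_symport
    L = spec.light_intensity
    U = UNBOUNDED

    def rxn(rid, stoich, lb, ub, tags, name=""):
        return Reaction(
            id=rid,
            stoichiometry=dict(stoich),
            lower_bound=lb,
            upper_bound=ub,
            tags=set(tags),
            name=name or rid,
        )

    out: List[Reaction] = []
    add = out.append

    # boundary exchanges
    add(rxn("EX_photon", {"photon_e": 1}, 0, U, {"exchange", "photon_exchange"}))
    add(rxn("EX_co2", {"co2_e": 1}, -U, U, {"exchange", "carbon_uptake"}))
    add(rxn("EX_o2", {"o2_e": 1}, -U, U, {"exchange"}))
    add(rxn("EX_no3", {"no3_e": 1}, 0, U, {"exchange"}))
    add(rxn("EX_h", {"h_e": 1}, -U, U, {"exchange", "proton_exchange"}))

    # gas / mineral transport (kept in every cell)
    add(rxn("T_co2", {"co2_e": -1, "co2_c": 1}, -U, U, {"gas_transport", "carbon_uptake"}))
    add(rxn("T_o2", {"o2_e": -1, "o2_c": 1}, -U, U, {"gas_transport"}))
    add(rxn("T_no3", {"no3_e": -1, "no3_c": 1}, 0, U, {"mineral_transport"}))

    # plasma-membrane sugar/amino-acid transport (apoplast cells only)
    add(rxn("T_suc_pm", {"suc_c": -1, "suc_e": 1}, -U, U, {"pm_transport", "sugar_efflux"}))
    add(rxn("T_glc_pm", {"glc_c": -1, "glc_e": 1}, -U, U, {"pm_transport", "sugar_efflux"}))
    add(rxn("T_fru_pm", {"fru_c": -1, "fru_e": 1}, -U, U, {"pm_transport", "sugar_efflux"}))
    add(rxn("SUC_SYMPORT", {"suc_e": -1, "h_e": -nH, "suc_c": 1, "h_c": nH},
            0, U, {"pm_symport", "sugar_symport"}, "sucrose-proton symporter"))
    add(rxn("GLC_SYMPORT", {"glc_e": -1, "h_e": -nH, "glc_c": 1, "h_c": nH},
            0, U, {"pm_symport", "sugar_symport", "hexose_symport"}))
    add(rxn("FRU_SYMPORT", {"fru_e": -1, "h_e": -nH, "fru_c": 1, "h_c": nH},
            0, U, {"pm_symport", "sugar_symport", "hexose_symport"}))
    for aa in spec.amino_acid_set:
        add(rxn(f"{aa.upper()}_EFFLUX", {f"{aa}_c": -1, f"{aa}_e": 1}, 0, U,
                {"pm_transport", "aa_efflux"}))
        add(rxn(f"{aa.upper()}_SYMPORT", {f"{aa}_e": -1, "h_e": -nH, f"{aa}_c": 1, "h_c": nH},
                0, U, {"pm_symport", "aa_symport"}))

    if spec.include.get("proton_pumps", True):
        add(rxn("PM_ATPASE", {"atp_c": -1, "h_c": -1, "adp_c": 1, "pi_c": 1, "h_e": 1},
                0, U, {"pm_pump", "atpase_pm", "cc_only"}, "plasma-membrane H+-ATPase"))
        add(rxn("PM_PPIASE", {"ppi_c": -1, "h_c": -1, "pi_c": 2, "h_e": 1},
                0, U, {"pm_pump", "ppiase_pm", "cc_only"}, "plasma-membrane H+-PPiase"))

    # photosynthetic electron transport, split so PSII removal leaves the
    # cyclic (PSI + ferredoxin-plastoquinone reductase) ATP route intact
    if spec.include.get("photosystems", True):
        add(rxn("Photon_ep", {"photon_e": -1, "photon_p": 1}, 0, L, {"photon_uptake"}))
        add(rxn("PSII", {"photon_p": -1, "pq_p": -1, "pqh2_p": 1, "o2_p": 0.5},
                0, U, {"psii", "light_reaction"}, "photosystem II"))
        add(rxn("B6F", {"pqh2_p": -1, "pcox_p": -2, "pq_p": 1, "pcred_p": 2, "pmf_p": 2},
                0, U, {"light_reaction"}, "cytochrome b6f"))
        add(rxn("PSI", {"photon_p": -1, "pcred_p": -1, "fdox_p": -1, "pcox_p": 1, "fdred_p": 1},
                0, U, {"psi", "light_reaction"}, "photosystem I"))
        add(rxn("FNR", {"fdred_p": -2, "nadp_p": -1, "fdox_p": 2, "nadph_p": 1},
                0, U, {"light_reaction"}))
        add(rxn("FQR", {"fdred_p": -2, "pq_p": -1, "fdox_p": 2, "pqh2_p": 1},
                0, U, {"light_reaction", "cyclic"}, "ferredoxin-plastoquinone reductase"))
        add(rxn("ATPS_p", {"pmf_p": -3, "adp_p": -1, "pi_p": -1, "atp_p": 1},
                0, U, {"atp_synthase_plastid", "atp_synthase"}, "plastidial ATP synthase"))
        # lumped Calvin cycle: one CO2 fixed per unit flux
        add(rxn("CBB", {"co2_p": -1, "atp_p": -3, "nadph_p": -2,
                        "gap_p": 1 / 3, "adp_p": 3, "pi_p": 8 / 3, "nadp_p": 2},
                0, U, {"rubisco", "carbon_fixation"}, "Rubisco carboxylation (lumped CBB)"))

    # plastid transport and shuttles
    add(rxn("GAPDH_p", {"pga_p": -1, "atp_p": -1, "nadph_p": -1,
                        "gap_p": 1, "adp_p": 1, "pi_p": 1, "nadp_p": 1},
            0, U, {"shuttle_leg"}, "plastid GAP dehydrogenase"))
    add(rxn("T_gap", {"gap_p": -1, "gap_c": 1}, -U, U, {"plastid_transport", "shuttle"}))
    add(rxn("T_pga", {"pga_p": -1, "pga_c": 1}, -U, U, {"plastid_transport", "shuttle"}))
    add(rxn("T_glc_p", {"glc_p": -1, "glc_c": 1}, -U, U, {"plastid_transport"}))
    add(rxn("T_co2_p", {"co2_c": -1, "co2_p": 1}, -U, U, {"plastid_transport"}))
    add(rxn("T_o2_p", {"o2_p": -1, "o2_c": 1}, -U, U, {"plastid_transport"}))
    add(rxn("ATP_AMP_SHUTTLE_p", {"atp_p": -1, "amp_c": -1, "atp_c": 1, "amp_p": 1},
            -U, U, {"plastid_transport", "shuttle"}, "plastid ATP-AMP shuttle"))

    # glycolysis / gluconeogenesis / sucrose metabolism (cytosol)
    if spec.include.get("glycolysis", True):
        add(rxn("GAPDH_c", {"gap_c": -1, "adp_c": -1, "pi_c": -1, "nad_c": -1,
                            "pga_c": 1, "atp_c": 1, "nadh_c": 1},
                -U, U, {"glycolysis"}, "cytosolic GAP dehydrogenase + PGA kinase"))
        add(rxn("PK", {"pga_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1},
                0, U, {"glycolysis"}, "pyruvate kinase (lumped lower glycolysis)"))
        add(rxn("ALD", {"fbp_c": -1, "gap_c": 2}, -U, U, {"glycolysis"}, "aldolase + TPI"))
        add(rxn("PFK", {"fru6p_c": -1, "atp_c": -1, "fbp_c": 1, "adp_c": 1},
                0, U, {"glycolysis"}))
        add(rxn("PFP", {"fru6p_c": -1, "ppi_c": -1, "fbp_c": 1, "pi_c": 1},
                -U, U, {"glycolysis", "ppi_enzyme"},
                "pyrophosphate-fructose-6-phosphate phosphotransferase"))
        add(rxn("FBPASE", {"fbp_c": -1, "fru6p_c": 1, "pi_c": 1}, 0, U, {"gluconeogenesis"}))
        add(rxn("PGI", {"glc6p_c": -1, "fru6p_c": 1}, -U, U, {"glycolysis"}))
        add(rxn("HXK", {"glc_c": -1, "atp_c": -1, "glc6p_c": 1, "adp_c": 1},
                0, U, {"hexokinase"}))
        add(rxn("FRK", {"fru_c": -1, "atp_c": -1, "fru6p_c": 1, "adp_c": 1},
                0, U, {"fructokinase"}))

    if spec.include.get("sucrose_metabolism", True):
        add(rxn("SPS", {"glc6p_c": -1, "fru6p_c": -1, "atp_c": -1,
                        "suc_c": 1, "adp_c": 1, "ppi_c": 1, "pi_c": 1},
                0, U, {"sucrose_synthesis", "ppi_source"},
                "sucrose synthesis (SPS + UGPase lump)"))
        add(rxn("INV", {"suc_c": -1, "glc_c": 1, "fru_c": 1}, 0, U,
                {"invertase", "sucrose_degradation"}))
        add(rxn("SUSY", {"suc_c": -1, "ppi_c": -1, "fru_c": 1, "glc6p_c": 1, "pi_c": 1},
                0, U, {"sucrose_synthase", "sucrose_degradation", "ppi_enzyme"},
                "sucrose synthase + UGPase route"))
        add(rxn("STARCH_SYNTH", {"gap_p": -2, "atp_p": -1, "starch_p": 1, "adp_p": 1, "ppi_p": 1, "pi_p": 1},
                0, U, {"starch"}, "starch synthesis (AGPase lump)"))
        add(rxn("STARCH_DEG", {"starch_p": -1, "glc_p": 1}, 0, U, {"starch"}))

    if spec.include.get("oppp", True):
        add(rxn("G6PDH", {"glc6p_c": -1, "nadp_c": -2, "ru5p_c": 1, "co2_c": 1, "nadph_c": 2},
                0, U, {"oppp"}, "oxidative pentose phosphate lump"))
        add(rxn("RPI", {"ru5p_c": -1, "r5p_c": 1}, -U, U, {"oppp"}))
        add(rxn("PPP_NONOX", {"ru5p_c": -6, "glc6p_c": 5, "pi_c": 1}, -U, U, {"oppp"},
                "non-oxidative pentose phosphate lump (reversible)"))

    # nitrogen assimilation
    add(rxn("NR", {"no3_c": -1, "nadh_c": -4, "nh4_c": 1, "nad_c": 4},
            0, U, {"nitrogen"}, "nitrate reduction lump"))

    # amino-acid biosynthesis with contrasting energy by-products
    if spec.include.get("amino_acids", True):
        aa = set(spec.amino_acid_set)
        if "glu" in aa:
            add(rxn("GLU_SYNTH", {"gap_c": -1, "pyr_c": -1, "nh4_c": -1, "nadph_c": -1,
                                  "atp_c": -1, "glu_c": 1, "co2_c": 1, "nadp_c": 1,
                                  "adp_c": 1, "pi_c": 2},
                    0, U, {"aa_synth", "aa_synth:glu"}, "glutamate synthesis lump"))
        if "his" in aa:
            add(rxn("HIS_SYNTH", {"r5p_c": -1, "gap_c": -1, "nh4_c": -2, "atp_c": -1,
                                  "nad_c": -2, "his_c": 1, "co2_c": 2, "amp_c": 1,
                                  "ppi_c": 1, "pi_c": 2, "nadh_c": 2},
                    0, U, {"aa_synth", "aa_synth:his", "ppi_source"},
                    "histidine synthesis lump (releases PPi + NADH)"))
        if "lys" in aa:
            add(rxn("LYS_SYNTH", {"pyr_c": -2, "nh4_c": -1, "atp_c": -2, "nadph_c": -2,
                                  "lys_c": 1, "adp_c": 2, "pi_c": 2, "nadp_c": 2},
                    0, U, {"aa_synth", "aa_synth:lys"},
                    "lysine synthesis lump (consumes ATP + NADPH)"))

    # amino-acid catabolism: imported glutamate can be burned for reducing
    # power and carbon skeletons (sieve elements rely on this)
    if spec.include.get("amino_acids", True) and "glu" in set(spec.amino_acid_set):
        add(rxn("GLU_CATAB", {"glu_c": -1, "nad_c": -2, "pyr_c": 1, "co2_c": 2,
                              "nh4_c": 1, "nadh_c": 2},
                0, U, {"aa_catab"}, "glutamate catabolism lump"))

    # malate (accumulation buffer + reducing-power store)
    add(rxn("ME", {"pyr_c": -1, "co2_c": -1, "nadh_c": -1, "mal_c": 1, "nad_c": 1},
            -U, U, {"malate"}, "malic enzyme (reversible)"))

    # mitochondrion
    add(rxn("T_pyr_m", {"pyr_c": -1, "pyr_m": 1}, 0, U, {"mito_transport"}))
    add(rxn("TCA", {"pyr_m": -1, "nad_m": -4, "adp_m": -1, "pi_m": -1,
                    "co2_m": 3, "nadh_m": 4, "atp_m": 1},
            0, U, {"tca"}, "pyruvate oxidation + TCA lump"))
    if spec.include.get("mito_atp_synthase", True):
        add(rxn("ETC", {"nadh_m": -1, "o2_m": -0.5, "adp_m": -2.5, "pi_m": -2.5,
                        "nad_m": 1, "atp_m": 2.5},
                0, U, {"atp_synthase_mito", "atp_synthase"},
                "respiratory chain + mitochondrial ATP synthase"))
    add(rxn("T_co2_m", {"co2_m": -1, "co2_c": 1}, -U, U, {"mito_transport"}))
    add(rxn("T_o2_m", {"o2_c": -1, "o2_m": 1}, -U, U, {"mito_transport"}))
    add(rxn("MAL_SHUTTLE_m", {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
            -U, U, {"shuttle"}, "mitochondrial redox shuttle (malate valve lump)"))
    add(rxn("ANT_m", {"atp_m": -1, "adp_c": -1, "adp_m": 1, "atp_c": 1},
            -U, U, {"mito_transport"}, "adenine nucleotide translocator"))
    add(rxn("T_amp_m", {"amp_c": -1, "amp_m": 1}, -U, U, {"mito_transport"}))
    add(rxn("T_adp_m", {"adp_c": -1, "adp_m": 1}, -U, U, {"mito_transport"},
            "mitochondrial ADP uniport (net adenine carrier)"))
    add(rxn("T_pi_m", {"pi_c": -1, "pi_m": 1}, -U, U, {"mito_transport"},
            "mitochondrial phosphate translocator"))
    add(rxn("T_pi_p", {"pi_c": -1, "pi_p": 1}, -U, U, {"plastid_transport"},
            "plastid phosphate translocator"))

    # adenylate kinase per compartment; inorganic pyrophosphatases
    add(rxn("AK_C", {"atp_c": -1, "amp_c": -1, "adp_c": 2}, -U, U, {"ak", "ak_c"},
            "adenylate kinase (cytosol)"))
    add(rxn("AK_M", {"atp_m": -1, "amp_m": -1, "adp_m": 2}, -U, U, {"ak", "ak_m"},
            "adenylate kinase (mitochondrion)"))
    add(rxn("AK_P", {"atp_p": -1, "amp_p": -1, "adp_p": 2}, -U, U, {"ak", "ak_p"},
            "adenylate kinase (plastid)"))
    add(rxn("PPASE_C", {"ppi_c": -1, "pi_c": 2}, 0, U, {"ppase", "ppase_c"},
            "cytosolic inorganic pyrophosphatase"))
    add(rxn("PPASE_P", {"ppi_p": -1, "pi_p": 2}, 0, U, {"ppase"},
            "plastidial inorganic pyrophosphatase"))

    # vacuole: proton pumps, proton-coupled storage, tonoplast proton leak
    if spec.include.get("vacuole", True):
        add(rxn("V_ATPASE", {"atp_c": -1, "h_c": -1, "adp_c": 1, "pi_c": 1, "h_v": 1},
                0, U, {"vacuole", "v_pump"}, "vacuolar H+-ATPase"))
        add(rxn("V_PPIASE", {"ppi_c": -1, "h_c": -1, "pi_c": 2, "h_v": 1},
                0, U, {"vacuole", "v_pump", "ppiase_v"}, "vacuolar H+-PPiase"))
        add(rxn("H_LEAK_V", {"h_v": -1, "h_c": 1}, 0, U, {"vacuole"}, "tonoplast proton leak"))
        for base in ("suc", "fru", "no3", "mal", "glu", "his", "lys"):
            add(rxn(f"T_{base}_v", {f"{base}_c": -1, "h_v": -1, f"{base}_v": 1, "h_c": 1},
                    -U, U, {"vacuole"}, f"tonoplast {base} antiport"))

    # maintenance and turnover pseudo-reactions
    add(rxn("ATP_MAINT", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, 0, U,
            {"maintenance"}, "generic ATP maintenance drain"))
    if spec.include.get("turnover_ppi", True):
        aa_cost = {f"{aa}_c": -0.05 for aa in spec.amino_acid_set}
        carbon = 0.05 * sum(
            {"glu": 5, "his": 6, "lys": 6}.get(aa, 5) for aa in spec.amino_acid_set
        )
        stoich = {"atp_c": -4.0, "co2_c": carbon, "adp_c": 2.0, "pi_c": 2.0,
                  "amp_c": 2.0, "ppi_c": 2.0}
        stoich.update(aa_cost)
        add(rxn("PROT_TURNOVER", stoich, 0, U,
                {"protein_turnover", "turnover", "ppi_source"},
                "protein turnover (synthesis/degradation cycle)"))
        add(rxn("RNA_TURNOVER", {"r5p_c": -0.1, "atp_c": -2.0, "co2_c": 0.5,
                                 "adp_c": 1.0, "pi_c": 1.1, "amp_c": 1.0, "ppi_c": 1.0},
                0, U, {"rna_turnover", "turnover", "ppi_source"},
                "mRNA turnover (synthesis/degradation cycle)"))
    return out


def make_toy_core_model(spec: Optional[ToyModelSpec] = None) -> MetabolicModel:
    """Deterministic toy core model of plant central metabolism.

    The structure is fixed by the spec's feature flags; the seed is recorded
    in the annotations (gene assignment and transcript generation use it).
    """
    if spec is None:
        spec = ToyModelSpec()
    spec.validate()

    model = MetabolicModel(id=f"toy_core_seed{spec.seed}")
    model.compartments = dict(_COMPARTMENT_NAMES)
    for base, comps, formula in _METABOLITES:
        if base in ("glu", "his", "lys") and base not in spec.amino_acid_set:
            continue
        for comp in comps:
            model.add_metabolite(
                Metabolite(id=f"{base}_{comp}", name=base, compartment=comp, formula=formula)
            )

    for rxn in _reactions(spec):
        # one pseudo-gene per reaction (exchanges and pseudo-reactions excluded)
        if not rxn.tags & {"exchange", "maintenance", "accumulation"}:
            rxn.gene_association = f"g_{rxn.id}"
        model.add_reaction(rxn)

    if spec.isoform_examples:
        model.reactions["INV"].gene_association = "g_INV_a or g_INV_b"
        model.gene_ids.update({"g_INV_a", "g_INV_b"})
        model.reactions["TCA"].gene_association = "g_TCA_1 and g_TCA_2"
        model.gene_ids.update({"g_TCA_1", "g_TCA_2"})

    model.annotations["seed"] = str(spec.seed)
    model.annotations["light_intensity"] = str(spec.light_intensity)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Transcript profiles
# ---------------------------------------------------------------------------


def make_synthetic_transcripts(
    model: MetabolicModel,
    cells: Sequence[str],
    spec: Optional[SyntheticTranscriptSpec] = None,
    ratios: Optional[Dict[str, float]] = None,
):
    """Synthetic gene x cell-type abundance profile.

    Without a ground truth, abundances are lognormal draws.  With
    ``ground_truth_flux`` (a tissue-level flux vector keyed by tissue
    reaction ids), the abundance of a reaction's gene in cell ``c`` is the
    summed light+dark absolute flux of that reaction in the cell group the
    weighting objective compares it against, divided by the cell ratio —
    so a noiseless profile is exactly recoverable (distance objective 0).
    """
    from .transcript_integration import TranscriptProfile

    if spec is None:
        spec = SyntheticTranscriptSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ratios = ratios or {"MC": 20.0, "CC": 1.0, "SE": 5.0, "pSE": 6.0}

    gene_of = {}
    for rxn in model.reactions.values():
        if rxn.gene_association and " " not in rxn.gene_association:
            gene_of[rxn.id] = rxn.gene_association

    abundance: Dict[tuple, float] = {}
    for rid, gene in sorted(gene_of.items()):
        for cell in cells:
            if spec.ground_truth_flux is not None:
                group = ["MC"] if cell == "MC" else ["CC", "SE", "pSE"]
                total = 0.0
                for member in group:
                    for phase in ("l", "d"):
                        total += abs(
                            spec.ground_truth_flux.get(f"{rid}_{member}_{phase}", 0.0)
                        )
                value = total / ratios[cell]
            else:
                value = float(rng.lognormal(mean=0.0, sigma=1.0))
            if spec.sigma > 0:
                value *= float(rng.lognormal(mean=0.0, sigma=spec.sigma))
            if spec.dropout > 0 and rng.random() < spec.dropout:
                continue
            abundance[(gene, cell)] = value

    return TranscriptProfile(abundance=abundance, normalization="raw")
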