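"""Assembly of the four-cell-type, two-phase leaf tissue model.

The tissue is one big stoichiometric network: a core cell model replicated
into mesophyll (MC), companion cell (CC), leaf sieve element (SE) and
petiolar sieve element (pSE) copies, each split into a light ("l") and a
dark ("d") phase.  The phases of one cell are joined by reversible
accumulation reactions (vacuolar stores, plastidial starch).  MC and CC
exchange sugars and amino acids through shared per-phase apoplast pools
(passive efflux out of MC, proton-coupled symport into CC); CC, SE and pSE
are joined by zero-cost symplastic transfer reactions with a size/charge
exclusion list; nucleotides travel downstream only.  The pSE carries the
fixed-composition phloem export reaction, whose dark-phase rate is coupled
to a fraction of the light-phase rate, plus a sucrose leak/retrieval pair
against a petiole apoplast.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .metnet_core import (
    AssemblyError,
    MetabolicModel,
    Metabolite,
    Reaction,
    UNBOUNDED,
    replicate_model,
)

logger = logging.getLogger("phloemflux")

PHASES = ("l", "d")
PHASE_NAMES = {"light": "l", "dark": "d"}

#: symplastic exclusion defaults: large molecules (heteroglycans,
#: polysaccharides, lipids), superoxide, protons and iron ions.
DEFAULT_SYMPLAST_EXCLUDED = {
    "h",
    "starch",
    "cellulose",
    "callose",
    "heteroglycan",
    "lipid",
    "superoxide",
    "fe2",
    "fe3",
}

#: nucleotide species restricted to downstream (CC -> SE -> pSE) transfer.
DEFAULT_NUCLEOTIDE_ONEWAY = {"atp", "adp", "amp", "nad", "nadh", "nadp", "nadph"}


class ValidationError(ValueError):
    """Invalid quantitative argument to an assembly operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CellSpec:
    """Structural customization of one cell type.

    ``extra_reactions`` lists core-reaction groups this cell retains that are
    not default (currently ``"cc_only"`` keeps the plasma-membrane proton
    pumps, which only companion cells carry).
    """

    name: str
    has_vacuole: bool = True
    has_mrna_turnover: bool = True
    apoplast_exchange: bool = False
    symplast_partners: Set[str] = field(default_factory=set)
    extra_reactions: List[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.name in ("SE", "pSE") and self.has_vacuole:
            raise ValidationError(f"{self.name} must not have a vacuole")
        if self.apoplast_exchange and self.name not in ("MC", "CC"):
            raise ValidationError(
                f"only MC and CC exchange sugars/amino acids with the apoplast, not {self.name}"
            )


def default_cell_specs() -> List[CellSpec]:
    """The four cell types of the phloem-loading tissue model."""
    return [
        CellSpec("MC", has_vacuole=True, has_mrna_turnover=True, apoplast_exchange=True),
        CellSpec(
            "CC",
            has_vacuole=True,
            has_mrna_turnover=True,
            apoplast_exchange=True,
            symplast_partners={"SE"},
            extra_reactions=["cc_only"],
        ),
        CellSpec(
            "SE",
            has_vacuole=False,
            has_mrna_turnover=False,
            apoplast_exchange=False,
            symplast_partners={"CC", "pSE"},
        ),
        CellSpec(
            "pSE",
            has_vacuole=False,
            has_mrna_turnover=False,
            apoplast_exchange=False,
            symplast_partners={"SE"},
        ),
    ]


@dataclass
class SapComposition:
    """Relative molar composition of exported phloem sap."""

    coefficients: Dict[str, float]

    def validate(self) -> None:
        if "suc" not in self.coefficients:
            raise ValidationError("sap composition must contain sucrose ('suc')")
        for name, coef in self.coefficients.items():
            if coef <= 0:
                raise ValidationError(f"sap coefficient for {name} must be > 0")


@dataclass
class Coupling:
    """A linear constraint over reaction fluxes: lb <= sum(coef*v) <= ub."""

    coefficients: Dict[str, float]
    lower: float
    upper: float
    name: str = ""


@dataclass
class TissueModel:
    """The assembled multi-cell diel network plus bookkeeping.

    ``provenance`` maps every reaction id to ``(cell, phase, origin)`` where
    origin is ``"core"`` for replicated core reactions or a linker kind.
    ``linker_index`` maps linker kinds (apoplast, symplast, accumulation,
    phloem_export, leak, retrieval) to the reaction ids implementing them.
    ``couplings`` holds inter-reaction constraints (e.g. the dark/light
    phloem-rate lock) that the LP layer adds as extra rows.
    """

    model: MetabolicModel
    cell_specs: List[CellSpec]
    phase_names: Dict[str, str] = field(default_factory=lambda: dict(PHASE_NAMES))
    linker_index: Dict[str, List[str]] = field(default_factory=dict)
    provenance: Dict[str, Tuple[str, str, str]] = field(default_factory=dict)
    couplings: List[Coupling] = field(default_factory=list)

    @property
    def cells(self) -> List[str]:
        return [s.name for s in self.cell_specs]

    def spec(self, cell: str) -> CellSpec:
        for s in self.cell_specs:
            if s.name == cell:
                return s
        raise KeyError(cell)

    def reactions_of(self, cell: Optional[str] = None, phase: Optional[str] = None,
                     origin: Optional[str] = None, tag: Optional[str] = None) -> List[str]:
        out = []
        for rid, (c, p, o) in self.provenance.items():
            if cell is not None and c != cell:
                continue
            if phase is not None and p != phase:
                continue
            if origin is not None and o != origin:
                continue
            if tag is not None and tag not in self.model.reactions[rid].tags:
                continue
            out.append(rid)
        return out

    def core_reaction_id(self, core_id: str, cell: str, phase: str) -> str:
        return f"{core_id}_{cell}_{phase}"

    def phloem_export_id(self, phase: str) -> str:
        for rid in self.linker_index.get("phloem_export", []):
            if self.provenance[rid][1] == phase:
                return rid
        raise KeyError(f"no phloem export reaction for phase {phase}")

    def copy(self) -> "TissueModel":
        return copy.deepcopy(self)

    def _register(self, rid: str, cell: str, phase: str, origin: str) -> None:
        self.provenance[rid] = (cell, phase, origin)
        if origin != "core":
            self.linker_index.setdefault(origin, []).append(rid)

    def _prune_registry(self) -> None:
        """Drop provenance/linker entries for reactions no longer in the model."""
        live = self.model.reactions
        self.provenance = {rid: v for rid, v in self.provenance.items() if rid in live}
        for kind in list(self.linker_index):
            self.linker_index[kind] = [r for r in self.linker_index[kind] if r in live]


def species_base(met: Metabolite) -> str:
    """The compartment-free species name (carried in ``Metabolite.name``)."""
    return met.name or met.id


# ---------------------------------------------------------------------------
# Per-cell diel construction
# ---------------------------------------------------------------------------


def _filter_core_for_cell(core: MetabolicModel, spec: CellSpec) -> MetabolicModel:
    cell_core = core.copy()
    drop: Set[str] = set()
    for rxn in cell_core.reactions.values():
        if "vacuole" in rxn.tags and not spec.has_vacuole:
            drop.add(rxn.id)
        if "rna_turnover" in rxn.tags and not spec.has_mrna_turnover:
            drop.add(rxn.id)
        if not spec.apoplast_exchange and rxn.tags & {
            "pm_transport",
            "pm_symport",
            "pm_pump",
            "proton_exchange",
        }:
            drop.add(rxn.id)
        if "cc_only" in rxn.tags and "cc_only" not in spec.extra_reactions:
            drop.add(rxn.id)
    for rid in drop:
        cell_core.remove_reaction(rid)
    cell_core.prune_orphan_metabolites()
    return cell_core


def build_diel_cell(
    core: MetabolicModel,
    spec: CellSpec,
    accumulables: Sequence[str],
) -> MetabolicModel:
    """Two phase replicas of a (cell-filtered) core joined by accumulation.

    Each accumulable species is stored in the vacuole where the cell has one,
    or in the plastid (starch); cells without a vacuole keep only plastidial
    accumulation.  The dark replica has no photon uptake.
    """
    spec.validate()
    # resolve accumulables against the unfiltered core so unknown names fail
    for base in accumulables:
        if not any(species_base(m) == base for m in core.metabolites.values()):
            raise AssemblyError(f"accumulable '{base}' not found in core model")

    cell_core = _filter_core_for_cell(core, spec)

    replicas = {}
    for phase in PHASES:
        rep = replicate_model(
            cell_core,
            f"_{spec.name}_{phase}",
            extra_tags={f"cell:{spec.name}", f"phase:{phase}"},
        )
        if phase == "d":
            for rxn in list(rep.reactions.values()):
                if rxn.tags & {"photon_uptake", "photon_exchange"}:
                    rep.remove_reaction(rxn.id)
            rep.prune_orphan_metabolites()
        replicas[phase] = rep

    merged = MetabolicModel(id=f"{core.id}_{spec.name}")
    for rep in replicas.values():
        merged.compartments.update(rep.compartments)
        for met in rep.metabolites.values():
            merged.add_metabolite(met)
        for rxn in rep.reactions.values():
            merged.add_reaction(rxn)

    # accumulation linkers between the phases
    comp_priority = ["v", "p"] if spec.has_vacuole else ["p"]
    for base in accumulables:
        store_id = None
        for comp in comp_priority:
            candidate = None
            for met in cell_core.metabolites.values():
                if species_base(met) == base and met.compartment == comp:
                    candidate = met.id
                    break
            if candidate:
                store_id = candidate
                break
        if store_id is None:
            # vacuolar-only accumulable in a cell without a vacuole: skipped
            # (sieve elements accumulate starch only)
            continue
        rid = f"ACC_{base}_{spec.name}"
        merged.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={
                    f"{store_id}_{spec.name}_l": -1.0,
                    f"{store_id}_{spec.name}_d": 1.0,
                },
                lower_bound=-UNBOUNDED,
                upper_bound=UNBOUNDED,
                tags={"accumulation", f"cell:{spec.name}"},
                name=base,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Tissue-level linkers
# ---------------------------------------------------------------------------


def _cytosolic_bases(core: MetabolicModel) -> List[str]:
    seen, out = set(), []
    for met in core.metabolites.values():
        if met.compartment == "c":
            base = species_base(met)
            if base not in seen:
                seen.add(base)
                out.append(base)
    return out


def build_symplast_linkers(
    tissue: TissueModel,
    core: MetabolicModel,
    excluded: Optional[Set[str]] = None,
    nucleotide_oneway: Optional[Set[str]] = None,
) -> TissueModel:
    """Zero-cost plasmodesmatal transfers CC<->SE and SE<->pSE per phase.

    Every cytosolic core species outside ``excluded`` gets a reversible
    transfer; species in ``nucleotide_oneway`` transfer only downstream
    (CC->SE, SE->pSE).
    """
    if excluded is None:
        excluded = set(DEFAULT_SYMPLAST_EXCLUDED)
    if not excluded:
        logger.warning("empty symplastic exclusion set: protons and polymers will diffuse")
    oneway = set(nucleotide_oneway or DEFAULT_NUCLEOTIDE_ONEWAY)
    for cell in ("CC", "SE", "pSE"):
        if cell not in tissue.cells:
            raise AssemblyError(f"symplast linkers require cell {cell}")

    pairs = [("CC", "SE"), ("SE", "pSE")]
    for base in _cytosolic_bases(core):
        if base in excluded:
            continue
        for up, down in pairs:
            for phase in PHASES:
                src = f"{base}_c_{up}_{phase}"
                dst = f"{base}_c_{down}_{phase}"
                if src not in tissue.model.metabolites or dst not in tissue.model.metabolites:
                    continue
                rid = f"SYM_{base}_{up}_{down}_{phase}"
                lb = 0.0 if base in oneway else -UNBOUNDED
                tissue.model.add_reaction(
                    Reaction(
                        id=rid,
                        stoichiometry={src: -1.0, dst: 1.0},
                        lower_bound=lb,
                        upper_bound=UNBOUNDED,
                        tags={"symplast", f"phase:{phase}", f"cell:{up}-{down}"},
                        name=base,
                    )
                )
                tissue._register(rid, f"{up}-{down}", phase, "symplast")
    return tissue


def build_apoplast(
    tissue: TissueModel,
    core: MetabolicModel,
    transported: Set[str],
) -> TissueModel:
    """Shared per-phase apoplast pools between MC and CC.

    The per-cell extracellular species of MC and CC replicas are merged into
    one apoplast pool per transported species and phase, turning the core's
    plasma-membrane reactions into apoplast linkers: passive efflux out of
    the mesophyll, proton-coupled symport into the companion cell.  Amino
    acids flow strictly MC -> apoplast -> CC.  Gases and minerals keep their
    per-cell boundary exchanges.
    """
    if "h" not in transported:
        raise AssemblyError("apoplast requires the proton species 'h' to be transported")
    model = tissue.model

    base_to_e = {}
    for met in core.metabolites.values():
        if met.compartment == "e" and species_base(met) in transported:
            base_to_e[species_base(met)] = met.id

    missing = transported - set(base_to_e)
    if missing:
        raise AssemblyError(f"transported species missing from core extracellular space: {sorted(missing)}")

    apoplast_cells = [s.name for s in tissue.cell_specs if s.apoplast_exchange]
    for phase in PHASES:
        comp = f"apo_{phase}"
        model.compartments.setdefault(comp, f"apoplast ({phase})")
        for base, e_id in base_to_e.items():
            pool_id = f"{base}_{comp}"
            model.add_metabolite(
                Metabolite(
                    id=pool_id,
                    name=base,
                    compartment=comp,
                    formula=core.metabolites[e_id].formula,
                )
            )
            for cell in apoplast_cells:
                old = f"{e_id}_{cell}_{phase}"
                if old not in model.metabolites:
                    continue
                for rxn in model.reactions.values():
                    if old in rxn.stoichiometry:
                        rxn.stoichiometry[pool_id] = rxn.stoichiometry.pop(old)
                del model.metabolites[old]

    # boundary proton exchanges of apoplast cells are replaced by the pools
    for rid in [r.id for r in model.reactions.values() if "proton_exchange" in r.tags]:
        model.remove_reaction(rid)

    # directionality: passive efflux belongs to the mesophyll (source) side
    # and runs outward only; companion-cell uptake is strictly proton-coupled
    # (concentrative), so CC keeps no passive sugar path and no amino-acid
    # efflux, and MC keeps no amino-acid symport.
    drop = []
    for rxn in model.reactions.values():
        cell = next((t.split(":", 1)[1] for t in rxn.tags if t.startswith("cell:")), None)
        if "aa_efflux" in rxn.tags and cell != "MC":
            drop.append(rxn.id)
        elif "aa_symport" in rxn.tags and cell != "CC":
            drop.append(rxn.id)
        elif "sugar_efflux" in rxn.tags:
            if cell == "MC":
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            else:
                drop.append(rxn.id)
    for rid in drop:
        model.remove_reaction(rid)
    model.prune_orphan_metabolites()

    tissue._prune_registry()
    for rxn in model.reactions.values():
        if rxn.tags & {"pm_transport", "pm_symport", "pm_pump"}:
            cell = next((t.split(":", 1)[1] for t in rxn.tags if t.startswith("cell:")), "?")
            phase = next((t.split(":", 1)[1] for t in rxn.tags if t.startswith("phase:")), "?")
            if rxn.id not in tissue.linker_index.get("apoplast", []):
                prov = tissue.provenance.get(rxn.id)
                tissue.provenance[rxn.id] = (cell, phase, "apoplast")
                tissue.linker_index.setdefault("apoplast", []).append(rxn.id)
    return tissue


def add_phloem_export(
    tissue: TissueModel,
    sap: SapComposition,
    dark_fraction: float = 1.0 / 3.0,
) -> TissueModel:
    """Fixed-stoichiometry sap export from the petiolar sieve element.

    One export reaction per phase consumes the sap species in their molar
    ratios; a coupling constraint locks the dark rate to ``dark_fraction``
    times the light rate.
    """
    sap.validate()
    if not 0 <= dark_fraction:
        raise ValidationError("dark_fraction must be nonnegative")
    model = tissue.model
    rids = {}
    for phase in PHASES:
        stoich = {}
        for base, coef in sap.coefficients.items():
            mid = f"{base}_c_pSE_{phase}"
            if mid not in model.metabolites:
                raise AssemblyError(f"sap species '{base}' missing from pSE cytosol ({mid})")
            stoich[mid] = -float(coef)
        rid = f"PHLOEM_{phase}"
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=UNBOUNDED,
                tags={"phloem_export", "objective", f"cell:pSE", f"phase:{phase}"},
                name="phloem sap export",
            )
        )
        tissue._register(rid, "pSE", phase, "phloem_export")
        rids[phase] = rid
    tissue.couplings.append(
        Coupling(
            coefficients={rids["d"]: 1.0, rids["l"]: -float(dark_fraction)},
            lower=0.0,
            upper=0.0,
            name="diel_phloem_coupling",
        )
    )
    return tissue


def add_petiole_leak(
    tissue: TissueModel,
    leak_flux: float,
    retrieval_flux: float,
    protons_per_sucrose: float = 1.0,
) -> TissueModel:
    """Sucrose leak from pSE to the petiole apoplast plus proton-coupled retrieval.

    The leak is a fixed flux (lb = ub = ``leak_flux``); retrieval is capped at
    ``retrieval_flux`` and costs ``protons_per_sucrose`` apoplastic protons,
    returned by a pSE plasma-membrane H+-ATPase.
    """
    if leak_flux < 0 or retrieval_flux < 0:
        raise ValidationError("leak and retrieval fluxes must be nonnegative")
    if "pSE" not in tissue.cells:
        raise AssemblyError("petiole leak requires a pSE cell")
    model = tissue.model
    for phase in PHASES:
        comp = f"pet_{phase}"
        model.compartments.setdefault(comp, f"petiole apoplast ({phase})")
        suc_pet = f"suc_{comp}"
        h_pet = f"h_{comp}"
        model.add_metabolite(Metabolite(suc_pet, name="suc", compartment=comp, formula="C12H22O11"))
        model.add_metabolite(Metabolite(h_pet, name="h", compartment=comp, formula="H"))
        h_cyt = f"h_c_pSE_{phase}"
        if h_cyt not in model.metabolites:
            # the pSE cytosolic proton may have been pruned with the vacuole
            # and plasma-membrane machinery; the retrieval/pump pair needs it
            model.add_metabolite(
                Metabolite(h_cyt, name="h", compartment=f"c_pSE_{phase}", formula="H")
            )
        leak_id = f"LEAK_suc_{phase}"
        model.add_reaction(
            Reaction(
                id=leak_id,
                stoichiometry={f"suc_c_pSE_{phase}": -1.0, suc_pet: 1.0},
                lower_bound=leak_flux,
                upper_bound=leak_flux,
                tags={"leak", "cell:pSE", f"phase:{phase}"},
                name="sucrose leak",
            )
        )
        tissue._register(leak_id, "pSE", phase, "leak")
        ret_id = f"RET_suc_{phase}"
        model.add_reaction(
            Reaction(
                id=ret_id,
                stoichiometry={
                    suc_pet: -1.0,
                    h_pet: -protons_per_sucrose,
                    f"suc_c_pSE_{phase}": 1.0,
                    f"h_c_pSE_{phase}": protons_per_sucrose,
                },
                lower_bound=0.0,
                upper_bound=retrieval_flux,
                tags={"retrieval", "cell:pSE", f"phase:{phase}"},
                name="sucrose retrieval",
            )
        )
        tissue._register(ret_id, "pSE", phase, "retrieval")
        pump_id = f"PM_ATPASE_pSE_{phase}"
        model.add_reaction(
            Reaction(
                id=pump_id,
                stoichiometry={
                    f"atp_c_pSE_{phase}": -1.0,
                    f"h_c_pSE_{phase}": -1.0,
                    f"adp_c_pSE_{phase}": 1.0,
                    f"pi_c_pSE_{phase}": 1.0,
                    h_pet: 1.0,
                },
                lower_bound=0.0,
                upper_bound=UNBOUNDED,
                tags={"pm_pump", "atpase_pm", "cell:pSE", f"phase:{phase}"},
                name="pSE plasma-membrane H+-ATPase",
            )
        )
        tissue._register(pump_id, "pSE", phase, "retrieval")
    return tissue


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def assemble_tissue(
    core: MetabolicModel,
    cell_specs: Optional[List[CellSpec]] = None,
    accumulables: Sequence[str] = ("starch", "suc", "no3", "mal", "glu", "his", "lys"),
    transported: Optional[Set[str]] = None,
    sap: Optional[SapComposition] = None,
    dark_fraction: float = 1.0 / 3.0,
    symplast_excluded: Optional[Set[str]] = None,
    nucleotide_oneway: Optional[Set[str]] = None,
    leak_flux: float = 0.005,
    retrieval_flux: float = 0.005,
) -> TissueModel:
    """Build the full tissue model from a core cell model.

    Defaults mirror the study system: MC/CC/SE/pSE cells, accumulation of
    starch, sucrose, nitrate, malate and amino acids, a 9:1
    sucrose:amino-acid sap, and a dark phloem rate of one third of the light
    rate.
    """
    if cell_specs is None:
        cell_specs = default_cell_specs()
    if transported is None:
        transported = {"suc", "glc", "fru", "glu", "his", "lys", "h"}
    if sap is None:
        sap = SapComposition({"suc": 9.0, "glu": 0.5, "his": 0.25, "lys": 0.25})

    merged = MetabolicModel(id=f"{core.id}_tissue")
    merged.annotations["core_model"] = core.id
    tissue = TissueModel(model=merged, cell_specs=cell_specs)
    for spec in cell_specs:
        cell_model = build_diel_cell(core, spec, accumulables)
        merged.compartments.update(cell_model.compartments)
        for met in cell_model.metabolites.values():
            merged.add_metabolite(met)
        for rxn in cell_model.reactions.values():
            merged.add_reaction(rxn)
    # provenance for core-derived and accumulation reactions
    for rxn in merged.reactions.values():
        cell = next((t.split(":", 1)[1] for t in rxn.tags if t.startswith("cell:")), "?")
        phase = next((t.split(":", 1)[1] for t in rxn.tags if t.startswith("phase:")), "both")
        if "accumulation" in rxn.tags:
            tissue._register(rxn.id, cell, phase, "accumulation")
        else:
            tissue.provenance[rxn.id] = (cell, phase, "core")

    build_symplast_linkers(tissue, core, symplast_excluded, nucleotide_oneway)
    build_apoplast(tissue, core, transported)
    add_phloem_export(tissue, sap, dark_fraction)
    add_petiole_leak(tissue, leak_flux, retrieval_flux)
    merged.validate()
    return tissue


def linker_table(tissue: TissueModel):
    """The linker index as a tidy table (reaction id, kind, cells, phase)."""
    import pandas as pd

    rows = []
    for kind, rids in tissue.linker_index.items():
        for rid in rids:
            cell, phase, _ = tissue.provenance[rid]
            rows.append(
                {
                    "reaction": rid,
                    "kind": kind,
                    "cells": cell,
                    "phase": phase,
                    "metabolite": tissue.model.reactions[rid].name,
                }
            )
    return pd.DataFrame(rows, columns=["reaction", "kind", "cells", "phase", "metabolite"])
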