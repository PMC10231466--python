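"""Summary quantities of a flux solution: energy budgets, proton-pump
shares, phloem carbon export fraction, transport tables and per-cell
amino-acid synthesis.

All accounting is a pure function of (solution, tissue): identical inputs
give identical tables.  Budgets rely on steady state — for every currency
species, flux-weighted production equals consumption — so production shares
are well defined.  "Per cell basis" comparisons divide leaf-area fluxes by
the cell-type ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .constraint_engine import CellRatios
from .solver_suite import FluxSolution
from .tissue_assembler import TissueModel

#: reactions below this flux are excluded from report tables (µmol m⁻² s⁻¹)
REPORT_FLUX_THRESHOLD = 0.005

CURRENCY_SPECIES = {
    "ATP": "atp",
    "NADH": "nadh",
    "NADPH": "nadph",
    "PPi": "ppi",
}


class AccountingError(ValueError):
    """Unknown currency or missing tags for an accounting operation."""


@dataclass
class EnergyBudget:
    """Flux-weighted production/consumption of one energy currency in one
    cell and phase, with producer shares of total production."""

    currency: str
    cell: str
    phase: str
    producers: Dict[str, float] = field(default_factory=dict)
    consumers: Dict[str, float] = field(default_factory=dict)
    transfers: Dict[str, float] = field(default_factory=dict)

    @property
    def total_production(self) -> float:
        return sum(self.producers.values())

    @property
    def total_consumption(self) -> float:
        return sum(self.consumers.values())

    @property
    def shares(self) -> Dict[str, float]:
        total = self.total_production
        if total <= 0:
            return {}
        return {rid: flux / total for rid, flux in self.producers.items()}

    @property
    def imbalance(self) -> float:
        return abs(self.total_production - self.total_consumption)


@dataclass
class TransportTable:
    """Linker fluxes (apoplast and symplast) per metabolite and phase."""

    frame: pd.DataFrame


def _currency_species_ids(tissue: TissueModel, base: str, cell: str, phase: str) -> List[str]:
    suffix = f"_{cell}_{phase}"
    return [
        mid
        for mid, met in tissue.model.metabolites.items()
        if met.name == base and met.compartment.endswith(suffix)
    ]


def energy_budget(
    solution: FluxSolution,
    tissue: TissueModel,
    cell: str,
    phase: str,
    currency: str,
) -> EnergyBudget:
    """Classify every reaction touching the currency in this cell/phase.

    A reaction's contribution is its net flux-weighted currency turnover
    summed over the cell's compartments; net producers and consumers make up
    the budget, while reactions that only move the currency between
    compartments (e.g. the adenine nucleotide translocator) are reported as
    transfers.  Counts the named species only (no ATP-equivalents).
    """
    if currency not in CURRENCY_SPECIES:
        raise AccountingError(f"unknown energy currency {currency}")
    species = _currency_species_ids(tissue, CURRENCY_SPECIES[currency], cell, phase)
    if not species:
        raise AccountingError(f"no {currency} species found in {cell} ({phase})")
    species_set = set(species)
    budget = EnergyBudget(currency=currency, cell=cell, phase=phase)
    for rid, flux in solution.v.items():
        if abs(flux) < 1e-12:
            continue
        stoich = tissue.model.reactions[rid].stoichiometry
        touched = species_set & stoich.keys()
        if not touched:
            continue
        net = sum(stoich[mid] for mid in touched) * flux
        if net > 1e-12:
            budget.producers[rid] = net
        elif net < -1e-12:
            budget.consumers[rid] = -net
        else:
            budget.transfers[rid] = abs(flux)
    return budget


def pump_share(
    solution: FluxSolution, tissue: TissueModel, cell: str
) -> Dict[str, Dict[str, float]]:
    """Proton export by the plasma-membrane H+-ATPase vs H+-PPiase, per phase.

    Returns proton fluxes, fractional shares and the ATPase:PPiase ratio.
    """
    for tag in ("atpase_pm", "ppiase_pm"):
        if not tissue.reactions_of(cell=cell, tag=tag):
            raise AccountingError(f"no {tag} reaction tagged in {cell}")
    out: Dict[str, Dict[str, float]] = {}
    for phase in ("l", "d"):
        flows = {}
        for label, tag in (("atpase", "atpase_pm"), ("ppiase", "ppiase_pm")):
            total = 0.0
            for rid in tissue.reactions_of(cell=cell, phase=phase, tag=tag):
                stoich = tissue.model.reactions[rid].stoichiometry
                exported = sum(
                    coef
                    for mid, coef in stoich.items()
                    if tissue.model.metabolites[mid].name == "h" and coef > 0
                )
                total += exported * solution.v.get(rid, 0.0)
            flows[label] = total
        pumped = flows["atpase"] + flows["ppiase"]
        out[phase] = {
            "atpase_protons": flows["atpase"],
            "ppiase_protons": flows["ppiase"],
            "atpase_share": flows["atpase"] / pumped if pumped > 0 else 0.0,
            "ppiase_share": flows["ppiase"] / pumped if pumped > 0 else 0.0,
            "atpase_to_ppiase": (
                flows["atpase"] / flows["ppiase"] if flows["ppiase"] > 0 else float("inf")
            ),
        }
    return out


def phloem_carbon_fraction(solution: FluxSolution, tissue: TissueModel) -> float:
    """Fraction of mesophyll-fixed carbon exported in the phloem sap.

    Carbon atoms per unit export flux come from the sap species' formulas;
    fixed carbon is the CO2 consumed by mesophyll Rubisco, summed over both
    phases.  Values slightly above 1 can only arise from stored-carbon
    release.
    """
    model = tissue.model
    exported = 0.0
    for rid in tissue.linker_index.get("phloem_export", []):
        flux = solution.v.get(rid, 0.0)
        carbon = sum(
            -coef * model.metabolites[mid].carbon_count()
            for mid, coef in model.reactions[rid].stoichiometry.items()
            if coef < 0
        )
        exported += carbon * flux
    fixed = 0.0
    for rid in tissue.reactions_of(cell="MC", tag="rubisco"):
        flux = solution.v.get(rid, 0.0)
        co2_in = sum(
            -coef
            for mid, coef in model.reactions[rid].stoichiometry.items()
            if model.metabolites[mid].name == "co2" and coef < 0
        )
        fixed += co2_in * flux
    if fixed <= 0:
        return 0.0
    return exported / fixed


def transport_summary(
    solution: FluxSolution,
    tissue: TissueModel,
    threshold: float = REPORT_FLUX_THRESHOLD,
) -> TransportTable:
    """Net linker fluxes per metabolite, route and phase.

    Positive flux follows the reaction's forward direction (MC→apoplast,
    apoplast→CC for symporters, upstream→downstream for symplast linkers).
    Rows below the reporting threshold are dropped.
    """
    rows = []
    for kind in ("apoplast", "symplast"):
        for rid in tissue.linker_index.get(kind, []):
            flux = solution.v.get(rid, 0.0)
            if abs(flux) < threshold:
                continue
            cell, phase, _ = tissue.provenance[rid]
            rows.append(
                {
                    "reaction": rid,
                    "kind": kind,
                    "metabolite": tissue.model.reactions[rid].name,
                    "route": cell,
                    "phase": phase,
                    "flux": flux,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["reaction", "kind", "metabolite", "route", "phase", "flux"]
    )
    return TransportTable(frame=frame)


def amino_acid_synthesis_by_cell(
    solution: FluxSolution,
    tissue: TissueModel,
    ratios: Optional[CellRatios] = None,
) -> pd.DataFrame:
    """Net amino-acid synthesis per cell and compartment, light and dark.

    The scaled column divides the leaf-area flux by the cell ratio so the
    activity of individual cells is comparable.
    """
    ratios = ratios or CellRatios()
    model = tissue.model
    rows = []
    for rid, rxn in model.reactions.items():
        aa_tags = [t for t in rxn.tags if t.startswith("aa_synth:")]
        if not aa_tags:
            continue
        cell, phase, _ = tissue.provenance.get(rid, ("?", "?", "?"))
        flux = solution.v.get(rid, 0.0)
        aa = aa_tags[0].split(":", 1)[1]
        produced = sum(
            coef * flux
            for mid, coef in rxn.stoichiometry.items()
            if model.metabolites[mid].name == aa and coef > 0
        )
        compartment = next(
            (
                model.metabolites[mid].compartment.split("_")[0]
                for mid, coef in rxn.stoichiometry.items()
                if model.metabolites[mid].name == aa
            ),
            "?",
        )
        scale = ratios[cell] if cell in ratios.ratios else 1.0
        rows.append(
            {
                "amino_acid": aa,
                "cell": cell,
                "compartment": compartment,
                "phase": phase,
                "raw_flux": produced,
                "scaled_flux": produced / scale,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["amino_acid", "cell", "compartment", "phase", "raw_flux", "scaled_flux"],
    )


def budget_table(budget: EnergyBudget) -> pd.DataFrame:
    rows = []
    for role, entries in (
        ("producer", budget.producers),
        ("consumer", budget.consumers),
        ("transfer", budget.transfers),
    ):
        for rid, value in sorted(entries.items(), key=lambda kv: -kv[1]):
            rows.append(
                {
                    "currency": budget.currency,
                    "cell": budget.cell,
                    "phase": budget.phase,
                    "reaction": rid,
                    "role": role,
                    "turnover": value,
                    "share": (
                        value / budget.total_production
                        if role == "producer" and budget.total_production > 0
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["currency", "cell", "phase", "reaction", "role", "turnover", "share"],
    )
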