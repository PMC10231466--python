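"""Energy budgets, pump shares, carbon export fraction, transport tables."""

import pytest

import phloemflux as pf
from phloemflux.flux_accounting import (
    AccountingError,
    budget_table,
    energy_budget,
    phloem_carbon_fraction,
    pump_share,
    transport_summary,
)
from phloemflux.metnet_core import MetabolicModel, Metabolite, Reaction
from phloemflux.solver_suite import FluxSolution, parsimonious_solve
from phloemflux.tissue_assembler import TissueModel

from conftest import make_mini_tissue


def fixed_flux_solution(fluxes):
    return FluxSolution(v=dict(fluxes), objective_ledger=[("phloem_light", 0.0)])


class TestEnergyBudget:
    def test_single_source_share_is_one(self):
        t = make_mini_tissue(
            [("atp_c_CC_l", "atp", "c_CC_l"), ("adp_c_CC_l", "adp", "c_CC_l")],
            [
                ("GEN", {"adp_c_CC_l": -1, "atp_c_CC_l": 1}, 0, 10, [], "CC", "l"),
                ("USE", {"atp_c_CC_l": -1, "adp_c_CC_l": 1}, 0, 10, [], "CC", "l"),
            ],
        )
        sol = fixed_flux_solution({"GEN": 2.0, "USE": 2.0})
        budget = energy_budget(sol, t, "CC", "l", "ATP")
        assert budget.shares == {"GEN": pytest.approx(1.0)}
        assert budget.imbalance <= 1e-8

    def test_plastid_synthase_supplying_two_thirds_reports_667(self):
        """Constructed budget: plastid ATP synthase 2/3, mitochondrial 1/3."""
        t = make_mini_tissue(
            [
                ("atp_p_CC_l", "atp", "p_CC_l"),
                ("adp_p_CC_l", "adp", "p_CC_l"),
                ("atp_m_CC_l", "atp", "m_CC_l"),
                ("adp_m_CC_l", "adp", "m_CC_l"),
            ],
            [
                ("ATPS_P", {"adp_p_CC_l": -1, "atp_p_CC_l": 1}, 0, 10,
                 ["atp_synthase_plastid"], "CC", "l"),
                ("ATPS_M", {"adp_m_CC_l": -1, "atp_m_CC_l": 1}, 0, 10,
                 ["atp_synthase_mito"], "CC", "l"),
                ("USE_P", {"atp_p_CC_l": -1, "adp_p_CC_l": 1}, 0, 10, [], "CC", "l"),
                ("USE_M", {"atp_m_CC_l": -1, "adp_m_CC_l": 1}, 0, 10, [], "CC", "l"),
            ],
        )
        sol = fixed_flux_solution({"ATPS_P": 2.0, "ATPS_M": 1.0, "USE_P": 2.0, "USE_M": 1.0})
        budget = energy_budget(sol, t, "CC", "l", "ATP")
        assert budget.shares["ATPS_P"] == pytest.approx(2 / 3, abs=1e-9)
        assert budget.total_production == pytest.approx(3.0)

    def test_transfer_reactions_excluded_from_shares(self):
        t = make_mini_tissue(
            [
                ("atp_c_CC_l", "atp", "c_CC_l"),
                ("adp_c_CC_l", "adp", "c_CC_l"),
                ("atp_m_CC_l", "atp", "m_CC_l"),
                ("adp_m_CC_l", "adp", "m_CC_l"),
            ],
            [
                ("GEN", {"adp_m_CC_l": -1, "atp_m_CC_l": 1}, 0, 10, [], "CC", "l"),
                ("ANT", {"atp_m_CC_l": -1, "adp_c_CC_l": -1,
                         "atp_c_CC_l": 1, "adp_m_CC_l": 1}, -10, 10, [], "CC", "l"),
                ("USE", {"atp_c_CC_l": -1, "adp_c_CC_l": 1}, 0, 10, [], "CC", "l"),
            ],
        )
        sol = fixed_flux_solution({"GEN": 1.0, "ANT": 1.0, "USE": 1.0})
        budget = energy_budget(sol, t, "CC", "l", "ATP")
        assert "ANT" in budget.transfers
        assert budget.shares == {"GEN": pytest.approx(1.0)}

    def test_all_budgets_balance_on_fixture(self, tissue, pfba_solution):
        for cell in tissue.cells:
            for phase in ("l", "d"):
                for currency in ("ATP", "NADH", "PPi"):
                    try:
                        budget = energy_budget(pfba_solution, tissue, cell, phase, currency)
                    except AccountingError:
                        continue  # currency absent from this stripped cell
                    assert budget.imbalance <= 1e-8, (cell, phase, currency)

    def test_unknown_currency_raises(self, tissue, pfba_solution):
        with pytest.raises(AccountingError):
            energy_budget(pfba_solution, tissue, "CC", "l", "GTP")

    def test_budget_table_shares_sum_to_one(self, tissue, pfba_solution):
        budget = energy_budget(pfba_solution, tissue, "CC", "l", "ATP")
        table = budget_table(budget)
        producers = table[table.role == "producer"]
        assert producers["share"].sum() == pytest.approx(1.0)


class TestPumpShare:
    def test_fixed_ppi_supply_gives_one_to_nine_ratio(self):
        """PPi supply pinned at 0.9 of a unit proton demand: ATPase covers
        the remaining 0.1, so ATPase:PPiase = 1:9."""
        t = make_mini_tissue(
            [
                ("h_c_CC_l", "h", "c_CC_l"),
                ("h_apo_l", "h", "apo_l"),
                ("atp_c_CC_l", "atp", "c_CC_l"),
                ("adp_c_CC_l", "adp", "c_CC_l"),
                ("ppi_c_CC_l", "ppi", "c_CC_l"),
                ("X_c_CC_l", "X", "c_CC_l"),
            ],
            [
                ("PPI_SRC", {"ppi_c_CC_l": 1}, 0.9, 0.9, [], "CC", "l"),
                ("ATP_SRC", {"adp_c_CC_l": -1, "atp_c_CC_l": 1}, 0, 10, [], "CC", "l"),
                ("ATPASE", {"atp_c_CC_l": -1, "h_c_CC_l": -1, "adp_c_CC_l": 1,
                            "h_apo_l": 1}, 0, 10, ["pm_pump", "atpase_pm"], "CC", "l"),
                ("PPIASE", {"ppi_c_CC_l": -1, "h_c_CC_l": -1, "h_apo_l": 1}, 0, 10,
                 ["pm_pump", "ppiase_pm"], "CC", "l"),
                ("IMPORT", {"h_apo_l": -1, "h_c_CC_l": 1, "X_c_CC_l": 1}, 1.0, 1.0,
                 [], "CC", "l"),
                ("X_SINK", {"X_c_CC_l": -1}, 0, 10, ["exchange"], "CC", "l"),
                ("ATPASE_D", {"atp_c_CC_l": -1, "h_c_CC_l": -1, "adp_c_CC_l": 1,
                              "h_apo_l": 1}, 0, 0, ["pm_pump", "atpase_pm"], "CC", "d"),
                ("PPIASE_D", {"ppi_c_CC_l": -1, "h_c_CC_l": -1, "h_apo_l": 1}, 0, 0,
                 ["pm_pump", "ppiase_pm"], "CC", "d"),
            ],
        )
        sol = fixed_flux_solution(
            {"PPI_SRC": 0.9, "ATP_SRC": 0.1, "ATPASE": 0.1, "PPIASE": 0.9, "IMPORT": 1.0}
        )
        share = pump_share(sol, t, "CC")["l"]
        assert share["atpase_to_ppiase"] == pytest.approx(1 / 9, abs=1e-9)
        assert share["atpase_share"] + share["ppiase_share"] == pytest.approx(1.0)

    def test_zero_ppiase_gives_full_atpase_share(self, tissue_copy):
        for rid in tissue_copy.reactions_of(tag="ppiase_pm"):
            tissue_copy.model.reactions[rid].upper_bound = 0.0
        sol = parsimonious_solve(tissue_copy)
        assert sol.optimal
        for phase, share in pump_share(sol, tissue_copy, "CC").items():
            if share["atpase_protons"] > 0:
                assert share["atpase_share"] == pytest.approx(1.0)

    def test_ppiase_preferred_on_fixture(self, tissue, pfba_solution):
        shares = pump_share(pfba_solution, tissue, "CC")
        total_ppiase = sum(s["ppiase_protons"] for s in shares.values())
        total_atpase = sum(s["atpase_protons"] for s in shares.values())
        assert total_ppiase > total_atpase


class TestCarbonFraction:
    def test_zero_export_gives_zero(self, tissue):
        sol = FluxSolution(v={rid: 0.0 for rid in tissue.model.reactions})
        assert phloem_carbon_fraction(sol, tissue) == 0.0

    def test_quarter_respired_gives_three_quarters(self):
        """Atom-count oracle: fix 4 CO2 into a C4 pool, export 3 C, respire 1."""
        model = MetabolicModel(id="carbon")
        model.add_metabolite(Metabolite("co2_p_MC_l", name="co2", compartment="p_MC_l",
                                        formula="CO2"))
        model.add_metabolite(Metabolite("sugar_c_pSE_l", name="sugar",
                                        compartment="c_pSE_l", formula="C3H6O3"))
        t = TissueModel(model=model, cell_specs=[])
        model.add_reaction(Reaction("FIX", {"co2_p_MC_l": -4, "sugar_c_pSE_l": 4 / 3},
                                    0, 10, tags={"rubisco"}))
        model.add_reaction(Reaction("RESP", {"sugar_c_pSE_l": -1 / 3, "co2_p_MC_l": 1},
                                    0, 10, tags={"tca"}))
        model.add_reaction(Reaction("EXPORT", {"sugar_c_pSE_l": -1}, 0, 10,
                                    tags={"phloem_export", "objective"}))
        t._register("FIX", "MC", "l", "core")
        t._register("RESP", "pSE", "l", "core")
        t._register("EXPORT", "pSE", "l", "phloem_export")
        sol = fixed_flux_solution({"FIX": 1.0, "RESP": 1.0, "EXPORT": 1.0})
        assert phloem_carbon_fraction(sol, t) == pytest.approx(0.75)

    def test_fixture_fraction_in_unit_interval(self, tissue, pfba_solution):
        frac = phloem_carbon_fraction(pfba_solution, tissue)
        assert 0.0 < frac <= 1.0 + 1e-6


class TestTransportSummary:
    def test_no_apoplastic_amino_acid_flux_toward_mesophyll(self, tissue, pfba_solution):
        table = transport_summary(pfba_solution, tissue, threshold=0.0).frame
        aa_rows = table[
            (table.kind == "apoplast") & table.metabolite.isin(["glu", "his", "lys"])
        ]
        for _, row in aa_rows.iterrows():
            # MC rows are effluxes (flux >= 0 means MC -> apoplast); CC rows
            # are symporters (flux >= 0 means apoplast -> CC)
            assert row.flux >= -1e-9

    def test_threshold_filters_rows(self, tissue, pfba_solution):
        full = transport_summary(pfba_solution, tissue, threshold=0.0).frame
        cut = transport_summary(pfba_solution, tissue, threshold=0.05).frame
        assert len(cut) <= len(full)
        assert (cut.flux.abs() >= 0.05).all()

    def test_symplast_sucrose_mass_balance(self, tissue, pfba_solution):
        """Sucrose entering SE via the symplast equals SE consumption plus
        onward transfer to pSE plus storage (mass-balance oracle)."""
        v = pfba_solution.v
        inflow = v["SYM_suc_CC_SE_l"]
        onward = v["SYM_suc_SE_pSE_l"]
        consumed = sum(
            -tissue.model.reactions[rid].stoichiometry.get("suc_c_SE_l", 0) * v[rid]
            for rid in tissue.reactions_of(cell="SE", phase="l")
            if "suc_c_SE_l" in tissue.model.reactions[rid].stoichiometry
        )
        assert inflow == pytest.approx(onward + consumed, abs=1e-8)


class TestAminoAcidSynthesis:
    def test_scaled_entry_divides_by_cell_ratio(self, tissue, pfba_solution, ratios):
        table = pf.amino_acid_synthesis_by_cell(pfba_solution, tissue, ratios)
        mc = table[(table.cell == "MC")]
        for _, row in mc.iterrows():
            assert row.scaled_flux == pytest.approx(row.raw_flux / 20.0)

    def test_total_synthesis_covers_export_and_turnover(self, tissue, pfba_solution):
        """Diel amino-acid production balances sap export plus the protein
        turnover drain (no other sinks exist)."""
        table = pf.amino_acid_synthesis_by_cell(pfba_solution, tissue)
        v = pfba_solution.v
        for aa, coef in [("glu", 0.5), ("his", 0.25), ("lys", 0.25)]:
            produced = table[table.amino_acid == aa].raw_flux.sum()
            if aa == "glu":
                # glutamate can also be catabolized
                produced -= sum(
                    v[rid] for rid in tissue.model.reactions
                    if rid.startswith("GLU_CATAB")
                )
            exported = coef * (v["PHLOEM_l"] + v["PHLOEM_d"])
            turnover = 0.05 * sum(
                v[rid] for rid in tissue.model.reactions
                if rid.startswith("PROT_TURNOVER")
            )
            assert produced == pytest.approx(exported + turnover, abs=1e-7)
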