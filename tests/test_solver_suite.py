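"""Parsimonious FBA, FVA, knockouts, scenarios — with brute-force LP oracles."""

import hashlib
import json

import numpy as np
import pytest

import phloemflux as pf
from phloemflux.solver_suite import (
    ScanError,
    ScenarioError,
    Scenario,
    TissueLP,
    _h_objective,
    check_steady_state,
    fva,
    knockout_scan,
    named_scenarios,
    parsimonious_solve,
    resolve_selector,
    run_scenario,
)

from conftest import enumerate_vertices, make_mini_tissue


def toy_with_futile_cycle():
    """src -> A -> export, plus a parallel A<->B futile pair."""
    return make_mini_tissue(
        [("A", "A", "c"), ("B", "B", "c")],
        [
            ("SRC", {"A": 1}, 0, 10, [], "MC", "l"),
            ("EXP", {"A": -1}, 0, 1, [], "pSE", "l"),
            ("W1", {"A": -1, "B": 1}, 0, 10, [], "MC", "l"),
            ("W2", {"B": -1, "A": 1}, 0, 10, [], "MC", "l"),
        ],
        phloem_id="EXP",
    )


class TestParsimoniousSolve:
    def test_futile_cycle_carries_no_flux(self):
        tissue = toy_with_futile_cycle()
        sol = parsimonious_solve(tissue)
        assert sol.optimal
        assert sol.v["EXP"] == pytest.approx(1.0)
        assert sol.v["W1"] == pytest.approx(0.0, abs=1e-9)
        assert sol.v["W2"] == pytest.approx(0.0, abs=1e-9)

    def test_removing_export_gives_zero_objective(self):
        tissue = toy_with_futile_cycle()
        tissue.model.reactions["EXP"].upper_bound = 0.0
        sol = parsimonious_solve(tissue)
        assert sol.objective("phloem_light") == pytest.approx(0.0, abs=1e-12)

    def test_flux_sum_matches_vertex_oracle(self):
        """Among all vertices with maximal export, pFBA finds the minimal
        total absolute flux (exhaustive enumeration)."""
        tissue = toy_with_futile_cycle()
        sol = parsimonious_solve(tissue)
        model = tissue.model
        S, mets, rxns = model.stoichiometric_matrix()
        lb = [model.reactions[r].lower_bound for r in rxns]
        ub = [model.reactions[r].upper_bound for r in rxns]
        verts = enumerate_vertices(S.toarray(), lb, ub)
        assert verts
        j = rxns.index("EXP")
        best_export = max(v[j] for v in verts)
        assert sol.objective("phloem_light") == pytest.approx(best_export)
        oracle_g = min(np.abs(v).sum() for v in verts if v[j] >= best_export - 1e-9)
        assert sol.objective("flux_sum") == pytest.approx(oracle_g, abs=1e-7)

    def test_fixture_solution_respects_steady_state_and_bounds(
        self, tissue, pfba_solution
    ):
        residual, violation = check_steady_state(pfba_solution, tissue)
        assert residual <= 1e-8
        assert violation <= 1e-9

    def test_infeasibility_reported_with_forced_bounds(self):
        tissue = toy_with_futile_cycle()
        tissue.model.reactions["EXP"].lower_bound = 5.0  # forced above supply
        tissue.model.reactions["EXP"].upper_bound = 5.0
        tissue.model.reactions["SRC"].upper_bound = 1.0
        sol = parsimonious_solve(tissue)
        assert sol.status == "infeasible"
        assert "EXP" in sol.message


class TestLexicographicOracle:
    def test_weighted_stages_match_vertex_enumeration(self):
        """On a 4-reaction toy with saturating transcript targets, the
        hierarchical (H, then G) optimum coincides with the best vertex."""
        tissue = make_mini_tissue(
            [("A", "A", "c"), ("B", "B", "c")],
            [
                ("SRC", {"A": 1}, 0, 4, [], "MC", "l"),
                ("R1", {"A": -1, "B": 1}, 0, 4, [], "MC", "l"),
                ("R2", {"A": -1, "B": 1}, 0, 4, [], "MC", "l"),
                ("EXP", {"B": -1}, 0, 2, [], "pSE", "l"),
            ],
            phloem_id="EXP",
        )
        lp = TissueLP(tissue)
        lp.add_flux_min({"EXP": 1.0}, 2.0)  # phloem pinned at its maximum
        # targets beyond reachable range, so distance decreases monotonically
        # in activity and the optimum sits on a vertex
        terms = [(5.0, ["R1"]), (0.0, ["R2"])]
        h_obj = _h_objective(lp, terms)
        status, x, h_star = lp.solve(h_obj, sense="min")
        assert status == "optimal"
        lp.add_ub(h_obj, h_star + 1e-9)
        status, x, g_star = lp.solve(lp.flux_sum_objective(), sense="min")
        v = lp.fluxes(x)

        model = tissue.model
        S, mets, rxns = model.stoichiometric_matrix()
        lb = [model.reactions[r].lower_bound for r in rxns]
        ub = [2.0 if r == "EXP" else model.reactions[r].upper_bound for r in rxns]
        lb = [2.0 if r == "EXP" else b for r, b in zip(rxns, lb)]
        verts = enumerate_vertices(S.toarray(), lb, ub)

        def h_of(vert):
            by = dict(zip(rxns, vert))
            return sum(abs(t - sum(abs(by[r]) for r in members)) for t, members in terms)

        h_min = min(h_of(w) for w in verts)
        assert h_star == pytest.approx(h_min, abs=1e-8)
        best = min(
            (w for w in verts if h_of(w) <= h_min + 1e-8),
            key=lambda w: np.abs(w).sum(),
        )
        assert g_star == pytest.approx(np.abs(best).sum(), abs=1e-8)
        for rid, val in zip(rxns, best):
            assert v[rid] == pytest.approx(val, abs=1e-7)


class TestFVA:
    def test_uniquely_determined_reaction_collapses(self):
        tissue = make_mini_tissue(
            [("A", "A", "c")],
            [
                ("SRC", {"A": 1}, 0, 10, [], "MC", "l"),
                ("EXP", {"A": -1}, 0, 1, [], "pSE", "l"),
            ],
            phloem_id="EXP",
        )
        sol = parsimonious_solve(tissue)
        res = fva(tissue, sol.objective_ledger, reactions=["SRC", "EXP"])
        for rid in ("SRC", "EXP"):
            lo, hi = res.ranges[rid]
            # widths shrink to the objective-fixing tolerance
            assert res.is_unique(rid, tol=2e-6)
            assert lo - 2e-6 <= sol.v[rid] <= hi + 2e-6

    def test_parallel_pathways_share_total_by_symmetry(self):
        tissue = make_mini_tissue(
            [("A", "A", "c"), ("B", "B", "c")],
            [
                ("SRC", {"A": 1}, 0, 10, [], "MC", "l"),
                ("P1", {"A": -1, "B": 1}, 0, 10, [], "MC", "l"),
                ("P2", {"A": -1, "B": 1}, 0, 10, [], "MC", "l"),
                ("EXP", {"B": -1}, 0, 2, [], "pSE", "l"),
            ],
            phloem_id="EXP",
        )
        sol = parsimonious_solve(tissue)
        res = fva(tissue, sol.objective_ledger, reactions=["P1", "P2"])
        for rid in ("P1", "P2"):
            lo, hi = res.ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-7)
            assert hi == pytest.approx(2.0, abs=1e-6)

    def test_intervals_contain_reported_solution(self, tissue, pfba_solution):
        some = list(tissue.linker_index["phloem_export"]) + [
            "PM_PPIASE_CC_l",
            "PM_PPIASE_CC_d",
            "SUC_SYMPORT_CC_l",
            "CBB_MC_l",
        ]
        res = fva(tissue, pfba_solution.objective_ledger, reactions=some)
        assert not res.failures
        for rid in some:
            lo, hi = res.ranges[rid]
            assert lo - 1e-6 <= pfba_solution.v[rid] <= hi + 1e-6

    def test_unknown_reaction_recorded_not_fatal(self, tissue, pfba_solution):
        res = fva(tissue, pfba_solution.objective_ledger, reactions=["NOPE"])
        assert "NOPE" in res.failures


class TestKnockouts:
    def test_unused_reaction_knockout_leaves_rate(self, tissue, pfba_solution):
        # starch synthesis in pSE carries no flux in the parsimonious solution
        rid = "STARCH_SYNTH_pSE_l"
        assert abs(pfba_solution.v[rid]) < 1e-9
        res = knockout_scan(tissue, {"noop": [rid]})
        assert res["noop"]["status"] == "optimal"
        assert res["noop"]["phloem_light"] == pytest.approx(
            pfba_solution.objective("phloem_light"), rel=1e-6
        )

    def test_knocking_out_sole_atp_supply_is_infeasible(self):
        tissue = make_mini_tissue(
            [("ATP", "atp", "c"), ("ADP", "adp", "c")],
            [
                ("GEN", {"ADP": -1, "ATP": 1}, 0, 10, [], "MC", "l"),
                ("MAINT", {"ATP": -1, "ADP": 1}, 0.5, 10, ["maintenance"], "MC", "l"),
                ("EXP", {}, 0, 1, ["exchange"], "pSE", "l"),
            ],
            phloem_id="EXP",
        )
        res = knockout_scan(tissue, {"gen": ["GEN"]})
        assert res["gen"]["status"] == "infeasible"

    def test_bounds_restored_after_scan(self, tissue):
        before = {
            rid: (r.lower_bound, r.upper_bound)
            for rid, r in tissue.model.reactions.items()
        }
        knockout_scan(tissue, {"g": ["PM_PPIASE_CC_l", "AK_C_CC_d"]})
        after = {
            rid: (r.lower_bound, r.upper_bound)
            for rid, r in tissue.model.reactions.items()
        }
        assert before == after

    def test_unknown_group_member_raises(self, tissue):
        with pytest.raises(ScanError):
            knockout_scan(tissue, {"bad": ["NOT_THERE"]})

    def test_adenylate_kinase_double_knockout_infeasible_single_not(self, tissue):
        """Mitochondrial+cytosolic adenylate kinase loss is lethal per phloem
        cell; either alone is rerouted."""
        for cell in ("CC", "SE"):
            ak_c = tissue.reactions_of(cell=cell, tag="ak_c")
            ak_m = tissue.reactions_of(cell=cell, tag="ak_m")
            res = knockout_scan(
                tissue,
                {"c": ak_c, "m": ak_m, "cm": ak_c + ak_m},
            )
            assert res["c"]["status"] == "optimal"
            assert res["m"]["status"] == "optimal"
            assert res["cm"]["status"] == "infeasible"


class TestScenarios:
    def test_selector_resolution(self, tissue):
        assert resolve_selector(tissue, "PHLOEM_l") == ["PHLOEM_l"]
        rids = resolve_selector(tissue, "tag:ppiase_pm,cell:CC")
        assert rids and all("CC" in r for r in rids)
        with pytest.raises(ScenarioError):
            resolve_selector(tissue, "tag:not_a_tag")

    def test_empty_scenario_identical_solution(self, tissue, pfba_solution):
        rep = run_scenario(tissue, Scenario("noop", []))
        assert rep["phloem_after"] == pytest.approx(rep["phloem_before"], rel=1e-9)
        assert rep["flux_deltas"] == {}

    def test_edits_are_reversible(self, tissue):
        digest_before = hashlib.sha256(
            json.dumps(
                {rid: (r.lower_bound, r.upper_bound) for rid, r in sorted(tissue.model.reactions.items())},
                sort_keys=True,
            ).encode()
        ).hexdigest()
        run_scenario(tissue, named_scenarios()["ppiase_cap_10pct"])
        digest_after = hashlib.sha256(
            json.dumps(
                {rid: (r.lower_bound, r.upper_bound) for rid, r in sorted(tissue.model.reactions.items())},
                sort_keys=True,
            ).encode()
        ).hexdigest()
        assert digest_before == digest_after

    def test_scale_bound_caps_flux(self, tissue, pfba_solution):
        scenario = Scenario("cap", [("tag:rubisco,cell:MC,phase:l", "scale_bound", 0.9)])
        rep = run_scenario(tissue, scenario)
        assert rep["edited"].optimal
        prior_ub = tissue.model.reactions["CBB_MC_l"].upper_bound
        assert rep["edited"].v["CBB_MC_l"] <= 0.9 * prior_ub + 1e-9

    def test_ppiase_cap_strictly_decreases_phloem(self, tissue):
        rep = run_scenario(tissue, named_scenarios()["ppiase_cap_10pct"])
        assert rep["edited"].optimal
        assert rep["phloem_after"] < rep["phloem_before"] - 1e-9

    def test_no_psii_scenario_zeroes_cc_psii(self, tissue):
        rep = run_scenario(tissue, named_scenarios()["no_PSII_CC"])
        assert rep["edited"].optimal
        assert rep["edited"].v["PSII_CC_l"] == pytest.approx(0.0, abs=1e-12)

    def test_halved_se_maintenance_increases_phloem(self, tissue):
        rep = run_scenario(tissue, named_scenarios()["halved_SE_maintenance"])
        assert rep["phloem_after"] > rep["phloem_before"]

    def test_unknown_edit_target_raises(self, tissue):
        with pytest.raises(ScenarioError):
            run_scenario(tissue, Scenario("bad", [("MISSING_RXN", "delete", None)]))
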