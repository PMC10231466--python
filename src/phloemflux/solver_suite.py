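"""LP machinery: parsimonious FBA, flux variability analysis, knockout
scans and named scenario experiments.

Every solve is a linear program over split flux variables (v = f − r with
f, r ≥ 0) so that absolute fluxes are linear; steady state S·v = 0 and the
tissue's coupling constraints (e.g. dark phloem rate = ⅓ light rate) are
equality rows.  Lexicographic objectives are handled by solving a stage,
fixing its optimum as a row (within a relative tolerance), and re-solving.
The backend is the HiGHS solver behind :func:`scipy.optimize.linprog`,
which is deterministic for a fixed column ordering, so reruns are
bit-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .metnet_core import UNBOUNDED
from .tissue_assembler import TissueModel

logger = logging.getLogger("phloemflux")

#: default tolerances (relative objective fixing, feasibility, FVA uniqueness)
DEFAULT_TOLERANCES = {"objective_rel": 1e-6, "feasibility": 1e-9, "unique_width": 1e-6}


class ScanError(ValueError):
    """A knockout group references an unknown reaction."""


class ScenarioError(ValueError):
    """A scenario edit targets an absent reaction."""


class SolveError(RuntimeError):
    """The LP backend failed unexpectedly."""


@dataclass
class FluxSolution:
    """A reaction-indexed flux vector with an ordered objective ledger.

    ``v`` holds net fluxes; ``activity`` holds the forward-plus-reverse
    directional totals of the split-variable representation.  The two agree
    in magnitude except where the transcript-distance stage keeps a
    reaction's activity above its net flux (see the weighting module).
    """

    v: Dict[str, float]
    objective_ledger: List[Tuple[str, float]] = field(default_factory=list)
    status: str = "optimal"
    message: str = ""
    activity: Dict[str, float] = field(default_factory=dict)

    def objective(self, name: str) -> float:
        for key, value in self.objective_ledger:
            if key == name:
                return value
        raise KeyError(name)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges under fixed prior objectives."""

    ranges: Dict[str, Tuple[float, float]]
    failures: Dict[str, str] = field(default_factory=dict)

    def width(self, rid: str) -> float:
        lo, hi = self.ranges[rid]
        return hi - lo

    def is_unique(self, rid: str, tol: float = DEFAULT_TOLERANCES["unique_width"]) -> bool:
        return self.width(rid) <= tol


@dataclass
class Scenario:
    """A named set of model edits applied before a re-solve.

    Each edit is ``(selector, op, value)``.  Selectors are reaction ids or
    ``"tag:<t>"`` / ``"tag:<t>,cell:<c>"`` filters; ops are ``delete``
    (bound-zeroing), ``scale_bound``, ``set_bound``, ``scale_lower`` and
    ``cap_to_flux_fraction`` (upper bound set to a fraction of the
    reaction's flux in a baseline solution).
    """

    name: str
    edits: List[Tuple[str, str, object]]
    description: str = ""


# ---------------------------------------------------------------------------
# LP construction
# ---------------------------------------------------------------------------


class TissueLP:
    """Split-variable LP over a tissue model.

    Columns 0..n-1 are forward parts, n..2n-1 reverse parts of the n
    reactions (in model insertion order); extra columns (objective slacks)
    may be appended.  Rows are collected as (coefs, rhs) equalities and
    (coefs, rhs) upper bounds and assembled per solve.
    """

    def __init__(self, tissue: TissueModel):
        self.tissue = tissue
        model = tissue.model
        S, self.met_ids, self.rxn_ids = model.stoichiometric_matrix()
        self.n = len(self.rxn_ids)
        self.col_of = {rid: i for i, rid in enumerate(self.rxn_ids)}
        self._S = S
        self.bounds: List[Tuple[float, float]] = []
        for rid in self.rxn_ids:
            rxn = model.reactions[rid]
            self.bounds.append((max(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0)))
        for rid in self.rxn_ids:
            rxn = model.reactions[rid]
            self.bounds.append((max(-rxn.upper_bound, 0.0), max(-rxn.lower_bound, 0.0)))
        self.extra_eq: List[Tuple[Dict[int, float], float]] = []
        self.extra_ub: List[Tuple[Dict[int, float], float]] = []
        for coupling in tissue.couplings:
            cols = self._flux_cols(coupling.coefficients)
            if coupling.lower == coupling.upper:
                self.extra_eq.append((cols, coupling.lower))
            else:
                if coupling.upper < UNBOUNDED:
                    self.extra_ub.append((cols, coupling.upper))
                if coupling.lower > -UNBOUNDED:
                    self.extra_ub.append(({c: -k for c, k in cols.items()}, -coupling.lower))

    # -- column helpers ------------------------------------------------------

    def _flux_cols(self, coefs: Dict[str, float]) -> Dict[int, float]:
        out: Dict[int, float] = {}
        for rid, k in coefs.items():
            j = self.col_of[rid]
            out[j] = out.get(j, 0.0) + k
            out[j + self.n] = out.get(j + self.n, 0.0) - k
        return out

    def abs_cols(self, rid: str) -> Dict[int, float]:
        j = self.col_of[rid]
        return {j: 1.0, j + self.n: 1.0}

    def add_column(self, lb: float, ub: float) -> int:
        self.bounds.append((lb, ub))
        return len(self.bounds) - 1

    def add_flux_min(self, coefs: Dict[str, float], floor: float) -> None:
        """sum coef*v >= floor."""
        cols = self._flux_cols(coefs)
        self.extra_ub.append(({c: -k for c, k in cols.items()}, -floor))

    def add_flux_eq(self, coefs: Dict[str, float], rhs: float) -> None:
        self.extra_eq.append((self._flux_cols(coefs), rhs))

    def add_eq(self, cols: Dict[int, float], rhs: float) -> None:
        self.extra_eq.append((dict(cols), rhs))

    def add_ub(self, cols: Dict[int, float], rhs: float) -> None:
        self.extra_ub.append((dict(cols), rhs))

    # -- solving --------------------------------------------------------------

    def _assemble(self):
        ncols = len(self.bounds)
        blocks = sparse.hstack([self._S, -self._S], format="coo")
        if ncols > 2 * self.n:
            pad = sparse.coo_matrix((self._S.shape[0], ncols - 2 * self.n))
            blocks = sparse.hstack([blocks, pad], format="coo")
        eq_rows = [blocks]
        b_eq = [np.zeros(self._S.shape[0])]
        for cols, rhs in self.extra_eq:
            row = sparse.coo_matrix(
                (list(cols.values()), ([0] * len(cols), list(cols.keys()))),
                shape=(1, ncols),
            )
            eq_rows.append(row)
            b_eq.append(np.array([rhs]))
        A_eq = sparse.vstack(eq_rows, format="csr")
        b_eq = np.concatenate(b_eq)
        if self.extra_ub:
            ub_rows, b_ub = [], []
            for cols, rhs in self.extra_ub:
                ub_rows.append(
                    sparse.coo_matrix(
                        (list(cols.values()), ([0] * len(cols), list(cols.keys()))),
                        shape=(1, ncols),
                    )
                )
                b_ub.append(rhs)
            A_ub = sparse.vstack(ub_rows, format="csr")
            b_ub = np.array(b_ub)
        else:
            A_ub, b_ub = None, None
        return A_eq, b_eq, A_ub, b_ub

    def solve(self, objective: Dict[int, float], sense: str = "min"):
        """Solve min/max of sum(objective[col]*x[col]); returns (status, x, value)."""
        ncols = len(self.bounds)
        c = np.zeros(ncols)
        for col, k in objective.items():
            c[col] = k if sense == "min" else -k
        A_eq, b_eq, A_ub, b_ub = self._assemble()
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=self.bounds,
            method="highs",
        )
        if res.status == 0:
            value = float(res.fun) if sense == "min" else -float(res.fun)
            return "optimal", res.x, value
        if res.status == 2:
            return "infeasible", None, np.nan
        if res.status == 3:
            return "unbounded", None, np.nan
        raise SolveError(f"LP backend failure: {res.message}")

    def fluxes(self, x: np.ndarray) -> Dict[str, float]:
        v = x[: self.n] - x[self.n : 2 * self.n]
        return {rid: float(v[i]) for i, rid in enumerate(self.rxn_ids)}

    def activities(self, x: np.ndarray) -> Dict[str, float]:
        a = x[: self.n] + x[self.n : 2 * self.n]
        return {rid: float(a[i]) for i, rid in enumerate(self.rxn_ids)}

    def flux_sum_objective(self) -> Dict[int, float]:
        return {j: 1.0 for j in range(2 * self.n)}


def _binding_bounds(tissue: TissueModel) -> List[str]:
    """Reactions with forced flux (positive lower or negative upper bound);
    the usual suspects in an infeasibility report."""
    out = []
    for rid, rxn in tissue.model.reactions.items():
        if rxn.lower_bound > 0 or rxn.upper_bound < 0:
            out.append(rid)
    return out


# ---------------------------------------------------------------------------
# Parsimonious FBA
# ---------------------------------------------------------------------------


def parsimonious_solve(
    tissue: TissueModel,
    tolerances: Optional[Dict[str, float]] = None,
) -> FluxSolution:
    """Maximize light-phase phloem export, then minimize total absolute flux.

    Both diel phases (and all four cells) are solved simultaneously as a
    single problem; the flux-sum stage removes futile cycles, acting as a
    proxy for efficient enzyme use.
    """
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    lp = TissueLP(tissue)
    phloem_l = tissue.phloem_export_id("l")
    status, x, p_star = lp.solve(lp._flux_cols({phloem_l: 1.0}), sense="max")
    if status != "optimal":
        return FluxSolution(
            v={},
            status=status,
            message=f"phloem maximization {status}; forced-flux bounds: "
            f"{_binding_bounds(tissue)}",
        )
    lp.add_flux_eq({phloem_l: 1.0}, p_star)
    status, x, g_star = lp.solve(lp.flux_sum_objective(), sense="min")
    if status != "optimal":  # pragma: no cover - stage 2 cannot lose feasibility
        raise SolveError("flux-sum stage infeasible after fixing phloem rate")
    return FluxSolution(
        v=lp.fluxes(x),
        objective_ledger=[("phloem_light", p_star), ("flux_sum", g_star)],
        status="optimal",
        activity=lp.activities(x),
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


def _apply_ledger(lp: TissueLP, tissue: TissueModel, fixed: Sequence[Tuple[str, float]],
                  tol: Dict[str, float], h_terms=None) -> None:
    for name, value in fixed:
        if name == "phloem_light":
            lp.add_flux_min(
                {tissue.phloem_export_id("l"): 1.0},
                value * (1 - tol["objective_rel"]) - tol["feasibility"],
            )
        elif name == "H":
            if h_terms is None:
                raise ValueError("fixing H requires the weighting terms")
            cols = _h_objective(lp, h_terms)
            lp.add_ub(cols, value + tol["objective_rel"] * max(1.0, value))
        elif name in ("flux_sum", "G"):
            lp.add_ub(lp.flux_sum_objective(), value * (1 + tol["objective_rel"]))
        elif name in ("phloem_reference", "phloem_floor"):
            lp.add_flux_min({tissue.phloem_export_id("l"): 1.0}, value)
        else:
            raise ValueError(f"unknown ledger entry {name}")


def _h_objective(lp: TissueLP, h_terms) -> Dict[int, float]:
    """Install slack columns for the distance terms; returns the H objective.

    Each term is (target, [reaction ids]); slack pair e+, e- satisfies
    sum|v| - target = e+ - e-, and H sums e+ + e-.
    """
    obj: Dict[int, float] = {}
    for target, rids in h_terms:
        ep = lp.add_column(0.0, np.inf)
        em = lp.add_column(0.0, np.inf)
        cols: Dict[int, float] = {}
        for rid in rids:
            for col, k in lp.abs_cols(rid).items():
                cols[col] = cols.get(col, 0.0) + k
        cols[ep] = -1.0
        cols[em] = 1.0
        lp.add_eq(cols, target)
        obj[ep] = obj.get(ep, 0.0) + 1.0
        obj[em] = obj.get(em, 0.0) + 1.0
    return obj


def fva(
    tissue: TissueModel,
    fixed: Sequence[Tuple[str, float]],
    reactions: Optional[Iterable[str]] = None,
    h_terms=None,
    tolerances: Optional[Dict[str, float]] = None,
) -> FVAResult:
    """Per-reaction flux ranges with all prior objectives held fixed.

    ``fixed`` is an objective ledger (e.g. from a prior solution); ``h_terms``
    must be supplied when the ledger fixes the transcriptome distance H.
    Per-reaction solver failures are recorded, not fatal.
    """
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    lp = TissueLP(tissue)
    _apply_ledger(lp, tissue, fixed, tol, h_terms=h_terms)
    if reactions is None:
        reactions = list(tissue.model.reactions)
    ranges: Dict[str, Tuple[float, float]] = {}
    failures: Dict[str, str] = {}
    for rid in reactions:
        if rid not in lp.col_of:
            failures[rid] = "unknown reaction"
            continue
        cols = lp._flux_cols({rid: 1.0})
        lo_status, _, lo = lp.solve(cols, sense="min")
        hi_status, _, hi = lp.solve(cols, sense="max")
        if lo_status != "optimal" or hi_status != "optimal":
            failures[rid] = f"min:{lo_status} max:{hi_status}"
            continue
        ranges[rid] = (lo, hi)
    return FVAResult(ranges=ranges, failures=failures)


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------


def knockout_scan(
    tissue: TissueModel,
    groups: Dict[str, Sequence[str]],
    tolerances: Optional[Dict[str, float]] = None,
) -> Dict[str, Dict[str, object]]:
    """Zero the bounds of each reaction group, re-run the parsimonious solve.

    Bounds are restored after each group, so indices stay stable across the
    scan.  Returns per-group status and phloem rate.
    """
    model = tissue.model
    for name, rids in groups.items():
        unknown = [rid for rid in rids if rid not in model.reactions]
        if unknown:
            raise ScanError(f"group {name} references unknown reactions: {unknown}")
    results: Dict[str, Dict[str, object]] = {}
    for name, rids in groups.items():
        saved = {rid: (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
                 for rid in rids}
        try:
            for rid in rids:
                model.reactions[rid].lower_bound = 0.0
                model.reactions[rid].upper_bound = 0.0
            sol = parsimonious_solve(tissue, tolerances)
            results[name] = {
                "status": sol.status,
                "phloem_light": sol.objective("phloem_light") if sol.optimal else None,
            }
        finally:
            for rid, (lb, ub) in saved.items():
                model.reactions[rid].lower_bound = lb
                model.reactions[rid].upper_bound = ub
    return results


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def resolve_selector(tissue: TissueModel, selector: str) -> List[str]:
    """Resolve an edit selector to reaction ids.

    A bare string is an exact reaction id; ``"tag:x"`` selects by tag and
    may be combined with ``",cell:C"`` and/or ``",phase:p"``.
    """
    if not selector.startswith("tag:"):
        if selector not in tissue.model.reactions:
            raise ScenarioError(f"no reaction {selector}")
        return [selector]
    tag = None
    cell = None
    phase = None
    for part in selector.split(","):
        key, _, val = part.partition(":")
        if key == "tag":
            tag = val
        elif key == "cell":
            cell = val
        elif key == "phase":
            phase = val
    rids = []
    for rid, rxn in tissue.model.reactions.items():
        if tag not in rxn.tags:
            continue
        c, p, _ = tissue.provenance.get(rid, ("?", "?", "?"))
        if cell is not None and c != cell:
            continue
        if phase is not None and p != phase:
            continue
        rids.append(rid)
    if not rids:
        raise ScenarioError(f"selector '{selector}' matched no reactions")
    return rids


def named_scenarios() -> Dict[str, Scenario]:
    """The shipped scenario catalogue."""
    return {
        "no_PSII_CC": Scenario(
            "no_PSII_CC",
            [("tag:psii,cell:CC", "delete", None)],
            "remove companion-cell photosystem II (grana-poor CC chloroplasts)",
        ),
        "ppiase_cap_10pct": Scenario(
            "ppiase_cap_10pct",
            [("tag:ppiase_pm,cell:CC", "cap_to_flux_fraction", 0.1)],
            "limit the CC plasma-membrane H+-PPiase to 10% of its prior flux",
        ),
        "halved_SE_maintenance": Scenario(
            "halved_SE_maintenance",
            [
                ("tag:maintenance,cell:SE", "scale_lower", 0.5),
                ("tag:maintenance,cell:pSE", "scale_lower", 0.5),
                ("tag:protein_turnover,cell:SE", "scale_lower", 0.5),
                ("tag:protein_turnover,cell:pSE", "scale_lower", 0.5),
            ],
            "halve sieve-element maintenance and protein-turnover costs",
        ),
        "no_hexose_import": Scenario(
            "no_hexose_import",
            [("tag:hexose_symport,cell:CC", "delete", None)],
            "remove hexose import into companion cells",
        ),
        "se_proteome_trim": Scenario(
            "se_proteome_trim",
            [("tag:aa_synth,cell:SE", "delete", None)],
            "remove amino-acid synthesis reactions absent from the SE proteome",
        ),
    }


def run_scenario(
    tissue: TissueModel,
    scenario: Scenario,
    pipeline: str = "parsimonious",
    solve_fn=None,
    delta_threshold: float = 0.005,
    tolerances: Optional[Dict[str, float]] = None,
) -> Dict[str, object]:
    """Apply a scenario's edits, re-run the chosen pipeline, report deltas.

    ``solve_fn(tissue) -> FluxSolution`` overrides the pipeline (used for the
    transcriptome-weighted solve, which needs its own context); otherwise the
    parsimonious pipeline runs.  Edits are applied to bound values only and
    fully restored afterwards.
    """
    if solve_fn is None:
        if pipeline != "parsimonious":
            raise ScenarioError(
                f"pipeline '{pipeline}' requires an explicit solve_fn"
            )
        solve_fn = lambda t: parsimonious_solve(t, tolerances)  # noqa: E731

    baseline = solve_fn(tissue)
    model = tissue.model
    saved: Dict[str, Tuple[float, float]] = {}

    def remember(rid):
        if rid not in saved:
            rxn = model.reactions[rid]
            saved[rid] = (rxn.lower_bound, rxn.upper_bound)

    try:
        for selector, op, value in scenario.edits:
            for rid in resolve_selector(tissue, selector):
                remember(rid)
                rxn = model.reactions[rid]
                if op == "delete":
                    rxn.lower_bound = 0.0
                    rxn.upper_bound = 0.0
                elif op == "scale_bound":
                    rxn.lower_bound *= value
                    rxn.upper_bound *= value
                elif op == "scale_lower":
                    rxn.lower_bound *= value
                elif op == "set_bound":
                    rxn.lower_bound, rxn.upper_bound = value
                elif op == "cap_to_flux_fraction":
                    if not baseline.optimal:
                        raise ScenarioError(
                            "cap_to_flux_fraction needs an optimal baseline"
                        )
                    prior = abs(baseline.v.get(rid, 0.0))
                    rxn.upper_bound = value * prior
                    rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
                else:
                    raise ScenarioError(f"unknown edit op {op}")
        edited = solve_fn(tissue)
    finally:
        for rid, (lb, ub) in saved.items():
            model.reactions[rid].lower_bound = lb
            model.reactions[rid].upper_bound = ub

    deltas = {}
    if baseline.optimal and edited.optimal:
        for rid in baseline.v:
            d = edited.v.get(rid, 0.0) - baseline.v[rid]
            if abs(d) > delta_threshold:
                deltas[rid] = d
    return {
        "scenario": scenario.name,
        "baseline": baseline,
        "edited": edited,
        "phloem_before": baseline.objective("phloem_light") if baseline.optimal else None,
        "phloem_after": edited.objective("phloem_light") if edited.optimal else None,
        "flux_deltas": deltas,
        "edited_reactions": sorted(saved),
    }


def check_steady_state(
    solution: FluxSolution, tissue: TissueModel
) -> Tuple[float, float]:
    """(max |S·v| relative residual, max bound violation) of a solution."""
    S, met_ids, rxn_ids = tissue.model.stoichiometric_matrix()
    v = np.array([solution.v.get(rid, 0.0) for rid in rxn_ids])
    residual = S.dot(v)
    scale = max(1.0, float(np.max(np.abs(v))) if len(v) else 1.0)
    bound_violation = 0.0
    for rid in rxn_ids:
        rxn = tissue.model.reactions[rid]
        x = solution.v.get(rid, 0.0)
        bound_violation = max(
            bound_violation, rxn.lower_bound - x, x - rxn.upper_bound
        )
    return float(np.max(np.abs(residual))) / scale, max(bound_violation, 0.0)
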