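"""Transcript-to-reaction mapping and the hierarchical transcriptome
weighting of the flux solution.

Cell-type transcript abundances are aggregated over each reaction's
gene-association tree (isoforms sum, complex subunits take the minimum),
max-normalized to flux-commensurate units, and compared against model
fluxes through the distance objective

    H = min Σ_{i ∈ D} ( | r_MC·d_i^MC − |v_i^MC| |
                        + | r_CC·d_i^CC − (|v_i^CC| + |v_i^SE| + |v_i^pSE|) | )

where companion cells synthesize the transcripts for the whole
CC/SE/pSE complex, r_cell are leaf cell-type ratios and D is the set of
reactions with transcript data.  |v| is the reaction's total directional
activity (forward plus reverse split variables, summed over the light and
dark phases): for loop-free solutions this equals the absolute net flux,
and it keeps the distance linear.  The solve is lexicographic: a floor on the light-phase phloem rate
relative to the parsimonious reference (1 − gap, gap defaulting to 0.32,
the reported transcript–flux correspondence), then minimize H, then,
holding H, minimize the total flux sum G.  All stages are plain LPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .constraint_engine import CellRatios
from .metnet_core import MetabolicModel, evaluate_gpr
from .solver_suite import (
    DEFAULT_TOLERANCES,
    FluxSolution,
    TissueLP,
    _h_objective,
    parsimonious_solve,
)
from .tissue_assembler import TissueModel

logger = logging.getLogger("phloemflux")


class MappingError(ValueError):
    """Transcript data references reactions absent from the model."""


class ValidationError(ValueError):
    """Invalid transcript data."""


@dataclass
class TranscriptProfile:
    """Gene-level abundance per cell type."""

    abundance: Dict[Tuple[str, str], float]
    normalization: str = "raw"

    def __post_init__(self):
        for (gene, cell), value in self.abundance.items():
            if value < 0:
                raise ValidationError(f"negative abundance for ({gene}, {cell})")

    @property
    def cells(self) -> List[str]:
        return sorted({cell for _, cell in self.abundance})

    @property
    def genes(self) -> Set[str]:
        return {gene for gene, _ in self.abundance}

    def per_cell(self, cell: str) -> Dict[str, float]:
        return {g: v for (g, c), v in self.abundance.items() if c == cell}

    def to_frame(self):
        import pandas as pd

        rows = [
            {"gene_id": g, "cell_type": c, "abundance": v}
            for (g, c), v in sorted(self.abundance.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "cell_type", "abundance"])

    @classmethod
    def from_tsv(cls, path) -> "TranscriptProfile":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "cell_type", "abundance"}
        if not required.issubset(df.columns):
            raise ValidationError(f"transcript TSV needs columns {sorted(required)}")
        return cls(
            abundance={
                (str(r.gene_id), str(r.cell_type)): float(r.abundance)
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReactionAbundance:
    """Reaction-level transcript projection d_i per cell type."""

    d: Dict[Tuple[str, str], float]
    cells: List[str] = field(default_factory=list)
    normalization: str = "raw"

    @property
    def mapped_reactions(self) -> Set[str]:
        return {rid for rid, _ in self.d}

    def value(self, rid: str, cell: str) -> float:
        return self.d[(rid, cell)]


@dataclass
class RegrExProblem:
    """The hierarchical transcriptome-weighting problem."""

    tissue: TissueModel
    d: ReactionAbundance
    ratios: CellRatios
    phloem_gap: float = 0.32
    reference_phloem_rate: Optional[float] = None
    H_value: Optional[float] = None
    G_value: Optional[float] = None
    #: cell groups compared against each data column: MC against itself,
    #: the CC column against the whole CC/SE/pSE complex
    cell_groups: Dict[str, Sequence[str]] = field(
        default_factory=lambda: {"MC": ("MC",), "CC": ("CC", "SE", "pSE")}
    )

    def __post_init__(self):
        if not 0 <= self.phloem_gap < 1:
            raise ValidationError("phloem_gap must be in [0, 1)")


# ---------------------------------------------------------------------------
# Mapping and scaling
# ---------------------------------------------------------------------------


def map_transcripts_to_reactions(
    profile: TranscriptProfile,
    model: MetabolicModel,
    or_rule: str = "sum",
    and_rule: str = "min",
) -> ReactionAbundance:
    """Aggregate gene abundances over each reaction's AND/OR association tree.

    Isoforms (OR) default to summing, enzyme-complex subunits (AND) to the
    minimum.  A reaction enters the mapped set only if a value is computable
    (all referenced genes measured) in every profiled cell type.
    """
    if or_rule not in ("sum", "max") or and_rule not in ("min", "mean"):
        raise ValidationError(f"unsupported aggregation rules ({or_rule}, {and_rule})")
    cells = profile.cells
    if not cells:
        raise ValidationError("transcript profile has no cell types")
    per_cell = {cell: profile.per_cell(cell) for cell in cells}
    d: Dict[Tuple[str, str], float] = {}
    for rid, rxn in model.reactions.items():
        if not rxn.gene_association:
            continue
        values = {
            cell: evaluate_gpr(rxn.gene_association, per_cell[cell], or_rule, and_rule)
            for cell in cells
        }
        if any(v is None for v in values.values()):
            continue
        for cell, v in values.items():
            d[(rid, cell)] = float(v)
    if not d:
        logger.warning("no reaction could be matched to transcript data")
    return ReactionAbundance(d=d, cells=list(cells), normalization=profile.normalization)


def scale_abundance(
    d: ReactionAbundance,
    ratios: CellRatios,
    flux_scale: float = 1.0,
) -> ReactionAbundance:
    """Max-normalize reaction abundances and rescale to flux units.

    Every value is divided by the global profile maximum and multiplied by
    ``flux_scale`` so transcript units are commensurate with fluxes.  The
    cell-ratio weighting r_cell enters the distance objective itself, not
    the data (``ratios`` is accepted here to keep the scaling call
    self-documenting).
    """
    if flux_scale <= 0:
        raise ValidationError("flux_scale must be positive")
    peak = max(d.d.values(), default=0.0)
    if peak <= 0:
        raise ValidationError("cannot scale an all-zero transcript profile")
    scaled = {key: value * flux_scale / peak for key, value in d.d.items()}
    return ReactionAbundance(d=scaled, cells=list(d.cells), normalization="max")


# ---------------------------------------------------------------------------
# Objective construction and hierarchical solve
# ---------------------------------------------------------------------------


def build_regrex_objective(
    tissue: TissueModel,
    d: ReactionAbundance,
    ratios: Optional[CellRatios] = None,
    phloem_gap: float = 0.32,
    reference_phloem_rate: Optional[float] = None,
) -> RegrExProblem:
    """Assemble the weighting problem; validates that the data map onto the tissue."""
    ratios = ratios or CellRatios()
    core_ids = set()
    for rid, (cell, phase, origin) in tissue.provenance.items():
        suffix = f"_{cell}_{phase}"
        if rid.endswith(suffix):
            core_ids.add(rid[: -len(suffix)])
    unknown = d.mapped_reactions - core_ids
    if unknown:
        raise MappingError(
            f"transcript data references reactions absent from the tissue: {sorted(unknown)[:5]}"
        )
    return RegrExProblem(
        tissue=tissue,
        d=d,
        ratios=ratios,
        phloem_gap=phloem_gap,
        reference_phloem_rate=reference_phloem_rate,
    )


def regrex_terms(problem: RegrExProblem) -> List[Tuple[float, List[str]]]:
    """The distance terms: (scaled target, tissue reaction ids whose summed
    absolute diel flux is compared to it)."""
    tissue = problem.tissue
    terms: List[Tuple[float, List[str]]] = []
    for (core_id, data_cell), value in sorted(problem.d.d.items()):
        group = problem.cell_groups.get(data_cell)
        if group is None:
            raise MappingError(f"no cell group defined for data column {data_cell}")
        members = []
        for cell in group:
            for phase in ("l", "d"):
                rid = f"{core_id}_{cell}_{phase}"
                if rid in tissue.model.reactions:
                    members.append(rid)
        if not members:
            continue  # the reaction exists in no cell of this group
        target = problem.ratios[data_cell] * value
        terms.append((target, members))
    return terms


def solve_hierarchical(
    problem: RegrExProblem,
    tolerances: Optional[Dict[str, float]] = None,
) -> FluxSolution:
    """Lexicographic transcriptome-weighted solve.

    Stage 0 floors the light-phase phloem rate at (1 − gap) times the
    parsimonious reference; stage 1 minimizes the transcript distance H;
    stage 2 fixes H within a relative tolerance and minimizes the flux sum
    G.  Returns the flux vector with the full objective ledger.
    """
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    tissue = problem.tissue
    if problem.reference_phloem_rate is None:
        reference = parsimonious_solve(tissue, tolerances)
        if not reference.optimal:
            return FluxSolution(
                v={}, status=reference.status,
                message=f"parsimonious reference solve failed: {reference.message}",
            )
        problem.reference_phloem_rate = reference.objective("phloem_light")
    ref = problem.reference_phloem_rate
    floor = (1.0 - problem.phloem_gap) * ref

    lp = TissueLP(tissue)
    lp.add_flux_min({tissue.phloem_export_id("l"): 1.0}, floor)
    terms = regrex_terms(problem)
    h_obj = _h_objective(lp, terms)

    status, x, h_star = lp.solve(h_obj, sense="min")
    if status != "optimal":
        return FluxSolution(
            v={}, status=status,
            message=(
                "weighted solve infeasible after the phloem gap constraint; "
                f"floor={floor:.6g} on reference {ref:.6g}"
            ),
        )
    lp.add_ub(h_obj, h_star + tol["objective_rel"] * max(1.0, h_star))
    status, x, g_star = lp.solve(lp.flux_sum_objective(), sense="min")
    if status != "optimal":  # pragma: no cover - G stage keeps feasibility
        raise RuntimeError("flux-sum stage infeasible after fixing H")
    problem.H_value = h_star
    problem.G_value = g_star
    sol = FluxSolution(
        v=lp.fluxes(x),
        objective_ledger=[
            ("phloem_reference", ref),
            ("phloem_floor", floor),
            ("H", h_star),
            ("G", g_star),
        ],
        status="optimal",
        activity=lp.activities(x),
    )
    sol.objective_ledger.append(
        ("phloem_light", sol.v[tissue.phloem_export_id("l")])
    )
    return sol


def mapping_report(problem: RegrExProblem):
    """Tidy table of the reaction-level transcript projection."""
    import pandas as pd

    rows = []
    for (rid, cell), value in sorted(problem.d.d.items()):
        rows.append({"reaction": rid, "cell_type": cell, "d": value})
    return pd.DataFrame(rows, columns=["reaction", "cell_type", "d"])


def solution_table(solution: FluxSolution, tissue: TissueModel,
                   problem: Optional[RegrExProblem] = None):
    """Per-reaction flux table (reaction, cell, phase, flux, in-H flag)."""
    import pandas as pd

    in_h: Set[str] = set()
    if problem is not None:
        for _, members in regrex_terms(problem):
            in_h.update(members)
    rows = []
    for rid, flux in solution.v.items():
        cell, phase, origin = tissue.provenance.get(rid, ("?", "?", "?"))
        rows.append(
            {
                "reaction": rid,
                "cell": cell,
                "phase": phase,
                "origin": origin,
                "flux": flux,
                "in_H": rid in in_h,
            }
        )
    return pd.DataFrame(rows, columns=["reaction", "cell", "phase", "origin", "flux", "in_H"])
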