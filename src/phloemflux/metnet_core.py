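"""Stoichiometric network data model and SBML round-trip I/O.

The in-memory containers here are deliberately lightweight: a
:class:`MetabolicModel` is a pair of ordered id->object maps plus a gene set.
Cell/phase membership of a reaction is carried in its ``tags`` set rather
than parsed out of its id, so downstream tissue-assembly code never has to
re-interpret id suffixes.

All flux bounds are in µmol m⁻² s⁻¹ of leaf area; "unbounded" is encoded as
±1000 following the COBRA convention.
"""

from __future__ import annotations

import ast
import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy import sparse

logger = logging.getLogger("phloemflux")

UNBOUNDED = 1000.0


class ModelError(ValueError):
    """Invariant violation in a stoichiometric model."""


class FormatError(ValueError):
    """Unparseable or invalid model document."""


class AssemblyError(ValueError):
    """Error while building or replicating model structure."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` is an optional elemental composition string (e.g. ``C12H22O11``);
    only carbon counts are consumed downstream (phloem carbon accounting).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    charge: int = 0
    formula: Optional[str] = None

    def carbon_count(self) -> int:
        if not self.formula:
            return 0
        m = re.search(r"C(\d*)(?![a-z])", self.formula)
        if not m:
            return 0
        return int(m.group(1)) if m.group(1) else 1


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds, gene association and tags.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    substrate).  ``gene_association`` is a boolean expression over gene ids
    ("G1 or (G2 and G3)"); empty string means no association.
    ``tags`` is a free set of labels (cell, phase, linker kind, functional
    class) used by the assembler and constraint engine.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -UNBOUNDED
    upper_bound: float = UNBOUNDED
    gene_association: str = ""
    tags: Set[str] = field(default_factory=set)
    name: str = ""

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry and not (
            "exchange" in self.tags or "objective" in self.tags
        ):
            raise ModelError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A compartmentalized stoichiometric network."""

    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    gene_ids: Set[str] = field(default_factory=set)
    compartments: Dict[str, str] = field(default_factory=dict)
    annotations: Dict[str, str] = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id}")
        if met.compartment not in self.compartments:
            self.compartments[met.compartment] = met.compartment
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelError(
                    f"reaction {rxn.id} references unknown metabolite {mid}"
                )
        for gene in gpr_genes(rxn.gene_association):
            self.gene_ids.add(gene)
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    def prune_orphan_metabolites(self) -> List[str]:
        """Drop metabolites referenced by no reaction; returns dropped ids."""
        used: Set[str] = set()
        for rxn in self.reactions.values():
            used.update(rxn.stoichiometry)
        orphans = [mid for mid in self.metabolites if mid not in used]
        for mid in orphans:
            del self.metabolites[mid]
        return orphans

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- queries ------------------------------------------------------------

    def reactions_with_tag(self, tag: str) -> List[Reaction]:
        return [r for r in self.reactions.values() if tag in r.tags]

    def metabolites_in_compartment(self, compartment: str) -> List[Metabolite]:
        return [m for m in self.metabolites.values() if m.compartment == compartment]

    def stoichiometric_matrix(
        self,
    ) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
        """Sparse S (metabolites × reactions) plus row/column id orders."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                data.append(coef)
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate()
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite {mid}"
                    )
            for gene in gpr_genes(rxn.gene_association):
                if gene not in self.gene_ids:
                    raise ModelError(
                        f"reaction {rxn.id} uses undeclared gene {gene}"
                    )


# ---------------------------------------------------------------------------
# Gene association (GPR) expressions
# ---------------------------------------------------------------------------


def _parse_gpr_ast(node) -> object:
    if isinstance(node, ast.BoolOp):
        op = "or" if isinstance(node.op, ast.Or) else "and"
        return (op, [_parse_gpr_ast(v) for v in node.values])
    if isinstance(node, ast.Name):
        return node.id
    raise FormatError(f"unsupported token in gene association: {ast.dump(node)}")


def parse_gpr(expression: str):
    """Parse a boolean gene-association string into a nested tree.

    Returns ``None`` for an empty expression, a gene id string for a single
    gene, or ``(op, [children])`` with ``op`` in {"and", "or"}.
    """
    expression = (expression or "").strip()
    if not expression:
        return None
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise FormatError(f"invalid gene association '{expression}': {exc}") from exc
    return _parse_gpr_ast(tree.body)


def gpr_genes(expression: str) -> Set[str]:
    tree = parse_gpr(expression)
    genes: Set[str] = set()

    def walk(node):
        if node is None:
            return
        if isinstance(node, str):
            genes.add(node)
        else:
            for child in node[1]:
                walk(child)

    walk(tree)
    return genes


def evaluate_gpr(expression: str, values: Dict[str, float], or_rule: str = "sum",
                 and_rule: str = "min") -> Optional[float]:
    """Aggregate per-gene values over a GPR tree.

    Returns ``None`` if the expression is empty or any referenced gene is
    unmeasured (the reaction then contributes no transcript datum).
    """
    tree = parse_gpr(expression)
    if tree is None:
        return None

    def agg(node) -> Optional[float]:
        if isinstance(node, str):
            return values.get(node)
        op, children = node
        vals = [agg(c) for c in children]
        if any(v is None for v in vals):
            return None
        if op == "or":
            return float(sum(vals)) if or_rule == "sum" else float(max(vals))
        return float(min(vals)) if and_rule == "min" else float(np.mean(vals))

    return agg(tree)


# ---------------------------------------------------------------------------
# SBML I/O (via COBRApy; tags round-tripped through SBML notes)
# ---------------------------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    cm.compartments = dict(model.compartments)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(
            met.id,
            name=met.name or met.id,
            compartment=met.compartment,
            charge=met.charge,
            formula=met.formula,
        )
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(
            rxn.id,
            name=rxn.name or rxn.id,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        rxns.append(r)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        r = cm.reactions.get_by_id(rxn.id)
        r.add_metabolites(
            {mets[mid]: coef for mid, coef in rxn.stoichiometry.items()}
        )
        if rxn.gene_association:
            r.gene_reaction_rule = rxn.gene_association
        if rxn.tags:
            r.notes["tags"] = ";".join(sorted(rxn.tags))
    return cm


def _from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    model.compartments = dict(cm.compartments)
    for m in cm.metabolites:
        model.add_metabolite(
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                charge=int(m.charge) if m.charge is not None else 0,
                formula=m.formula or None,
            )
        )
    for r in cm.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if lb is None or ub is None:  # pragma: no cover - defensive
            logger.warning("reaction %s missing bound; defaulting to ±%s", r.id, UNBOUNDED)
            lb = -UNBOUNDED if lb is None else lb
            ub = UNBOUNDED if ub is None else ub
        tags: Set[str] = set()
        note_tags = r.notes.get("tags") if r.notes else None
        if note_tags:
            tags = set(str(note_tags).split(";"))
        model.add_reaction(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_association=r.gene_reaction_rule or "",
                tags=tags,
            )
        )
    return model


def read_sbml(path) -> MetabolicModel:
    """Read an SBML (L2 or L3, fbc-aware) document into a MetabolicModel."""
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse SBML document {path}: {exc}") from exc
    return _from_cobra(cm)


def write_sbml(model: MetabolicModel, path) -> None:
    """Write a MetabolicModel as SBML Level 3 + fbc."""
    import cobra.io

    model.validate()
    cm = _to_cobra(model)
    try:
        cobra.io.write_sbml_model(cm, str(path))
    except OSError as exc:
        raise IOError(f"cannot write SBML to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------


def replicate_model(
    model: MetabolicModel,
    suffix: str,
    extra_tags: Optional[Iterable[str]] = None,
) -> MetabolicModel:
    """Copy a model with every metabolite/reaction/compartment id suffixed.

    Stoichiometry is remapped consistently and bounds are copied verbatim.
    ``extra_tags`` (e.g. cell and phase labels) are added to every reaction
    of the replica.
    """
    if not suffix:
        raise AssemblyError("replication suffix must be nonempty")
    extra = set(extra_tags or ())
    rep = MetabolicModel(id=model.id + suffix)
    rep.annotations = dict(model.annotations)
    for comp, name in model.compartments.items():
        rep.compartments[comp + suffix] = name + suffix
    for met in model.metabolites.values():
        new_id = met.id + suffix
        if new_id in model.metabolites:
            raise AssemblyError(f"suffix {suffix} collides with existing id {new_id}")
        rep.add_metabolite(
            Metabolite(
                id=new_id,
                name=met.name,
                compartment=met.compartment + suffix,
                charge=met.charge,
                formula=met.formula,
            )
        )
    for rxn in model.reactions.values():
        new_id = rxn.id + suffix
        if new_id in model.reactions:
            raise AssemblyError(f"suffix {suffix} collides with existing id {new_id}")
        rep.add_reaction(
            Reaction(
                id=new_id,
                name=rxn.name,
                stoichiometry={
                    mid + suffix: coef for mid, coef in rxn.stoichiometry.items()
                },
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                gene_association=rxn.gene_association,
                tags=set(rxn.tags) | extra,
            )
        )
    return rep
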