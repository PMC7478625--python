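"""Boolean pathway-requirement evaluation and synthesis-vs-salvage calling.

A pathway definition is an AND/OR expression tree over function ids
(canonical gene symbols). A leaf is satisfied in a genome when some gene
carries that function at or above the definition's minimum confidence
tier (default MODERATE — family-level calls rescued by genome context are
accepted as evidence of pathway presence).

Completeness is counted in "missing gene" units: the fraction of
satisfied top-level AND children, where an OR subtree counts as a single
child (one alternative route, satisfied or not). A leaf-weighted
completeness is available via ``leaf_weighted=True``.

The shipped definitions (``data/pathways.yaml``) encode central carbon
metabolism (EMP glycolysis, oxidative and non-oxidative pentose phosphate
branches), the butyrogenesis operon with its terminal butyryl-CoA:acetate
CoA-transferase, fermentation branches (lactate dehydrogenases, pyruvate
formate-lyase / pyruvate:ferredoxin oxidoreductase, the Rnf complex),
amino-acid routes (serine with the thrH bypass, the histidine operon),
and for each B vitamin a de-novo synthesis definition paired with a
salvage/transport definition (ECF transporters such as ThiT, RibU, BioY,
FolT, PdxU2) so genomes can be classified as synthesizers or salvagers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .reconcile import FunctionAssignment, Tier

__all__ = [
    "Expr",
    "parse_expression",
    "format_expression",
    "PathwayDefinition",
    "PathwayCall",
    "load_pathway_definitions",
    "shipped_pathway_definitions",
    "evaluate_requirement",
    "call_pathway",
    "classify_strategy",
    "profile_matrix",
    "best_tiers",
]


# ---------------------------------------------------------------------------
# expression trees


@dataclass(frozen=True)
class Expr:
    """AND/OR expression node. ``op`` is 'AND', 'OR' or 'LEAF'."""

    op: str
    children: tuple["Expr", ...] = ()
    function_id: str | None = None

    def leaves(self) -> set[str]:
        if self.op == "LEAF":
            return {self.function_id}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return out


def parse_expression(text: str) -> Expr:
    """Parse a prefix s-expression like ``(AND thiC (OR thiD cytX))``.

    A bare token parses to a single leaf.
    """
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise ValueError("empty pathway expression")
    pos = 0

    def parse() -> Expr:
        nonlocal pos
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            op = tokens[pos].upper()
            if op not in ("AND", "OR"):
                raise ValueError(f"expected AND/OR after '(' , got {tokens[pos]!r}")
            pos += 1
            children = []
            while pos < len(tokens) and tokens[pos] != ")":
                children.append(parse())
            if pos >= len(tokens):
                raise ValueError("unbalanced parentheses in pathway expression")
            pos += 1  # consume ')'
            if not children:
                raise ValueError(f"{op} node with no children")
            return Expr(op, tuple(children))
        if tok == ")":
            raise ValueError("unexpected ')' in pathway expression")
        pos += 1
        return Expr("LEAF", function_id=tok)

    expr = parse()
    if pos != len(tokens):
        raise ValueError("trailing tokens in pathway expression")
    return expr


def format_expression(expr: Expr) -> str:
    if expr.op == "LEAF":
        return expr.function_id
    return "(" + expr.op + " " + " ".join(format_expression(c) for c in expr.children) + ")"


def _compact(expr: Expr) -> str:
    """Human-readable rendering used for 'missing' entries, e.g. ``c|d``."""
    if expr.op == "LEAF":
        return expr.function_id
    sep = "&" if expr.op == "AND" else "|"
    return sep.join(
        _compact(c) if c.op == "LEAF" else "(" + _compact(c) + ")" for c in expr.children
    )


# ---------------------------------------------------------------------------
# definitions and calls


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    category: str  # 'synthesis' or 'salvage_transport'
    requirement: Expr
    min_tier: Tier = Tier.MODERATE
    vitamin: str | None = None  # groups a synthesis/salvage pair

    def __post_init__(self) -> None:
        if self.category not in ("synthesis", "salvage_transport"):
            raise ValueError(f"unknown pathway category {self.category!r}")


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    pathway_id: str
    completeness: float
    status: str  # 'complete' | 'partial' | 'absent'
    missing: tuple[str, ...] = ()


def load_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Load definitions from a YAML file.

    Each entry: ``id``, ``category``, ``expression`` (prefix notation),
    optional ``min_tier`` (default MODERATE) and ``vitamin``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for entry in raw["pathways"]:
        defs.append(
            PathwayDefinition(
                pathway_id=entry["id"],
                category=entry["category"],
                requirement=parse_expression(entry["expression"]),
                min_tier=Tier[entry.get("min_tier", "MODERATE")],
                vitamin=entry.get("vitamin"),
            )
        )
    return defs


def shipped_pathway_definitions() -> list[PathwayDefinition]:
    """The definitions shipped with the package (see module docstring)."""
    ref = resources.files("panvita.data").joinpath("pathways.yaml")
    with resources.as_file(ref) as path:
        return load_pathway_definitions(path)


# ---------------------------------------------------------------------------
# evaluation


def best_tiers(
    assignments: Sequence[FunctionAssignment],
) -> dict[str, Tier]:
    """Collapse per-gene assignments to each function's best tier."""
    out: dict[str, Tier] = {}
    for a in assignments:
        if a.function_id is None:
            continue
        if a.tier > out.get(a.function_id, Tier.NONE):
            out[a.function_id] = a.tier
    return out


def _satisfied(expr: Expr, tiers: Mapping[str, Tier], min_tier: Tier) -> bool:
    if expr.op == "LEAF":
        return tiers.get(expr.function_id, Tier.NONE) >= min_tier
    if expr.op == "AND":
        return all(_satisfied(c, tiers, min_tier) for c in expr.children)
    return any(_satisfied(c, tiers, min_tier) for c in expr.children)


def evaluate_requirement(
    expr: Expr,
    tiers: Mapping[str, Tier],
    min_tier: Tier = Tier.MODERATE,
    known_functions: frozenset[str] | set[str] | None = None,
    leaf_weighted: bool = False,
) -> tuple[bool, float, list[str]]:
    """Evaluate a requirement tree against per-function best tiers.

    Returns ``(satisfied, completeness, missing)``. Completeness counts
    satisfied top-level AND children (an OR subtree is one child); with
    ``leaf_weighted=True`` it instead counts satisfied leaves over all
    leaves. ``missing`` lists the unsatisfied top-level children in
    compact form (e.g. ``serB|thrH``).

    ``known_functions``, when given, is the function dictionary's
    vocabulary; a leaf outside it raises ``ValueError``.
    """
    if known_functions is not None:
        unknown = expr.leaves() - set(known_functions)
        if unknown:
            raise ValueError(
                f"pathway expression references unknown functions: {sorted(unknown)}"
            )

    if leaf_weighted:
        leaves = sorted(expr.leaves())
        sat = [f for f in leaves if tiers.get(f, Tier.NONE) >= min_tier]
        completeness = len(sat) / len(leaves)
        missing = [f for f in leaves if f not in sat]
        return _satisfied(expr, tiers, min_tier), completeness, missing

    top_children = expr.children if expr.op == "AND" else (expr,)
    n_sat = 0
    missing: list[str] = []
    for child in top_children:
        if _satisfied(child, tiers, min_tier):
            n_sat += 1
        else:
            missing.append(_compact(child))
    completeness = n_sat / len(top_children)
    return _satisfied(expr, tiers, min_tier), completeness, missing


def call_pathway(
    genome_id: str,
    definition: PathwayDefinition,
    assignments: Sequence[FunctionAssignment],
    known_functions: frozenset[str] | None = None,
    leaf_weighted: bool = False,
) -> PathwayCall:
    """Per-genome pathway verdict: complete (1.0), partial ((0,1)) or absent (0)."""
    tiers = best_tiers(assignments)
    satisfied, completeness, missing = evaluate_requirement(
        definition.requirement,
        tiers,
        min_tier=definition.min_tier,
        known_functions=known_functions,
        leaf_weighted=leaf_weighted,
    )
    if satisfied:
        status = "complete"
        completeness = 1.0
        missing = []
    elif completeness == 0.0:
        status = "absent"
    else:
        status = "partial"
    return PathwayCall(
        genome_id=genome_id,
        pathway_id=definition.pathway_id,
        completeness=completeness,
        status=status,
        missing=tuple(missing),
    )


def classify_strategy(
    genome_id: str,
    synthesis_def: PathwayDefinition,
    salvage_def: PathwayDefinition,
    assignments: Sequence[FunctionAssignment],
) -> str:
    """Classify a genome's acquisition strategy for one vitamin.

    Returns ``synthesizer``, ``salvager``, ``both`` or ``neither`` from
    the two satisfied flags.
    """
    if synthesis_def.category != "synthesis":
        raise ValueError(
            f"{synthesis_def.pathway_id!r} is not a synthesis definition"
        )
    if salvage_def.category != "salvage_transport":
        raise ValueError(f"{salvage_def.pathway_id!r} is not a salvage definition")
    if (
        synthesis_def.vitamin is not None
        and salvage_def.vitamin is not None
        and synthesis_def.vitamin != salvage_def.vitamin
    ):
        raise ValueError(
            f"definitions target different vitamins: "
            f"{synthesis_def.vitamin!r} vs {salvage_def.vitamin!r}"
        )
    tiers = best_tiers(assignments)
    synth = _satisfied(synthesis_def.requirement, tiers, synthesis_def.min_tier)
    salv = _satisfied(salvage_def.requirement, tiers, salvage_def.min_tier)
    if synth and salv:
        return "both"
    if synth:
        return "synthesizer"
    if salv:
        return "salvager"
    return "neither"


def profile_matrix(
    assignments_by_genome: Mapping[str, Sequence[FunctionAssignment]],
    definitions: Sequence[PathwayDefinition],
    known_functions: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Genome × pathway status matrix ('complete'/'partial'/'absent').

    Rows follow the input genome order, columns the definition order;
    the result is TSV-serialisable and deterministic.
    """
    genomes = list(assignments_by_genome)
    cols = [d.pathway_id for d in definitions]
    data = {
        g: [
            call_pathway(g, d, assignments_by_genome[g], known_functions).status
            for d in definitions
        ]
        for g in genomes
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
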