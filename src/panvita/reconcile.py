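"""Multi-evidence function-call reconciliation with an ordinal confidence scale.

Four independent evidence streams can support a gene's function: equivalog
profile HMMs (expert-curated, function-specific), KO assignments, protein
family assignments (FIGfam-style), and domain-level HMMs (Pfam-style,
"hole fillers"). The scale fuses them, together with genome context —
co-localisation with same-pathway genes within a short gene-rank window,
the operon signal — into one tier per gene:

==========  ============================================================
HIGH        an equivalog HMM hit, or KO and FAMILY agreeing on the
            same function
MODERATE    KO alone, or FAMILY alone when rescued by conserved genome
            context
LOW         FAMILY alone without context, or a domain HMM alone
NONE        no evidence
==========  ============================================================

The table above is the default ``ConfidenceScale``; it is plain data and
can be replaced wholesale by a curated scale without touching code.

Context evaluation is two-pass: tiers are first assigned with no context,
then context-eligible genes are re-scored against the pass-1 (non-context)
tiers of their neighbours. This makes the result a fixed point and rules
out circular context support.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import SOURCES, EvidenceHit, GeneRecord

__all__ = [
    "Tier",
    "FunctionAssignment",
    "FunctionDictionary",
    "ConfidenceScale",
    "DEFAULT_SCALE",
    "genome_context_support",
    "assign_confidence",
    "annotate_genome",
    "write_assignments",
]


class Tier(enum.IntEnum):
    """Ordinal confidence tier; comparisons follow integer order."""

    NONE = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


@dataclass(frozen=True)
class FunctionAssignment:
    gene_id: str
    function_id: str | None
    tier: Tier
    supporting_sources: frozenset[str] = frozenset()
    context_supported: bool = False

    def __post_init__(self) -> None:
        if (self.tier == Tier.NONE) != (not self.supporting_sources):
            raise ValueError(
                f"{self.gene_id}: tier NONE must coincide with empty sources"
            )


@dataclass
class FunctionDictionary:
    """Cross-walk from per-source accessions to canonical function ids.

    ``accession_to_function`` maps ``(source, accession)`` to a function id
    (each accession resolves to exactly one function);
    ``function_pathways`` maps a function id to the pathway ids it
    participates in.
    """

    accession_to_function: dict[tuple[str, str], str]
    function_pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def function_of(self, source: str, accession: str) -> str:
        try:
            return self.accession_to_function[(source, accession)]
        except KeyError:
            raise KeyError(
                f"accession {accession!r} (source {source}) not in function dictionary"
            ) from None

    def pathways_of(self, function_id: str) -> frozenset[str]:
        return self.function_pathways.get(function_id, frozenset())

    def same_pathway_functions(self, function_id: str) -> frozenset[str]:
        """All functions sharing at least one pathway with ``function_id``."""
        mine = self.pathways_of(function_id)
        if not mine:
            return frozenset()
        return frozenset(
            f for f, ps in self.function_pathways.items() if ps & mine and f != function_id
        )

    @classmethod
    def from_tsv(
        cls, accessions_path: str | Path, pathways_path: str | Path | None = None
    ) -> "FunctionDictionary":
        """Load from TSVs: ``source\taccession\tfunction_id`` and
        (optionally) ``function_id\tpathway_id``."""
        acc: dict[tuple[str, str], str] = {}
        with open(accessions_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[:3] == ["source", "accession", "function_id"]:
                    continue
                if len(parts) < 3:
                    raise ValueError(f"{accessions_path}:{lineno}: malformed row")
                key = (parts[0], parts[1])
                if key in acc and acc[key] != parts[2]:
                    raise ValueError(
                        f"{accessions_path}:{lineno}: accession {parts[1]!r} maps to "
                        f"two functions"
                    )
                acc[key] = parts[2]
        pathways: dict[str, set[str]] = {}
        if pathways_path is not None:
            with open(pathways_path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if parts[:2] == ["function_id", "pathway_id"]:
                        continue
                    pathways.setdefault(parts[0], set()).add(parts[1])
        return cls(acc, {f: frozenset(p) for f, p in pathways.items()})

    def to_tsv(
        self, accessions_path: str | Path, pathways_path: str | Path | None = None
    ) -> None:
        with open(accessions_path, "w") as fh:
            fh.write("source\taccession\tfunction_id\n")
            for (source, accession), func in sorted(self.accession_to_function.items()):
                fh.write(f"{source}\t{accession}\t{func}\n")
        if pathways_path is not None:
            with open(pathways_path, "w") as fh:
                fh.write("function_id\tpathway_id\n")
                for func in sorted(self.function_pathways):
                    for pw in sorted(self.function_pathways[func]):
                        fh.write(f"{func}\t{pw}\n")


# ---------------------------------------------------------------------------
# the confidence scale


@dataclass(frozen=True)
class ConfidenceScale:
    """Rule table mapping an evidence profile to a tier.

    ``rules`` is an ordered sequence of ``(condition, tier)`` pairs where
    the condition is a frozenset drawn from the vocabulary:

    - ``"EQUIVALOG_HMM"``, ``"KO"``, ``"FAMILY"``, ``"DOMAIN_HMM"`` —
      source supports the chosen function;
    - ``"KO+FAMILY_AGREE"`` — both KO and FAMILY support it;
    - ``"CONTEXT"`` — genome context supports it.

    The first rule whose condition is a subset of the gene's evidence
    profile wins; with no match and no evidence the tier is NONE, with
    unmatched evidence it is LOW.
    """

    rules: tuple[tuple[frozenset[str], Tier], ...]

    def tier_for(self, profile: frozenset[str]) -> Tier:
        for condition, tier in self.rules:
            if condition <= profile:
                return tier
        return Tier.NONE if not profile else Tier.LOW


DEFAULT_SCALE = ConfidenceScale(
    rules=(
        (frozenset({"EQUIVALOG_HMM"}), Tier.HIGH),
        (frozenset({"KO+FAMILY_AGREE"}), Tier.HIGH),
        (frozenset({"KO"}), Tier.MODERATE),
        (frozenset({"FAMILY", "CONTEXT"}), Tier.MODERATE),
        (frozenset({"FAMILY"}), Tier.LOW),
        (frozenset({"DOMAIN_HMM"}), Tier.LOW),
    )
)

_PRIORITY = {s: i for i, s in enumerate(SOURCES)}  # EQUIVALOG_HMM highest


# ---------------------------------------------------------------------------
# operations


def genome_context_support(
    gene: GeneRecord,
    neighbors: Sequence[tuple[GeneRecord, FunctionAssignment]],
    pathway_functions: frozenset[str] | set[str],
    window: int = 5,
) -> bool:
    """True iff a gene within ``±window`` ranks on the same contig carries
    (at any tier above NONE) a function from ``pathway_functions``.

    Strand-agnostic: operons are read off gene adjacency alone.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    for rec, asg in neighbors:
        if rec.contig_id != gene.contig_id or rec.gene_id == gene.gene_id:
            continue
        if abs(rec.position_index - gene.position_index) > window:
            continue
        if asg.tier > Tier.NONE and asg.function_id in pathway_functions:
            return True
    return False


def assign_confidence(
    gene_id: str,
    hits: Sequence[EvidenceHit],
    dictionary: FunctionDictionary,
    context: bool = False,
    scale: ConfidenceScale = DEFAULT_SCALE,
) -> FunctionAssignment:
    """Fuse (trusted-cutoff-filtered) hits for one gene into an assignment.

    The called function is that of the highest-priority source
    (equivalog > KO > FAMILY > domain); among equal-priority hits the
    lexicographically smallest accession wins, for determinism. All
    sources with any hit are recorded in ``supporting_sources`` so
    cross-source conflicts remain auditable.
    """
    for h in hits:
        if h.gene_id != gene_id:
            raise ValueError(f"hit for {h.gene_id!r} passed to gene {gene_id!r}")

    if not hits:
        return FunctionAssignment(gene_id, None, Tier.NONE)

    # resolve every hit to a function id (errors on unknown accessions)
    resolved: list[tuple[EvidenceHit, str]] = []
    for h in hits:
        try:
            func = dictionary.function_of(h.source, h.accession)
        except KeyError as exc:
            raise ValueError(str(exc)) from None
        resolved.append((h, func))

    winner = min(resolved, key=lambda hf: (_PRIORITY[hf[0].source], hf[0].accession))
    function_id = winner[1]

    supporters = {h.source for h, f in resolved if f == function_id}
    profile = set(supporters)
    if "KO" in supporters and "FAMILY" in supporters:
        profile.add("KO+FAMILY_AGREE")
    if context:
        profile.add("CONTEXT")
    tier = scale.tier_for(frozenset(profile))

    return FunctionAssignment(
        gene_id=gene_id,
        function_id=function_id,
        tier=tier,
        supporting_sources=frozenset(h.source for h, _ in resolved),
        context_supported=context,
    )


def annotate_genome(
    genome: Sequence[GeneRecord],
    hits: Iterable[EvidenceHit],
    dictionary: FunctionDictionary,
    window: int = 5,
    scale: ConfidenceScale = DEFAULT_SCALE,
) -> list[FunctionAssignment]:
    """Two-pass annotation of a whole genome.

    Pass 1 assigns every gene a tier with context off. Pass 2 recomputes
    context-eligible genes (those whose tier would change with context)
    against the pass-1 assignments of their neighbours, so context support
    never feeds back on itself. Exactly one assignment per gene, in genome
    order; deterministic under permutation of the input hit stream.
    """
    by_gene: dict[str, list[EvidenceHit]] = {}
    for h in sorted(hits, key=lambda h: (h.gene_id, _PRIORITY[h.source], h.accession)):
        by_gene.setdefault(h.gene_id, []).append(h)

    known = {g.gene_id for g in genome}
    stray = set(by_gene) - known
    if stray:
        raise ValueError(f"hits reference unknown genes: {sorted(stray)[:5]}")

    pass1 = {
        g.gene_id: assign_confidence(
            g.gene_id, by_gene.get(g.gene_id, []), dictionary, context=False, scale=scale
        )
        for g in genome
    }

    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genome:
        by_contig.setdefault(g.contig_id, []).append(g)

    final: list[FunctionAssignment] = []
    for g in genome:
        a = pass1[g.gene_id]
        if a.function_id is None:
            final.append(a)
            continue
        with_ctx = assign_confidence(
            g.gene_id, by_gene.get(g.gene_id, []), dictionary, context=True, scale=scale
        )
        if with_ctx.tier == a.tier:
            final.append(a)  # context cannot change the verdict
            continue
        same_pathway = dictionary.same_pathway_functions(a.function_id)
        neighbors = [
            (n, pass1[n.gene_id])
            for n in by_contig[g.contig_id]
            if n.gene_id != g.gene_id
        ]
        ctx = genome_context_support(g, neighbors, same_pathway, window=window)
        final.append(with_ctx if ctx else a)
    return final


def write_assignments(
    assignments: Sequence[FunctionAssignment], path: str | Path
) -> None:
    """TSV output: gene_id, function_id, tier, sources, context flag."""
    with open(path, "w") as fh:
        fh.write("gene_id\tfunction_id\ttier\tsources\tcontext_supported\n")
        for a in assignments:
            srcs = ",".join(sorted(a.supporting_sources))
            fh.write(
                f"{a.gene_id}\t{a.function_id or '-'}\t{a.tier.name}\t{srcs or '-'}\t"
                f"{'yes' if a.context_supported else 'no'}\n"
            )
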