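"""Orthologue-group tables and core/pan-genome co-occurrence statistics.

The substrate is a genome × orthologue-group membership table, normally
produced upstream by a dedicated orthology tool (PorthoMCL-style pair
lists collapsed to groups). A built-in reciprocal-best-hit (RBH) +
single-linkage clusterer is provided so the pipeline runs end-to-end with
no external tool; it is a stand-in, not a Markov-clustering
reimplementation, and the precomputed-table path is first-class.

Counting semantics: a group is *present* in a genome if the genome has at
least one member (paralogues count once). At the species level, presence
defaults to ``all_strains`` — the group must be present in every strain of
the species — matching the co-occurrence counting the core/pan statistics
are built on; ``any_strain`` is exposed as an option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import GeneRecord

__all__ = [
    "OrthologueTable",
    "CooccurrenceResult",
    "cluster_orthologues",
    "core_genome",
    "pairwise_shared_matrix",
    "intersection_counts",
    "read_orthologue_table",
    "write_orthologue_table",
    "write_venn_counts",
]


@dataclass
class OrthologueTable:
    """group_id → genome_id → member gene ids, plus the genome roster."""

    groups: dict[str, dict[str, tuple[str, ...]]]
    roster: tuple[str, ...]
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roster = set(self.roster)
        seen_genes: set[tuple[str, str]] = set()
        for gid, members in self.groups.items():
            for genome, genes in members.items():
                if genome not in roster:
                    raise ValueError(
                        f"group {gid!r} references genome {genome!r} not in roster"
                    )
                for gene in genes:
                    key = (genome, gene)
                    if key in seen_genes:
                        raise ValueError(
                            f"gene {gene!r} ({genome}) appears in multiple groups"
                        )
                    seen_genes.add(key)

    def genomes_of(self, group_id: str) -> frozenset[str]:
        return frozenset(self.groups[group_id])

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups)

    def n_genes(self, genome_id: str) -> int:
        return sum(len(m.get(genome_id, ())) for m in self.groups.values())


@dataclass
class CooccurrenceResult:
    """Pairwise shared-orthologue matrix and exclusive subset counts."""

    pairwise: pd.DataFrame
    subset_counts: dict[frozenset[str], int] | None = None


# ---------------------------------------------------------------------------
# built-in RBH stand-in clusterer


def _identity(a: str, b: str) -> float:
    """Normalised global-alignment identity: 1 − editdist / max(len)."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_orthologues(
    genomes: Sequence[Sequence[GeneRecord]],
    identity_threshold: float = 0.7,
) -> OrthologueTable:
    """Cluster genes into orthologue groups by reciprocal best hits.

    For every ordered genome pair, each gene's best match (highest global
    identity, ties broken by lexicographic gene id) is found; reciprocal
    best pairs with identity ≥ ``identity_threshold`` become edges, and
    groups are the connected components (single linkage). Unmatched genes
    form singleton groups. Group ids are assigned in order of each
    component's lexicographically smallest (genome_id, gene_id) member, so
    the output is deterministic.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes to cluster orthologues")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")

    roster = tuple(g[0].genome_id for g in genomes)
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate genome ids in input")

    all_genes: list[GeneRecord] = [g for genome in genomes for g in genome]
    parent: dict[tuple[str, str], tuple[str, str]] = {
        (g.genome_id, g.gene_id): (g.genome_id, g.gene_id) for g in all_genes
    }

    def find(x: tuple[str, str]) -> tuple[str, str]:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: tuple[str, str], b: tuple[str, str]) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for gi, gj in itertools.combinations(range(len(genomes)), 2):
        A = sorted(genomes[gi], key=lambda g: g.gene_id)
        B = sorted(genomes[gj], key=lambda g: g.gene_id)
        ident = np.array(
            [[_identity(a.protein_seq, b.protein_seq) for b in B] for a in A]
        )
        best_ab = ident.argmax(axis=1)  # argmax takes first (lexicographic) on ties
        best_ba = ident.argmax(axis=0)
        for ia, ib in enumerate(best_ab):
            if best_ba[ib] == ia and ident[ia, ib] >= identity_threshold:
                union(
                    (A[ia].genome_id, A[ia].gene_id), (B[ib].genome_id, B[ib].gene_id)
                )

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for g in all_genes:
        key = (g.genome_id, g.gene_id)
        components.setdefault(find(key), []).append(key)

    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    width = len(str(len(components)))
    for idx, root in enumerate(sorted(components), start=1):
        members: dict[str, list[str]] = {}
        for genome, gene in sorted(components[root]):
            members.setdefault(genome, []).append(gene)
        groups[f"OG{idx:0{width}d}"] = {
            genome: tuple(genes) for genome, genes in members.items()
        }
    return OrthologueTable(groups=groups, roster=roster)


# ---------------------------------------------------------------------------
# co-occurrence statistics


def core_genome(table: OrthologueTable, genome_ids: Iterable[str]) -> set[str]:
    """Groups with at least one member in EVERY listed genome."""
    ids = set(genome_ids)
    if not ids:
        raise ValueError("genome_ids must be non-empty")
    unknown = ids - set(table.roster)
    if unknown:
        raise ValueError(f"unknown genome ids: {sorted(unknown)}")
    return {gid for gid, members in table.groups.items() if ids <= set(members)}


def _validate_taxa(
    table: OrthologueTable, taxa: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    seen: set[str] = set()
    for name, genomes in taxa.items():
        gs = frozenset(genomes)
        if not gs:
            raise ValueError(f"taxon {name!r} is empty")
        unknown = gs - set(table.roster)
        if unknown:
            raise ValueError(f"taxon {name!r} lists unknown genomes {sorted(unknown)}")
        if gs & seen:
            raise ValueError(f"taxon {name!r} overlaps another taxon")
        seen |= gs
        out[name] = gs
    return out


def _present(
    members: Mapping[str, tuple[str, ...]], taxon: frozenset[str], rule: str
) -> bool:
    if rule == "all_strains":
        return taxon <= set(members)
    if rule == "any_strain":
        return bool(taxon & set(members))
    raise ValueError(f"unknown presence_rule {rule!r}")


def pairwise_shared_matrix(
    table: OrthologueTable,
    taxa: Mapping[str, Iterable[str]],
    presence_rule: str = "all_strains",
) -> CooccurrenceResult:
    """Symmetric taxon × taxon matrix of co-occurring orthologue groups.

    Entry (A, B) counts groups present in A and in B under
    ``presence_rule``; the diagonal is each taxon's core size under
    ``all_strains`` (the count of groups every strain of the taxon
    carries).
    """
    tx = _validate_taxa(table, taxa)
    names = list(tx)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for members in table.groups.values():
        present = {n for n, gs in tx.items() if _present(members, gs, presence_rule)}
        present_all = {n for n, gs in tx.items() if _present(members, gs, "all_strains")}
        for a, b in itertools.combinations(sorted(present), 2):
            mat.loc[a, b] += 1
            mat.loc[b, a] += 1
        for n in present_all:
            mat.loc[n, n] += 1
    return CooccurrenceResult(pairwise=mat)


def intersection_counts(
    table: OrthologueTable,
    taxa: Mapping[str, Iterable[str]],
    presence_rule: str = "all_strains",
) -> dict[frozenset[str], int]:
    """Venn-exclusive region counts over ≤7 taxa.

    Each group present in ≥1 taxon is classified by the exact set of taxa
    containing it; the counts over all non-empty subsets therefore sum to
    the pan-genome size (number of groups present anywhere).
    """
    tx = _validate_taxa(table, taxa)
    if len(tx) > 7:
        raise ValueError(
            f"{len(tx)} taxa would enumerate {2 ** len(tx)} subsets; aggregate "
            "taxa to 7 or fewer"
        )
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(tx) + 1):
        for combo in itertools.combinations(sorted(tx), r):
            counts[frozenset(combo)] = 0
    for members in table.groups.values():
        present = frozenset(
            n for n, gs in tx.items() if _present(members, gs, presence_rule)
        )
        if present:
            counts[present] += 1
    return counts


# ---------------------------------------------------------------------------
# TSV interfaces


def read_orthologue_table(
    path: str | Path,
    roster: Sequence[str] | None = None,
    species_map: Mapping[str, str] | None = None,
) -> OrthologueTable:
    """Read a long-form TSV: ``group_id\tgenome_id\tgene_id`` per member."""
    groups: dict[str, dict[str, list[str]]] = {}
    genomes_seen: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[:3] == ["group_id", "genome_id", "gene_id"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed orthologue row")
            gid, genome, gene = parts[:3]
            groups.setdefault(gid, {}).setdefault(genome, []).append(gene)
            if genome not in genomes_seen:
                genomes_seen.append(genome)
    final_roster = tuple(roster) if roster is not None else tuple(sorted(genomes_seen))
    return OrthologueTable(
        groups={
            gid: {g: tuple(genes) for g, genes in members.items()}
            for gid, members in groups.items()
        },
        roster=final_roster,
        species_map=dict(species_map or {}),
    )


def write_orthologue_table(table: OrthologueTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgenome_id\tgene_id\n")
        for gid in sorted(table.groups):
            for genome in sorted(table.groups[gid]):
                for gene in table.groups[gid][genome]:
                    fh.write(f"{gid}\t{genome}\t{gene}\n")


def write_venn_counts(counts: Mapping[frozenset[str], int], path: str | Path) -> None:
    """TSV of exclusive-region counts; taxa joined by '&' in each key."""
    with open(path, "w") as fh:
        fh.write("taxa\tcount\n")
        for subset in sorted(counts, key=lambda s: (len(s), tuple(sorted(s)))):
            fh.write(f"{'&'.join(sorted(subset))}\t{counts[subset]}\n")
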