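"""Synthetic cohorts with known truth for every pipeline stage.

The generator emulates the structure of a small multi-species bacterial
pangenome cohort: a genus-wide core of gene families, species-level
accessory families shared by all strains of one species, strain-private
families, and — on top of those — the functional gene complement implied
by a set of pathway definitions, with per-genome synthesis/salvage
strategies drawn at random. Evidence tables for all four annotation
sources are emitted with tunable false-negative and false-positive rates
and HMM bit scores drawn relative to each model's trusted cutoff, and
marker alignments are evolved site-independently (no indels) along a
known tree.

Sequences are produced by mutating per-family ancestor proteins at a
fixed within-family divergence rather than by forward evolution along a
genealogy; that is sufficient for clustering and distance tests and keeps
generation cheap and fully seeded. All randomness flows from the single
integer seed in :class:`SimulationConfig`; independent stages draw from
child streams of that seed, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .io import (
    EvidenceHit,
    GeneRecord,
    write_cutoffs,
    write_genome,
    write_hit_table,
)
from .pangenome import OrthologueTable, write_orthologue_table
from .pathways import Expr, PathwayDefinition, shipped_pathway_definitions
from .reconcile import FunctionDictionary

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_pangenome",
    "simulate_evidence",
    "simulate_marker_alignments",
    "write_cohort",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions.

    The cohort shape (a handful of species with 1–3 strains each, a core
    of families shared genus-wide plus species accessory and strain-
    private families) mirrors a small single-genus comparative study.
    ``f_n``/``f_p`` are the per-source evidence false-negative and
    false-positive rates; HMM bit scores for true hits sit above the
    trusted cutoff by |N(margin_mean, margin_sd)| bits, spurious hits
    scatter around the cutoff so trusted-cutoff filtering has work to do.
    """

    n_species: int = 3
    strains_per_species: int = 2
    core_size: int = 40
    accessory_size: int = 8
    private_genes: int = 3
    f_n: float = 0.0
    f_p: float = 0.0
    score_margin_mean: float = 25.0
    score_margin_sd: float = 8.0
    pathway_complete_prob: float = 0.7
    operon_blocks: bool = True
    protein_length: tuple[int, int] = (80, 120)
    within_family_divergence: float = 0.02
    n_markers: int = 18
    marker_length: int = 120
    tree_newick: str | None = None
    model: str = "poisson_aa"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_n", "f_p", "pathway_complete_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.core_size < 0:
            raise ValueError("core_size must be >= 0")
        if self.model not in ("poisson_aa", "jc_nt", "tn93_nt"):
            raise ValueError(f"unknown substitution model {self.model!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    families: dict[str, dict[str, tuple[str, ...]]]  # family -> genome -> genes
    gene_functions: dict[str, str]  # gene_id -> function_id
    pathway_truth: pd.DataFrame  # genome x pathway status
    strategy_truth: pd.DataFrame  # genome x vitamin verdict
    dictionary: FunctionDictionary
    cutoffs: dict[str, float]
    accession_of: dict[tuple[str, str], str]  # (source, function) -> accession
    species_map: dict[str, str]
    roster: tuple[str, ...]
    tree_newick: str | None = None

    def orthologue_table(self) -> OrthologueTable:
        return OrthologueTable(
            groups={f: dict(m) for f, m in self.families.items()},
            roster=self.roster,
            species_map=dict(self.species_map),
        )


# ---------------------------------------------------------------------------
# independent truth evaluation (deliberately separate from pathways.py)


def _truth_satisfied(expr: Expr, funcs: frozenset[str]) -> bool:
    if expr.op == "LEAF":
        return expr.function_id in funcs
    results = [_truth_satisfied(c, funcs) for c in expr.children]
    return all(results) if expr.op == "AND" else any(results)


def _truth_status(expr: Expr, funcs: frozenset[str]) -> str:
    if _truth_satisfied(expr, funcs):
        return "complete"
    children = expr.children if expr.op == "AND" else (expr,)
    n_sat = sum(_truth_satisfied(c, funcs) for c in children)
    return "partial" if n_sat > 0 else "absent"


def _satisfying_functions(expr: Expr, rng: np.random.Generator) -> set[str]:
    """One randomly chosen minimal-ish satisfying set of leaf functions."""
    if expr.op == "LEAF":
        return {expr.function_id}
    if expr.op == "AND":
        out: set[str] = set()
        for c in expr.children:
            out |= _satisfying_functions(c, rng)
        return out
    pick = expr.children[int(rng.integers(0, len(expr.children)))]
    return _satisfying_functions(pick, rng)


# ---------------------------------------------------------------------------
# pangenome simulation


def _mutate(seq: str, rate: float, alphabet: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [c for c in alphabet if c != chars[i]]
        chars[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def _random_seq(length: int, alphabet: str, rng: np.random.Generator) -> str:
    return "".join(
        alphabet[i] for i in rng.integers(0, len(alphabet), size=length)
    )


def simulate_pangenome(
    config: SimulationConfig,
    definitions: Sequence[PathwayDefinition] | None = None,
) -> tuple[dict[str, list[GeneRecord]], SyntheticTruth]:
    """Generate a cohort of genomes and its ground truth.

    Families: one per pathway function (content drawn per genome by the
    strategy lottery), ``core_size`` genus-core hypothetical families,
    ``accessory_size`` per species and ``private_genes`` per strain.
    Pathway genes are co-localised in operon-like blocks when
    ``operon_blocks`` is set; block order and the placement of the
    remaining genes are randomised per genome. Deterministic for a fixed
    seed.
    """
    if definitions is None:
        definitions = shipped_pathway_definitions()
    rng = np.random.default_rng([config.seed, 0])

    species = [f"species{si + 1:02d}" for si in range(config.n_species)]
    roster: list[str] = []
    species_map: dict[str, str] = {}
    for si, sp in enumerate(species):
        for ti in range(config.strains_per_species):
            gid = f"sp{si + 1:02d}_st{ti + 1:02d}"
            roster.append(gid)
            species_map[gid] = sp

    pathway_functions: list[str] = sorted(
        {f for d in definitions for f in d.requirement.leaves()}
    )
    core_fams = [f"hyp_core{k:04d}" for k in range(config.core_size)]
    acc_fams = {
        sp: [f"{sp}_acc{k:03d}" for k in range(config.accessory_size)]
        for sp in species
    }
    priv_fams = {
        g: [f"{g}_priv{k:03d}" for k in range(config.private_genes)] for g in roster
    }
    all_family_ids = (
        pathway_functions
        + core_fams
        + [f for sp in species for f in acc_fams[sp]]
        + [f for g in roster for f in priv_fams[g]]
    )

    # ancestor sequences; families are mutually unrelated random proteins
    lo, hi = config.protein_length
    ancestors = {
        fam: _random_seq(int(rng.integers(lo, hi + 1)), _AA, rng)
        for fam in all_family_ids
    }

    # per-genome pathway content: complete / partial / absent lottery
    content: dict[str, set[str]] = {}
    for g in roster:
        funcs: set[str] = set()
        for d in definitions:
            r = rng.random()
            sat = _satisfying_functions(d.requirement, rng)
            if r < config.pathway_complete_prob:
                funcs |= sat
            elif r < config.pathway_complete_prob + (1 - config.pathway_complete_prob) / 2:
                if len(sat) > 1:  # drop ≥1 gene: partial (or absent if size 1)
                    keep = sorted(sat)
                    n_drop = int(rng.integers(1, len(keep)))
                    drop = set(
                        np.array(keep)[rng.choice(len(keep), n_drop, replace=False)]
                    )
                    funcs |= sat - drop
            # else: absent — contribute nothing
        content[g] = funcs

    # assemble genomes
    genomes: dict[str, list[GeneRecord]] = {}
    families: dict[str, dict[str, list[str]]] = {f: {} for f in all_family_ids}
    gene_functions: dict[str, str] = {}
    for g in roster:
        fams = (
            sorted(content[g])
            + core_fams
            + acc_fams[species_map[g]]
            + priv_fams[g]
        )
        # units: operon blocks for pathway genes, singletons otherwise
        units: list[list[str]] = []
        if config.operon_blocks:
            placed: set[str] = set()
            for d in definitions:
                block = sorted(d.requirement.leaves() & content[g] - placed)
                if block:
                    units.append(block)
                    placed |= set(block)
            units += [[f] for f in fams if f not in placed]
        else:
            units = [[f] for f in fams]
        order = rng.permutation(len(units))
        flat = [f for k in order for f in units[k]]

        records: list[GeneRecord] = []
        for pos, fam in enumerate(flat):
            gene_id = f"{g}_g{pos:04d}"
            seq = _mutate(
                ancestors[fam], config.within_family_divergence, _AA, rng
            )
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=g,
                    contig_id="c1",
                    position_index=pos,
                    strand="+" if rng.random() < 0.5 else "-",
                    protein_seq=seq,
                )
            )
            families[fam].setdefault(g, []).append(gene_id)
            gene_functions[gene_id] = fam
        genomes[g] = records

    # function dictionary: every family is a function with one accession
    # per source; HMM accessions get trusted cutoffs
    accession_of: dict[tuple[str, str], str] = {}
    acc_map: dict[tuple[str, str], str] = {}
    cutoffs: dict[str, float] = {}
    for k, fam in enumerate(sorted(all_family_ids)):
        for source, prefix in (
            ("EQUIVALOG_HMM", "TIGR9"),
            ("KO", "K9"),
            ("FAMILY", "FIG9"),
            ("DOMAIN_HMM", "PF9"),
        ):
            acc = f"{prefix}{k:04d}"
            accession_of[(source, fam)] = acc
            acc_map[(source, acc)] = fam
            if source in ("EQUIVALOG_HMM", "DOMAIN_HMM"):
                cutoffs[acc] = float(np.round(rng.uniform(20.0, 100.0), 2))

    function_pathways: dict[str, set[str]] = {}
    for d in definitions:
        for f in d.requirement.leaves():
            function_pathways.setdefault(f, set()).add(d.pathway_id)
    dictionary = FunctionDictionary(
        accession_to_function=acc_map,
        function_pathways={f: frozenset(p) for f, p in function_pathways.items()},
    )

    # truth matrices via the independent evaluator
    pw_status = pd.DataFrame(
        {
            d.pathway_id: [
                _truth_status(d.requirement, frozenset(content[g])) for g in roster
            ]
            for d in definitions
        },
        index=roster,
    )
    vitamins = sorted(
        {d.vitamin for d in definitions if d.vitamin is not None}
    )
    strat_rows = {}
    for g in roster:
        funcs = frozenset(content[g])
        row = {}
        for v in vitamins:
            synth = next(
                d for d in definitions if d.vitamin == v and d.category == "synthesis"
            )
            salv = next(
                d
                for d in definitions
                if d.vitamin == v and d.category == "salvage_transport"
            )
            s1 = _truth_satisfied(synth.requirement, funcs)
            s2 = _truth_satisfied(salv.requirement, funcs)
            row[v] = (
                "both" if s1 and s2 else "synthesizer" if s1 else
                "salvager" if s2 else "neither"
            )
        strat_rows[g] = row
    strategy_truth = pd.DataFrame.from_dict(strat_rows, orient="index")[vitamins]

    truth = SyntheticTruth(
        families={
            f: {g: tuple(genes) for g, genes in m.items()}
            for f, m in families.items()
            if m
        },
        gene_functions=gene_functions,
        pathway_truth=pw_status,
        strategy_truth=strategy_truth,
        dictionary=dictionary,
        cutoffs=cutoffs,
        accession_of=accession_of,
        species_map=species_map,
        roster=tuple(roster),
        tree_newick=config.tree_newick,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# evidence simulation


def simulate_evidence(
    genomes: Mapping[str, Sequence[GeneRecord]],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> dict[str, dict[str, list[EvidenceHit]]]:
    """Emit per-genome evidence hits for all four sources.

    Each gene's true function emits one hit per source, independently
    dropped with probability ``f_n``; spurious hits to a random wrong
    accession are added per gene and source with probability ``f_p``.
    True HMM scores sit above the trusted cutoff by an absolute-normal
    margin; spurious HMM scores scatter symmetrically around the cutoff,
    so roughly half are removed by trusted-cutoff filtering.

    Returns ``{genome_id: {source: [EvidenceHit, ...]}}``.
    """
    rng = np.random.default_rng([config.seed, 1])
    sources = ("EQUIVALOG_HMM", "KO", "FAMILY", "DOMAIN_HMM")
    wrong_pool = {
        src: sorted(
            acc for (s, acc) in truth.dictionary.accession_to_function if s == src
        )
        for src in sources
    }
    out: dict[str, dict[str, list[EvidenceHit]]] = {}
    for g in truth.roster:
        per_source: dict[str, list[EvidenceHit]] = {s: [] for s in sources}
        for rec in genomes[g]:
            fam = truth.gene_functions[rec.gene_id]
            for src in sources:
                if rng.random() >= config.f_n:  # emit the true hit
                    acc = truth.accession_of[(src, fam)]
                    score = cutoff = None
                    if src in ("EQUIVALOG_HMM", "DOMAIN_HMM"):
                        cutoff = truth.cutoffs[acc]
                        score = cutoff + abs(
                            rng.normal(config.score_margin_mean, config.score_margin_sd)
                        )
                    per_source[src].append(
                        EvidenceHit(
                            gene_id=rec.gene_id,
                            source=src,
                            accession=acc,
                            bit_score=score,
                            trusted_cutoff=cutoff,
                        )
                    )
                if config.f_p > 0 and rng.random() < config.f_p:  # spurious hit
                    true_acc = truth.accession_of[(src, fam)]
                    pool = wrong_pool[src]
                    acc = pool[int(rng.integers(0, len(pool)))]
                    if acc == true_acc:
                        acc = pool[(pool.index(acc) + 1) % len(pool)]
                    score = cutoff = None
                    if src in ("EQUIVALOG_HMM", "DOMAIN_HMM"):
                        cutoff = truth.cutoffs[acc]
                        score = cutoff + rng.normal(0.0, config.score_margin_sd)
                    per_source[src].append(
                        EvidenceHit(
                            gene_id=rec.gene_id,
                            source=src,
                            accession=acc,
                            bit_score=score,
                            trusted_cutoff=cutoff,
                        )
                    )
        out[g] = per_source
    return out


# ---------------------------------------------------------------------------
# marker alignment simulation


def _tn93_rate_matrix(
    pi: np.ndarray, alpha1: float, alpha2: float, beta: float
) -> np.ndarray:
    """TN93 generator over (A, C, G, T), scaled to 1 substitution/site."""
    A, C, G, T = range(4)
    Q = np.zeros((4, 4))
    rates = {
        (A, G): alpha1, (G, A): alpha1,
        (C, T): alpha2, (T, C): alpha2,
    }
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            r = rates.get((i, j), beta)
            Q[i, j] = r * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def simulate_marker_alignments(
    config: SimulationConfig,
    pi: Sequence[float] = (0.3, 0.2, 0.2, 0.3),
    alpha1: float = 4.0,
    alpha2: float = 8.0,
    beta: float = 1.0,
) -> tuple[dict[str, dict[str, str]], str]:
    """Evolve gap-free marker sequences along ``config.tree_newick``.

    Sites evolve independently with no indels. ``poisson_aa`` and
    ``jc_nt`` draw a Poisson number of substitution events per site and
    branch (each event jumps to a uniformly chosen different residue);
    ``tn93_nt`` uses the exact TN93 transition probabilities (matrix
    exponential of the scaled generator) with base frequencies ``pi`` and
    transition-rate factors ``alpha1`` (purines) / ``alpha2``
    (pyrimidines). Branch lengths are substitutions per site; a negative
    length raises.

    Returns ``({marker: {taxon: sequence}}, tree_newick)``.
    """
    if config.tree_newick is None:
        raise ValueError("config.tree_newick must be set to simulate markers")
    from .phylo import read_newick

    tree = read_newick(config.tree_newick)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length {node.length} in tree")

    rng = np.random.default_rng([config.seed, 2])
    if config.model == "poisson_aa":
        alphabet = _AA
    else:
        alphabet = _NT
    n_states = len(alphabet)

    use_matrix = config.model == "tn93_nt"
    if use_matrix:
        pi_arr = np.asarray(pi, dtype=float)
        if not np.isclose(pi_arr.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        Qm = _tn93_rate_matrix(pi_arr, alpha1, alpha2, beta)

    markers: dict[str, dict[str, str]] = {}
    for k in range(config.n_markers):
        L = config.marker_length
        if use_matrix:
            root = rng.choice(n_states, size=L, p=pi_arr)
        else:
            root = rng.integers(0, n_states, size=L)

        leaf_states: dict[str, np.ndarray] = {}

        def evolve(node, states: np.ndarray) -> None:
            for child in node.children:
                b = float(child.length or 0.0)
                new = states.copy()
                if use_matrix:
                    P = expm(Qm * b)
                    for s in range(n_states):
                        idx = np.nonzero(states == s)[0]
                        if idx.size:
                            new[idx] = rng.choice(n_states, size=idx.size, p=P[s])
                else:
                    n_events = rng.poisson(b, size=L)
                    for i in np.nonzero(n_events)[0]:
                        s = new[i]
                        for _ in range(n_events[i]):
                            jump = int(rng.integers(0, n_states - 1))
                            s = jump if jump < s else jump + 1
                        new[i] = s
                if child.is_tip():
                    leaf_states[child.name] = new
                else:
                    evolve(child, new)

        evolve(tree, root)
        markers[f"m{k + 1:02d}"] = {
            taxon: "".join(alphabet[s] for s in states)
            for taxon, states in leaf_states.items()
        }
    return markers, config.tree_newick


# ---------------------------------------------------------------------------
# cohort emission


def write_cohort(
    outdir: str | Path,
    genomes: Mapping[str, Sequence[GeneRecord]],
    truth: SyntheticTruth,
    evidence: Mapping[str, Mapping[str, Sequence[EvidenceHit]]] | None = None,
) -> dict:
    """Write a cohort in exactly the dialects the readers consume.

    Per genome: ``<id>.faa`` + ``<id>.features.tsv`` and one hit table
    per source; cohort-wide: trusted cutoffs, function dictionary,
    true orthologue table, pathway/strategy truth and a species map.
    Returns a manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"genomes": {}, "files": {}}
    suffix = {
        "EQUIVALOG_HMM": "tigr.tblout",
        "DOMAIN_HMM": "pfam.tblout",
        "KO": "ko.tsv",
        "FAMILY": "family.tsv",
    }
    for g in truth.roster:
        faa = outdir / f"{g}.faa"
        feat = outdir / f"{g}.features.tsv"
        write_genome(genomes[g], faa, feat)
        entry = {"fasta": faa.name, "features": feat.name, "hits": {}}
        if evidence is not None:
            for src, hits in evidence[g].items():
                path = outdir / f"{g}.{suffix[src]}"
                write_hit_table(list(hits), path)
                entry["hits"][src] = path.name
        manifest["genomes"][g] = entry

    write_cutoffs(truth.cutoffs, outdir / "trusted_cutoffs.tsv")
    truth.dictionary.to_tsv(
        outdir / "function_dictionary.tsv", outdir / "function_pathways.tsv"
    )
    write_orthologue_table(truth.orthologue_table(), outdir / "orthologues.truth.tsv")
    truth.pathway_truth.to_csv(outdir / "pathway_truth.tsv", sep="\t")
    truth.strategy_truth.to_csv(outdir / "strategy_truth.tsv", sep="\t")
    with open(outdir / "species_map.tsv", "w") as fh:
        fh.write("genome_id\tspecies\n")
        for g in truth.roster:
            fh.write(f"{g}\t{truth.species_map[g]}\n")
    if truth.tree_newick:
        (outdir / "true_tree.nwk").write_text(truth.tree_newick + "\n")
    manifest["files"] = {
        "cutoffs": "trusted_cutoffs.tsv",
        "dictionary": "function_dictionary.tsv",
        "function_pathways": "function_pathways.tsv",
        "orthologue_truth": "orthologues.truth.tsv",
        "pathway_truth": "pathway_truth.tsv",
        "strategy_truth": "strategy_truth.tsv",
        "species_map": "species_map.tsv",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
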