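"""Configuration-driven drivers tying the analysis stages together.

Three independent strands, mirroring how a comparative-genomics study is
actually organised:

- :func:`run_profile` — annotate every genome from its evidence tables
  and emit the confidence-tiered assignments, the genome × pathway status
  matrix and the vitamin strategy table;
- :func:`run_pangenome` — build or load the orthologue table and emit
  the genus core list, the pairwise shared-orthologue matrix and the
  Venn-exclusive subset counts;
- :func:`run_tree` — extract single-copy markers, concatenate, compute
  model-corrected distances and write a bootstrapped NJ tree.

Each driver is deterministic for fixed inputs (and seed, where
bootstrapping is involved) and writes a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as pio
from . import pangenome as pg
from . import pathways as pw
from . import phylo
from . import reconcile as rc

__all__ = ["PipelineConfig", "run_profile", "run_pangenome", "run_tree"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see ``PipelineConfig.from_yaml``).

    YAML layout::

        genomes:
          - id: sp01_st01
            fasta: sp01_st01.faa
            features: sp01_st01.features.tsv
            hits:
              EQUIVALOG_HMM: sp01_st01.tigr.tblout
              DOMAIN_HMM: sp01_st01.pfam.tblout
              KO: sp01_st01.ko.tsv
              FAMILY: sp01_st01.family.tsv
        species_map: {sp01_st01: species01}
        cutoffs: trusted_cutoffs.tsv
        dictionary: function_dictionary.tsv
        function_pathways: function_pathways.tsv
        pathway_definitions: null        # null -> shipped definitions
        orthologue_table: null           # null -> built-in RBH clusterer
        identity_threshold: 0.7
        context_window: 5
        markers: null                    # null -> shipped 18-marker list
        bootstrap_reps: 100
        seed: 0
        outdir: out/

    Relative paths resolve against the config file's directory.
    """

    genomes: list[dict[str, Any]]
    species_map: dict[str, str]
    cutoffs: Path | None = None
    dictionary: Path | None = None
    function_pathways: Path | None = None
    pathway_definitions: Path | None = None
    orthologue_table: Path | None = None
    identity_threshold: float = 0.7
    context_window: int = 5
    markers: Path | None = None
    marker_alignments: dict[str, Path] = field(default_factory=dict)
    bootstrap_reps: int = 100
    seed: int = 0
    outdir: Path = Path("out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        base = path.parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def resolve(p: Any) -> Path | None:
            return None if p is None else (base / p)

        genomes = []
        for entry in raw.get("genomes", []):
            g = dict(entry)
            g["fasta"] = base / g["fasta"]
            g["features"] = base / g["features"]
            g["hits"] = {s: base / p for s, p in g.get("hits", {}).items()}
            genomes.append(g)
        cfg = cls(
            genomes=genomes,
            species_map=dict(raw.get("species_map", {})),
            cutoffs=resolve(raw.get("cutoffs")),
            dictionary=resolve(raw.get("dictionary")),
            function_pathways=resolve(raw.get("function_pathways")),
            pathway_definitions=resolve(raw.get("pathway_definitions")),
            orthologue_table=resolve(raw.get("orthologue_table")),
            identity_threshold=float(raw.get("identity_threshold", 0.7)),
            context_window=int(raw.get("context_window", 5)),
            markers=resolve(raw.get("markers")),
            marker_alignments={
                m: base / p for m, p in (raw.get("marker_alignments") or {}).items()
            },
            bootstrap_reps=int(raw.get("bootstrap_reps", 100)),
            seed=int(raw.get("seed", 0)),
            outdir=base / raw.get("outdir", "out"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for g in self.genomes:
            for key in ("fasta", "features"):
                if not Path(g[key]).exists():
                    raise FileNotFoundError(f"missing input file: {g[key]}")
            for p in g.get("hits", {}).values():
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
        for p in (
            self.cutoffs,
            self.dictionary,
            self.function_pathways,
            self.pathway_definitions,
            self.orthologue_table,
            self.markers,
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")


def _stage(name: str):
    """Decorator re-raising stage failures with the stage name attached."""

    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


def _load_genomes(config: PipelineConfig) -> dict[str, list[pio.GeneRecord]]:
    return {
        g["id"]: pio.read_genome(g["fasta"], g["features"], genome_id=g["id"])
        for g in config.genomes
    }


def _load_hits(
    config: PipelineConfig, cutoffs: Mapping[str, float]
) -> dict[str, list[pio.EvidenceHit]]:
    out: dict[str, list[pio.EvidenceHit]] = {}
    for g in config.genomes:
        hits: list[pio.EvidenceHit] = []
        for source, path in sorted(g.get("hits", {}).items()):
            hits.extend(pio.read_hit_table(path, source, cutoffs=cutoffs))
        out[g["id"]] = hits
    return out


def _write_manifest(config: PipelineConfig, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "genomes": [g["id"] for g in config.genomes],
        **extra,
    }
    with open(config.outdir / f"{stage}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


@_stage("profile")
def run_profile(config: PipelineConfig) -> dict[str, Path]:
    """Annotate genomes and profile pathways; returns output paths."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    cutoffs = pio.read_cutoffs(config.cutoffs) if config.cutoffs else {}
    dictionary = rc.FunctionDictionary.from_tsv(
        config.dictionary, config.function_pathways
    )
    genomes = _load_genomes(config)
    raw_hits = _load_hits(config, cutoffs)

    if config.pathway_definitions is not None:
        definitions = pw.load_pathway_definitions(config.pathway_definitions)
    else:
        definitions = pw.shipped_pathway_definitions()

    assignments: dict[str, list[rc.FunctionAssignment]] = {}
    n_dropped = 0
    outputs: dict[str, Path] = {}
    for gid in sorted(genomes):
        kept = pio.filter_trusted(raw_hits[gid])
        n_dropped += len(raw_hits[gid]) - len(kept)
        asg = rc.annotate_genome(
            genomes[gid], kept, dictionary, window=config.context_window
        )
        assignments[gid] = asg
        path = config.outdir / f"{gid}.assignments.tsv"
        rc.write_assignments(asg, path)
        outputs[f"assignments:{gid}"] = path
    logger.info("trusted-cutoff filtering dropped %d hits", n_dropped)

    known = frozenset(
        {f for d in definitions for f in d.requirement.leaves()}
        | set(dictionary.accession_to_function.values())
    )
    matrix = pw.profile_matrix(assignments, definitions, known_functions=known)
    matrix_path = config.outdir / "pathway_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    outputs["pathway_matrix"] = matrix_path

    vitamins = sorted({d.vitamin for d in definitions if d.vitamin})
    rows = []
    for gid in sorted(genomes):
        for v in vitamins:
            synth = next(
                d for d in definitions if d.vitamin == v and d.category == "synthesis"
            )
            salv = next(
                d
                for d in definitions
                if d.vitamin == v and d.category == "salvage_transport"
            )
            rows.append(
                {
                    "genome_id": gid,
                    "vitamin": v,
                    "strategy": pw.classify_strategy(gid, synth, salv, assignments[gid]),
                }
            )
    import pandas as pd

    strategy_path = config.outdir / "strategy_table.tsv"
    pd.DataFrame(rows).to_csv(strategy_path, sep="\t", index=False)
    outputs["strategy_table"] = strategy_path

    _write_manifest(
        config, "profile", {"dropped_hits": n_dropped, "n_pathways": len(definitions)}
    )
    return outputs


@_stage("pangenome")
def run_pangenome(config: PipelineConfig) -> dict[str, Path]:
    """Core list, pairwise shared matrix and Venn counts; returns paths."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    if config.orthologue_table is not None:
        table = pg.read_orthologue_table(
            config.orthologue_table, species_map=config.species_map
        )
    else:
        genomes = _load_genomes(config)
        table = pg.cluster_orthologues(
            [genomes[g["id"]] for g in config.genomes],
            identity_threshold=config.identity_threshold,
        )
        table.species_map = dict(config.species_map)

    outputs: dict[str, Path] = {}
    table_path = config.outdir / "orthologue_table.tsv"
    pg.write_orthologue_table(table, table_path)
    outputs["orthologue_table"] = table_path

    core = sorted(pg.core_genome(table, table.roster))
    core_path = config.outdir / "core_groups.tsv"
    with open(core_path, "w") as fh:
        fh.write("group_id\n")
        fh.writelines(f"{gid}\n" for gid in core)
    outputs["core_groups"] = core_path

    species = table.species_map or {g: g for g in table.roster}
    taxa: dict[str, list[str]] = {}
    for genome in table.roster:
        taxa.setdefault(species.get(genome, genome), []).append(genome)

    result = pg.pairwise_shared_matrix(table, taxa)
    matrix_path = config.outdir / "pairwise_shared.tsv"
    result.pairwise.to_csv(matrix_path, sep="\t")
    outputs["pairwise_shared"] = matrix_path

    if len(taxa) <= 7:
        counts = pg.intersection_counts(table, taxa)
        venn_path = config.outdir / "venn_counts.tsv"
        pg.write_venn_counts(counts, venn_path)
        outputs["venn_counts"] = venn_path

    _write_manifest(
        config,
        "pangenome",
        {"n_groups": len(table.groups), "core_size": len(core)},
    )
    return outputs


@_stage("tree")
def run_tree(config: PipelineConfig) -> dict[str, Path]:
    """Concatenated single-copy-marker NJ tree with bootstrap supports."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    if len(config.genomes) < 3:
        raise ValueError("tree building needs at least 3 genomes")

    if config.markers is not None:
        marker_ids = [
            line.split("\t")[0]
            for line in Path(config.markers).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
    else:
        marker_ids = [acc for acc, _ in phylo.default_markers()]

    if config.marker_alignments:
        per_marker = {
            m: phylo.read_alignment_fasta(p).rows
            for m, p in sorted(config.marker_alignments.items())
        }
        order = sorted(per_marker)
    else:
        cutoffs = pio.read_cutoffs(config.cutoffs) if config.cutoffs else {}
        genomes = _load_genomes(config)
        seqs = {
            gid: {r.gene_id: r.protein_seq for r in recs}
            for gid, recs in genomes.items()
        }
        hits: dict[str, dict[str, list[str]]] = {m: {} for m in marker_ids}
        for g in config.genomes:
            gid = g["id"]
            path = g.get("hits", {}).get("EQUIVALOG_HMM")
            if path is None:
                raise ValueError(f"genome {gid!r} lacks an EQUIVALOG_HMM hit table")
            kept = pio.filter_trusted(
                pio.read_hit_table(path, "EQUIVALOG_HMM", cutoffs=cutoffs)
            )
            for h in kept:
                if h.accession in hits:
                    hits[h.accession].setdefault(gid, []).append(h.gene_id)
        matrix = phylo.extract_single_copy(
            hits, marker_ids, [g["id"] for g in config.genomes]
        )
        per_marker = {}
        for m in matrix.marker_ids:
            block = {
                gid: seqs[gid][matrix.genes[(m, gid)]] for gid in matrix.genome_ids
            }
            lengths = {len(s) for s in block.values()}
            if len(lengths) != 1:
                raise ValueError(
                    f"marker {m!r}: unaligned member lengths {sorted(lengths)}; "
                    "supply pre-aligned marker FASTAs via marker_alignments"
                )
            per_marker[m] = block
        order = list(matrix.marker_ids)

    aln = phylo.concatenate(per_marker, order)
    tree = phylo.bootstrap_supports(
        aln,
        phylo.poisson_distance,
        n_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    tree_path = config.outdir / "concatenated_nj.nwk"
    phylo.write_newick(tree, tree_path)
    _write_manifest(
        config,
        "tree",
        {
            "n_markers": len(order),
            "alignment_length": aln.n_sites,
            "bootstrap_reps": config.bootstrap_reps,
        },
    )
    return {"tree": tree_path}
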