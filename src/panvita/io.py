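"""Readers, writers and trusted-cutoff filtering for annotation artifacts.

The input artifacts are the ones a typical bacterial comparative-genomics
workflow produces upstream: per-genome protein FASTA plus a gene feature
table (gene rank along each contig, not nucleotide coordinates), HMMER
per-target tabular hit files ("tblout") for equivalog- and domain-level
profile HMM searches, and plain TSVs for KEGG-orthology (KO) and protein
family (e.g. FIGfam) assignments.

Trusted cutoffs are per-HMM bit-score thresholds curated by the model
authors; hits at or above the cutoff are treated as reliable. HMMER's
tblout format does not carry the cutoff, so it is supplied separately as a
``{accession: cutoff}`` mapping (see :func:`read_cutoffs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SOURCES",
    "HMM_SOURCES",
    "GeneRecord",
    "EvidenceHit",
    "read_genome",
    "write_genome",
    "read_hit_table",
    "write_hit_table",
    "read_assignment_tsv",
    "read_cutoffs",
    "write_cutoffs",
    "filter_trusted",
]

#: Recognised evidence source tags, in descending priority order.
SOURCES = ("EQUIVALOG_HMM", "KO", "FAMILY", "DOMAIN_HMM")

#: Sources whose hits carry bit scores and trusted cutoffs.
HMM_SOURCES = frozenset({"EQUIVALOG_HMM", "DOMAIN_HMM"})

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with its rank-based genomic position.

    ``position_index`` is the 0-based rank of the gene along its contig;
    gene-neighbourhood reasoning (operon context) works in gene ranks, not
    base pairs.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    position_index: int
    strand: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.position_index < 0:
            raise ValueError(f"position_index must be >= 0, got {self.position_index}")
        if not self.protein_seq:
            raise ValueError(f"empty protein sequence for gene {self.gene_id!r}")
        bad = set(self.protein_seq) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non-canonical residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class EvidenceHit:
    """One raw annotation evidence item for a gene.

    ``bit_score`` and ``trusted_cutoff`` are present exactly for the HMM
    tiers (equivalog and domain); KO and FAMILY assignments carry neither.
    """

    gene_id: str
    source: str
    accession: str
    bit_score: float | None = None
    trusted_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if not self.accession:
            raise ValueError(f"empty accession for gene {self.gene_id!r}")
        if self.source in HMM_SOURCES:
            if self.bit_score is None:
                raise ValueError(
                    f"{self.source} hit for {self.gene_id!r} lacks a bit score"
                )
            if not _finite(self.bit_score) or (
                self.trusted_cutoff is not None and not _finite(self.trusted_cutoff)
            ):
                raise ValueError(
                    f"non-finite score/cutoff on hit {self.gene_id!r}/{self.accession!r}"
                )


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


# ---------------------------------------------------------------------------
# genomes


def read_genome(
    fasta_path: str | Path,
    feature_table_path: str | Path,
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Read one genome's protein FASTA plus its gene feature table.

    The feature table is a TSV with header columns ``gene_id``,
    ``contig_id``, ``position_index``, ``strand``. Every FASTA entry must
    appear in the table. Returns records sorted by
    ``(contig_id, position_index)``.

    Raises ``ValueError`` on duplicated gene ids (either file) or a FASTA
    gene missing from the table, naming the offending gene.
    """
    fasta_path = Path(fasta_path)
    feature_table_path = Path(feature_table_path)
    gid = genome_id if genome_id is not None else fasta_path.stem

    features: dict[str, tuple[str, int, str]] = {}
    with open(feature_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "contig_id", "position_index", "strand"]
        if header[: len(required)] != required:
            raise ValueError(
                f"{feature_table_path}: expected columns {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{feature_table_path}:{lineno}: malformed row")
            g, contig, pos, strand = parts[:4]
            if g in features:
                raise ValueError(
                    f"{feature_table_path}: duplicate gene_id {g!r} (line {lineno})"
                )
            features[g] = (contig, int(pos), strand)

    seen: set[str] = set()
    records: list[GeneRecord] = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{fasta_path}: duplicate FASTA header {entry.id!r}")
        seen.add(entry.id)
        if entry.id not in features:
            raise ValueError(
                f"{fasta_path}: gene {entry.id!r} absent from feature table"
            )
        contig, pos, strand = features[entry.id]
        records.append(
            GeneRecord(
                gene_id=entry.id,
                genome_id=gid,
                contig_id=contig,
                position_index=pos,
                strand=strand,
                protein_seq=str(entry.seq).upper(),
            )
        )

    records.sort(key=lambda r: (r.contig_id, r.position_index))
    _check_unique_positions(records)
    return records


def _check_unique_positions(records: Sequence[GeneRecord]) -> None:
    seen: set[tuple[str, str, int]] = set()
    for r in records:
        key = (r.genome_id, r.contig_id, r.position_index)
        if key in seen:
            raise ValueError(
                f"duplicate position {r.position_index} on contig {r.contig_id!r}"
            )
        seen.add(key)


def write_genome(
    records: Sequence[GeneRecord],
    fasta_path: str | Path,
    feature_table_path: str | Path,
) -> None:
    """Write a genome's FASTA (60-column wrap) and feature table.

    Output order is ``(contig_id, position_index)`` so write→read
    round-trips are byte-identical.
    """
    ordered = sorted(records, key=lambda r: (r.contig_id, r.position_index))
    seq_records = [
        SeqRecord(Seq(r.protein_seq), id=r.gene_id, description="") for r in ordered
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    with open(feature_table_path, "w") as fh:
        fh.write("gene_id\tcontig_id\tposition_index\tstrand\n")
        for r in ordered:
            fh.write(f"{r.gene_id}\t{r.contig_id}\t{r.position_index}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# evidence hit tables


def read_hit_table(
    path: str | Path,
    source_tag: str,
    cutoffs: Mapping[str, float] | None = None,
    score_field: str = "full",
) -> list[EvidenceHit]:
    """Read an evidence table into :class:`EvidenceHit` records.

    For the HMM tiers (``EQUIVALOG_HMM``, ``DOMAIN_HMM``) the file follows
    the HMMER per-target tabular layout ("tblout"): whitespace-separated
    columns, ``#`` comment lines; column 1 is the target (gene id), column
    3 the query (HMM accession), column 6 the full-sequence bit score and
    column 9 the best-domain bit score. ``score_field`` selects ``"full"``
    (default) or ``"best_domain"``. ``cutoffs`` maps accession →
    trusted-cutoff bit score and is required for HMM tiers.

    For ``KO`` / ``FAMILY`` the file is a TSV with columns
    ``gene_id\taccession`` (a header row is allowed).

    Raises ``ValueError`` on an unknown source tag or a malformed row,
    citing the line number.
    """
    if source_tag not in SOURCES:
        raise ValueError(f"unknown source_tag {source_tag!r}; expected one of {SOURCES}")
    path = Path(path)
    hits: list[EvidenceHit] = []

    if source_tag in HMM_SOURCES:
        if score_field not in ("full", "best_domain"):
            raise ValueError(f"score_field must be 'full' or 'best_domain'")
        if cutoffs is None:
            raise ValueError(
                f"{source_tag} tables need a trusted-cutoff mapping (see read_cutoffs)"
            )
        col = 5 if score_field == "full" else 8
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) <= col:
                    raise ValueError(f"{path}:{lineno}: malformed tblout row")
                gene_id, accession = parts[0], parts[2]
                try:
                    score = float(parts[col])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable bit score {parts[col]!r}"
                    ) from exc
                if accession not in cutoffs:
                    raise ValueError(
                        f"{path}:{lineno}: no trusted cutoff known for {accession!r}"
                    )
                hits.append(
                    EvidenceHit(
                        gene_id=gene_id,
                        source=source_tag,
                        accession=accession,
                        bit_score=score,
                        trusted_cutoff=float(cutoffs[accession]),
                    )
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if lineno == 1 and parts[:2] == ["gene_id", "accession"]:
                    continue
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: malformed assignment row")
                hits.append(
                    EvidenceHit(gene_id=parts[0], source=source_tag, accession=parts[1])
                )
    return hits


def write_hit_table(hits: Sequence[EvidenceHit], path: str | Path) -> None:
    """Write hits of one source to disk in the dialect read_hit_table expects."""
    if not hits:
        with open(path, "w") as fh:
            fh.write("# empty hit table\n")
        return
    sources = {h.source for h in hits}
    if len(sources) != 1:
        raise ValueError(f"mixed sources in one table: {sorted(sources)}")
    source = next(iter(sources))
    with open(path, "w") as fh:
        if source in HMM_SOURCES:
            fh.write("# target name  accession  query name  query accession"
                     "  evalue  score  bias  dom-evalue  dom-score\n")
            for h in hits:
                fh.write(
                    f"{h.gene_id} - {h.accession} - 1e-20 {h.bit_score:.1f} 0.0 "
                    f"1e-20 {h.bit_score:.1f}\n"
                )
        else:
            fh.write("gene_id\taccession\n")
            for h in hits:
                fh.write(f"{h.gene_id}\t{h.accession}\n")


def read_assignment_tsv(path: str | Path, source_tag: str) -> list[EvidenceHit]:
    """Alias for :func:`read_hit_table` restricted to KO/FAMILY TSVs."""
    if source_tag in HMM_SOURCES:
        raise ValueError("use read_hit_table with a cutoff mapping for HMM tiers")
    return read_hit_table(path, source_tag)


def read_cutoffs(path: str | Path) -> dict[str, float]:
    """Read a TSV of ``accession\ttrusted_cutoff`` into a mapping."""
    cutoffs: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[:2] == ["accession", "trusted_cutoff"]:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed cutoff row")
            cutoffs[parts[0]] = float(parts[1])
    return cutoffs


def write_cutoffs(cutoffs: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\ttrusted_cutoff\n")
        for acc in sorted(cutoffs):
            fh.write(f"{acc}\t{cutoffs[acc]:.2f}\n")


# ---------------------------------------------------------------------------
# trusted-cutoff filtering


def filter_trusted(hits: Iterable[EvidenceHit]) -> list[EvidenceHit]:
    """Keep HMM-tier hits whose bit score reaches the trusted cutoff.

    The comparison is inclusive (``score >= cutoff``), matching HMMER's own
    ``--cut_tc`` convention. KO/FAMILY hits pass through unchanged. Input
    order of surviving hits is preserved; the operation is idempotent.

    Raises ``ValueError`` if an HMM-tier hit lacks a cutoff.
    """
    kept: list[EvidenceHit] = []
    for h in hits:
        if h.source in HMM_SOURCES:
            if h.trusted_cutoff is None:
                raise ValueError(
                    f"{h.source} hit {h.gene_id!r}/{h.accession!r} has no trusted cutoff"
                )
            if h.bit_score >= h.trusted_cutoff:
                kept.append(h)
        else:
            kept.append(h)
    return kept
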