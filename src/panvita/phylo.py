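"""Single-copy-marker phylogenomics: distances, neighbor joining, bootstraps.

The marker set defaults to 18 universal single-copy ribosomal/translation
proteins with curated equivalog HMMs (``data/markers.txt``). Genomes are
screened with trusted-cutoff-filtered HMM hits; a marker is usable only
where every genome has exactly one above-cutoff protein. Retained marker
alignments are concatenated and pairwise distances computed under the
Poisson correction (amino acids, d = −ln(1−p)) or the Tamura–Nei 1993
model (nucleotides, distinct purine/pyrimidine transition rates and
unequal base frequencies). Trees are built by neighbor joining — a
distance-based method that is topologically consistent on additive
matrices — with bootstrap supports from column resampling.

Gaps and ambiguity codes are removed pairwise (pairwise deletion), so
each pair of sequences is compared over the sites both resolve.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from importlib import resources
from math import log
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "MarkerMatrix",
    "Alignment",
    "DistanceMatrix",
    "default_markers",
    "extract_single_copy",
    "concatenate",
    "poisson_distance",
    "tamura_nei_distance",
    "neighbor_joining",
    "bootstrap_supports",
    "bipartitions",
    "write_newick",
    "read_newick",
    "read_alignment_fasta",
    "write_alignment_fasta",
]

logger = logging.getLogger(__name__)

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_NT = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def default_markers() -> list[tuple[str, str]]:
    """The shipped 18-marker set as (accession, protein symbol) pairs."""
    ref = resources.files("panvita.data").joinpath("markers.txt")
    out: list[tuple[str, str]] = []
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc, name = line.split("\t")
        out.append((acc, name))
    return out


# ---------------------------------------------------------------------------
# marker matrix


@dataclass
class MarkerMatrix:
    """marker_id × genome_id grid of single-copy gene ids."""

    marker_ids: tuple[str, ...]
    genome_ids: tuple[str, ...]
    genes: dict[tuple[str, str], str]  # (marker, genome) -> gene_id
    dropped: tuple[str, ...] = ()  # markers removed under drop_marker policy


def extract_single_copy(
    hits: Mapping[str, Mapping[str, Sequence[str]]],
    marker_ids: Sequence[str],
    genome_ids: Sequence[str],
    policy: str = "drop_marker",
) -> MarkerMatrix:
    """Screen per-marker, per-genome (post trusted-cutoff) hit lists.

    ``hits[marker][genome]`` lists the gene ids hitting that marker HMM
    above its trusted cutoff. A cell with exactly one hit is retained;
    a marker with any 0-hit or multi-hit genome is removed genus-wide
    (``policy="drop_marker"``, logged) or raises (``policy="fail"``,
    naming marker and genome). Raises if every marker is dropped.
    """
    if not marker_ids:
        raise ValueError("marker list is empty")
    if policy not in ("drop_marker", "fail"):
        raise ValueError(f"unknown policy {policy!r}")
    kept: dict[tuple[str, str], str] = {}
    retained: list[str] = []
    dropped: list[str] = []
    for marker in marker_ids:
        cells: dict[str, str] = {}
        bad: tuple[str, int] | None = None
        for genome in genome_ids:
            found = list(hits.get(marker, {}).get(genome, []))
            if len(found) != 1:
                bad = (genome, len(found))
                break
            cells[genome] = found[0]
        if bad is not None:
            if policy == "fail":
                raise ValueError(
                    f"marker {marker!r}: genome {bad[0]!r} has {bad[1]} above-cutoff "
                    f"hits (need exactly 1)"
                )
            logger.warning(
                "dropping marker %s: genome %s has %d hits", marker, bad[0], bad[1]
            )
            dropped.append(marker)
            continue
        retained.append(marker)
        for genome, gene in cells.items():
            kept[(marker, genome)] = gene
    if not retained:
        raise ValueError("all markers dropped; no usable single-copy markers")
    return MarkerMatrix(
        marker_ids=tuple(retained),
        genome_ids=tuple(genome_ids),
        genes=kept,
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """Equal-length rows over an ordered taxon list, with marker partitions."""

    taxa: tuple[str, ...]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        missing = set(self.taxa) - set(self.rows)
        if missing:
            raise ValueError(f"taxa without rows: {sorted(missing)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[self.taxa[0]])

    def subsample_columns(self, cols: Sequence[int]) -> "Alignment":
        rows = {t: "".join(self.rows[t][c] for c in cols) for t in self.taxa}
        return Alignment(taxa=self.taxa, rows=rows)


def concatenate(
    per_marker: Mapping[str, Mapping[str, str]], marker_order: Sequence[str]
) -> Alignment:
    """Append per-marker alignments column-wise in ``marker_order``.

    Every marker alignment must cover the same taxon set; the partition
    map records each marker's column range.
    """
    if not marker_order:
        raise ValueError("no markers to concatenate")
    taxa: tuple[str, ...] | None = None
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {}
    offset = 0
    for marker in marker_order:
        block = per_marker[marker]
        if taxa is None:
            taxa = tuple(sorted(block))
            chunks = {t: [] for t in taxa}
        missing = set(taxa) - set(block)
        if missing:
            raise ValueError(
                f"marker {marker!r} lacks taxa {sorted(missing)}"
            )
        lengths = {len(s) for s in block.values()}
        if len(lengths) != 1:
            raise ValueError(f"marker {marker!r} rows have unequal lengths")
        width = lengths.pop()
        for t in taxa:
            chunks[t].append(block[t].upper())
        parts[marker] = (offset, offset + width)
        offset += width
    rows = {t: "".join(chunks[t]) for t in taxa}
    return Alignment(taxa=taxa, rows=rows, partitions=parts)


def read_alignment_fasta(path: str | Path) -> Alignment:
    from Bio import SeqIO

    rows = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return Alignment(taxa=tuple(sorted(rows)), rows=rows)


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n")
            seq = aln.rows[t]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with saturation flags.

    Saturated pairs (observed divergence beyond the model's invertible
    range) hold ``inf`` and are listed in ``saturated``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    saturated: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T):
            raise ValueError("saturation flags must be symmetric")
        vals = self.values.copy()
        vals[~finite] = 0.0
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])

    @property
    def is_finite(self) -> bool:
        return not self.saturated

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.ids)


def _pairwise_sites(a: str, b: str, alphabet: frozenset[str]) -> list[tuple[str, str]]:
    return [(x, y) for x, y in zip(a, b) if x in alphabet and y in alphabet]


def poisson_distance(aln: Alignment) -> DistanceMatrix:
    """Poisson-corrected amino-acid distance d = −ln(1−p).

    p is the mismatch fraction over pairwise-complete sites (gaps and X
    excluded per pair). p ≥ 1 would leave the correction undefined; such
    pairs are flagged saturated. Raises if a pair shares zero comparable
    sites.
    """
    n = len(aln.taxa)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            sites = _pairwise_sites(aln.rows[aln.taxa[i]], aln.rows[aln.taxa[j]], _AA)
            if not sites:
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            p = sum(x != y for x, y in sites) / len(sites)
            if p >= 1.0:
                d[i, j] = d[j, i] = np.inf
                saturated.append((aln.taxa[i], aln.taxa[j]))
            else:
                d[i, j] = d[j, i] = -log(1.0 - p)
    return DistanceMatrix(ids=aln.taxa, values=d, saturated=tuple(saturated))


def tn93_pair(a: str, b: str) -> float:
    """Tamura–Nei (1993) distance for one aligned nucleotide pair.

    Uses the closed form with empirical base frequencies averaged over
    both sequences (pairwise-complete ACGT sites only), the two
    transition proportions P1 (A↔G) and P2 (C↔T), and the transversion
    proportion Q:

        d = −k1·ln(w1) − k2·ln(w2) − k3·ln(w3)
        k1 = 2·gA·gG/gR          w1 = 1 − P1/(2·gA·gG/gR) − Q/(2·gR)
        k2 = 2·gT·gC/gY          w2 = 1 − P2/(2·gT·gC/gY) − Q/(2·gY)
        k3 = 2·(gR·gY − gA·gG·gY/gR − gT·gC·gR/gY)
                                 w3 = 1 − Q/(2·gR·gY)

    Returns ``inf`` when any log argument is non-positive (saturation) or
    when a required frequency class is absent with divergence present.
    """
    sites = _pairwise_sites(a, b, _NT)
    if not sites:
        raise ValueError("no comparable ACGT sites for pair")
    L = len(sites)
    pooled = [x for pair in sites for x in pair]
    gA = pooled.count("A") / (2 * L)
    gC = pooled.count("C") / (2 * L)
    gG = pooled.count("G") / (2 * L)
    gT = pooled.count("T") / (2 * L)
    gR, gY = gA + gG, gC + gT

    p1 = sum(1 for x, y in sites if x != y and {x, y} == {"A", "G"}) / L
    p2 = sum(1 for x, y in sites if x != y and {x, y} == {"C", "T"}) / L
    q = (
        sum(1 for x, y in sites if x != y and (x in _PURINES) != (y in _PURINES)) / L
    )
    if p1 == 0.0 and p2 == 0.0 and q == 0.0:
        return 0.0

    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gT * gC / gY if gY > 0 else 0.0
    if (p1 > 0 and k1 == 0.0) or (p2 > 0 and k2 == 0.0) or gR == 0 or gY == 0:
        return float("inf")
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)

    terms = 0.0
    if k1 > 0:
        w1 = 1.0 - p1 / k1 - q / (2.0 * gR)
        if w1 <= 0:
            return float("inf")
        terms -= k1 * log(w1)
    if k2 > 0:
        w2 = 1.0 - p2 / k2 - q / (2.0 * gY)
        if w2 <= 0:
            return float("inf")
        terms -= k2 * log(w2)
    w3 = 1.0 - q / (2.0 * gR * gY)
    if w3 <= 0:
        return float("inf")
    terms -= k3 * log(w3)
    return terms


def tamura_nei_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise Tamura–Nei 1993 distances for a nucleotide alignment."""
    n = len(aln.taxa)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                val = tn93_pair(aln.rows[aln.taxa[i]], aln.rows[aln.taxa[j]])
            except ValueError:
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                ) from None
            if not np.isfinite(val):
                d[i, j] = d[j, i] = np.inf
                saturated.append((aln.taxa[i], aln.taxa[j]))
            else:
                d[i, j] = d[j, i] = val
    return DistanceMatrix(ids=aln.taxa, values=d, saturated=tuple(saturated))


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie breaking.

    Joins are selected by the Q criterion; ties are resolved by the
    lexicographically smallest (label_i, label_j) pair, where an internal
    node inherits the smallest leaf label beneath it. Negative branch
    lengths are clamped to zero (the deficit is logged). Returns an
    unrooted tree as an skbio ``TreeNode`` whose root is the final
    trifurcation (bifurcation for 3 taxa joined at the end).

    Raises on fewer than 3 taxa or on saturated/non-finite entries.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.saturated or not np.all(np.isfinite(dm.values)):
        raise ValueError(
            f"distance matrix has saturated/non-finite pairs: {list(dm.saturated)[:5]}"
        )

    labels = list(dm.ids)  # representative (smallest leaf) label per node
    nodes = [TreeNode(name=t) for t in dm.ids]
    D = dm.values.astype(float).copy()

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.debug("clamping negative branch %.3g at %s", x, where)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for i in range(n):
            for j in range(i + 1, n):
                qij = (n - 2) * D[i, j] - r[i] - r[j]
                li, lj = sorted((labels[i], labels[j]))
                cand = (qij, li, lj, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = D[i, j] - vi
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(vi, labels[i])
        child_j.length = clamp(vj, labels[j])
        new = TreeNode(children=[child_i, child_j])
        new_dists = np.array(
            [0.5 * (D[i, k] + D[j, k] - D[i, j]) for k in range(n) if k not in (i, j)]
        )
        keep = [k for k in range(n) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_dists
        D[:-1, -1] = new_dists
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # resolve the final three nodes around an unrooted trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc), labels[0])
    b.length = clamp(0.5 * (dab + dbc - dac), labels[1])
    c.length = clamp(0.5 * (dac + dbc - dab), labels[2])
    order = np.argsort([labels[0], labels[1], labels[2]], kind="stable")
    root = TreeNode(children=[nodes[k] for k in order])
    return root


# ---------------------------------------------------------------------------
# bootstrap


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is encoded as the side of the split NOT containing
    the lexicographically smallest leaf, so the encoding is orientation-
    free.
    """
    leaves = sorted(n.name for n in tree.tips())
    anchor = leaves[0]
    full = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        if anchor in side:
            side = full - side
        out.add(side)
    return out


def bootstrap_supports(
    aln: Alignment,
    distance_fn: Callable[[Alignment], DistanceMatrix],
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ point tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times (single
    columns, not partitions); an internal edge's support is the
    percentage of replicate NJ trees containing its bipartition.
    Deterministic for a fixed seed. Supports are written into internal
    node names (as in newick support labels).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    point = neighbor_joining(distance_fn(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point)}
    n_sites = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep_aln = aln.subsample_columns(list(cols))
        try:
            rep_tree = neighbor_joining(distance_fn(rep_aln))
        except ValueError:
            continue  # saturated replicate contributes no support
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    leaves = sorted(n.name for n in point.tips())
    anchor, full = leaves[0], frozenset(leaves)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        key = side if anchor not in side else full - side
        node.name = f"{100.0 * counts[key] / n_reps:g}"
    return point


# ---------------------------------------------------------------------------
# newick


def write_newick(tree: TreeNode, path: str | Path) -> None:
    with open(path, "w") as fh:
        tree.write(fh, format="newick")


def read_newick(source: str | Path) -> TreeNode:
    """Read a newick tree from a path or a literal newick string."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        return TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise ValueError(f"malformed newick: {exc}") from None
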