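"""Distances, neighbor joining, bootstraps and newick round-trips."""

import io
import math
from collections import Counter

import numpy as np
import pytest
import skbio
from skbio.tree import nj as skbio_nj

from panvita.phylo import (
    Alignment,
    DistanceMatrix,
    bipartitions,
    bootstrap_supports,
    concatenate,
    default_markers,
    extract_single_copy,
    neighbor_joining,
    poisson_distance,
    read_newick,
    tamura_nei_distance,
    tn93_pair,
    write_newick,
)

# ---------------------------------------------------------------------------
# helpers


def random_binary_tree(taxa, rng):
    """Random binary topology with branch lengths in [0.1, 1.0]."""
    nodes = [skbio.TreeNode(name=t, length=float(rng.uniform(0.1, 1.0))) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = skbio.TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 1.0))
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = skbio.TreeNode(children=nodes)
    return root


def additive_matrix(tree):
    dm = tree.tip_tip_distances()
    ids = tuple(sorted(dm.ids))
    order = [dm.ids.index(t) for t in ids]
    return DistanceMatrix(ids=ids, values=dm.data[np.ix_(order, order)])


def tn93_reference(a, b):
    """Independent literal transcription of the 1993 closed-form distance."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    counts = Counter()
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
    gA, gC, gG, gT = (counts[c] / (2 * n) for c in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1 = sum(1 for x, y in pairs if (x, y) in (("A", "G"), ("G", "A"))) / n
    P2 = sum(1 for x, y in pairs if (x, y) in (("C", "T"), ("T", "C"))) / n
    Q = sum(
        1 for x, y in pairs if x != y and ((x in "AG") is not (y in "AG"))
    ) / n
    c1 = 2 * gA * gG / gR
    c2 = 2 * gT * gC / gY
    c3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    return (
        -c1 * math.log(1 - P1 / c1 - Q / (2 * gR))
        - c2 * math.log(1 - P2 / c2 - Q / (2 * gY))
        - c3 * math.log(1 - Q / (2 * gR * gY))
    )


# ---------------------------------------------------------------------------
# single-copy extraction and concatenation


class TestExtractSingleCopy:
    def _hits(self, markers, genomes):
        return {m: {g: [f"{g}|{m}"] for g in genomes} for m in markers}

    def test_full_matrix_when_all_single_hits(self):
        markers = [acc for acc, _ in default_markers()]
        genomes = [f"G{i}" for i in range(5)]
        mm = extract_single_copy(self._hits(markers, genomes), markers, genomes)
        assert len(mm.marker_ids) == 18
        assert mm.genes[("TIGR02013", "G0")] == "G0|TIGR02013"

    def test_duplicate_hit_drops_marker_genus_wide(self):
        markers = [acc for acc, _ in default_markers()]
        genomes = ["G0", "G1"]
        hits = self._hits(markers, genomes)
        hits["TIGR00086"]["G1"] = ["x", "y"]
        mm = extract_single_copy(hits, markers, genomes, policy="drop_marker")
        assert len(mm.marker_ids) == 17
        assert mm.dropped == ("TIGR00086",)

    def test_fail_policy_names_marker_and_genome(self):
        markers = ["M1", "M2"]
        hits = self._hits(markers, ["G0", "G1"])
        hits["M2"]["G1"] = []
        with pytest.raises(ValueError, match="M2.*G1"):
            extract_single_copy(hits, markers, ["G0", "G1"], policy="fail")

    def test_all_markers_dropped_is_an_error(self):
        with pytest.raises(ValueError, match="all markers"):
            extract_single_copy({}, ["M1"], ["G0"], policy="drop_marker")


class TestConcatenate:
    def test_two_markers_tile_the_columns(self):
        m1 = {"A": "M" * 10, "B": "K" * 10}
        m2 = {"A": "W" * 10, "B": "Y" * 10}
        aln = concatenate({"m1": m1, "m2": m2}, ["m1", "m2"])
        assert aln.n_sites == 20
        assert aln.partitions == {"m1": (0, 10), "m2": (10, 20)}
        assert aln.rows["A"] == "M" * 10 + "W" * 10

    def test_single_marker_identity(self):
        aln = concatenate({"m1": {"A": "MKW", "B": "MKY"}}, ["m1"])
        assert aln.rows == {"A": "MKW", "B": "MKY"}

    def test_missing_taxon_rejected(self):
        with pytest.raises(ValueError, match="m2"):
            concatenate(
                {"m1": {"A": "MK", "B": "MK"}, "m2": {"A": "MW"}}, ["m1", "m2"]
            )

    def test_marker_permutation_preserves_p_distances(self):
        rng = np.random.default_rng(31)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        markers = {
            f"m{k}": {
                t: "".join(aas[i] for i in rng.integers(0, 20, size=15))
                for t in "ABCD"
            }
            for k in range(4)
        }
        d1 = poisson_distance(concatenate(markers, ["m0", "m1", "m2", "m3"]))
        d2 = poisson_distance(concatenate(markers, ["m3", "m1", "m0", "m2"]))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


# ---------------------------------------------------------------------------
# distances


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(taxa=("A", "B"), rows={"A": "MKWY" * 5, "B": "MKWY" * 5})
        assert poisson_distance(aln)[("A", "B")] == 0.0

    def test_closed_form_at_p_0_1(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        aln = Alignment(taxa=("A", "B"), rows={"A": a, "B": b})
        assert poisson_distance(aln)[("A", "B")] == pytest.approx(
            -math.log(0.9), abs=1e-12
        )
        assert poisson_distance(aln)[("A", "B")] == pytest.approx(0.1053605, abs=1e-6)

    def test_saturated_pair_flagged(self):
        aln = Alignment(taxa=("A", "B"), rows={"A": "AAAA", "B": "CCCC"})
        dm = poisson_distance(aln)
        assert ("A", "B") in dm.saturated and not dm.is_finite

    def test_pairwise_deletion_of_gaps_and_x(self):
        aln = Alignment(taxa=("A", "B"), rows={"A": "MK-XWY", "B": "MKAAWF"})
        # comparable sites: positions 0,1,4,5 -> one mismatch of four
        assert poisson_distance(aln)[("A", "B")] == pytest.approx(-math.log(0.75))

    def test_zero_comparable_sites_names_pair(self):
        aln = Alignment(taxa=("A", "B"), rows={"A": "--MM", "B": "KK--"})
        with pytest.raises(ValueError, match="'A'.*'B'"):
            poisson_distance(aln)

    def test_correction_dominates_p_distance(self):
        rng = np.random.default_rng(33)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(aas[i] for i in rng.integers(0, 20, size=200))
            b = "".join(
                c if rng.random() > 0.3 else aas[int(rng.integers(0, 20))] for c in a
            )
            p = sum(x != y for x, y in zip(a, b)) / 200
            d = poisson_distance(
                Alignment(taxa=("A", "B"), rows={"A": a, "B": b})
            )[("A", "B")]
            assert d >= p
            if p > 0:
                assert d > p


class TestTamuraNei:
    def test_identical_rows_zero(self):
        aln = Alignment(taxa=("A", "B"), rows={"A": "ACGT" * 10, "B": "ACGT" * 10})
        assert tamura_nei_distance(aln)[("A", "B")] == 0.0

    def test_reduces_to_jukes_cantor_in_symmetric_limit(self):
        # equal base frequencies with equal rates over the 12 substitution
        # types means P1 = P2 = Q/4 (transitions are 4/12 of the types)
        blocks = []
        blocks += [("A", "G")] * 6 + [("G", "A")] * 6  # P1 = 12/L
        blocks += [("C", "T")] * 6 + [("T", "C")] * 6  # P2 = 12/L
        for x, y in ("AC", "CA", "GT", "TG", "AT", "TA", "CG", "GC"):
            blocks += [(x, y)] * 6  # Q = 48/L
        for c in "ACGT":
            blocks += [(c, c)] * 282
        a = "".join(x for x, _ in blocks)
        b = "".join(y for _, y in blocks)
        L = len(blocks)
        p = sum(x != y for x, y in blocks) / L
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_pair(a, b) == pytest.approx(jc, abs=1e-9)

    def test_matches_independent_transcription_on_random_pairs(self):
        rng = np.random.default_rng(34)
        nt = "ACGT"
        probs = [0.35, 0.15, 0.2, 0.3]
        for _ in range(20):
            a = "".join(rng.choice(list(nt), p=probs) for _ in range(400))
            b = list(a)
            for i in rng.choice(400, size=60, replace=False):
                b[i] = nt[(nt.index(b[i]) + int(rng.integers(1, 4))) % 4]
            b = "".join(b)
            assert tn93_pair(a, b) == pytest.approx(tn93_reference(a, b), abs=1e-12)

    def test_saturation_flagged_not_raised(self):
        aln = Alignment(
            taxa=("A", "B"), rows={"A": "AG" * 20, "B": "GA" * 20}
        )
        dm = tamura_nei_distance(aln)
        assert ("A", "B") in dm.saturated

    def test_zero_comparable_sites_is_an_error(self):
        aln = Alignment(taxa=("A", "B"), rows={"A": "NNNN", "B": "ACGT"})
        with pytest.raises(ValueError, match="comparable"):
            tamura_nei_distance(aln)


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(
            ids=("A", "B", "C"),
            values=np.array([[0, 4.0, 6.0], [4.0, 0, 8.0], [6.0, 8.0, 0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(5.0)

    def test_recovers_quartet_from_additive_matrix(self):
        # the tree ((A:1,B:2):1,(C:3,D:4)): AB=3 AC=5 AD=6 BC=6 BD=7 CD=7
        ids = ("A", "B", "C", "D")
        vals = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(ids=ids, values=vals))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # the internal edge has length 1: it is the branch of the CD (or AB)
        # cherry ancestor
        internal = [n for n in tree.non_tips()]
        assert any(n.length == pytest.approx(1.0) for n in internal)

    def test_consistency_on_random_additive_matrices(self):
        rng = np.random.default_rng(35)
        for trial in range(100):
            n = int(rng.integers(4, 9))
            taxa = [f"t{k}" for k in range(n)]
            tree = random_binary_tree(taxa, rng)
            dm = additive_matrix(tree)
            recovered = neighbor_joining(dm)
            assert bipartitions(recovered) == bipartitions(tree), f"trial {trial}"

    def test_agrees_with_skbio_topology(self):
        rng = np.random.default_rng(36)
        for _ in range(20):
            taxa = [f"t{k}" for k in range(6)]
            tree = random_binary_tree(taxa, rng)
            dm = additive_matrix(tree)
            noisy = dm.values + rng.uniform(0, 0.05, dm.values.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            ours = neighbor_joining(DistanceMatrix(ids=dm.ids, values=noisy))
            theirs = skbio_nj(skbio.DistanceMatrix(noisy, ids=dm.ids))
            assert bipartitions(ours) == bipartitions(theirs)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(37)
        taxa = [f"t{k}" for k in range(7)]
        tree = random_binary_tree(taxa, rng)
        dm = additive_matrix(tree)
        ref = bipartitions(neighbor_joining(dm))
        for _ in range(5):
            perm = rng.permutation(len(dm.ids))
            shuffled = DistanceMatrix(
                ids=tuple(dm.ids[i] for i in perm),
                values=dm.values[np.ix_(perm, perm)],
            )
            assert bipartitions(neighbor_joining(shuffled)) == ref

    def test_branch_lengths_clamped_nonnegative(self):
        rng = np.random.default_rng(38)
        vals = rng.uniform(0.5, 1.0, (6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        tree = neighbor_joining(
            DistanceMatrix(ids=tuple("ABCDEF"), values=vals)
        )
        for node in tree.traverse(include_self=False):
            assert node.length >= 0

    def test_too_few_taxa_and_saturation_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(
                DistanceMatrix(ids=("A", "B"), values=np.array([[0, 1.0], [1.0, 0]]))
            )
        vals = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="saturated"):
            neighbor_joining(
                DistanceMatrix(
                    ids=("A", "B", "C"), values=vals, saturated=(("A", "C"),)
                )
            )


# ---------------------------------------------------------------------------
# bootstrap and newick


class TestBootstrap:
    def _signal_alignment(self):
        # every column supports AB|CD at 40% between-group divergence
        cols_same = 60
        cols_diff = 40
        a = "M" * cols_same + "K" * cols_diff
        c = "M" * cols_same + "W" * cols_diff
        return Alignment(taxa=("A", "B", "C", "D"), rows={"A": a, "B": a, "C": c, "D": c})

    def test_fixed_seed_reproducible(self):
        aln = self._signal_alignment()
        t1 = bootstrap_supports(aln, poisson_distance, n_reps=30, seed=5)
        t2 = bootstrap_supports(aln, poisson_distance, n_reps=30, seed=5)
        s1 = io.StringIO()
        s2 = io.StringIO()
        t1.write(s1, format="newick")
        t2.write(s2, format="newick")
        assert s1.getvalue() == s2.getvalue()

    def test_congruent_signal_gets_full_support(self):
        aln = self._signal_alignment()
        tree = bootstrap_supports(aln, poisson_distance, n_reps=50, seed=6)
        supports = [float(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_within_range(self):
        rng = np.random.default_rng(39)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rows = {
            t: "".join(aas[i] for i in rng.integers(0, 20, size=80))
            for t in "ABCDE"
        }
        aln = Alignment(taxa=tuple("ABCDE"), rows=rows)
        tree = bootstrap_supports(aln, poisson_distance, n_reps=25, seed=7)
        for n in tree.non_tips(include_self=False):
            if n.name:
                assert 0.0 <= float(n.name) <= 100.0

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports(self._signal_alignment(), poisson_distance, n_reps=0)


class TestNewick:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(40)
        tree = random_binary_tree([f"t{k}" for k in range(8)], rng)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert bipartitions(back) == bipartitions(tree)
        d1, d2 = tree.tip_tip_distances(), back.tip_tip_distances()
        order = [d2.ids.index(t) for t in d1.ids]
        np.testing.assert_allclose(d1.data, d2.data[np.ix_(order, order)], atol=1e-9)

    def test_hand_written_three_taxon_string(self):
        tree = read_newick("(A:1,B:2,C:3);")
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]
        assert {t.name: t.length for t in tree.tips()}["C"] == 3.0

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("(A:1,B:2(;")
        with pytest.raises(ValueError, match="newick"):
            read_newick(p)

    def test_random_trees_round_trip_bipartition_sets(self, tmp_path):
        rng = np.random.default_rng(41)
        for k in range(10):
            n = int(rng.integers(4, 21))
            tree = random_binary_tree([f"x{j}" for j in range(n)], rng)
            p = tmp_path / f"t{k}.nwk"
            write_newick(tree, p)
            assert bipartitions(read_newick(p)) == bipartitions(tree)
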