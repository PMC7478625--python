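"""Orthologue clustering and core/pan co-occurrence statistics."""

import itertools

import numpy as np
import pytest

from panvita.io import GeneRecord
from panvita.pangenome import (
    OrthologueTable,
    cluster_orthologues,
    core_genome,
    intersection_counts,
    pairwise_shared_matrix,
    read_orthologue_table,
    write_orthologue_table,
)


def random_table(rng, n_genomes=6, n_groups=50):
    roster = tuple(f"G{i}" for i in range(n_genomes))
    groups = {}
    for k in range(n_groups):
        members = {
            g: tuple(f"{g}_x{k}_{j}" for j in range(rng.integers(1, 3)))
            for g in roster
            if rng.random() < 0.6
        }
        if members:
            groups[f"og{k:03d}"] = members
    return OrthologueTable(groups=groups, roster=roster)


class TestCoreGenome:
    def test_group_missing_one_genome_excluded(self):
        t = OrthologueTable(
            groups={
                "g1": {"A": ("a1",), "B": ("b1",), "C": ("c1",)},
                "g2": {"A": ("a2",), "B": ("b2",)},
            },
            roster=("A", "B", "C"),
        )
        assert core_genome(t, {"A", "B", "C"}) == {"g1"}
        assert core_genome(t, {"A", "B"}) == {"g1", "g2"}

    def test_single_genome_core_is_all_its_groups(self):
        t = OrthologueTable(
            groups={"g1": {"A": ("a1",)}, "g2": {"B": ("b1",)}},
            roster=("A", "B"),
        )
        assert core_genome(t, {"A"}) == {"g1"}

    def test_empty_or_unknown_genomes_rejected(self):
        t = OrthologueTable(groups={}, roster=("A",))
        with pytest.raises(ValueError):
            core_genome(t, set())
        with pytest.raises(ValueError):
            core_genome(t, {"Z"})

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = random_table(rng)
            ids = set(
                rng.choice(t.roster, size=rng.integers(1, len(t.roster) + 1), replace=False)
            )
            expected = {
                gid
                for gid, members in t.groups.items()
                if all(g in members for g in ids)
            }
            assert core_genome(t, ids) == expected

    def test_anti_monotone_adding_genomes_never_grows_core(self):
        rng = np.random.default_rng(8)
        t = random_table(rng)
        sets = [{"G0"}, {"G0", "G1"}, {"G0", "G1", "G2"}, set(t.roster)]
        cores = [core_genome(t, s) for s in sets]
        for small, big in zip(cores, cores[1:]):
            assert big <= small


class TestPairwiseShared:
    def test_two_single_genome_taxa(self):
        groups = {}
        for k in range(8):
            members = {}
            if k < 7:
                members["A"] = (f"a{k}",)
            if k < 5 or k == 7:
                members["B"] = (f"b{k}",)
            groups[f"og{k}"] = members
        t = OrthologueTable(groups=groups, roster=("A", "B"))
        res = pairwise_shared_matrix(t, {"ta": ["A"], "tb": ["B"]})
        assert res.pairwise.loc["ta", "tb"] == 5
        assert res.pairwise.loc["ta", "ta"] == 7
        assert res.pairwise.loc["tb", "tb"] == 6

    def test_symmetric_and_bounded_by_diagonal(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = random_table(rng)
            taxa = {"t1": t.roster[:2], "t2": t.roster[2:4], "t3": t.roster[4:]}
            m = pairwise_shared_matrix(t, taxa).pairwise
            assert (m.values == m.values.T).all()
            for a, b in itertools.combinations(m.index, 2):
                assert m.loc[a, b] <= min(m.loc[a, a], m.loc[b, b])

    def test_diagonal_equals_taxon_core(self):
        rng = np.random.default_rng(10)
        t = random_table(rng)
        taxa = {"t1": t.roster[:3], "t2": t.roster[3:]}
        m = pairwise_shared_matrix(t, taxa).pairwise
        for name, genomes in taxa.items():
            assert m.loc[name, name] == len(core_genome(t, set(genomes)))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        for rule in ("all_strains", "any_strain"):
            t = random_table(rng)
            taxa = {"t1": t.roster[:2], "t2": t.roster[2:4], "t3": t.roster[4:]}
            m = pairwise_shared_matrix(t, taxa, presence_rule=rule).pairwise

            def present(members, genomes):
                if rule == "all_strains":
                    return all(g in members for g in genomes)
                return any(g in members for g in genomes)

            for a, b in itertools.combinations(taxa, 2):
                expected = sum(
                    present(mem, taxa[a]) and present(mem, taxa[b])
                    for mem in t.groups.values()
                )
                assert m.loc[a, b] == expected

    def test_overlapping_taxa_rejected(self):
        rng = np.random.default_rng(12)
        t = random_table(rng)
        with pytest.raises(ValueError, match="overlap"):
            pairwise_shared_matrix(t, {"t1": t.roster[:3], "t2": t.roster[2:]})


class TestIntersectionCounts:
    def test_two_taxa_venn_regions(self):
        groups = {}
        for k in range(3):
            groups[f"both{k}"] = {"A": (f"a{k}",), "B": (f"b{k}",)}
        for k in range(2):
            groups[f"onlya{k}"] = {"A": (f"ax{k}",)}
        groups["onlyb0"] = {"B": ("bx0",)}
        t = OrthologueTable(groups=groups, roster=("A", "B"))
        counts = intersection_counts(t, {"ta": ["A"], "tb": ["B"]})
        assert counts[frozenset({"ta", "tb"})] == 3
        assert counts[frozenset({"ta"})] == 2
        assert counts[frozenset({"tb"})] == 1

    def test_regions_sum_to_pan_genome(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            t = random_table(rng)
            taxa = {"t1": t.roster[:2], "t2": t.roster[2:4], "t3": t.roster[4:]}
            counts = intersection_counts(t, taxa, presence_rule="any_strain")
            pan = sum(1 for m in t.groups.values() if m)
            assert sum(counts.values()) == pan

    def test_matches_exhaustive_per_group_classification(self):
        rng = np.random.default_rng(14)
        t = random_table(rng, n_genomes=4)
        taxa = {f"t{i}": (t.roster[i],) for i in range(4)}
        counts = intersection_counts(t, taxa)
        expected: dict[frozenset, int] = {}
        for members in t.groups.values():
            key = frozenset(f"t{i}" for i in range(4) if t.roster[i] in members)
            if key:
                expected[key] = expected.get(key, 0) + 1
        assert {k: v for k, v in counts.items() if v} == expected

    def test_more_than_seven_taxa_advises_aggregation(self):
        roster = tuple(f"G{i}" for i in range(8))
        t = OrthologueTable(
            groups={"g": {r: (f"{r}_x",) for r in roster}}, roster=roster
        )
        with pytest.raises(ValueError, match="[Aa]ggregate"):
            intersection_counts(t, {r: (r,) for r in roster})


class TestClusterer:
    def _genomes_with_identical_families(self, n_genomes=3, n_fams=10, seed=0):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        fams = [
            "".join(aas[i] for i in rng.integers(0, 20, size=90))
            for _ in range(n_fams)
        ]
        genomes = []
        for g in range(n_genomes):
            genomes.append(
                [
                    GeneRecord(f"G{g}_f{k}", f"G{g}", "c1", k, "+", fams[k])
                    for k in range(n_fams)
                ]
            )
        return genomes

    def test_identical_copies_give_one_group_per_family(self):
        genomes = self._genomes_with_identical_families()
        table = cluster_orthologues(genomes)
        assert len(table.groups) == 10
        assert all(len(m) == 3 for m in table.groups.values())

    def test_unmatched_protein_becomes_singleton(self):
        genomes = self._genomes_with_identical_families(n_genomes=2)
        rng = np.random.default_rng(99)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        odd = "".join(aas[i] for i in rng.integers(0, 20, size=90))
        genomes[0].append(GeneRecord("G0_odd", "G0", "c1", 10, "+", odd))
        table = cluster_orthologues(genomes)
        singletons = [m for m in table.groups.values() if sum(map(len, m.values())) == 1]
        assert len(singletons) == 1
        assert singletons[0] == {"G0": ("G0_odd",)}

    def test_fewer_than_two_genomes_rejected(self):
        genomes = self._genomes_with_identical_families(n_genomes=1)
        with pytest.raises(ValueError):
            cluster_orthologues(genomes)

    def test_recovers_generator_families_exactly(self, clean_cohort):
        """Rand index 1.0 against truth on a zero-divergence-threshold cohort."""
        _, genomes, truth, _ = clean_cohort
        table = cluster_orthologues([genomes[g] for g in truth.roster])
        inferred = {
            gene: gid
            for gid, members in table.groups.items()
            for genes in members.values()
            for gene in genes
        }
        true_label = {
            gene: fam
            for fam, members in truth.families.items()
            for genes in members.values()
            for gene in genes
        }
        assert set(inferred) == set(true_label)
        # partitions identical <=> same co-membership relation (Rand index 1)
        by_inferred: dict[str, set] = {}
        by_truth: dict[str, set] = {}
        for gene, lab in inferred.items():
            by_inferred.setdefault(lab, set()).add(gene)
        for gene, lab in true_label.items():
            by_truth.setdefault(lab, set()).add(gene)
        assert set(map(frozenset, by_inferred.values())) == set(
            map(frozenset, by_truth.values())
        )


class TestTableIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        t = random_table(rng)
        p = tmp_path / "orth.tsv"
        write_orthologue_table(t, p)
        back = read_orthologue_table(p, roster=t.roster)
        assert back.groups == t.groups
        assert back.roster == t.roster

    def test_duplicate_gene_across_groups_rejected(self):
        with pytest.raises(ValueError, match="multiple groups"):
            OrthologueTable(
                groups={"g1": {"A": ("a1",)}, "g2": {"A": ("a1",)}},
                roster=("A",),
            )
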