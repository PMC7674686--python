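"""Gene-tree classification: clade extraction, merge logic, synteny rescue."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tnfevo import fixtures
from tnfevo.model import GeneTree, UNASSIGNED
from tnfevo.orthogroup import (
    ClassificationConfig,
    assignments_to_matrix,
    classify,
    merged_group_name,
    supported_clades,
)
from tnfevo.synteny import SyntenyEvidence
from tnfevo.synthgen import SimulationConfig, copy_id, simulate_gene_tree, simulate_history


def naive_clades(newick: str) -> list[tuple[frozenset[str], int | None]]:
    """Minimal recursive newick reader used as an independent oracle."""
    text = newick.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            assert text[pos] == ")"
            pos += 1
            label = ""
            while pos < len(text) and text[pos] not in ",()":
                label += text[pos]
                pos += 1
            support = int(label.split(":")[0]) if label.split(":")[0] else None
            leaves = frozenset().union(*(c[0] for c in children))
            collected.append((leaves, support, children))
            return leaves, support, children
        label = ""
        while pos < len(text) and text[pos] not in ",()":
            label += text[pos]
            pos += 1
        return frozenset([label.split(":")[0]]), None, []

    collected: list = []
    root = parse()
    out = []
    for leaves, support, _ in collected:
        if leaves != root[0]:  # root clade excluded: no subtending branch
            out.append((leaves, support))
    return out


def random_newick(rng: np.random.Generator, n_leaves: int) -> str:
    labels = [f"s{i}|g{i}" for i in range(n_leaves)]

    def build(items):
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(1, len(items)))
        left, right = build(items[:k]), build(items[k:])
        support = int(rng.integers(0, 101))
        return f"({left},{right}){support}"

    rng.shuffle(labels)
    return build(labels) + ";"


class TestSupportedClades:
    def test_star_tree_yields_only_singletons(self):
        tree = GeneTree.from_newick("(a|1,b|2,c|3);")
        clades = supported_clades(tree, 95)
        assert all(len(c) == 1 for c in clades)
        assert len(clades) == 3

    def test_high_support_clade_returned(self):
        tree = GeneTree.from_newick("((a|1,b|2)99,(c|3,d|4)80);")
        clades = supported_clades(tree, 95)
        assert frozenset({"a|1", "b|2"}) in clades
        assert frozenset({"c|3", "d|4"}) not in clades

    def test_matches_exhaustive_edge_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            newick = random_newick(rng, 20)
            tree = GeneTree.from_newick(newick)
            for threshold in (0, 50, 95, 100):
                got = {c for c in supported_clades(tree, threshold) if len(c) > 1}
                expected = {
                    leaves
                    for leaves, support in naive_clades(newick)
                    if len(leaves) > 1 and (support or 0) >= threshold
                }
                assert got == expected

    def test_clade_set_shrinks_as_threshold_rises(self):
        rng = np.random.default_rng(5)
        tree = GeneTree.from_newick(random_newick(rng, 15))
        previous = None
        for threshold in (0, 25, 50, 75, 95, 100):
            current = set(supported_clades(tree, threshold))
            if previous is not None:
                assert current <= previous
            previous = current


class TestMergedNames:
    @pytest.mark.parametrize(
        "names,expected",
        [
            (["TNFSF1", "TNFSF2"], "TNFSF1/2"),
            (["TNFSF1"], "TNFSF1"),
            (["EDA", "BALM"], "BALM/EDA"),
            (["TNFSF13", "TNFSF13B"], "TNFSF13/TNFSF13B"),
        ],
    )
    def test_naming(self, names, expected):
        assert merged_group_name(names) == expected


class TestClassify:
    def test_inseparable_reference_pair_merges(self):
        # two human genes plus fish co-orthologs inside one 100% clade with
        # no supported internal structure: a single slash-named group
        newick = (
            "((Homo|TNFSF1,Homo|TNFSF2,Danio|d1,Takifugu|t1)100,"
            "(Danio|x1,Latimeria|x2)100);"
        )
        tree = GeneTree.from_newick(newick)
        refs = {"TNFSF1": "TNFSF1", "TNFSF2": "TNFSF2"}
        assignments = classify(tree, ClassificationConfig(reference_species="Homo"), [], refs)
        by_acc = {a.accession: a.group for a in assignments}
        assert by_acc["TNFSF1"] == by_acc["TNFSF2"] == "TNFSF1/2"
        assert by_acc["d1"] == "TNFSF1/2"

    def test_supported_split_separates_references(self):
        # a 100% branch splits the two human genes with each fish species
        # wholly on one side: two distinct groups
        newick = (
            "((Homo|TNFSF10,Danio|d1,Rhincodon|r1)100,"
            "(Homo|TNFSF11,Takifugu|t1,Latimeria|l1)100)100;"
        )
        tree = GeneTree.from_newick(newick)
        refs = {"TNFSF10": "TNFSF10", "TNFSF11": "TNFSF11"}
        assignments = classify(tree, ClassificationConfig(reference_species="Homo"), [], refs)
        by_acc = {a.accession: a.group for a in assignments}
        assert by_acc["TNFSF10"] == "TNFSF10"
        assert by_acc["d1"] == "TNFSF10"
        assert by_acc["TNFSF11"] == "TNFSF11"
        assert by_acc["t1"] == "TNFSF11"

    def test_novel_group_auto_named_from_smallest_accession(self):
        newick = "((Danio|zzz,Latimeria|aaa)100,(Homo|TNFSF6,Danio|d6)100);"
        tree = GeneTree.from_newick(newick)
        assignments = classify(tree, ClassificationConfig(), [], {"TNFSF6": "TNFSF6"})
        by_acc = {a.accession: a.group for a in assignments}
        assert by_acc["zzz"] == by_acc["aaa"] == "GRP-aaa"

    def test_single_species_clade_is_not_a_novel_group(self):
        newick = "((Danio|a,Danio|b)100,(Homo|TNFSF6,Danio|d6)100);"
        tree = GeneTree.from_newick(newick)
        assignments = classify(tree, ClassificationConfig(), [], {"TNFSF6": "TNFSF6"})
        by_acc = {a.accession: a.group for a in assignments}
        assert by_acc["a"] == UNASSIGNED

    def test_low_support_stragglers_rescued_by_synteny(self):
        # strongly supported core with the human reference; two shark genes
        # attach only at 79% but share chromosome-level synteny with the core
        newick = (
            "(((Homo|TNFSF15,Rhincodon|r_core,Callorhinchus|c_core)98,"
            "Rhincodon|r_stray,Callorhinchus|c_stray)79,"
            "(Homo|TNFSF6,Danio|d6)100);"
        )
        tree = GeneTree.from_newick(newick)
        evidence = [
            SyntenyEvidence(
                species_a="Rhincodon",
                gene_a="r_stray",
                species_b="Homo",
                gene_b="TNFSF15",
                evidence_class="same_chromosome",
                collision_probability=0.05,
            ),
            SyntenyEvidence(
                species_a="Callorhinchus",
                gene_a="c_stray",
                species_b="Homo",
                gene_b="TNFSF15",
                evidence_class="same_chromosome",
                collision_probability=0.05,
            ),
        ]
        refs = {"TNFSF15": "TNFSF15", "TNFSF6": "TNFSF6"}
        assignments = classify(tree, ClassificationConfig(reference_species="Homo"), evidence, refs)
        by_acc = {a.accession: a for a in assignments}
        assert by_acc["r_core"].group == "TNFSF15"
        assert by_acc["r_stray"].group == "TNFSF15"
        assert "synteny_same_chromosome" in by_acc["r_stray"].flags

    def test_conflicting_rescue_stays_unassigned(self):
        newick = (
            "((Homo|TNFSF15,Rhincodon|r1)100,(Homo|TNFSF6,Danio|d6)100,"
            "Callorhinchus|stray);"
        )
        tree = GeneTree.from_newick(newick)
        evidence = [
            SyntenyEvidence(
                species_a="Callorhinchus", gene_a="stray", species_b="Homo",
                gene_b="TNFSF15", evidence_class="same_chromosome",
                collision_probability=0.05,
            ),
            SyntenyEvidence(
                species_a="Callorhinchus", gene_a="stray", species_b="Homo",
                gene_b="TNFSF6", evidence_class="same_chromosome",
                collision_probability=0.05,
            ),
        ]
        refs = {"TNFSF15": "TNFSF15", "TNFSF6": "TNFSF6"}
        assignments = classify(tree, ClassificationConfig(reference_species="Homo"), evidence, refs)
        stray = next(a for a in assignments if a.accession == "stray")
        assert stray.group == UNASSIGNED
        assert "conflict" in stray.flags

    def test_rescue_off_leaves_out_of_clade_leaves_unassigned(self):
        newick = "((Homo|TNFSF15,Rhincodon|r1)100,Callorhinchus|stray);"
        tree = GeneTree.from_newick(newick)
        config = ClassificationConfig(min_support=100, allow_synteny_rescue=False)
        assignments = classify(tree, config, [], {"TNFSF15": "TNFSF15"})
        stray = next(a for a in assignments if a.accession == "stray")
        assert stray.group == UNASSIGNED

    def test_simulator_truth_recovered_without_noise(self, species_tree):
        config = SimulationConfig(
            seed=17, loss_rate=0.0, tandem_rate=0.0, rearrangement_rate=0.0,
            support_noise=0.0, wgd_retention_prob=0.8, genome_gene_count=50,
        )
        history, matrix = simulate_history(config, species_tree)
        gene_tree = simulate_gene_tree(history, config)
        refs = {
            copy_id(g, "Homo_sapiens", i): g
            for g in history.groups
            for i in range(history.repertoires["Homo_sapiens"].get(g, 0))
        }
        assignments = classify(gene_tree, ClassificationConfig(), [], refs)
        # compare leaf partitions, ignoring group naming
        truth: dict[str, set] = {}
        for leaf in gene_tree.leaves:
            truth.setdefault(leaf.accession.rsplit("-", 2)[0], set()).add(leaf.accession)
        inferred: dict[str, set] = {}
        for a in assignments:
            inferred.setdefault(a.group, set()).add(a.accession)
        inferred.pop(UNASSIGNED, None)
        assert set(map(frozenset, truth.values())) == set(map(frozenset, inferred.values()))


class TestMonotonicity:
    def test_group_count_non_increasing_in_support_on_simulated_trees(self, species_tree):
        # supports are bimodal here (100 minus half-normal noise), the regime
        # the threshold is designed for
        for seed in range(6):
            config = SimulationConfig(
                seed=seed, loss_rate=0.25, tandem_rate=0.0, rearrangement_rate=0.0,
                support_noise=12.0, wgd_retention_prob=0.8, genome_gene_count=50,
            )
            history, _ = simulate_history(config, species_tree)
            if len(history.groups) < 2:
                continue
            gene_tree = simulate_gene_tree(history, config)
            refs = {
                copy_id(g, "Homo_sapiens", i): g
                for g in history.groups
                for i in range(history.repertoires["Homo_sapiens"].get(g, 0))
            }
            counts = []
            for threshold in (50, 70, 80, 90, 95, 99, 100):
                cfg = ClassificationConfig(min_support=threshold, allow_synteny_rescue=False)
                assignments = classify(gene_tree, cfg, [], refs)
                groups = {a.group for a in assignments if a.assigned}
                counts.append(len(groups))
            assert counts == sorted(counts, reverse=True)


class TestAssignmentsToMatrix:
    def test_census_expansion_reproduces_totals(self):
        assignments = fixtures.census_assignments()
        gnath = {
            "Callorhinchus_milii", "Rhincodon_typus", "Danio_rerio",
            "Takifugu_rubripes", "Lepisosteus_oculatus", "Latimeria_chalumnae",
            "Homo_sapiens",
        }
        gn = [a for a in assignments if a.species in gnath]
        assert len(gn) == 145
        assert sum(a.assigned for a in gn) == 140
        matrix = assignments_to_matrix(assignments)
        assert int(matrix.other[sorted(gnath)].sum()) == 5
        reference = fixtures.count_matrix()
        assert matrix.totals.sort_index().equals(reference.totals.sort_index())

    def test_empty_assignment_list(self):
        matrix = assignments_to_matrix([])
        assert matrix.groups == [] and matrix.species == []

    @given(st.integers(1, 5), st.integers(1, 5))
    @settings(max_examples=20, deadline=None)
    def test_column_sums_equal_assignment_counts(self, n_a, n_b):
        from tnfevo.model import SequenceAssignment

        assignments = [
            SequenceAssignment(accession=f"x{i}", species="spA", group="G")
            for i in range(n_a)
        ] + [
            SequenceAssignment(accession=f"y{i}", species="spB", group="G")
            for i in range(n_b)
        ]
        matrix = assignments_to_matrix(assignments)
        assert int(matrix.counts["G"].sum()) == n_a + n_b
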