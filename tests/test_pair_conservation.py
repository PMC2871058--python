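"""Canonical pair keys, the induced-subtree conservation score, summaries."""

import numpy as np
import pytest

from geneorder import (
    CODIRECTIONAL,
    aggregate_conserved_pairs,
    canonical_key,
    conservation_score,
    conservation_vs_distance,
    conservation_orientation_curve,
    dedup_splice_variants,
    extract_adjacent_pairs,
    generate_flip_fixture,
    read_newick_string,
)
from geneorder.errors import MissingDataError
from geneorder.pair_conservation import ConservedPair, PairKey, PairOccurrence
from geneorder.synthetic_data import random_coalescent_tree, subtree_length_bruteforce
from conftest import make_gene


def pair_from_strands(left_strand, right_strand, left_cluster="X",
                      right_cluster="Y"):
    left = make_gene(gene_id="gL", start=100, end=200, strand=left_strand,
                     cluster_id=left_cluster)
    right = make_gene(gene_id="gR", start=500, end=600, strand=right_strand,
                      cluster_id=right_cluster)
    (pair,) = extract_adjacent_pairs([left, right])
    return pair


class TestCanonicalKey:
    def test_divergent_key_is_symmetric_in_groups(self):
        k1 = canonical_key(pair_from_strands("-", "+", "X", "Y"), "orthomcl")
        k2 = canonical_key(pair_from_strands("-", "+", "Y", "X"), "orthomcl")
        assert k1 == k2

    def test_unassigned_gene_gives_no_key(self):
        pair = pair_from_strands("-", "+", "X", None)
        assert canonical_key(pair, "orthomcl") is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_codirectional_key_invariant_under_chromosome_flip(self, strand):
        left = make_gene(gene_id="gU", start=100, end=200, strand=strand,
                         cluster_id="X")
        right = make_gene(gene_id="gD", start=500, end=600, strand=strand,
                          cluster_id="Y")
        records = [left, right]
        (pair,) = extract_adjacent_pairs(records)
        (flipped_pair,) = extract_adjacent_pairs(
            generate_flip_fixture(records, "spA", "chr1"))
        key = canonical_key(pair, "orthomcl")
        assert key == canonical_key(flipped_pair, "orthomcl")
        assert key.orientation == CODIRECTIONAL
        # upstream gene is the one transcribed toward the other
        assert key.groups == (("X", "Y") if strand == "+" else ("Y", "X"))


class TestConservationScore:
    def test_pairwise_path(self, tree_abc):
        assert conservation_score({"A", "B"}, tree_abc) == pytest.approx(0.3)

    def test_path_through_root(self, tree_abc):
        assert conservation_score({"A", "C"}, tree_abc) == pytest.approx(0.45)

    def test_full_leaf_set(self, tree_abc):
        assert conservation_score({"A", "B", "C"}, tree_abc) == pytest.approx(0.65)

    def test_singleton_scores_zero(self, tree_abc):
        assert conservation_score({"A"}, tree_abc) == 0.0

    def test_unknown_species_rejected_by_name(self, tree_abc):
        with pytest.raises(MissingDataError, match="Z"):
            conservation_score({"A", "Z"}, tree_abc)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        names = [f"L{i}" for i in range(n)]
        tree = random_coalescent_tree(names, 0.3, rng)
        for _ in range(5):
            k = int(rng.integers(1, n + 1))
            subset = list(rng.choice(names, size=k, replace=False))
            assert conservation_score(subset, tree) == pytest.approx(
                subtree_length_bruteforce(tree, subset), abs=1e-9)

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(123)
        names = [f"L{i}" for i in range(10)]
        tree = random_coalescent_tree(names, 0.3, rng)
        subset: list[str] = []
        previous = 0.0
        for name in rng.permutation(names):
            subset.append(str(name))
            score = conservation_score(subset, tree)
            assert score >= previous - 1e-12
            previous = score

    def test_root_independent(self):
        rng = np.random.default_rng(7)
        names = [f"L{i}" for i in range(8)]
        tree = random_coalescent_tree(names, 0.3, rng)
        subset = ["L0", "L3", "L5"]
        reference = conservation_score(subset, tree)
        clone = read_newick_string(tree.as_newick())
        edges = [n.edge for n in clone.tree.preorder_node_iter()
                 if n is not clone.tree.seed_node and n.edge.length]
        edge = edges[len(edges) // 2]
        clone.tree.reroot_at_edge(edge, length1=edge.length / 2,
                                  length2=edge.length / 2)
        rerooted = read_newick_string(
            clone.tree.as_string(schema="newick").strip())
        assert conservation_score(subset, rerooted) == pytest.approx(
            reference, abs=1e-9)


def make_records_for_pair(species, cluster_pair, strand_pair=("-", "+"),
                          copies=1, offset=0):
    records = []
    pos = 1_000_000 * (offset + 1)
    for c in range(copies):
        for i, (cluster, strand) in enumerate(zip(cluster_pair, strand_pair)):
            records.append(make_gene(
                species=species, gene_id=f"{species}_{cluster}_{c}_{offset}",
                start=pos, end=pos + 299, strand=strand, cluster_id=cluster))
            pos += 700
        pos += 50_000  # separate copies so they do not touch each other
    return records


class TestAggregateConservedPairs:
    def test_pair_in_two_species_scored_by_their_path(self, tree_abc):
        records = (make_records_for_pair("A", ("X", "Y"))
                   + make_records_for_pair("B", ("X", "Y")))
        conserved = aggregate_conserved_pairs(
            extract_adjacent_pairs(records), "orthomcl", tree_abc)
        relevant = [cp for cp in conserved
                    if set(cp.key.groups) == {"X", "Y"}]
        assert len(relevant) == 1
        assert relevant[0].conservation == pytest.approx(0.3)
        assert relevant[0].species_set == {"A", "B"}

    def test_multiple_occurrences_per_species_counted_separately(self, tree_abc):
        # histone-like tandem duplication: occurrences exceed species
        records = []
        for sp in ("A", "B", "C"):
            records += make_records_for_pair(sp, ("H2B", "H2A"), copies=2)
        conserved = aggregate_conserved_pairs(
            extract_adjacent_pairs(records), "orthomcl", tree_abc)
        (cp,) = [c for c in conserved if set(c.key.groups) == {"H2A", "H2B"}
                 and c.key.orientation == "divergent"]
        assert cp.n_species == 3
        assert cp.n_occurrences == 6
        assert cp.conservation == pytest.approx(0.65)

    def test_single_species_pair_excluded(self, tree_abc):
        records = make_records_for_pair("A", ("X", "Y"))
        conserved = aggregate_conserved_pairs(
            extract_adjacent_pairs(records), "orthomcl", tree_abc)
        assert conserved == []

    def test_clade_filter_restricts_occurrences(self, tree_abc):
        records = []
        for sp in ("A", "B", "C"):
            records += make_records_for_pair(sp, ("X", "Y"))
        conserved = aggregate_conserved_pairs(
            extract_adjacent_pairs(records), "orthomcl", tree_abc,
            clade={"A", "B"})
        (cp,) = conserved
        assert cp.species_set == {"A", "B"}
        assert cp.conservation == pytest.approx(0.3)

    def test_pfam_grouping_is_at_least_as_coarse(self, planted_dataset):
        records = dedup_splice_variants(planted_dataset.records)
        pairs = extract_adjacent_pairs(records)
        ortho = {cp.key: cp for cp in aggregate_conserved_pairs(
            pairs, "orthomcl", planted_dataset.tree, min_species=1)}
        pfam_mapping = planted_dataset.pfam_assignment.mapping
        pfam = {cp.key: cp for cp in aggregate_conserved_pairs(
            pairs, "pfam", planted_dataset.tree, min_species=1)}
        cluster_to_arch = {}
        for member, cluster in planted_dataset.assignment.mapping.items():
            cluster_to_arch[cluster] = pfam_mapping[member]
        for key, cp in ortho.items():
            merged = tuple(cluster_to_arch[g] for g in key.groups)
            if key.orientation != CODIRECTIONAL:
                merged = tuple(sorted(merged))
            pfam_key = PairKey("pfam", key.orientation, merged)
            assert pfam_key in pfam
            assert pfam[pfam_key].n_species >= cp.n_species


def make_conserved(orientation, conservation, distance=500.0, gs2=None,
                   label="K"):
    key = PairKey("orthomcl", orientation, (f"{label}a", f"{label}b"))
    occ = PairOccurrence("spA", "chr1", "g1", "g2", int(distance))
    return ConservedPair(key=key, species_set=frozenset({"spA", "spB"}),
                         occurrences=[occ], conservation=conservation, gs2=gs2)


class TestCurves:
    def test_bin_counts_and_cumulative(self):
        conserved = [make_conserved("divergent", c, label=f"K{i}")
                     for i, c in enumerate([0.005, 0.005, 0.025])]
        curve = conservation_orientation_curve(conserved, bin_width=0.01)
        div = curve[curve["orientation"] == "divergent"].set_index("bin_low")
        assert div.loc[0.0, "count"] == 2
        assert div.loc[0.02, "count"] == 1
        assert div.loc[0.02, "cumulative"] == 1
        series = div["cumulative"].to_numpy()
        assert (np.diff(series) <= 0).all()

    def test_empty_input_gives_empty_curve(self):
        assert conservation_orientation_curve([]).empty

    def test_lowess_flat_for_constant_conservation(self):
        conserved = [make_conserved("divergent", 0.2, distance=10 ** (1 + i / 4),
                                    label=f"K{i}") for i in range(12)]
        smoothed = conservation_vs_distance(conserved, "divergent")
        assert np.allclose(smoothed["smoothed"], 0.2, atol=1e-6)

    def test_lowess_requires_ten_points(self):
        conserved = [make_conserved("divergent", 0.2, label=f"K{i}")
                     for i in range(5)]
        with pytest.raises(MissingDataError, match="raw"):
            conservation_vs_distance(conserved, "divergent")

    def test_lowess_tracks_monotone_decay(self):
        rng = np.random.default_rng(4)
        conserved = []
        for i in range(60):
            d = float(10 ** rng.uniform(2, 5))
            cons = max(0.02, 0.6 - 0.15 * np.log10(d) + rng.normal(0, 0.01))
            conserved.append(make_conserved("divergent", cons, distance=d,
                                            label=f"K{i}"))
        smoothed = conservation_vs_distance(conserved, "divergent")["smoothed"]
        assert smoothed.iloc[0] > smoothed.iloc[-1]
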