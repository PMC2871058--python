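"""Synthetic multi-species datasets with planted gene-order structure.

Emulates the kind of input the pipeline consumes from real genome
annotations: several species related by a known phylogeny, each genome an
ordered, stranded list of coding genes with log-normal gene lengths and
intergenic gaps, homology labels drawn from a cluster inventory shared
across species, and a small GO DAG with per-gene annotations.  On top of
that background, *planted* adjacent pairs — chosen orientation, chosen
species subset, chosen intergenic-distance range, chosen probability of
being functionally co-annotated — provide exact ground truth for every
pipeline stage, recorded in a manifest together with the expected
conservation score of each planted pair (computed here by a brute-force
union-of-pairwise-paths traversal, independent of the scoring module).

Distance archetypes follow the two regimes seen across eukaryotes:
fungi-like genomes with median intergenic gaps near 700 bp and
metazoa-like genomes with gaps around 30 kb.  The optional divergent
excess plants extra head-to-head pairs at 100-1000 bp, the hallmark of
mammalian bidirectional promoters.

Everything is driven by one :class:`numpy.random.Generator`; the same seed
and config give byte-identical output files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import dendropy
import networkx as nx
import numpy as np

from .annotation_io import (
    GeneRecord,
    GoAnnotation,
    GoOntology,
    GroupAssignment,
    SpeciesTree,
    read_newick_string,
    write_gene_table,
    write_go_annotation,
    write_obo_subset,
    write_orthomcl_groups,
)
from .errors import MissingDataError
from .gene_model import CODIRECTIONAL, CONVERGENT, DIVERGENT

_STRANDS = ("+", "-")

#: log-scale means of the intergenic-gap distributions per clade archetype
DISTANCE_ARCHETYPES = {
    "fungi": math.log(700.0),
    "metazoa": math.log(30000.0),
}


@dataclass(frozen=True)
class PlantedPair:
    """Specification of one conserved adjacent pair to plant."""

    orientation: str
    species: tuple[str, ...]
    distance_range: tuple[int, int] = (100, 1000)
    co_annotation_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in (DIVERGENT, CONVERGENT, CODIRECTIONAL):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not 0.0 <= self.co_annotation_probability <= 1.0:
            raise ValueError("co_annotation_probability must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; see the module docstring for the model."""

    seed: int = 0
    n_species: int = 8
    tree_newick: str | None = None  # user tree; None -> random coalescent
    coalescent_mean_depth: float = 0.25  # expected root depth, tree units
    genes_per_species: int = 200
    chromosomes_per_species: int = 1
    strand_model: str = "random"  # or "codirectional_blocks"
    codirectional_block_p: float = 0.9  # P(next gene keeps the strand)
    distance_archetype: str = "fungi"
    distance_sigma: float = 1.0
    divergent_excess_fraction: float = 0.0  # planted 100-1000 nt head-to-head gaps
    gene_length_mu: float = math.log(1500.0)
    gene_length_sigma: float = 0.5
    cluster_retention: float = 0.8  # P(gene carries a shared cluster label)
    pfam_merge_factor: int = 2  # clusters merged per architecture label
    planted_pairs: tuple[PlantedPair, ...] = ()
    n_terms: int = 500
    go_layers: int = 6
    go_parent_degree: int = 2
    background_annotation_rate: float = 0.5
    background_coannotation_rate: float = 0.1

    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def validate(self) -> None:
        if self.n_species < 1 or self.genes_per_species < 2:
            raise ValueError("need >= 1 species and >= 2 genes per species")
        for p in (self.cluster_retention, self.background_annotation_rate,
                  self.background_coannotation_rate,
                  self.divergent_excess_fraction, self.codirectional_block_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.distance_archetype not in DISTANCE_ARCHETYPES:
            raise ValueError(f"unknown archetype {self.distance_archetype!r}")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus the ground-truth manifest."""

    config: SyntheticConfig
    records: list[GeneRecord]
    assignment: GroupAssignment  # orthomcl scheme
    pfam_assignment: GroupAssignment
    tree: SpeciesTree
    ontology: GoOntology
    annotation: GoAnnotation
    manifest: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# brute-force conservation oracle (kept independent of pair_conservation)


def subtree_length_bruteforce(tree: SpeciesTree, leaves: Sequence[str]) -> float:
    """Induced-subtree length as the union of all pairwise leaf paths.

    Deliberately naive O(k^2 * depth) traversal used to stamp expected
    conservation values into the manifest and as a test oracle.
    """
    wanted = set(leaves)
    missing = wanted - tree.leaf_names
    if missing:
        raise MissingDataError(f"species not in the tree: {sorted(missing)}")
    if len(wanted) <= 1:
        return 0.0
    node_for = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}

    def path_to_root(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    edge_nodes: dict[int, dendropy.Node] = {}
    for a, b in combinations(sorted(wanted), 2):
        pa = path_to_root(node_for[a])
        pb = path_to_root(node_for[b])
        ids_b = {id(n) for n in pb}
        # nodes on the a-b path are those whose root-paths differ
        for node in pa:
            if id(node) not in ids_b:
                edge_nodes[id(node)] = node
        ids_a = {id(n) for n in pa}
        for node in pb:
            if id(node) not in ids_a:
                edge_nodes[id(node)] = node
    return sum(node.edge.length or 0.0 for node in edge_nodes.values())


# ---------------------------------------------------------------------------
# tree simulation


def random_coalescent_tree(species: Sequence[str], mean_depth: float,
                           rng: np.random.Generator) -> SpeciesTree:
    """Ultrametric tree from random pairwise joins with exponential waiting times."""
    if len(species) == 1:
        return read_newick_string(f"({species[0]}:{mean_depth:.6f});")
    lineages = [(name, 0.0) for name in species]  # (newick, height)
    n = len(species)
    time = 0.0
    # scale waiting times so the expected root height is ~mean_depth
    expected_total = sum(1.0 / (k * (k - 1) / 2.0) for k in range(2, n + 1))
    rate_scale = expected_total / mean_depth
    while len(lineages) > 1:
        k = len(lineages)
        time += rng.exponential(1.0 / (k * (k - 1) / 2.0)) / rate_scale
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_i, h_i) = lineages[i]
        (nwk_j, h_j) = lineages[j]
        merged = (f"({nwk_i}:{time - h_i:.9f},{nwk_j}:{time - h_j:.9f})", time)
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    newick, _ = lineages[0]
    return read_newick_string(newick + ";")


# ---------------------------------------------------------------------------
# GO DAG simulation


def random_go_dag(n_terms: int, n_layers: int, parent_degree: int,
                  rng: np.random.Generator) -> GoOntology:
    """Layered random DAG with a single root; term ids T0000, T0001, ..."""
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    layers: list[list[str]] = [["T0000"]]
    graph.add_node("T0000")
    names["T0000"] = "synthetic root"
    next_id = 1
    remaining = n_terms - 1
    # geometric-ish layer sizes, deeper layers wider
    weights = np.array([2.0 ** l for l in range(1, n_layers)])
    sizes = np.maximum(1, (remaining * weights / weights.sum()).astype(int))
    sizes[-1] += remaining - sizes.sum()
    # shallow layer-1 terms get the uninformative-term names so the
    # blacklist machinery is exercised on synthetic ontologies too
    shallow_names = ["cytosol", "nucleolus", "cytoplasm", "protein binding",
                     "nucleus"]
    for depth, layer_size in enumerate(sizes, start=1):
        layer: list[str] = []
        pool = layers[-1]
        for _ in range(layer_size):
            term = f"T{next_id:04d}"
            next_id += 1
            graph.add_node(term)
            if depth == 1 and shallow_names:
                names[term] = shallow_names.pop(0)
            else:
                names[term] = f"synthetic term {term}"
            n_parents = int(rng.integers(1, parent_degree + 1))
            for parent_idx in rng.choice(len(pool), size=min(n_parents, len(pool)),
                                         replace=False):
                graph.add_edge(term, pool[parent_idx])
            layer.append(term)
        layers.append(layer)
    ontology = GoOntology(graph, names)
    ontology.layers = layers  # type: ignore[attr-defined]
    return ontology


# ---------------------------------------------------------------------------
# genome simulation


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset described by ``config``; deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = config.species_names()

    if config.tree_newick is not None:
        tree = read_newick_string(config.tree_newick)
        if set(species) - tree.leaf_names:
            raise MissingDataError("tree leaves do not cover the configured species")
    else:
        tree = random_coalescent_tree(species, config.coalescent_mean_depth, rng)
    for planted in config.planted_pairs:
        missing = set(planted.species) - tree.leaf_names
        if missing:
            raise MissingDataError(
                f"planted species not in tree: {sorted(missing)}")

    ontology = random_go_dag(config.n_terms, config.go_layers,
                             config.go_parent_degree, rng)
    deep_terms = ontology.layers[-1]  # type: ignore[attr-defined]
    mid_terms = [t for layer in ontology.layers[2:] for t in layer]  # type: ignore[attr-defined]

    inventory = [f"C{i:05d}" for i in range(config.genes_per_species)]
    records: list[GeneRecord] = []
    annotation_raw: dict[tuple[str, str], set[str]] = {}
    manifest: list[dict] = []

    # each planted pair owns one dedicated deep term; in every species where
    # the pair occurs, both genes receive that term with the pair's
    # co-annotation probability (functional relatedness shows up per species)
    planted_terms: list[str] = [
        deep_terms[int(rng.integers(len(deep_terms)))]
        for _ in config.planted_pairs
    ]
    coannotated: list[set[str]] = [set() for _ in config.planted_pairs]

    for sp in species:
        sp_records, sp_annot = _simulate_species(
            sp, config, inventory, rng, planted_terms, coannotated,
            mid_terms, deep_terms)
        records.extend(sp_records)
        for key, terms in sp_annot.items():
            annotation_raw.setdefault(key, set()).update(terms)

    # group assignments: orthomcl from cluster labels, pfam by merging clusters
    mapping = {(r.species, r.gene_id): r.cluster_id
               for r in records if r.cluster_id is not None}
    assignment = GroupAssignment(scheme="orthomcl", mapping=mapping)
    pfam_mapping = {member: _pfam_label(label, config.pfam_merge_factor)
                    for member, label in mapping.items()}
    pfam_assignment = GroupAssignment(scheme="pfam", mapping=pfam_mapping)
    records = [r.with_label("pfam", pfam_mapping.get((r.species, r.gene_id)))
               for r in records]

    for j, planted in enumerate(config.planted_pairs):
        labels = _planted_labels(j)
        manifest.append({
            "orientation": planted.orientation,
            "labels": sorted(labels) if planted.orientation != CODIRECTIONAL
            else list(labels),
            "species": sorted(planted.species),
            "distance_range": list(planted.distance_range),
            "co_annotation_probability": planted.co_annotation_probability,
            "co_annotated_species": sorted(coannotated[j]),
            "expected_conservation": subtree_length_bruteforce(
                tree, planted.species),
        })

    annotation = {key: frozenset(terms) for key, terms in annotation_raw.items()}
    return SyntheticDataset(
        config=config,
        records=records,
        assignment=assignment,
        pfam_assignment=pfam_assignment,
        tree=tree,
        ontology=ontology,
        annotation=annotation,
        manifest=manifest,
    )


def _planted_labels(j: int) -> tuple[str, str]:
    return (f"P{j:03d}A", f"P{j:03d}B")


def _pfam_label(cluster: str, merge_factor: int) -> str:
    """Architectures are coarser than clusters: merge every few cluster ids."""
    if cluster.startswith("P"):
        return "A" + cluster  # planted labels keep their own architecture
    idx = int(cluster[1:])
    return f"A{idx // max(merge_factor, 1):05d}"


def _simulate_species(sp, config, inventory, rng, planted_terms,
                      coannotated, mid_terms, deep_terms):
    """One species: ordered stranded genes on chromosomes, labels, GO terms."""
    n_total = config.genes_per_species
    n_chrom = config.chromosomes_per_species
    base = n_total // n_chrom
    chrom_sizes = [base + (1 if c < n_total % n_chrom else 0)
                   for c in range(n_chrom)]

    # per-species label order is an independent permutation of the shared
    # inventory, so background adjacency is uncorrelated across species
    perm = rng.permutation(len(inventory))
    labels: list[str | None] = [
        inventory[perm[i]] if rng.random() < config.cluster_retention else None
        for i in range(n_total)
    ]
    lengths = np.maximum(
        150, rng.lognormal(config.gene_length_mu, config.gene_length_sigma,
                           n_total).astype(int))
    lengths -= lengths % 3
    mu = DISTANCE_ARCHETYPES[config.distance_archetype]
    gaps = np.maximum(
        1, rng.lognormal(mu, config.distance_sigma, n_total).astype(int))

    if config.strand_model == "random":
        strands = [_STRANDS[int(b)] for b in rng.integers(0, 2, n_total)]
    elif config.strand_model == "codirectional_blocks":
        strands = [_STRANDS[int(rng.integers(0, 2))]]
        for _ in range(1, n_total):
            if rng.random() < config.codirectional_block_p:
                strands.append(strands[-1])
            else:
                strands.append("+" if strands[-1] == "-" else "-")
    else:
        raise ValueError(f"unknown strand model {config.strand_model!r}")

    # chromosome boundaries: gene index -> (chromosome, local index)
    boundaries: list[tuple[int, int]] = []  # (chrom_start, chrom_end) inclusive
    cursor = 0
    for size in chrom_sizes:
        boundaries.append((cursor, cursor + size - 1))
        cursor += size

    def slot_is_internal(k: int) -> bool:
        """gap k sits between genes k and k+1 of the same chromosome"""
        return any(lo <= k and k + 1 <= hi for lo, hi in boundaries)

    # divergent excess: a fraction of internal slots becomes a short
    # head-to-head pair, emulating the mammalian bidirectional-promoter peak
    used_genes: set[int] = set()
    if config.divergent_excess_fraction > 0:
        for k in range(n_total - 1):
            if not slot_is_internal(k):
                continue
            if rng.random() < config.divergent_excess_fraction:
                strands[k], strands[k + 1] = "-", "+"
                gaps[k] = int(rng.integers(100, 1001))

    # planted pairs override background structure at a fresh slot
    for j, planted in enumerate(config.planted_pairs):
        if sp not in planted.species:
            continue
        slot = _pick_slot(rng, n_total, used_genes, slot_is_internal)
        used_genes.update((slot, slot + 1))
        la, lb = _planted_labels(j)
        labels[slot], labels[slot + 1] = la, lb
        lo, hi = planted.distance_range
        gaps[slot] = int(rng.integers(lo, hi + 1))
        if planted.orientation == DIVERGENT:
            strands[slot], strands[slot + 1] = "-", "+"
        elif planted.orientation == CONVERGENT:
            strands[slot], strands[slot + 1] = "+", "-"
        else:
            strands[slot] = strands[slot + 1] = "+"

    # coordinates: cumulate lengths and gaps along each chromosome
    records: list[GeneRecord] = []
    annot: dict[tuple[str, str], set[str]] = {}
    gene_index = 0
    for c, size in enumerate(chrom_sizes):
        pos = 1
        for _ in range(size):
            i = gene_index
            start = pos
            end = pos + int(lengths[i]) - 1
            pos = end + 1 + int(gaps[i])
            records.append(GeneRecord(
                species=sp,
                chromosome=f"chr{c + 1}",
                gene_id=f"{sp}_g{i + 1:05d}",
                start=start,
                end=end,
                strand=strands[i],
                protein_length=int(lengths[i]) // 3,
                cluster_id=labels[i],
            ))
            gene_index += 1

    # GO annotations: background terms per gene; planted-pair genes are
    # recognised by their dedicated labels (avoids extra slot bookkeeping)
    label_to_pair = {}
    for j in range(len(config.planted_pairs)):
        la, lb = _planted_labels(j)
        label_to_pair[la] = j
        label_to_pair[lb] = j
    for rec in records:
        key = (sp, rec.gene_id)
        if rng.random() < config.background_annotation_rate:
            n_terms = int(rng.integers(1, 4))
            picks = rng.choice(len(mid_terms), size=min(n_terms, len(mid_terms)),
                               replace=False)
            annot.setdefault(key, set()).update(mid_terms[p] for p in picks)
    # co-annotation of planted pairs, decided per species occurrence
    seen_pairs: set[int] = set()
    for rec in records:
        j = label_to_pair.get(rec.cluster_id)
        if j is None or j in seen_pairs:
            continue
        seen_pairs.add(j)
        if rng.random() < config.planted_pairs[j].co_annotation_probability:
            coannotated[j].add(sp)
            la, lb = _planted_labels(j)
            for other in records:
                if other.cluster_id in (la, lb):
                    annot.setdefault((sp, other.gene_id), set()).add(
                        planted_terms[j])
    # background co-annotation: some adjacent background pairs share a term
    for i in range(len(records) - 1):
        a, b = records[i], records[i + 1]
        if a.chromosome != b.chromosome:
            continue
        if a.cluster_id in label_to_pair or b.cluster_id in label_to_pair:
            continue
        if rng.random() < config.background_coannotation_rate:
            term = deep_terms[int(rng.integers(len(deep_terms)))]
            annot.setdefault((sp, a.gene_id), set()).add(term)
            annot.setdefault((sp, b.gene_id), set()).add(term)
    return records, annot


def _pick_slot(rng, n_total, used_genes, slot_is_internal, max_tries=10000):
    for _ in range(max_tries):
        k = int(rng.integers(0, n_total - 1))
        if slot_is_internal(k) and k not in used_genes and k + 1 not in used_genes:
            return k
    raise MissingDataError("could not place planted pair; genome too crowded")


# ---------------------------------------------------------------------------
# flip fixture


def generate_flip_fixture(records: Sequence[GeneRecord], species: str,
                          chromosome: str) -> list[GeneRecord]:
    """Coordinate-reverse one chromosome: x -> L+1-x, strands toggled.

    L is the rightmost coding coordinate of the chromosome, so the gene
    order is exactly reversed while every pairwise gap is preserved.  All
    other records are returned unchanged.
    """
    on_chrom = [r for r in records
                if r.species == species and r.chromosome == chromosome]
    if not on_chrom:
        return list(records)
    L = max(r.end for r in on_chrom)
    out = []
    for r in records:
        if r.species == species and r.chromosome == chromosome:
            out.append(replace(
                r,
                start=L + 1 - r.end,
                end=L + 1 - r.start,
                strand="+" if r.strand == "-" else "-",
            ))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# serialization


def write_dataset(dataset: SyntheticDataset, outdir: str | os.PathLike) -> None:
    """Write every input file the pipeline reads, plus the manifest (JSONL)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_gene_table(dataset.records, os.path.join(outdir, "genes.tsv"))
    write_orthomcl_groups(dataset.assignment, os.path.join(outdir, "groups.txt"))
    with open(os.path.join(outdir, "architectures.tsv"), "w") as handle:
        handle.write("species\tgene_id\treduced_architecture\n")
        for (sp, gene), label in sorted(dataset.pfam_assignment.mapping.items()):
            handle.write(f"{sp}\t{gene}\t{label}\n")
    with open(os.path.join(outdir, "tree.nwk"), "w") as handle:
        handle.write(dataset.tree.as_newick() + "\n")
    write_obo_subset(dataset.ontology, os.path.join(outdir, "ontology.obo"))
    write_go_annotation(dataset.annotation, os.path.join(outdir, "annotations.tsv"))
    with open(os.path.join(outdir, "manifest.jsonl"), "w") as handle:
        for entry in dataset.manifest:
            handle.write(json.dumps(entry, sort_keys=True) + "\n")
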