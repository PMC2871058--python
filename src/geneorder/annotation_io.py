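"""Readers and writers for the pipeline's external formats.

The pipeline consumes per-species gene tables (GFF3 or a 7-column TSV
dialect), homology-group assignments (OrthoMCL ``groups`` text), a rooted
species tree with branch lengths (Newick), a GO ontology subset (OBO,
``is_a`` edges only) and a gene-to-GO-term annotation TSV.  Everything is
mapped onto a small set of dataclasses; all downstream arithmetic is defined
on 1-based inclusive coordinates (the GFF3 convention).
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import dendropy
import networkx as nx
import obonet

from .errors import InvalidRecordError, MissingDataError, ParseError

VALID_STRANDS = frozenset({"+", "-"})

GENE_TABLE_COLUMNS = [
    "species",
    "chromosome",
    "gene_id",
    "start",
    "end",
    "strand",
    "protein_length",
]


@dataclass(frozen=True)
class GeneRecord:
    """A stranded CDS interval on one chromosome of one species.

    ``start`` and ``end`` are the 1-based inclusive genomic coordinates of
    the leftmost and rightmost coding bases.  ``protein_length`` (amino
    acids) is required only by splice-variant deduplication; ``cluster_id``
    and ``architecture_id`` carry the homology-group labels under the
    OrthoMCL and Pfam-architecture schemes respectively.
    """

    species: str
    chromosome: str
    gene_id: str
    start: int
    end: int
    strand: str
    protein_length: int | None = None
    cluster_id: str | None = None
    architecture_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidRecordError(
                f"gene {self.gene_id!r} ({self.species}/{self.chromosome}): "
                f"start {self.start} > end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise InvalidRecordError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )

    def group_label(self, scheme: str) -> str | None:
        """Return the homology label under ``scheme`` ('orthomcl' or 'pfam')."""
        if scheme == "orthomcl":
            return self.cluster_id
        if scheme == "pfam":
            return self.architecture_id
        raise ValueError(f"unknown grouping scheme {scheme!r}")

    def with_label(self, scheme: str, label: str | None) -> "GeneRecord":
        if scheme == "orthomcl":
            return replace(self, cluster_id=label)
        if scheme == "pfam":
            return replace(self, architecture_id=label)
        raise ValueError(f"unknown grouping scheme {scheme!r}")


@dataclass
class GroupAssignment:
    """A homology-group labelling of genes under one scheme.

    ``mapping`` sends ``(species, gene_id)`` to an opaque group label; each
    gene belongs to at most one group per scheme.
    """

    scheme: str
    mapping: dict[tuple[str, str], str] = field(default_factory=dict)

    def groups(self) -> dict[str, list[tuple[str, str]]]:
        """Invert the mapping: group label -> member (species, gene_id) list."""
        inverse: dict[str, list[tuple[str, str]]] = {}
        for member, label in self.mapping.items():
            inverse.setdefault(label, []).append(member)
        return inverse

    def species_per_group(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for (species, _), label in self.mapping.items():
            out.setdefault(label, set()).add(species)
        return out


class SpeciesTree:
    """A rooted species phylogeny with named leaves and branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` that enforces unique leaf
    names and non-negative lengths on every non-root edge.  Branch lengths
    are in whatever evolutionary-distance units the input tree carries; the
    conservation score inherits those units.
    """

    def __init__(self, tree: dendropy.Tree):
        leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = {name for name in leaves if leaves.count(name) > 1}
        if dupes:
            raise ParseError(f"duplicate leaf names in tree: {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise ParseError(f"missing branch length on edge above {label!r}")
            if node.edge.length < 0:
                label = node.taxon.label if node.taxon else "<internal>"
                raise ParseError(
                    f"negative branch length {node.edge.length} above {label!r}"
                )
        self.tree = tree
        self.leaf_names: frozenset[str] = frozenset(leaves)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


class GoOntology:
    """A GO subset: term ids plus directed acyclic ``is_a`` edges child->parent."""

    def __init__(self, graph: nx.DiGraph, names: Mapping[str, str] | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ParseError(f"is_a graph contains a cycle: {cycle}")
        self.graph = graph
        self.names = dict(names or {})

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (excluding the term itself)."""
        if term not in self.graph:
            raise MissingDataError(f"unknown GO term {term!r}")
        return nx.descendants(self.graph, term)

    def id_for_name(self, name: str) -> str | None:
        for term, term_name in self.names.items():
            if term_name == name:
                return term
        return None


GoAnnotation = dict[tuple[str, str], frozenset[str]]


# ---------------------------------------------------------------------------
# gene tables


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad {what} {value!r}") from exc


def read_gene_table(path: str | os.PathLike, format: str = "tsv",
                    species: str | None = None) -> list[GeneRecord]:
    """Read a per-species gene table into :class:`GeneRecord` objects.

    ``format='tsv'`` expects the 7 documented columns (header optional):
    species, chromosome, gene_id, start, end, strand, protein_length.
    ``format='gff3'`` reads CDS features grouped by mRNA (or gene) ID;
    since GFF3 carries no species field, ``species`` must be given.
    Coordinates are kept 1-based inclusive.  Returns one record per
    annotated coding isoform; splice-variant dedup is a separate step.
    """
    if format == "tsv":
        return _read_gene_tsv(path)
    if format == "gff3":
        if species is None:
            raise MissingDataError("species must be given for GFF3 input")
        return _read_gene_gff3(path, species)
    raise ValueError(f"unknown gene-table format {format!r}")


def _read_gene_tsv(path: str | os.PathLike) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "species":  # header row
                continue
            if len(fields) < 7:
                raise ParseError(
                    f"line {lineno}: expected 7 tab-separated columns, got {len(fields)}"
                )
            sp, chrom, gene_id, start, end, strand, plen = fields[:7]
            try:
                record = GeneRecord(
                    species=sp,
                    chromosome=chrom,
                    gene_id=gene_id,
                    start=_parse_int(start, "start", lineno),
                    end=_parse_int(end, "end", lineno),
                    strand=strand,
                    protein_length=None if plen in ("", ".", "NA") else _parse_int(
                        plen, "protein_length", lineno),
                )
            except InvalidRecordError as exc:
                raise InvalidRecordError(f"line {lineno}: {exc}") from exc
            records.append(record)
    _check_unique_ids(records)
    return records


def _read_gene_gff3(path: str | os.PathLike, species: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    seen_parents: set[str] = set()
    # one record per mRNA isoform, with the CDS span as the coding interval
    for mrna in db.features_of_type("mRNA"):
        cds = list(db.children(mrna, featuretype="CDS"))
        if not cds:
            continue
        start = min(c.start for c in cds)
        end = max(c.end for c in cds)
        coding = sum(c.end - c.start + 1 for c in cds)
        records.append(GeneRecord(
            species=species,
            chromosome=mrna.seqid,
            gene_id=mrna.id,
            start=start,
            end=end,
            strand=mrna.strand,
            protein_length=max(coding // 3 - 1, 1),
        ))
        seen_parents.add(mrna.id)
    # gene features without mRNA children (compact annotations)
    for gene in db.features_of_type("gene"):
        if any(child.id in seen_parents for child in db.children(gene, featuretype="mRNA")):
            continue
        cds = list(db.children(gene, featuretype="CDS"))
        if cds:
            start = min(c.start for c in cds)
            end = max(c.end for c in cds)
            coding = sum(c.end - c.start + 1 for c in cds)
            plen = max(coding // 3 - 1, 1)
        else:
            start, end = gene.start, gene.end
            plen = max((end - start + 1) // 3 - 1, 1)
        records.append(GeneRecord(
            species=species,
            chromosome=gene.seqid,
            gene_id=gene.id,
            start=start,
            end=end,
            strand=gene.strand,
            protein_length=plen,
        ))
    _check_unique_ids(records)
    return records


def _check_unique_ids(records: Iterable[GeneRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.species, rec.gene_id)
        if key in seen:
            raise InvalidRecordError(
                f"gene id {rec.gene_id!r} occurs more than once in species {rec.species!r}"
            )
        seen.add(key)


def write_gene_table(records: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    """Write records to the 7-column TSV dialect (header included)."""
    with open(path, "w") as handle:
        handle.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for rec in records:
            plen = "" if rec.protein_length is None else str(rec.protein_length)
            handle.write("\t".join([
                rec.species, rec.chromosome, rec.gene_id,
                str(rec.start), str(rec.end), rec.strand, plen,
            ]) + "\n")


# ---------------------------------------------------------------------------
# OrthoMCL groups


def read_orthomcl_groups(path: str | os.PathLike) -> GroupAssignment:
    """Parse an OrthoMCL ``groups`` file: ``GROUPID: species|gene ...`` per line."""
    mapping: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"line {lineno}: missing 'GROUPID:' prefix")
            group_id, _, members = line.partition(":")
            group_id = group_id.strip()
            member_tokens = members.split()
            if not member_tokens:
                warnings.warn(f"line {lineno}: empty group {group_id!r} skipped")
                continue
            for token in member_tokens:
                if "|" not in token:
                    raise ParseError(
                        f"line {lineno}: member {token!r} is not of form species|gene"
                    )
                sp, _, gene = token.partition("|")
                key = (sp, gene)
                if key in mapping and mapping[key] != group_id:
                    raise ParseError(
                        f"gene {sp}|{gene} assigned to both {mapping[key]!r} "
                        f"and {group_id!r}"
                    )
                mapping[key] = group_id
    return GroupAssignment(scheme="orthomcl", mapping=mapping)


def write_orthomcl_groups(assignment: GroupAssignment, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for group_id, members in sorted(assignment.groups().items()):
            tokens = " ".join(f"{sp}|{gene}" for sp, gene in sorted(members))
            handle.write(f"{group_id}: {tokens}\n")


# ---------------------------------------------------------------------------
# Newick species tree


def read_newick(path: str | os.PathLike) -> SpeciesTree:
    """Read a single rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from exc
    if tree.is_rooted is False:
        raise ParseError("unrooted tree ([&U]) rejected; provide a rooted tree")
    return SpeciesTree(tree)


def read_newick_string(text: str) -> SpeciesTree:
    tree = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if tree.is_rooted is False:
        raise ParseError("unrooted tree ([&U]) rejected; provide a rooted tree")
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# OBO subset and GO annotation


def read_obo_subset(path: str | os.PathLike) -> GoOntology:
    """Read an OBO file, keeping term ids, names, and ``is_a`` edges only.

    obonet stores edges child->parent already; non-is_a relationship edges
    are dropped here since only the is_a closure enters the similarity score.
    """
    try:
        multigraph = obonet.read_obo(str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        graph.add_node(term)
        if "name" in data:
            names[term] = data["name"]
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    return GoOntology(graph, names)


def read_go_annotation(path: str | os.PathLike, ontology: GoOntology) -> GoAnnotation:
    """Read a (species, gene_id, term) TSV; every term must be in the ontology."""
    raw: dict[tuple[str, str], set[str]] = {}
    unknown: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "species":
                continue
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns")
            sp, gene, term = fields[:3]
            if term not in ontology.terms:
                unknown.add(term)
                continue
            raw.setdefault((sp, gene), set()).add(term)
    if unknown:
        raise MissingDataError(
            f"annotation references terms absent from the ontology: {sorted(unknown)}"
        )
    return {key: frozenset(terms) for key, terms in raw.items()}


def write_go_annotation(annotation: GoAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("species\tgene_id\tterm\n")
        for (sp, gene), terms in sorted(annotation.items()):
            for term in sorted(terms):
                handle.write(f"{sp}\t{gene}\t{term}\n")


def write_obo_subset(ontology: GoOntology, path: str | os.PathLike) -> None:
    """Write a minimal OBO file (id/name/is_a) readable by :func:`read_obo_subset`."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\n\n")
    for term in sorted(ontology.terms):
        buf.write("[Term]\n")
        buf.write(f"id: {term}\n")
        name = ontology.names.get(term, term)
        buf.write(f"name: {name}\n")
        for parent in sorted(ontology.graph.successors(term)):
            buf.write(f"is_a: {parent}\n")
        buf.write("\n")
    with open(path, "w") as handle:
        handle.write(buf.getvalue())
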