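"""Homology grouping: Pfam-architecture reduction and group filtering.

A Pfam architecture is the ordered list of domains in a protein, e.g.
``DEAD~Helicase_C``.  Domain repeats are collapsed so that proteins
differing only in repeat copy number fall into the same group: by default
only *consecutive* runs are collapsed (``PPR PPR PPR`` -> ``PPR``) while
non-adjacent recurrences survive (``A A B A`` -> ``A~B~A``), preserving
domain order.  ``collapse='global'`` keeps only the first occurrence of
every domain instead.

Groups whose members all come from a single organism say nothing about
cross-species gene-order conservation and are dropped.
"""

from __future__ import annotations

import os
from typing import Sequence

from .annotation_io import GroupAssignment
from .errors import MissingDataError, ParseError

ARCHITECTURE_SEPARATOR = "~"


def reduce_architecture(domains: Sequence[str], collapse: str = "runs") -> str:
    """Collapse domain repeats and return the '~'-joined architecture label."""
    if not domains:
        raise MissingDataError("empty domain list has no architecture")
    if collapse == "runs":
        reduced = [domains[0]]
        for domain in domains[1:]:
            if domain != reduced[-1]:
                reduced.append(domain)
    elif collapse == "global":
        seen: set[str] = set()
        reduced = []
        for domain in domains:
            if domain not in seen:
                seen.add(domain)
                reduced.append(domain)
    else:
        raise ValueError(f"collapse must be 'runs' or 'global', got {collapse!r}")
    return ARCHITECTURE_SEPARATOR.join(reduced)


def read_architecture_table(path: str | os.PathLike,
                            collapse: str = "runs") -> GroupAssignment:
    """Read a protein->domain-order TSV and build the Pfam grouping.

    Columns: species, gene_id, domain_order (comma-separated domain names).
    The group label of each protein is its reduced architecture.
    """
    mapping: dict[tuple[str, str], str] = {}
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
            sp, gene, domain_order = fields[:3]
            domains = [d for d in domain_order.split(",") if d]
            if not domains:
                raise ParseError(f"line {lineno}: empty domain list for {gene!r}")
            key = (sp, gene)
            if key in mapping:
                raise ParseError(f"line {lineno}: duplicate protein {sp}|{gene}")
            mapping[key] = reduce_architecture(domains, collapse=collapse)
    return GroupAssignment(scheme="pfam", mapping=mapping)


def write_architecture_table(assignment: GroupAssignment,
                             path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("species\tgene_id\treduced_architecture\n")
        for (sp, gene), label in sorted(assignment.mapping.items()):
            handle.write(f"{sp}\t{gene}\t{label}\n")


def filter_single_organism_groups(assignment: GroupAssignment) -> GroupAssignment:
    """Drop groups represented in fewer than two species; members become unassigned."""
    species_per_group = assignment.species_per_group()
    kept = {
        member: label
        for member, label in assignment.mapping.items()
        if len(species_per_group[label]) >= 2
    }
    return GroupAssignment(scheme=assignment.scheme, mapping=kept)
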