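"""From raw gene records to the ordered gene model and adjacent pairs.

Splice variants are removed by keeping, within every set of same-strand
overlapping coding intervals, only the record encoding the longest protein.
The surviving genes of each chromosome are then ordered by start coordinate
and every consecutive pair is classified by relative transcriptional
orientation:

* divergent (head-to-head, ``<- ->``): left gene on ``-``, right on ``+``;
* convergent (tail-to-tail, ``-> <-``): left on ``+``, right on ``-``;
* co-directional (``-> ->``): both genes on the same strand.

The intergenic distance of a pair is ``right.start - left.end - 1`` base
pairs and is negative when the coding spans overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneRecord
from .errors import InvalidRecordError, MissingDataError

DIVERGENT = "divergent"
CONVERGENT = "convergent"
CODIRECTIONAL = "codirectional"
ORIENTATIONS = (DIVERGENT, CONVERGENT, CODIRECTIONAL)


@dataclass(frozen=True)
class GenePair:
    """Two adjacent genes on one chromosome, left having the smaller start."""

    species: str
    chromosome: str
    left: GeneRecord
    right: GeneRecord
    orientation: str
    intergenic_distance: int


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class of an adjacent pair given the two strands.

    The left gene is the one with the smaller start coordinate.
    """
    if left_strand == right_strand:
        return CODIRECTIONAL
    if (left_strand, right_strand) == ("-", "+"):
        return DIVERGENT
    return CONVERGENT


def intergenic_distance(left: GeneRecord, right: GeneRecord) -> int:
    """Base pairs between left CDS end and right CDS start; may be negative."""
    if left.chromosome != right.chromosome or left.species != right.species:
        raise InvalidRecordError(
            f"genes {left.gene_id!r} and {right.gene_id!r} are not on the "
            "same chromosome"
        )
    if left.start > right.start:
        raise InvalidRecordError("left gene must have the smaller start")
    return right.start - left.end - 1


def dedup_splice_variants(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Keep only the longest-protein record within each same-strand overlap group.

    Overlap means >= 1 bp of shared CDS span on the same strand of the same
    chromosome; overlap groups are closed transitively and one survivor is
    kept per group.  Opposite-strand overlaps are untouched.  Length ties
    are broken by the lexicographically smallest gene id.  Input order is
    not preserved; output is sorted by (species, chromosome, start).
    """
    for rec in records:
        if rec.protein_length is None:
            raise MissingDataError(
                f"gene {rec.gene_id!r} lacks protein_length, required for dedup"
            )
    survivors: list[GeneRecord] = []
    by_context: dict[tuple[str, str, str], list[GeneRecord]] = {}
    for rec in records:
        by_context.setdefault((rec.species, rec.chromosome, rec.strand), []).append(rec)
    for group in by_context.values():
        group.sort(key=lambda r: (r.start, r.end, r.gene_id))
        # sweep: intervals sharing >=1 bp, transitively, form one component
        component: list[GeneRecord] = []
        reach = -1
        for rec in group:
            if component and rec.start > reach:
                survivors.append(_best_of(component))
                component = []
                reach = -1
            component.append(rec)
            reach = max(reach, rec.end)
        if component:
            survivors.append(_best_of(component))
    survivors.sort(key=lambda r: (r.species, r.chromosome, r.start, r.end, r.gene_id))
    return survivors


def _best_of(component: list[GeneRecord]) -> GeneRecord:
    # longest protein wins; ties broken by smallest gene id for determinism
    return min(component, key=lambda r: (-r.protein_length, r.gene_id))


def extract_adjacent_pairs(records: Sequence[GeneRecord]) -> list[GenePair]:
    """All adjacent pairs per chromosome; n genes yield n - 1 pairs.

    Records are assumed deduplicated; genes are ordered by start (ties by
    end, then gene id).  Two records with identical (start, end, gene_id)
    on one chromosome are rejected.
    """
    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in records:
        by_chrom.setdefault((rec.species, rec.chromosome), []).append(rec)
    pairs: list[GenePair] = []
    for (species, chrom), genes in sorted(by_chrom.items()):
        genes.sort(key=lambda r: (r.start, r.end, r.gene_id))
        for a, b in zip(genes, genes[1:]):
            if (a.start, a.end, a.gene_id) == (b.start, b.end, b.gene_id):
                raise InvalidRecordError(
                    f"identical records {a.gene_id!r} on {species}/{chrom}"
                )
            pairs.append(GenePair(
                species=species,
                chromosome=chrom,
                left=a,
                right=b,
                orientation=classify_orientation(a.strand, b.strand),
                intergenic_distance=intergenic_distance(a, b),
            ))
    return pairs


def orientation_frequencies(pairs: Iterable[GenePair]) -> pd.DataFrame:
    """Per-species fractions of the three orientation classes.

    Returns a DataFrame indexed by species with columns divergent,
    convergent, codirectional and n_pairs; the three fractions sum to 1.
    """
    counts: dict[str, dict[str, int]] = {}
    for pair in pairs:
        row = counts.setdefault(pair.species, {o: 0 for o in ORIENTATIONS})
        row[pair.orientation] += 1
    rows = []
    for species, row in sorted(counts.items()):
        total = sum(row.values())
        rows.append({
            "species": species,
            **{o: row[o] / total for o in ORIENTATIONS},
            "n_pairs": total,
        })
    return pd.DataFrame(rows).set_index("species")


def intergenic_distance_histogram(
    pairs: Iterable[GenePair],
    orientation: str,
    bins_per_decade: int = 10,
    max_decade: int = 7,
) -> pd.DataFrame:
    """Counts of intergenic distances over log10-spaced bins for one orientation.

    Distances <= 0 (abutting or overlapping pairs) are pooled into a single
    underflow bin reported with ``bin_low = -inf``.  Bin counts sum to the
    number of pairs of the requested orientation.
    """
    distances = [p.intergenic_distance for p in pairs if p.orientation == orientation]
    edges = np.logspace(0, max_decade, bins_per_decade * max_decade + 1)
    positive = [d for d in distances if d > 0]
    underflow = len(distances) - len(positive)
    counts, _ = np.histogram(positive, bins=edges)
    # values beyond the last edge fall into the last bin
    overflow = sum(1 for d in positive if d >= edges[-1])
    counts[-1] += overflow
    rows = [{"bin_low": -math.inf, "bin_high": 1.0, "count": underflow}]
    for low, high, count in zip(edges[:-1], edges[1:], counts):
        rows.append({"bin_low": low, "bin_high": high, "count": int(count)})
    return pd.DataFrame(rows)


def pairs_to_table(pairs: Iterable[GenePair]) -> pd.DataFrame:
    """Flatten pairs into the exported pair-table layout."""
    rows = [{
        "species": p.species,
        "chromosome": p.chromosome,
        "left_gene": p.left.gene_id,
        "right_gene": p.right.gene_id,
        "orientation": p.orientation,
        "intergenic_distance": p.intergenic_distance,
        "left_cluster": p.left.cluster_id or "",
        "right_cluster": p.right.cluster_id or "",
    } for p in pairs]
    return pd.DataFrame(rows, columns=[
        "species", "chromosome", "left_gene", "right_gene", "orientation",
        "intergenic_distance", "left_cluster", "right_cluster",
    ])
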