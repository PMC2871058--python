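"""Cross-species pair identity and the evolutionary-conservation score.

A gene pair observed in one species is matched to "the same" pair in other
species through the homology labels of its two genes plus its orientation
class: that triple is the pair's canonical key.  Divergent and convergent
keys are unordered in the two labels (the mirror image of a head-to-head
pair is the same head-to-head pair), while co-directional keys are ordered
(upstream, downstream) because transcriptional order is flip-invariant and
biologically meaningful.

The conservation of a key found in a set S of species is the total branch
length of the minimal subtree of the species phylogeny spanning the leaves
in S — the union of all pairwise leaf-to-leaf paths, with no edge counted
twice and no stem branch above the common ancestor.  This makes the score
independent of the root position.  A key found in a single species scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import SpeciesTree
from .errors import MissingDataError
from .gene_model import CODIRECTIONAL, GenePair, ORIENTATIONS


@dataclass(frozen=True)
class PairKey:
    """Species-independent identity of a gene pair under one grouping scheme.

    ``groups`` is sorted for divergent/convergent keys and ordered
    (upstream, downstream) for co-directional keys.
    """

    scheme: str
    orientation: str
    groups: tuple[str, str]


@dataclass(frozen=True)
class PairOccurrence:
    """One physical occurrence of a conserved pair in one species."""

    species: str
    chromosome: str
    left_gene: str
    right_gene: str
    intergenic_distance: int


@dataclass
class ConservedPair:
    """A canonical pair with its species spread and conservation score."""

    key: PairKey
    species_set: frozenset[str]
    occurrences: list[PairOccurrence] = field(default_factory=list)
    conservation: float = 0.0
    gs2: float | None = None

    @property
    def n_species(self) -> int:
        return len(self.species_set)

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)

    @property
    def mean_intergenic_distance(self) -> float:
        return float(np.mean([o.intergenic_distance for o in self.occurrences]))


def canonical_key(pair: GenePair, scheme: str,
                  codirectional_ordered: bool = True) -> PairKey | None:
    """Canonical key of a pair, or None when either gene lacks a group label.

    For co-directional pairs the upstream gene is the one transcribed
    toward the other: the left gene on '+' strands, the right gene on '-'.
    """
    left_label = pair.left.group_label(scheme)
    right_label = pair.right.group_label(scheme)
    if left_label is None or right_label is None:
        return None
    if pair.orientation == CODIRECTIONAL and codirectional_ordered:
        if pair.left.strand == "+":
            groups = (left_label, right_label)
        else:
            groups = (right_label, left_label)
    else:
        groups = tuple(sorted((left_label, right_label)))
    return PairKey(scheme=scheme, orientation=pair.orientation, groups=groups)


def conservation_score(species_set: Iterable[str], tree: SpeciesTree) -> float:
    """Total branch length of the induced subtree spanning the given leaves.

    An edge contributes iff it separates the leaf set nontrivially, i.e. the
    number of selected leaves below it is neither 0 nor all of them; this is
    exactly the union of all pairwise paths and is root-independent.
    """
    wanted = set(species_set)
    missing = wanted - tree.leaf_names
    if missing:
        raise MissingDataError(
            f"species not in the tree: {sorted(missing)}"
        )
    k = len(wanted)
    if k <= 1:
        return 0.0
    total = 0.0
    below: dict[int, int] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            count = 1 if node.taxon.label in wanted else 0
        else:
            count = sum(below[id(child)] for child in node.child_nodes())
        below[id(node)] = count
        if node is not tree.tree.seed_node and 0 < count < k:
            total += node.edge.length
    return total


def aggregate_conserved_pairs(
    pairs: Sequence[GenePair],
    scheme: str,
    tree: SpeciesTree,
    clade: Iterable[str] | None = None,
    codirectional_ordered: bool = True,
    min_species: int = 2,
) -> list[ConservedPair]:
    """Group pairs by canonical key and score their cross-species conservation.

    ``clade`` restricts occurrences to a named leaf subset before counting
    (None means all species).  A species occurring several times for one key
    counts once for the species set but every occurrence is retained for the
    occurrence count and the distance mean.  Keys left with fewer than
    ``min_species`` species are dropped.
    """
    clade_set = set(clade) if clade is not None else None
    if clade_set is not None:
        missing = clade_set - tree.leaf_names
        if missing:
            raise MissingDataError(f"clade species not in the tree: {sorted(missing)}")
    buckets: dict[PairKey, list[GenePair]] = {}
    for pair in pairs:
        if clade_set is not None and pair.species not in clade_set:
            continue
        key = canonical_key(pair, scheme, codirectional_ordered=codirectional_ordered)
        if key is None:
            continue
        buckets.setdefault(key, []).append(pair)
    conserved: list[ConservedPair] = []
    for key, members in buckets.items():
        species = frozenset(p.species for p in members)
        if len(species) < min_species:
            continue
        occurrences = [
            PairOccurrence(
                species=p.species,
                chromosome=p.chromosome,
                left_gene=p.left.gene_id,
                right_gene=p.right.gene_id,
                intergenic_distance=p.intergenic_distance,
            )
            for p in sorted(members, key=lambda p: (p.species, p.chromosome,
                                                    p.left.start))
        ]
        conserved.append(ConservedPair(
            key=key,
            species_set=species,
            occurrences=occurrences,
            conservation=conservation_score(species, tree),
        ))
    conserved.sort(key=lambda cp: (-cp.conservation, cp.key.orientation,
                                   cp.key.groups))
    return conserved


def conservation_orientation_curve(
    conserved: Sequence[ConservedPair],
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Counts of distinct conserved pairs per conservation bin and orientation.

    For each orientation the curve reports, per ``bin_width``-wide bin of
    the conservation score, the number of pairs falling in the bin and the
    cumulative number of pairs at least as conserved as the bin's lower
    edge (a non-increasing series).
    """
    if not conserved:
        return pd.DataFrame(columns=["orientation", "bin_low", "count", "cumulative"])
    max_cons = max(cp.conservation for cp in conserved)
    n_bins = int(np.floor(max_cons / bin_width)) + 1
    rows = []
    for orientation in ORIENTATIONS:
        scores = np.array([cp.conservation for cp in conserved
                           if cp.key.orientation == orientation])
        counts = np.zeros(n_bins, dtype=int)
        if scores.size:
            idx = np.minimum((scores / bin_width).astype(int), n_bins - 1)
            np.add.at(counts, idx, 1)
        cumulative = counts[::-1].cumsum()[::-1]
        for i in range(n_bins):
            rows.append({
                "orientation": orientation,
                "bin_low": round(i * bin_width, 10),
                "count": int(counts[i]),
                "cumulative": int(cumulative[i]),
            })
    return pd.DataFrame(rows)


def conservation_vs_distance(
    conserved: Sequence[ConservedPair],
    orientation: str,
    frac: float = 0.3,
    it: int = 3,
) -> pd.DataFrame:
    """Lowess-smoothed conservation as a function of log10 mean intergenic distance.

    Returns the raw points with a ``smoothed`` column.  Mean distances <= 0
    are clamped to 1 bp before the log.  Requires at least 10 pairs of the
    requested orientation.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    points = [cp for cp in conserved if cp.key.orientation == orientation]
    if len(points) < 10:
        raise MissingDataError(
            f"only {len(points)} {orientation} pairs; need >= 10 for a smoothed "
            "curve — export the raw points instead"
        )
    x = np.log10(np.maximum([cp.mean_intergenic_distance for cp in points], 1.0))
    y = np.array([cp.conservation for cp in points])
    order = np.argsort(x, kind="stable")
    smoothed = lowess(y[order], x[order], frac=frac, it=it, return_sorted=False)
    df = pd.DataFrame({
        "log10_mean_distance": x[order],
        "mean_distance": 10 ** x[order],
        "conservation": y[order],
        "smoothed": smoothed,
    })
    return df


def conserved_pairs_to_table(conserved: Sequence[ConservedPair],
                             min_conservation: float | None = 0.3) -> pd.DataFrame:
    """Flatten conserved pairs into the exported table layout.

    By default only pairs with conservation above 0.3 are exported;
    ``min_conservation=None`` exports everything.
    """
    rows = []
    for cp in conserved:
        if min_conservation is not None and cp.conservation <= min_conservation:
            continue
        rows.append({
            "n_species": cp.n_species,
            "n_occurrences": cp.n_occurrences,
            "conservation": round(cp.conservation, 6),
            "gs2": "" if cp.gs2 is None else round(cp.gs2, 4),
            "orientation": cp.key.orientation,
            "group1": cp.key.groups[0],
            "group2": cp.key.groups[1],
            "mean_intergenic_distance": round(cp.mean_intergenic_distance, 1),
            "species": ",".join(sorted(cp.species_set)),
        })
    return pd.DataFrame(rows, columns=[
        "n_species", "n_occurrences", "conservation", "gs2", "orientation",
        "group1", "group2", "mean_intergenic_distance", "species",
    ])
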