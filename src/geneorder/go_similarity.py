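"""GO-based functional similarity of adjacent gene pairs (GS² score).

Annotations are propagated to all ``is_a`` ancestors, then a short
blacklist of uninformative terms ("cytosol", "nucleolus", "cytoplasm",
"protein binding", "nucleus") is removed.  The two-gene specialization of
the GS² gene-set similarity scores a pair of closures C1, C2 as

    GS2(C1, C2) = ( |C1 ∩ C2| / |C1| + |C1 ∩ C2| / |C2| ) / 2

i.e. the per-gene overlap fraction averaged over the two genes: symmetric,
in [0, 1], equal to 1 iff the closures coincide, and undefined when either
closure is empty (the pair is reported without a score).  A score of 0.4 —
the expectation for random gene sets — is the conventional threshold for
calling a pair functionally related.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GoAnnotation, GoOntology, GroupAssignment
from .gene_model import ORIENTATIONS
from .pair_conservation import ConservedPair

#: term *names* removed from every analysis after ancestor propagation
DEFAULT_BLACKLIST_NAMES = (
    "cytosol",
    "nucleolus",
    "cytoplasm",
    "protein binding",
    "nucleus",
)

#: GS² value expected for random gene sets; threshold for "functionally related"
RANDOM_GS2_THRESHOLD = 0.4


def blacklist_ids(ontology: GoOntology,
                  names: Iterable[str] = DEFAULT_BLACKLIST_NAMES) -> frozenset[str]:
    """Map blacklist term names to ids via the loaded ontology.

    Names absent from the ontology (e.g. in a synthetic ontology) are
    skipped with a warning.
    """
    ids = set()
    for name in names:
        term = ontology.id_for_name(name)
        if term is None:
            warnings.warn(f"blacklist term name {name!r} not in ontology; ignored")
        else:
            ids.add(term)
    return frozenset(ids)


def propagate_terms(terms: Iterable[str], ontology: GoOntology,
                    blacklist: frozenset[str] = frozenset()) -> frozenset[str]:
    """Close a term set under is_a ancestors, then drop blacklisted ids.

    Only the blacklisted ids themselves are removed; ancestors reached
    through them remain in the closure.
    """
    closure: set[str] = set()
    for term in terms:
        closure.add(term)
        closure |= ontology.ancestors(term)
    return frozenset(closure - blacklist)


def gene_closures(annotation: GoAnnotation, ontology: GoOntology,
                  blacklist: frozenset[str] = frozenset()
                  ) -> dict[tuple[str, str], frozenset[str]]:
    """Propagated, blacklist-filtered closure per annotated gene."""
    return {
        gene: propagate_terms(terms, ontology, blacklist)
        for gene, terms in annotation.items()
    }


def group_terms(assignment: GroupAssignment,
                closures: Mapping[tuple[str, str], frozenset[str]]
                ) -> dict[str, frozenset[str]]:
    """Union of member closures per homology group (may be empty)."""
    combined: dict[str, set[str]] = {}
    for member, label in assignment.mapping.items():
        combined.setdefault(label, set()).update(closures.get(member, frozenset()))
    return {label: frozenset(terms) for label, terms in combined.items()}


def gs2_pair_score(closure1: frozenset[str],
                   closure2: frozenset[str]) -> float | None:
    """Two-gene GS² similarity; None when either closure is empty."""
    if not closure1 or not closure2:
        return None
    overlap = len(closure1 & closure2)
    return (overlap / len(closure1) + overlap / len(closure2)) / 2.0


def score_conserved_pairs(
    conserved: Sequence[ConservedPair],
    closures: Mapping[tuple[str, str], frozenset[str]],
    group_closures: Mapping[str, frozenset[str]] | None = None,
    gene_groups: Mapping[tuple[str, str], str] | None = None,
    level: str = "gene",
) -> None:
    """Attach a GS² score to each conserved pair (in place).

    ``level='gene'`` scores each occurrence from the two member genes'
    closures and averages the defined occurrence scores.  A gene without
    annotation of its own falls back to the combined closure of its
    homology group, when both ``group_closures`` and the ``gene_groups``
    membership mapping are supplied.  ``level='group'`` scores the pair
    once from the two group closures.  Pairs with no defined score keep
    ``gs2=None``.
    """
    group_closures = group_closures or {}
    gene_groups = gene_groups or {}
    for cp in conserved:
        if level == "group":
            c1 = group_closures.get(cp.key.groups[0], frozenset())
            c2 = group_closures.get(cp.key.groups[1], frozenset())
            cp.gs2 = gs2_pair_score(c1, c2)
            continue
        if level != "gene":
            raise ValueError(f"level must be 'gene' or 'group', got {level!r}")
        scores = []
        for occ in cp.occurrences:
            left = _gene_closure(occ.species, occ.left_gene, closures,
                                 group_closures, gene_groups)
            right = _gene_closure(occ.species, occ.right_gene, closures,
                                  group_closures, gene_groups)
            score = gs2_pair_score(left, right)
            if score is not None:
                scores.append(score)
        cp.gs2 = sum(scores) / len(scores) if scores else None


def _gene_closure(species, gene, closures, group_closures, gene_groups):
    own = closures.get((species, gene), frozenset())
    if own:
        return own
    label = gene_groups.get((species, gene))
    if label is None:
        return frozenset()
    return group_closures.get(label, frozenset())


def fraction_related_by_conservation(
    conserved: Sequence[ConservedPair],
    threshold: float = RANDOM_GS2_THRESHOLD,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Fraction of pairs with GS² above threshold, per conservation bin.

    For every orientation and every ``bin_width``-wide conservation bin the
    fraction (#pairs with gs2 > threshold) / (#pairs with a defined gs2) is
    reported, together with both denominators (pairs with a defined score
    and all pairs in the bin).  Bins with no defined-score pair get an
    empty fraction (NaN).
    """
    if not conserved:
        return pd.DataFrame(columns=["orientation", "bin_low", "fraction",
                                     "n_defined", "n_total"])
    max_cons = max(cp.conservation for cp in conserved)
    n_bins = int(max_cons / bin_width) + 1
    rows = []
    for orientation in ORIENTATIONS:
        members = [cp for cp in conserved if cp.key.orientation == orientation]
        for i in range(n_bins):
            low = i * bin_width
            high = low + bin_width
            in_bin = [cp for cp in members
                      if low <= cp.conservation < high
                      or (i == n_bins - 1 and cp.conservation >= high)]
            defined = [cp for cp in in_bin if cp.gs2 is not None]
            related = [cp for cp in defined if cp.gs2 > threshold]
            rows.append({
                "orientation": orientation,
                "bin_low": round(low, 10),
                "fraction": len(related) / len(defined) if defined else float("nan"),
                "n_defined": len(defined),
                "n_total": len(in_bin),
            })
    return pd.DataFrame(rows)
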