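"""Bidirectional-promoter candidate nomination.

Divergently transcribed gene pairs separated by less than ~1 kb are assumed
to share a promoter region between their 5' ends.  Candidates are divergent
pairs that (a) occur in the focus species with an intergenic distance below
the cutoff — overlapping coding spans (negative distances) qualify — and
(b) whose canonical key is found in at least ``min_species`` species,
ranked by evolutionary conservation.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .errors import MissingDataError
from .gene_model import DIVERGENT
from .pair_conservation import ConservedPair


def bidirectional_candidates(
    conserved: Sequence[ConservedPair],
    focus_species: str,
    max_distance: int = 1000,
    min_species: int = 2,
) -> pd.DataFrame:
    """Ranked bidirectional-promoter candidates for one focus species.

    The distance test is strict (< ``max_distance``) and uses the minimum
    distance when the pair occurs several times in the focus species; all
    focus-species occurrences are listed.  Sorted by conservation
    descending, ties by GS² descending then by group labels.
    """
    species_present = {occ.species for cp in conserved for occ in cp.occurrences}
    if focus_species not in species_present:
        raise MissingDataError(
            f"focus species {focus_species!r} absent from the conserved-pair set"
        )
    rows = []
    for cp in conserved:
        if cp.key.orientation != DIVERGENT or cp.n_species < min_species:
            continue
        focus_occ = [o for o in cp.occurrences if o.species == focus_species]
        if not focus_occ:
            continue
        min_dist = min(o.intergenic_distance for o in focus_occ)
        if min_dist >= max_distance:
            continue
        for occ in focus_occ:
            rows.append({
                "gene1": occ.left_gene,
                "gene2": occ.right_gene,
                "conservation": round(cp.conservation, 6),
                "intergenic_distance": occ.intergenic_distance,
                "gs2": float("nan") if cp.gs2 is None else round(cp.gs2, 4),
                "group1": cp.key.groups[0],
                "group2": cp.key.groups[1],
                "n_species": cp.n_species,
                "species": ",".join(sorted(cp.species_set)),
                "_sort_gs2": -1.0 if cp.gs2 is None else cp.gs2,
            })
    df = pd.DataFrame(rows, columns=[
        "gene1", "gene2", "conservation", "intergenic_distance", "gs2",
        "group1", "group2", "n_species", "species", "_sort_gs2",
    ])
    df = df.sort_values(
        by=["conservation", "_sort_gs2", "group1", "group2"],
        ascending=[False, False, True, True],
        kind="stable",
    ).drop(columns="_sort_gs2").reset_index(drop=True)
    return df
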