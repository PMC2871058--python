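"""Shuffle null model for cross-species sharing of adjacent gene pairs.

Observed cross-species pair sharing is compared against a null in which,
independently for every species, the homology labels are permuted uniformly
over that species' gene positions.  Gene coordinates, strands and therefore
adjacency and orientation-class frequencies are untouched; only "which gene
carries which label" is randomized, so the per-species label multiset
(including unassigned genes) is exactly preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneRecord
from .gene_model import ORIENTATIONS, extract_adjacent_pairs
from .pair_conservation import canonical_key


def shuffle_group_labels(records: Sequence[GeneRecord], scheme: str,
                         rng: np.random.Generator) -> list[GeneRecord]:
    """Permute homology labels over gene positions, independently per species."""
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_species.setdefault(rec.species, []).append(i)
    out = list(records)
    for species in sorted(by_species):
        idx = by_species[species]
        labels = [records[i].group_label(scheme) for i in idx]
        perm = rng.permutation(len(idx))
        for slot, j in zip(idx, perm):
            out[slot] = records[slot].with_label(scheme, labels[j])
    return out


@dataclass
class NullEstimate:
    """Monte-Carlo summary of the shuffle null for shared pair keys."""

    shared_pair_probability: float
    ci_low: float
    ci_high: float
    n_replicates: int
    observed_shared: int
    null_shared_counts: np.ndarray
    per_orientation: pd.DataFrame

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_shared_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_shared_counts, ddof=1)) if \
            len(self.null_shared_counts) > 1 else 0.0

    def empirical_p(self) -> float:
        """P(null >= observed), with the +1 correction for a valid p-value."""
        exceed = int(np.sum(self.null_shared_counts >= self.observed_shared))
        return (exceed + 1) / (self.n_replicates + 1)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.null_shared_counts, q))

    def to_table(self) -> pd.DataFrame:
        return self.per_orientation


def _shared_key_counts(records: Sequence[GeneRecord], scheme: str) -> dict[str, int]:
    """Per orientation: number of distinct keys present in >= 2 species."""
    species_per_key: dict = {}
    for pair in extract_adjacent_pairs(records):
        key = canonical_key(pair, scheme)
        if key is None:
            continue
        species_per_key.setdefault(key, set()).add(pair.species)
    counts = {o: 0 for o in ORIENTATIONS}
    counts["total_keys"] = len(species_per_key)
    for key, species in species_per_key.items():
        if len(species) >= 2:
            counts[key.orientation] += 1
    counts["shared"] = sum(counts[o] for o in ORIENTATIONS)
    return counts


def null_shared_pair_probability(
    records: Sequence[GeneRecord],
    scheme: str,
    n_replicates: int = 100,
    seed: int = 0,
) -> NullEstimate:
    """Estimate the chance probability that a pair key is shared by >= 2 species.

    For each replicate the labels of every species are shuffled and the
    fraction of distinct pair keys appearing in at least two species is
    recorded; the reported probability is the mean fraction over replicates
    with a normal-approximation 95% CI over replicate fractions.  The
    observed (unshuffled) shared-key count is kept for comparison with the
    null distribution of shared counts.
    """
    if n_replicates < 10:
        raise ValueError("need at least 10 replicates for a meaningful null")
    n_species = len({r.species for r in records})
    if n_species < 2:
        raise ValueError("need >= 2 species to assess cross-species sharing")
    rng = np.random.default_rng(seed)
    observed = _shared_key_counts(records, scheme)

    fractions = np.empty(n_replicates)
    shared_counts = np.empty(n_replicates, dtype=int)
    orient_counts = {o: np.empty(n_replicates, dtype=int) for o in ORIENTATIONS}
    for rep in range(n_replicates):
        shuffled = shuffle_group_labels(records, scheme, rng)
        counts = _shared_key_counts(shuffled, scheme)
        shared_counts[rep] = counts["shared"]
        total = counts["total_keys"]
        fractions[rep] = counts["shared"] / total if total else 0.0
        for o in ORIENTATIONS:
            orient_counts[o][rep] = counts[o]

    prob = float(np.mean(fractions))
    se = float(np.std(fractions, ddof=1) / np.sqrt(n_replicates)) if \
        n_replicates > 1 else 0.0
    per_orientation = pd.DataFrame([{
        "orientation": o,
        "observed_shared": observed[o],
        "null_mean": float(np.mean(orient_counts[o])),
        "null_sd": float(np.std(orient_counts[o], ddof=1)),
        "empirical_p": (int(np.sum(orient_counts[o] >= observed[o])) + 1)
        / (n_replicates + 1),
    } for o in ORIENTATIONS])
    return NullEstimate(
        shared_pair_probability=prob,
        ci_low=max(0.0, prob - 1.96 * se),
        ci_high=min(1.0, prob + 1.96 * se),
        n_replicates=n_replicates,
        observed_shared=observed["shared"],
        null_shared_counts=shared_counts,
        per_orientation=per_orientation,
    )
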