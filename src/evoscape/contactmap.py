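"""Residue–residue contact maps from inter-residue distance tables.

A pair (i, j) is a contact when the minimal heavy-atom distance between the
two residues is strictly below a cutoff (8 Å by default; 5.5 Å is used for
families whose structural variability is well covered) and the positions
are separated by at least `min_separation` (default 5) along the sequence,
the standard in coevolutionary contact prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContactMap", "contact_map_from_distances"]


@dataclass
class ContactMap:
    """True contacts as a set of unordered position pairs (0-based)."""

    L: int
    contacts: set[tuple[int, int]] = field(default_factory=set)
    min_separation: int = 5
    distance_cutoff: float = 8.0

    def __post_init__(self) -> None:
        norm = set()
        for (i, j) in self.contacts:
            if i == j:
                raise ValueError(f"self-contact ({i},{i})")
            i, j = (i, j) if i < j else (j, i)
            if not (0 <= i and j < self.L):
                raise ValueError(f"contact ({i},{j}) out of range for L={self.L}")
            if j - i < self.min_separation:
                raise ValueError(f"contact ({i},{j}) violates min_separation="
                                 f"{self.min_separation}")
            norm.add((i, j))
        self.contacts = norm

    def __contains__(self, pair) -> bool:
        i, j = pair
        return ((i, j) if i < j else (j, i)) in self.contacts

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def n_eligible_pairs(self) -> int:
        s = self.min_separation
        return max(self.L - s, 0) * (self.L - s + 1) // 2

    @property
    def density(self) -> float:
        """Contact fraction among separation-eligible pairs."""
        n = self.n_eligible_pairs
        return len(self.contacts) / n if n else 0.0

    def to_frame(self) -> pd.DataFrame:
        pairs = sorted(self.contacts)
        return pd.DataFrame(pairs, columns=["i", "j"])


def contact_map_from_distances(distances, L: int, cutoff: float = 8.0,
                               min_separation: int = 5) -> ContactMap:
    """Build a ContactMap from per-pair minimal heavy-atom distances (Å).

    `distances` is a DataFrame (or path to a TSV) with columns i, j,
    distance (0-based positions).  Pairs at distance strictly below
    `cutoff` and separation >= `min_separation` are kept.
    """
    if not isinstance(distances, pd.DataFrame):
        distances = pd.read_csv(distances, sep="\t")
    cols = list(distances.columns[:3])
    contacts = set()
    for i, j, d in distances[cols].itertuples(index=False):
        i, j = int(i), int(j)
        if d < 0:
            raise ValueError(f"negative distance for pair ({i},{j})")
        if abs(i - j) < min_separation:
            continue
        if d < cutoff:
            contacts.add((min(i, j), max(i, j)))
    return ContactMap(L=L, contacts=contacts, min_separation=min_separation,
                      distance_cutoff=cutoff)
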