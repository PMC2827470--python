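"""Pathway annotation sets with inverse-membership gene weights.

A gene annotated to k overlapping pathways contributes 1/k to each of them,
so every annotated gene carries total weight 1 across the whole annotation.
This is the correction for multiple pathway membership used throughout the
enrichment statistics; it makes per-pathway "counts" non-integer in general.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import DataError

__all__ = ["PathwayAnnotation"]


@dataclass(frozen=True)
class PathwayAnnotation:
    """Mapping pathway id -> gene-id set, with derived membership weights.

    Attributes
    ----------
    sets:
        Pathway id -> frozenset of gene ids. Sets may overlap.
    descriptions:
        Optional pathway id -> free-text description (carried through GMT
        round trips).
    membership_count:
        Gene id -> number of pathways the gene belongs to (k >= 1).
    weight:
        Gene id -> 1/k. For every annotated gene the weights over its
        pathways sum to exactly 1.
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    membership_count: dict[str, int] = field(init=False)
    weight: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"pathway {name!r} has no members")
            for g in members:
                counts[g] = counts.get(g, 0) + 1
        object.__setattr__(self, "membership_count", counts)
        object.__setattr__(
            self, "weight", {g: 1.0 / k for g, k in counts.items()}
        )

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> "PathwayAnnotation":
        return cls(
            sets={name: frozenset(members) for name, members in sets.items()},
            descriptions=dict(descriptions or {}),
        )

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.sets)

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self.membership_count)

    def weighted_count(self, genes: Iterable[str], pathway: str) -> float:
        """Sum of 1/k weights of ``genes`` that belong to ``pathway``."""
        members = self.sets[pathway]
        return float(sum(self.weight[g] for g in genes if g in members))

    def __len__(self) -> int:
        return len(self.sets)
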