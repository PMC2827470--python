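"""Cross-platform signature mapping, Venn partitioning, direction
concordance and condition-crosstalk partitioning.

After mapping, gene identity is the join key everywhere: probe-level
comparison across platforms is unsupported by design, because platforms are
compared through a shared non-redundant gene-id namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, StatError
from .io_formats import SignatureTable

__all__ = [
    "ProbeMap",
    "VennPartition",
    "ConcordanceReport",
    "CrosstalkPartition",
    "FoldChangeMatrix",
    "map_signature",
    "venn_partition",
    "concordance",
    "crosstalk_partition",
    "foldchange_matrix",
]


@dataclass(frozen=True)
class ProbeMap:
    """Probe id -> gene id in a shared non-redundant namespace."""

    mapping: dict[str, str]
    platform: str = ""

    def __post_init__(self) -> None:
        if any(not g for g in self.mapping.values()):
            raise DataError("empty gene id in probe map")

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region decomposition of 2 or 3 labeled gene sets.

    Regions use canonical labels A, B, C, AB, AC, BC, ABC where the letters
    follow the input order; ``labels`` records which input set each letter
    denotes. Regions are pairwise disjoint and their union is the union of
    the inputs.
    """

    labels: tuple[str, ...]
    regions: dict[str, frozenset[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {region: len(genes) for region, genes in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (region, len(genes), ";".join(sorted(genes)))
            for region, genes in self.regions.items()
        ]
        return pd.DataFrame(rows, columns=["region", "count", "genes"])


@dataclass(frozen=True)
class ConcordanceReport:
    same: frozenset[str]
    opposite: frozenset[str]

    @property
    def fraction_same(self) -> float:
        return len(self.same) / (len(self.same) + len(self.opposite))


@dataclass(frozen=True)
class CrosstalkPartition:
    only_1: frozenset[str]
    only_2: frozenset[str]
    both: frozenset[str]
    reference: str  # 'union' or 'condition1'

    def percentages(self) -> dict[str, float]:
        if self.reference == "union":
            denom = len(self.only_1) + len(self.only_2) + len(self.both)
        else:
            denom = len(self.only_1) + len(self.both)
        if denom == 0:
            raise StatError("crosstalk percentages undefined: empty reference")
        return {
            "only_1": 100.0 * len(self.only_1) / denom,
            "only_2": 100.0 * len(self.only_2) / denom,
            "both": 100.0 * len(self.both) / denom,
        }


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Genes x signatures log2fc matrix for heat-map style views.

    ``values`` holds 0.0 where a gene is absent from a signature and
    ``present`` marks which cells carry a measured value; absent cells are
    masked, never imputed. Rows are ordered by the first signature's log2fc
    descending; genes absent from the first signature follow, by gene id.
    """

    values: pd.DataFrame
    present: pd.DataFrame


# ---------------------------------------------------------------------------

def map_signature(
    sig: SignatureTable,
    source_map: ProbeMap,
    target_universe: Iterable[str],
) -> tuple[SignatureTable, float]:
    """Translate a probe-level signature into the shared gene namespace.

    Entries are retained iff their gene lies in ``target_universe``; probes
    missing from the map are dropped and counted against the mapped
    fraction. When several probes map to one gene the smallest-P entry wins
    (ties: largest |log2fc|, then probe id). Returns the gene-level table
    (probe_id column rewritten to the gene id, making the operation
    idempotent) and the mapped fraction retained/total.
    """
    universe = frozenset(target_universe)
    if not universe:
        raise DataError("empty target universe")
    total = len(sig)
    if total == 0:
        raise DataError("empty signature table")

    frame = sig.frame.copy()
    frame["gene_id"] = [
        source_map.mapping.get(p) for p in frame["probe_id"]
    ]
    frame = frame[frame["gene_id"].notna()]
    frame = frame[frame["gene_id"].isin(universe)]
    frame = frame.assign(_abs=frame["log2fc"].abs()).sort_values(
        by=["p_value", "_abs", "probe_id"], ascending=[True, False, True],
        kind="mergesort",
    )
    frame = frame.drop_duplicates(subset="gene_id", keep="first")
    frame = frame.drop(columns="_abs")
    frame["probe_id"] = frame["gene_id"]
    frame = frame.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    mapped = SignatureTable(frame=frame, background_size=sig.background_size)
    return mapped, len(mapped) / total


def venn_partition(
    sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> VennPartition:
    """Exact disjoint region decomposition of 2 or 3 labeled gene sets."""
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    labels = [label for label, _ in items]
    if len(labels) != len(set(labels)):
        raise DataError("duplicate set labels")
    if len(items) not in (2, 3):
        raise DataError("venn_partition takes 2 or 3 sets")
    letters = "ABC"[: len(items)]
    as_sets = {letter: frozenset(members)
               for letter, (_, members) in zip(letters, items)}

    regions: dict[str, frozenset[str]] = {}
    for k in range(1, len(items) + 1):
        for combo in combinations(letters, k):
            inside = frozenset.intersection(*(as_sets[c] for c in combo))
            outside = frozenset().union(
                *(as_sets[c] for c in letters if c not in combo)
            )
            regions["".join(combo)] = inside - outside
    return VennPartition(labels=tuple(labels), regions=regions)


def _gene_signs(table: SignatureTable) -> pd.Series:
    return np.sign(table.log2fc_by_gene())


def concordance(
    sig_a: SignatureTable,
    sig_b: SignatureTable,
    orientation_b: str = "as-is",
) -> ConcordanceReport:
    """Classify genes significant in both tables by fold-change sign.

    ``orientation_b='inverted'`` flips B's signs before comparison (for
    depletion-vs-induction designs read in the opposite orientation).
    """
    if orientation_b not in ("as-is", "inverted"):
        raise DataError(f"unknown orientation {orientation_b!r}")
    signs_a = _gene_signs(sig_a)
    signs_b = _gene_signs(sig_b)
    if orientation_b == "inverted":
        signs_b = -signs_b
    shared = signs_a.index.intersection(signs_b.index)
    if len(shared) == 0:
        raise StatError("no genes shared between the signatures")
    same = frozenset(g for g in shared if signs_a[g] == signs_b[g])
    return ConcordanceReport(same=same, opposite=frozenset(shared) - same)


def crosstalk_partition(
    sig_condition1: SignatureTable,
    sig_condition2: SignatureTable,
    reference: str = "union",
) -> CrosstalkPartition:
    """Partition genes by which condition(s) their regulation requires."""
    if reference not in ("union", "condition1"):
        raise DataError(f"unknown reference {reference!r}")
    g1, g2 = sig_condition1.genes, sig_condition2.genes
    if not g1 and not g2:
        raise StatError("both signatures are empty")
    return CrosstalkPartition(
        only_1=frozenset(g1 - g2),
        only_2=frozenset(g2 - g1),
        both=frozenset(g1 & g2),
        reference=reference,
    )


def foldchange_matrix(
    signatures: Sequence[tuple[str, SignatureTable]],
) -> FoldChangeMatrix:
    """Union-of-genes x signatures log2fc matrix with a missingness mask."""
    if not signatures:
        raise DataError("no signatures given")
    columns = {}
    for label, table in signatures:
        if label in columns:
            raise DataError(f"duplicate signature label {label!r}")
        columns[label] = table.log2fc_by_gene()
    values = pd.DataFrame(columns)
    present = values.notna()
    first = signatures[0][0]
    in_first = values[first].notna()
    head = values[in_first].sort_values(first, ascending=False, kind="mergesort")
    tail = values[~in_first].sort_index(kind="mergesort")
    values = pd.concat([head, tail])
    present = present.loc[values.index]
    return FoldChangeMatrix(values=values.fillna(0.0), present=present)
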