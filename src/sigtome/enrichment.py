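"""Weighted pathway overrepresentation with a binomial null, and
pathway-pair interconnectivity testing.

Each annotated gene is weighted by the inverse of the number of pathways it
belongs to (see :mod:`sigtome.annotations`), so per-pathway observed and
expected counts are non-integer in general. The null model is binomial: a
random gene set of the same size as the signature drawn from the array
background, with per-draw success probability equal to the pathway's share
of the background's total weight. P-values are one-sided
(overrepresentation only). For non-integer observed counts the upper tail
Pr(X >= w) is evaluated by its continuous extension, the regularized
incomplete beta function I_p(w, n - w + 1), which coincides with the exact
probability-mass summation at every integer w; a ceiling mode
(Pr(X >= ceil(w)), the literal tail of the integer-valued null) is
available behind a flag.

Interconnectivity tests, for each pair of selected pathways, whether the
signature contains more of the pair's shared genes than a random same-size
set would; shared-gene counts are unweighted by default (a weighted mode is
provided). Pairs sharing fewer than two regulated genes are reported but
flagged unassessed. Tiers follow the two-threshold convention: highly
significant P < 0.05, significant P < 0.10, otherwise low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import special

from .annotations import PathwayAnnotation
from .errors import DataError, StatError
from .io_formats import PajekNetwork, PajekVertex

__all__ = [
    "EnrichmentResult",
    "PairLink",
    "binomial_tail",
    "overrepresentation",
    "interconnectivity",
    "pathway_network",
    "enrichment_frame",
    "links_frame",
]

TIER_HIGH, TIER_SIGNIFICANT, TIER_LOW = "high", "significant", "low"
_TIER_COLORS = {TIER_HIGH: "Red", TIER_SIGNIFICANT: "Orange", TIER_LOW: "Gray"}


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    count: float        # weighted observed count (non-integer in general)
    expect: float       # weighted expected count under the null
    p_value: float
    significant: bool   # at alpha = 0.05 unless overridden


@dataclass(frozen=True)
class PairLink:
    pathways: tuple[str, str]   # unordered pair, stored sorted
    shared_regulated: float
    shared_background: float
    p_value: float
    tier: str
    assessed: bool              # False when shared_regulated < 2


def binomial_tail(n: int, p: float, w: float) -> float:
    """Upper-tail probability Pr(X >= w) for X ~ Binomial(n, p).

    ``w`` may be non-integer (weighted counts): the continuous extension
    I_p(w, n - w + 1) is used, which equals the exact pmf summation at
    integer w. By convention w <= 0 returns exactly 1.
    """
    if n < 1:
        raise StatError("binomial_tail needs n >= 1")
    if not 0.0 <= p <= 1.0:
        raise StatError(f"success probability {p} outside [0, 1]")
    if w > n:
        raise StatError(f"observed count {w} exceeds trials {n}")
    if w <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    return float(special.betainc(w, n - w + 1.0, p))


def overrepresentation(
    sig_genes: Iterable[str],
    background: Iterable[str],
    ann: PathwayAnnotation,
    alpha: float = 0.05,
    tail: str = "continuous",
    annotated_background_only: bool = False,
) -> list[EnrichmentResult]:
    """Weighted overrepresentation of each pathway in the signature.

    For pathway P with background weight S_P = sum of 1/k over background
    genes in P: count = sum of 1/k over signature genes in P,
    expect = |sig| * S_P / |background|, and the P-value is the binomial
    upper tail with n = |sig| and per-draw probability S_P / |background|.
    Results are sorted by ascending P-value, ties by pathway id.

    ``annotated_background_only`` restricts the universe to genes carrying
    at least one annotation; the default universe is the whole array.
    """
    sig = frozenset(sig_genes)
    bg = frozenset(background)
    if not bg:
        raise StatError("background is empty")
    if annotated_background_only:
        bg = bg & ann.annotated_genes
        sig = sig & bg
    if not sig <= bg:
        raise StatError("signature genes must be a subset of the background")
    if not sig:
        raise StatError("signature is empty")
    if tail not in ("continuous", "ceiling"):
        raise StatError(f"unknown tail mode {tail!r}")

    n, n_bg = len(sig), len(bg)
    results = []
    for pw in ann.pathway_ids:
        members = ann.sets[pw]
        s_p = sum(ann.weight[g] for g in members if g in bg)
        count = sum(ann.weight[g] for g in members if g in sig)
        prob = s_p / n_bg
        expect = n * prob
        w = math.ceil(count) if tail == "ceiling" else count
        w = min(w, n)  # weighted count can never exceed n; guard rounding
        p_value = binomial_tail(n, prob, w)
        results.append(EnrichmentResult(
            pathway=pw, count=float(count), expect=float(expect),
            p_value=p_value, significant=p_value < alpha,
        ))
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def _tier(p_value: float) -> str:
    if p_value < 0.05:
        return TIER_HIGH
    if p_value < 0.10:
        return TIER_SIGNIFICANT
    return TIER_LOW


def interconnectivity(
    selected: Sequence[str],
    sig_genes: Iterable[str],
    background: Iterable[str],
    ann: PathwayAnnotation,
    weighted: bool = False,
) -> list[PairLink]:
    """Shared-regulated-gene overrepresentation for each selected pair.

    For pathways A, B: shared_background = |A & B & background| and
    shared_regulated = |A & B & signature| (1/k-weighted sums when
    ``weighted``); the P-value is the binomial tail with n = |signature|
    and per-draw probability shared_background / |background|. Pairs with
    fewer than two shared regulated genes are reported with tier low and
    ``assessed=False``.
    """
    sig = frozenset(sig_genes)
    bg = frozenset(background)
    if not sig <= bg:
        raise StatError("signature genes must be a subset of the background")
    for pw in selected:
        if pw not in ann.sets:
            raise DataError(f"unknown pathway {pw!r}")
    n, n_bg = len(sig), len(bg)
    if n_bg == 0 or n == 0:
        raise StatError("background and signature must be non-empty")

    links = []
    ordered = sorted(set(selected))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            shared = ann.sets[a] & ann.sets[b]
            in_bg = shared & bg
            in_sig = shared & sig
            if weighted:
                shared_bg = sum(ann.weight[g] for g in in_bg)
                shared_reg = sum(ann.weight[g] for g in in_sig)
            else:
                shared_bg, shared_reg = float(len(in_bg)), float(len(in_sig))
            if shared_bg == 0 and shared_reg > 0:
                raise DataError(
                    f"pair ({a}, {b}): regulated shared genes outside background"
                )
            p_value = binomial_tail(n, shared_bg / n_bg, min(shared_reg, n))
            assessed = len(in_sig) >= 2
            links.append(PairLink(
                pathways=(a, b),
                shared_regulated=shared_reg,
                shared_background=shared_bg,
                p_value=p_value,
                tier=_tier(p_value) if assessed else TIER_LOW,
                assessed=assessed,
            ))
    links.sort(key=lambda l: (l.p_value, l.pathways))
    return links


def pathway_network(
    results: Sequence[EnrichmentResult],
    links: Sequence[PairLink],
) -> PajekNetwork:
    """Network of significant pathways joined by >=2-shared-gene links.

    Vertices are the significant pathways, colored by the tier of their
    strongest (smallest-P assessed) link; edge weight is the shared
    regulated-gene count.
    """
    known = {r.pathway for r in results}
    for link in links:
        if not set(link.pathways) <= known:
            raise DataError(f"link {link.pathways} references unknown pathway")
    vertices_names = sorted(r.pathway for r in results if r.significant)
    index = {name: i + 1 for i, name in enumerate(vertices_names)}

    best_tier: dict[str, str] = {}
    edges = []
    for link in sorted(links, key=lambda l: (l.p_value, l.pathways)):
        a, b = link.pathways
        if not link.assessed or a not in index or b not in index:
            continue
        edges.append((index[a], index[b], float(link.shared_regulated)))
        for name in (a, b):
            best_tier.setdefault(name, link.tier)

    vertices = [
        PajekVertex(id=index[name], label=name,
                    color=_TIER_COLORS[best_tier.get(name, TIER_LOW)])
        for name in vertices_names
    ]
    net = PajekNetwork(vertices=vertices, edges=edges)
    net.validate()
    return net


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway, r.count, r.expect, r.p_value, r.significant)
         for r in results],
        columns=["pathway", "count", "expect", "p_value", "significant"],
    )


def links_frame(links: Sequence[PairLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.pathways[0], l.pathways[1], l.shared_regulated,
          l.shared_background, l.p_value, l.tier, l.assessed)
         for l in links],
        columns=["pathway_a", "pathway_b", "shared_regulated",
                 "shared_background", "p_value", "tier", "assessed"],
    )
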