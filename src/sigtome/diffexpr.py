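"""Two-condition differential expression: normalization, per-probe Welch
t statistics, significance filtering, probe-to-gene collapsing and direction
summaries.

Fold changes are always base-2 logarithms, treated minus control. The
significance filter keeps probes with raw P < alpha (no multiple-testing
correction by default; Benjamini-Hochberg is available as an opt-in flag),
matching the convention of signature studies that report raw P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, StatError
from .io_formats import SignatureTable
from .synthetic_data import ExpressionStudy

__all__ = [
    "Signature",
    "SignatureEntry",
    "DirectionSummary",
    "normalize",
    "probe_statistics",
    "build_signature",
    "collapse_to_genes",
    "summarize_direction",
]


@dataclass(frozen=True)
class SignatureEntry:
    probe_id: str
    gene_id: str
    log2fc: float
    p_value: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class Signature:
    """Probes passing the significance filter, sorted by ascending P-value.

    Ties are broken by |log2fc| descending, then probe id, so the ordering
    is bit-stable across runs.
    """

    entries: tuple[SignatureEntry, ...]
    background_size: int
    alpha: float

    def __post_init__(self) -> None:
        probes = [e.probe_id for e in self.entries]
        if len(probes) != len(set(probes)):
            raise DataError("duplicate probe ids in signature")
        for e in self.entries:
            if not e.p_value < self.alpha:
                raise DataError(
                    f"entry {e.probe_id} has p={e.p_value} >= alpha={self.alpha}"
                )
            if e.log2fc == 0:
                raise DataError(f"entry {e.probe_id} has zero log2fc")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries)

    def to_table(self) -> SignatureTable:
        frame = pd.DataFrame(
            [(e.probe_id, e.gene_id, e.log2fc, e.p_value) for e in self.entries],
            columns=["probe_id", "gene_id", "log2fc", "p_value"],
        )
        return SignatureTable(frame=frame, background_size=self.background_size)


@dataclass(frozen=True)
class DirectionSummary:
    n_up: int
    n_down: int

    @property
    def pct_up(self) -> float:
        return round(100.0 * self.n_up / (self.n_up + self.n_down), 1)

    @property
    def pct_down(self) -> float:
        return round(100.0 * self.n_down / (self.n_up + self.n_down), 1)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _check_positive(study: ExpressionStudy) -> None:
    values = study.intensities
    bad = values <= 0
    if bad.to_numpy().any():
        stacked = bad.stack()
        probe, sample = stacked[stacked].index[0]
        raise DataError(
            f"non-positive intensity at probe {probe!r}, sample {sample!r}"
        )


def normalize(study: ExpressionStudy, method: str = "median") -> ExpressionStudy:
    """Return a normalized copy of the study; the input is never modified.

    median: shift each sample's log2 intensities so its median equals the
    global median of all log2 intensities. quantile: replace each sample's
    values with the mean sorted profile, rank for rank, equalizing the
    per-sample empirical distributions. none: identity.
    """
    if method == "none":
        return replace(study, intensities=study.intensities.copy())
    _check_positive(study)
    log2 = np.log2(study.intensities.to_numpy(dtype=float))
    if method == "median":
        target = np.median(log2)
        shifted = log2 - np.median(log2, axis=0) + target
        out = np.exp2(shifted)
    elif method == "quantile":
        order = np.argsort(log2, axis=0, kind="stable")
        mean_profile = np.mean(np.sort(log2, axis=0), axis=1)
        normed = np.empty_like(log2)
        rows = np.arange(log2.shape[0])
        for j in range(log2.shape[1]):
            normed[order[:, j], j] = mean_profile[rows]
        out = np.exp2(normed)
    else:
        raise DataError(f"unknown normalization method {method!r}")
    frame = pd.DataFrame(out, index=study.intensities.index,
                         columns=study.intensities.columns)
    return replace(study, intensities=frame)


# ---------------------------------------------------------------------------
# Per-probe statistics
# ---------------------------------------------------------------------------

def probe_statistics(study: ExpressionStudy) -> pd.DataFrame:
    """Per-probe log2 fold change and two-sided Welch t-test P-value.

    log2fc = mean(log2 treated) - mean(log2 control). Degenerate probes
    with zero variance in both groups get P = 1 when the group means are
    equal (no evidence of change) and the smallest positive float when they
    differ (change certain under the model).
    """
    trt = study.samples("treated")
    ctl = study.samples("control")
    if len(trt) < 2 or len(ctl) < 2:
        raise StatError("need >= 2 replicates per group")
    _check_positive(study)
    x = np.log2(study.intensities[trt].to_numpy(dtype=float))
    y = np.log2(study.intensities[ctl].to_numpy(dtype=float))
    log2fc = x.mean(axis=1) - y.mean(axis=1)

    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    degenerate = (vx == 0) & (vy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = np.finfo(float).tiny
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p},
        index=study.intensities.index.copy(),
    )


def _sort_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.assign(_abs=frame["log2fc"].abs())
    frame = frame.sort_values(
        by=["p_value", "_abs", "probe_id"], ascending=[True, False, True],
        kind="mergesort",
    )
    return frame.drop(columns="_abs").reset_index(drop=True)


def build_signature(
    stats_frame: pd.DataFrame,
    alpha: float = 0.05,
    background_size: int | None = None,
    probe_gene_map: dict[str, str] | None = None,
    correction: str | None = None,
) -> Signature:
    """Filter per-probe statistics to the significant signature.

    Keeps exactly the probes with p_value < alpha (after optional
    Benjamini-Hochberg adjustment when ``correction='bh'``). Probes with a
    fold change of exactly zero cannot be assigned a direction and are
    dropped. ``probe_gene_map`` supplies gene ids; absent probes keep their
    probe id as gene id.
    """
    if not 0.0 < alpha < 1.0:
        raise StatError("alpha must lie in (0, 1)")
    p = stats_frame["p_value"].to_numpy(dtype=float)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, method="fdr_bh")[1]
    elif correction is not None:
        raise StatError(f"unknown correction {correction!r}")
    keep = (p < alpha) & (stats_frame["log2fc"].to_numpy(dtype=float) != 0.0)
    sub = stats_frame.loc[keep].copy()
    sub["p_value"] = p[keep]
    sub = sub.reset_index().rename(columns={sub.index.name or "index": "probe_id"})
    gene_map = probe_gene_map or {}
    sub["gene_id"] = [gene_map.get(pid, pid) for pid in sub["probe_id"]]
    sub = _sort_frame(sub)
    entries = tuple(
        SignatureEntry(row.probe_id, row.gene_id, float(row.log2fc),
                       float(row.p_value))
        for row in sub.itertuples(index=False)
    )
    return Signature(
        entries=entries,
        background_size=background_size or len(stats_frame),
        alpha=alpha,
    )


def signature_from_table(table: SignatureTable, alpha: float = 0.05) -> Signature:
    """Re-apply the significance filter to an already-tabulated signature."""
    frame = table.frame.set_index("probe_id")[["log2fc", "p_value"]]
    gene_map = dict(zip(table.frame["probe_id"], table.frame["gene_id"]))
    return build_signature(
        frame, alpha=alpha,
        background_size=table.background_size or len(table),
        probe_gene_map=gene_map,
    )


def collapse_to_genes(sig: Signature) -> Signature:
    """One entry per gene: keep the probe with the smallest P-value
    (ties: largest |log2fc|, then probe id). Idempotent."""
    best: dict[str, SignatureEntry] = {}
    for e in sig.entries:
        cur = best.get(e.gene_id)
        if cur is None:
            best[e.gene_id] = e
            continue
        key_new = (e.p_value, -abs(e.log2fc), e.probe_id)
        key_cur = (cur.p_value, -abs(cur.log2fc), cur.probe_id)
        if key_new < key_cur:
            best[e.gene_id] = e
    entries = sorted(
        best.values(), key=lambda e: (e.p_value, -abs(e.log2fc), e.probe_id)
    )
    return Signature(entries=tuple(entries), background_size=sig.background_size,
                     alpha=sig.alpha)


def summarize_direction(sig: Signature) -> DirectionSummary:
    if not sig.entries:
        raise StatError("direction split undefined for an empty signature")
    n_up = sum(1 for e in sig.entries if e.log2fc > 0)
    return DirectionSummary(n_up=n_up, n_down=len(sig.entries) - n_up)
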