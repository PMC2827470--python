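"""ddCt fold changes from qPCR Ct tables and their concordance with array
fold changes.

The comparative Ct method with an internal-control (reference) gene:
dCt = Ct(target) - Ct(reference) within each condition, ddCt is the treated
minus control difference of dCt, and -ddCt is the log2 fold change under the
standard 100% amplification-efficiency assumption (fold = 2^-ddCt).
Replicate Cts are averaged before differencing. Agreement with array
measurements is quantified by the Pearson product-moment correlation of the
two log2 fold-change vectors; R^2 is reported as in validation figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, StatError
from .io_formats import SignatureTable

__all__ = ["QpcrMeasurement", "ValidationReport", "ddct", "validate_panel"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one target gene in both conditions."""

    gene_id: str
    ct_target_treated: np.ndarray
    ct_reference_treated: np.ndarray
    ct_target_control: np.ndarray
    ct_reference_control: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ct_target_treated", "ct_reference_treated",
                     "ct_target_control", "ct_reference_control"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size == 0:
                raise DataError(f"{self.gene_id}: {name} has no replicates")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{self.gene_id}: non-finite Ct in {name}")


@dataclass(frozen=True)
class ValidationReport:
    per_gene: pd.DataFrame  # columns: array_log2fc, qpcr_log2fc; index gene
    pearson_r: float

    @property
    def r_squared(self) -> float:
        return self.pearson_r ** 2


def ddct(m: QpcrMeasurement) -> float:
    """-ddCt as log2 fold change (treated vs control).

    Adding any constant to all Ct values leaves the result unchanged: the
    reference gene cancels plate- or input-level offsets.
    """
    dct_treated = m.ct_target_treated.mean() - m.ct_reference_treated.mean()
    dct_control = m.ct_target_control.mean() - m.ct_reference_control.mean()
    return float(-(dct_treated - dct_control))


def validate_panel(
    array_sig: SignatureTable,
    panel: Sequence[QpcrMeasurement],
) -> ValidationReport:
    """Pearson correlation between array and qPCR log2 fold changes.

    Computed over genes present in both the signature table and the panel;
    at least 3 shared genes are required, and either vector being constant
    makes the correlation undefined.
    """
    array_lfc = array_sig.log2fc_by_gene()
    rows = []
    for m in panel:
        if m.gene_id in array_lfc.index:
            rows.append((m.gene_id, float(array_lfc[m.gene_id]), ddct(m)))
    if len(rows) < 3:
        raise StatError(
            f"need >= 3 genes shared between panel and signature, got {len(rows)}"
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "array_log2fc", "qpcr_log2fc"]
    ).set_index("gene_id")
    x = per_gene["array_log2fc"].to_numpy()
    y = per_gene["qpcr_log2fc"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatError("correlation undefined: zero variance in a vector")
    r = float(stats.pearsonr(x, y).statistic)
    return ValidationReport(per_gene=per_gene, pearson_r=r)
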