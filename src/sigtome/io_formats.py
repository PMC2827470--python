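"""Readers and writers for every external representation the pipeline touches.

Formats
-------
- Signature tables: CSV with canonical columns ``probe_id, gene_id, log2fc,
  p_value``; the background size (number of probes surveyed) travels in a
  ``#background=N`` comment line because CSV has no standard slot for it.
  Column-name aliases are configurable because supplementary tables in the
  wild rarely agree on headers. Unknown extra columns are preserved verbatim.
- Expression matrices: CSV, probes x samples, first column ``probe_id``.
- Group labels and probe maps: two-column TSV.
- Gene sets: GMT (name <TAB> description <TAB> member...).
- Networks: Pajek ``.net`` (``*Vertices`` / ``*Edges`` sections), the plain
  text carrier for network visualisation tools.

All text I/O is UTF-8 with "." as the decimal point; readers reject rather
than silently coerce malformed numerics and report line numbers.
"""

from __future__ import annotations

import io
import math
import re
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import PathwayAnnotation
from .errors import DataError, FormatError

__all__ = [
    "SignatureTable",
    "PajekVertex",
    "PajekNetwork",
    "read_signature_csv",
    "write_signature_csv",
    "read_gmt",
    "write_gmt",
    "read_pajek",
    "write_pajek",
    "read_expression_csv",
    "write_expression_csv",
    "read_groups_tsv",
    "write_groups_tsv",
    "read_probe_map_tsv",
    "write_probe_map_tsv",
    "read_ct_csv",
    "write_ct_csv",
]

SIGNATURE_COLUMNS = ("probe_id", "gene_id", "log2fc", "p_value")


# ---------------------------------------------------------------------------
# Signature tables
# ---------------------------------------------------------------------------

@dataclass
class SignatureTable:
    """A filtered signature: one row per probe with fold change and P-value.

    ``frame`` always contains the four canonical columns (probe_id, gene_id,
    log2fc, p_value) and may carry extra annotation columns, which round-trip
    through the CSV writer untouched. ``background_size`` is the number of
    probes surveyed on the platform, needed by the enrichment null.
    """

    frame: pd.DataFrame
    background_size: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SIGNATURE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"signature table missing columns: {missing}")
        probes = self.frame["probe_id"]
        if probes.duplicated().any():
            dup = probes[probes.duplicated()].iloc[0]
            raise DataError(f"duplicate probe_id in signature table: {dup!r}")
        lfc = self.frame["log2fc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lfc)):
            raise DataError("non-finite log2fc in signature table")
        p = self.frame["p_value"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise DataError("p_value outside (0, 1] in signature table")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene_id"])

    @property
    def probes(self) -> frozenset[str]:
        return frozenset(self.frame["probe_id"])

    def log2fc_by_gene(self) -> pd.Series:
        """Gene id -> log2fc. Requires a gene-level (one row per gene) table."""
        genes = self.frame["gene_id"]
        if genes.duplicated().any():
            raise DataError("table is probe-level; collapse to genes first")
        return self.frame.set_index("gene_id")["log2fc"]

    def copy(self) -> "SignatureTable":
        return replace(self, frame=self.frame.copy())


def _resolve_aliases(
    columns: list[str], aliases: Mapping[str, str] | None
) -> dict[str, str]:
    """Map file column names onto canonical ones via an alias table."""
    alias_map = {k.lower(): v for k, v in (aliases or {}).items()}
    rename: dict[str, str] = {}
    for col in columns:
        canon = alias_map.get(col.lower())
        if canon is None and col.lower() in SIGNATURE_COLUMNS:
            canon = col.lower()
        if canon is not None:
            rename[col] = canon
    return rename


def read_signature_csv(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> SignatureTable:
    """Read a signature CSV in the supplementary-table dialect.

    ``aliases`` maps file headers onto the canonical column names, e.g.
    ``{"Probe ID": "probe_id", "FC (log2)": "log2fc"}``. A leading comment
    line ``#background=N`` sets ``background_size``.
    """
    path = Path(path)
    background: int | None = None
    data_lines: list[str] = []
    line_numbers: list[int] = []  # physical line of each retained line
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                m = re.match(r"#\s*background\s*=\s*(\d+)\s*$", line.strip())
                if m:
                    background = int(m.group(1))
                continue
            if line.strip():
                data_lines.append(line)
                line_numbers.append(lineno)
    if not data_lines:
        raise FormatError(f"{path}: empty signature CSV")
    frame = pd.read_csv(io.StringIO("".join(data_lines)), dtype=str)
    frame = frame.rename(columns=_resolve_aliases(list(frame.columns), aliases))
    missing = [c for c in SIGNATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}", line=line_numbers[0]
        )
    for col in ("log2fc", "p_value"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric {col} value {frame[col].iloc[row]!r}",
                line=line_numbers[row + 1],
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise FormatError(
                f"{path}: missing {col}", line=line_numbers[row + 1]
            )
        frame[col] = converted.astype(float)
    return SignatureTable(frame=frame, background_size=background)


def write_signature_csv(table: SignatureTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if table.background_size is not None:
            fh.write(f"#background={table.background_size}\n")
        table.frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> PathwayAnnotation:
    """Read tab-separated gene sets: name, description, then members.

    Duplicate members within one set are deduplicated; a set left empty
    after deduplication is rejected.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}",
                    line=lineno,
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: gene set {name!r} is empty", line=lineno)
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r}", line=lineno)
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return PathwayAnnotation(sets=sets, descriptions=descriptions)


def write_gmt(ann: PathwayAnnotation, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for name in ann.pathway_ids:
            desc = ann.descriptions.get(name, "")
            members = "\t".join(sorted(ann.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Pajek networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PajekVertex:
    id: int  # 1-based, contiguous
    label: str
    color: str | None = None


@dataclass
class PajekNetwork:
    """An undirected weighted network in the Pajek .net text dialect."""

    vertices: list[PajekVertex] = field(default_factory=list)
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def validate(self) -> None:
        ids = [v.id for v in self.vertices]
        if ids != list(range(1, len(ids) + 1)):
            raise DataError("Pajek vertex ids must be contiguous from 1")
        valid = set(ids)
        for a, b, w in self.edges:
            if a not in valid or b not in valid:
                raise DataError(f"edge ({a}, {b}) references unknown vertex")
            if w < 0:
                raise DataError(f"edge ({a}, {b}) has negative weight {w}")


def _format_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def write_pajek(net: PajekNetwork, path: str | Path) -> None:
    net.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"*Vertices {len(net.vertices)}\n")
        for v in net.vertices:
            line = f'{v.id} "{v.label}"'
            if v.color is not None:
                line += f" ic {v.color}"
            fh.write(line + "\n")
        fh.write("*Edges\n")
        for a, b, w in net.edges:
            fh.write(f"{a} {b} {_format_weight(w)}\n")


_VERTEX_RE = re.compile(r'^(\d+)\s+"([^"]*)"(?:\s+ic\s+(\S+))?\s*$')


def read_pajek(path: str | Path) -> PajekNetwork:
    path = Path(path)
    vertices: list[PajekVertex] = []
    edges: list[tuple[int, int, float]] = []
    section = None
    n_declared = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "vertices"
                parts = line.split()
                if len(parts) != 2 or not parts[1].isdigit():
                    raise FormatError(f"{path}: malformed *Vertices header", line=lineno)
                n_declared = int(parts[1])
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                section = "edges"
                continue
            if section == "vertices":
                m = _VERTEX_RE.match(line)
                if not m:
                    raise FormatError(f"{path}: malformed vertex line", line=lineno)
                vertices.append(
                    PajekVertex(id=int(m.group(1)), label=m.group(2), color=m.group(3))
                )
            elif section == "edges":
                parts = line.split()
                if len(parts) not in (2, 3):
                    raise FormatError(f"{path}: malformed edge line", line=lineno)
                try:
                    a, b = int(parts[0]), int(parts[1])
                    w = float(parts[2]) if len(parts) == 3 else 1.0
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric edge field", line=lineno
                    ) from exc
                if not math.isfinite(w):
                    raise FormatError(f"{path}: non-finite edge weight", line=lineno)
                edges.append((a, b, w))
            else:
                raise FormatError(f"{path}: content before *Vertices", line=lineno)
    if n_declared is not None and n_declared != len(vertices):
        raise FormatError(
            f"{path}: *Vertices declares {n_declared} but {len(vertices)} listed"
        )
    net = PajekNetwork(vertices=vertices, edges=edges)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Expression matrices, group labels, probe maps, truth sidecars
# ---------------------------------------------------------------------------

def read_expression_csv(path: str | Path) -> pd.DataFrame:
    """Probes x samples intensity matrix; first column is probe_id."""
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'", line=1)
    frame = frame.set_index("probe_id")
    if frame.index.duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity: {exc}") from exc
    return frame


def write_expression_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(Path(path), index_label="probe_id")


def read_groups_tsv(path: str | Path) -> pd.Series:
    """Sample -> group label ('treated' / 'control'), tab-separated, no header."""
    path = Path(path)
    samples, labels = [], []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected sample<TAB>group", line=lineno)
            if parts[1] not in ("treated", "control"):
                raise FormatError(
                    f"{path}: group must be 'treated' or 'control', "
                    f"got {parts[1]!r}",
                    line=lineno,
                )
            samples.append(parts[0])
            labels.append(parts[1])
    return pd.Series(labels, index=samples, name="group")


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for sample, label in groups.items():
            fh.write(f"{sample}\t{label}\n")


def read_probe_map_tsv(path: str | Path) -> dict[str, str]:
    """probe_id <TAB> gene_id, no header; many probes may share one gene."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[1]:
                raise FormatError(f"{path}: expected probe<TAB>gene", line=lineno)
            if parts[0] in mapping:
                raise FormatError(f"{path}: duplicate probe {parts[0]!r}", line=lineno)
            mapping[parts[0]] = parts[1]
    return mapping


def write_probe_map_tsv(mapping: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for probe in sorted(mapping):
            fh.write(f"{probe}\t{mapping[probe]}\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

CT_COLUMNS = ("gene", "condition", "replicate", "ct_target", "ct_reference")


def read_ct_csv(path: str | Path):
    """Read a long-format Ct table into QpcrMeasurement records.

    Columns: gene, condition (treated/control), replicate, ct_target,
    ct_reference.
    """
    from .qpcr_validate import QpcrMeasurement  # local import avoids a cycle

    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}", line=1)
    for col in ("ct_target", "ct_reference"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric {col}", line=row + 2
            )
        frame[col] = converted
    bad = ~frame["condition"].isin(["treated", "control"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: condition must be treated/control", line=row + 2
        )
    measurements = []
    for gene, sub in frame.groupby("gene", sort=True):
        trt = sub[sub["condition"] == "treated"]
        ctl = sub[sub["condition"] == "control"]
        measurements.append(
            QpcrMeasurement(
                gene_id=str(gene),
                ct_target_treated=trt["ct_target"].to_numpy(float),
                ct_reference_treated=trt["ct_reference"].to_numpy(float),
                ct_target_control=ctl["ct_target"].to_numpy(float),
                ct_reference_control=ctl["ct_reference"].to_numpy(float),
            )
        )
    return measurements


def write_ct_csv(measurements, path: str | Path) -> None:
    rows = []
    for m in measurements:
        for cond, tgt, ref in (
            ("treated", m.ct_target_treated, m.ct_reference_treated),
            ("control", m.ct_target_control, m.ct_reference_control),
        ):
            for i, (t, r) in enumerate(zip(tgt, ref), start=1):
                rows.append((m.gene_id, cond, i, t, r))
    frame = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    frame.to_csv(Path(path), index=False)
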