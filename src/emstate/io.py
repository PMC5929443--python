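"""Text-format readers and writers (TSV/CSV/GMT/JSON) and coordinate helpers.

All formats are plain text: expression matrices as gene-rows TSV, single-cell
Ct tables and cytometry events as CSV, survival cohorts as TSV, signatures as
GMT, gates/truth/manifests as JSON.  Readers reject malformed input with
located errors; writer/reader pairs are round-trip identities.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bulk import ExpressionMatrix, GeneSignature
from .cytometry import GateSpec
from .errors import ParseError
from .scstate import CtTable, DEFAULT_LOD
from .survival import MARKERS, SurvivalCohort

_CT_META_COLUMNS = ("sample_kind", "ref_group")


# ---------------------------------------------------------------------------
# expression matrices (TSV, genes as rows, first column = gene id)


def read_expression_tsv(
    path: str | Path,
    annotations_path: str | Path | None = None,
    log_scale: bool = False,
    normalized: bool = False,
) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError("header needs a gene-id column plus >= 1 sample", str(path), 1)
        samples = header[1:]
        genes, rows = [], []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"ragged row: {len(fields)} fields, expected {len(header)}",
                    str(path),
                    lineno,
                )
            gene = fields[0]
            if gene in seen:
                raise ParseError(f"duplicate gene id {gene!r}", str(path), lineno)
            seen.add(gene)
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as err:
                raise ParseError(f"non-numeric value ({err})", str(path), lineno)
            genes.append(gene)
    values = pd.DataFrame(rows, index=genes, columns=samples)
    annotations = None
    if annotations_path is not None:
        annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=values, annotations=annotations, log_scale=log_scale, normalized=normalized
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# gene signatures (GMT: name <tab> description <tab> gene...)


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file into signatures.

    The direction label is taken from the leading ``E`` or ``M`` of the set
    name (e.g. ``M_HMLER_150``); names without that prefix default to ``E``
    with a warning.  Empty gene fields are skipped with a warning.
    """
    path = Path(path)
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, needs >= 3", str(path), lineno
                )
            name = fields[0]
            genes = []
            n_empty = 0
            for g in fields[2:]:
                if g:
                    genes.append(g)
                else:
                    n_empty += 1
            if n_empty:
                warnings.warn(
                    f"{path}:{lineno}: skipped {n_empty} empty gene fields",
                    stacklevel=2,
                )
            prefix = name.split("_", 1)[0]
            if prefix in ("E", "M"):
                label = prefix
                source = name.split("_", 1)[1] if "_" in name else "gmt"
            else:
                warnings.warn(
                    f"{path}:{lineno}: set name {name!r} has no E/M prefix; "
                    "defaulting label to 'E'",
                    stacklevel=2,
                )
                label, source = "E", name
            # strip a trailing _<k> size suffix from the source tag
            parts = source.rsplit("_", 1)
            if len(parts) == 2 and parts[1].isdigit():
                source = parts[0]
            signatures.append(GeneSignature(label=label, genes=tuple(genes), source=source))
    return signatures


def write_gmt(
    signatures: list[GeneSignature], path: str | Path, description: str = "emstate"
) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# single-cell Ct tables (CSV: cell_id, sample_kind, ref_group, genes...)


def read_ct_csv(path: str | Path, lod: float = DEFAULT_LOD) -> CtTable:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in _CT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"Ct table missing columns: {missing}", str(path))
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ParseError(f"duplicate cell ids: {list(dupes[:5])}", str(path))
    kinds = df["sample_kind"].unique()
    if len(kinds) != 1:
        raise ParseError(f"mixed sample kinds in one table: {list(kinds)}", str(path))
    ref_groups = None
    if kinds[0] == "ref_100cell":
        ref_groups = df["ref_group"].astype(str)
        ref_groups.name = "ref_group"
    values = df.drop(columns=list(_CT_META_COLUMNS)).astype(float)
    return CtTable(
        values=values, lod=lod, sample_kind=str(kinds[0]), ref_groups=ref_groups
    )


def write_ct_csv(table: CtTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "sample_kind", table.sample_kind)
    ref = table.ref_groups if table.ref_groups is not None else ""
    out.insert(1, "ref_group", ref)
    out.index.name = "cell_id"
    out.to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# cytometry events (CSV: sample_id, CD24, CD44, YFP)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "CD24", "CD44") if c not in df.columns]
    if missing:
        raise ParseError(f"event table missing columns: {missing}", str(path))
    return df


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# survival cohorts (TSV: patient_id, time, event, ESR, HER2, MKI67, genes...)


def read_cohort_tsv(path: str | Path, endpoint: str = "OS") -> SurvivalCohort:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    fixed = ("patient_id", "time", "event") + MARKERS
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ParseError(f"cohort missing columns: {missing}", str(path))
    gene_columns = tuple(c for c in df.columns if c not in fixed)
    return SurvivalCohort(data=df, gene_columns=gene_columns, endpoint=endpoint)


def write_cohort_tsv(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# gates and generic JSON sidecars


def write_gates_json(gates: GateSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(gates), fh, indent=2)
        fh.write("\n")


def read_gates_json(path: str | Path) -> GateSpec:
    with open(path) as fh:
        payload = json.load(fh)
    return GateSpec(**payload)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): _jsonable(obj[c]) for c in obj.columns}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a truth sidecar (dataclass or dict) to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# promoter-coordinate arithmetic


@dataclass(frozen=True)
class UpstreamInterval:
    """1-based inclusive interval upstream of the initiator ATG.

    Positions count distance from the ATG (larger = farther upstream); signed
    inputs such as -1178 are accepted and interpreted as distances.
    ``start`` is the far (upstream) end, ``end`` the near end.
    """

    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "start", abs(int(self.start)))
        object.__setattr__(self, "end", abs(int(self.end)))
        if self.end < 1:
            raise ValueError("end must be >= 1 (positions are 1-based)")
        if self.end > self.start:
            raise ValueError(
                f"end ({self.end}) farther upstream than start ({self.start})"
            )


def upstream_interval_length(interval: UpstreamInterval) -> int:
    """Inclusive length in bp, e.g. (-1178, -57) -> 1122."""
    return interval.start - interval.end + 1
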