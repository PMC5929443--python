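"""Single-cell qPCR E/M state space: Ct transformation, 100-cell reference
normalization, per-cell E/M scoring and hybrid classification.

The assay measures a small panel of epithelial (E) and mesenchymal (M) marker
genes per sorted single cell on a microfluidic qPCR platform.  Ct values below
the limit of detection (LOD) are linearized as 2**(LOD - Ct); undetected genes
(sentinel Ct 999) become 0.  Each gene is then scaled to the per-cell
equivalent of the maximum value seen in simultaneously run 100-cell reference
samples of the matching cell type (E genes against E references, M genes
against M references).  A cell's E and M scores are the panel means of these
normalized values, and a cell co-expressing both panels above threshold is a
hybrid E/M cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PanelMismatchError, ReferenceSampleError

#: Default marker panels (9 epithelial, 11 mesenchymal genes).
DEFAULT_E_GENES = (
    "CDH1", "EPCAM", "KRT5", "LCN2", "S100A8", "S100P", "SLPI", "TP63", "TNFSF10",
)
DEFAULT_M_GENES = (
    "ABCA6", "AR", "CDH2", "DCN", "FN1", "PCOLCE", "SNAI1", "VIM", "WNT5A",
    "ZEB1", "ZEB2",
)

#: Sentinel Ct value for undetected genes (>= any plausible LOD).
UNDETECTED_CT = 999.0

#: Default limit of detection in cycles (platform convention; configurable).
DEFAULT_LOD = 24.0

CLASSES = ("E", "M", "hybrid", "not_evaluable")


@dataclass(frozen=True)
class ScPanel:
    """Disjoint ordered E and M marker gene panels."""

    e_genes: tuple[str, ...] = DEFAULT_E_GENES
    m_genes: tuple[str, ...] = DEFAULT_M_GENES

    def __post_init__(self):
        if not self.e_genes or not self.m_genes:
            raise ValueError("panels must be non-empty")
        if set(self.e_genes) & set(self.m_genes):
            raise ValueError("E and M panels must be disjoint")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.e_genes + self.m_genes

    def panel_of(self, gene: str) -> str:
        if gene in self.e_genes:
            return "E"
        if gene in self.m_genes:
            return "M"
        raise KeyError(gene)


@dataclass
class CtTable:
    """Cells x genes Ct matrix with LOD and sample-kind metadata.

    ``ref_groups`` labels each row of a reference table as an E-reference or
    M-reference 100-cell aggregate; it is None for single-cell tables.
    """

    values: pd.DataFrame
    lod: float = DEFAULT_LOD
    sample_kind: str = "single_cell"  # or "ref_100cell"
    ref_groups: pd.Series | None = None

    def __post_init__(self):
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        if (self.values.values < 0).any():
            raise ValueError("negative Ct values")
        if self.sample_kind not in ("single_cell", "ref_100cell"):
            raise ValueError(f"unknown sample_kind {self.sample_kind!r}")
        if self.ref_groups is not None:
            self.ref_groups = self.ref_groups.reindex(self.values.index)


@dataclass(frozen=True)
class CellStateCall:
    """Per-cell E/M classification with scores and detection counts."""

    cell_id: str
    e_score: float
    m_score: float
    state: str  # one of CLASSES
    n_e_detected: int
    n_m_detected: int


@dataclass
class StateSpaceSummary:
    """Population summary: class counts, fractions over evaluable cells,
    integer report percentages, and per-cell state-space coordinates."""

    counts: dict[str, int]
    n_total: int
    n_evaluable: int
    fractions: dict[str, float] | None  # over evaluable cells; None if none
    percentages: dict[str, int] | None  # rounded half-away-from-zero
    coordinates: pd.DataFrame = field(repr=False, default=None)  # type: ignore


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def ct_to_linear(table: CtTable) -> pd.DataFrame:
    """Linearize Ct values: detected (Ct < LOD) -> 2**(LOD - Ct), else 0."""
    ct = table.values.astype(float)
    detected = ct.values < table.lod
    linear = np.where(detected, np.exp2(table.lod - ct.values), 0.0)
    return pd.DataFrame(linear, index=ct.index, columns=ct.columns)


def reference_normalize(
    linear: pd.DataFrame,
    ref_linear: pd.DataFrame,
    ref_groups: pd.Series,
    panel: ScPanel,
    cells_per_reference: int = 100,
) -> pd.DataFrame:
    """Scale each panel gene to the per-cell equivalent of its reference max.

    For gene g the scale factor is max over designated reference samples of
    the linearized reference value, divided by ``cells_per_reference``; E-panel
    genes use E references, M-panel genes use M references.  A cell expressing
    g at one reference-cell equivalent scores 1.  Genes absent from the table
    or with zero reference maximum are dropped with a warning.
    """
    out: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for gene in panel.genes:
        if gene not in linear.columns:
            dropped.append(gene)
            continue
        group = panel.panel_of(gene)
        designated = ref_groups[ref_groups == group].index
        if len(designated) == 0:
            raise ReferenceSampleError(f"no {group}-reference samples provided")
        if gene not in ref_linear.columns:
            dropped.append(gene)
            continue
        ref_max = float(ref_linear.loc[designated, gene].max())
        if ref_max <= 0:
            dropped.append(gene)
            continue
        out[gene] = linear[gene].values / (ref_max / cells_per_reference)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} panel genes without usable reference: "
            f"{dropped}",
            stacklevel=2,
        )
    if not out:
        raise PanelMismatchError("no panel gene could be normalized")
    return pd.DataFrame(out, index=linear.index)


def cell_scores(normalized: pd.DataFrame, panel: ScPanel) -> pd.DataFrame:
    """Per-cell E and M scores: panel means of normalized expression.

    Returns a DataFrame indexed by cell id with columns ``e_score``,
    ``m_score``, ``n_e_detected``, ``n_m_detected`` (detected = value > 0).
    Panel genes missing from the table are excluded with a warning; a panel
    with zero genes present raises PanelMismatchError.
    """
    e_present = [g for g in panel.e_genes if g in normalized.columns]
    m_present = [g for g in panel.m_genes if g in normalized.columns]
    missing = [g for g in panel.genes if g not in normalized.columns]
    if missing:
        warnings.warn(f"panel genes missing from table: {missing}", stacklevel=2)
    if not e_present or not m_present:
        raise PanelMismatchError(
            f"panel genes present: E={len(e_present)}, M={len(m_present)}; "
            "need >= 1 in each panel"
        )
    return pd.DataFrame(
        {
            "e_score": normalized[e_present].mean(axis=1),
            "m_score": normalized[m_present].mean(axis=1),
            "n_e_detected": (normalized[e_present] > 0).sum(axis=1),
            "n_m_detected": (normalized[m_present] > 0).sum(axis=1),
        }
    )


def classify_cells(
    scores: pd.DataFrame,
    tau_e: float = 0.0,
    tau_m: float = 0.0,
    min_genes_detected: int = 1,
) -> list[CellStateCall]:
    """Classify cells as E, M, hybrid E/M or not evaluable.

    A cell above both thresholds is a hybrid; above only one is pure E or M;
    above neither (or with fewer than ``min_genes_detected`` detected panel
    genes in total) it is not evaluable.  Defaults tau=0 implement
    any-detection ("exclusively expressing") semantics.
    """
    if tau_e < 0 or tau_m < 0:
        raise ValueError("thresholds must be >= 0")
    calls = []
    for cell_id, row in scores.iterrows():
        e_on = row["e_score"] > tau_e
        m_on = row["m_score"] > tau_m
        n_det = int(row.get("n_e_detected", 0) + row.get("n_m_detected", 0))
        if n_det < min_genes_detected:
            state = "not_evaluable"
        elif e_on and m_on:
            state = "hybrid"
        elif e_on:
            state = "E"
        elif m_on:
            state = "M"
        else:
            state = "not_evaluable"
        calls.append(
            CellStateCall(
                cell_id=str(cell_id),
                e_score=float(row["e_score"]),
                m_score=float(row["m_score"]),
                state=state,
                n_e_detected=int(row.get("n_e_detected", 0)),
                n_m_detected=int(row.get("n_m_detected", 0)),
            )
        )
    return calls


def population_summary(calls: list[CellStateCall]) -> StateSpaceSummary:
    """Counts and evaluable-cell fractions per class.

    Fractions (and integer report percentages, rounded half away from zero)
    are computed over evaluable cells only; with zero evaluable cells they are
    flagged None.
    """
    if not calls:
        raise ValueError("population_summary requires >= 1 call")
    counts = {c: 0 for c in CLASSES}
    for call in calls:
        counts[call.state] += 1
    n_total = len(calls)
    n_eval = n_total - counts["not_evaluable"]
    if n_eval > 0:
        fractions = {c: counts[c] / n_eval for c in ("E", "M", "hybrid")}
        percentages = {c: _round_half_away(100.0 * f) for c, f in fractions.items()}
    else:
        fractions = None
        percentages = None
    coords = pd.DataFrame(
        {
            "e_score": [c.e_score for c in calls],
            "m_score": [c.m_score for c in calls],
            "state": [c.state for c in calls],
        },
        index=[c.cell_id for c in calls],
    )
    return StateSpaceSummary(
        counts=counts,
        n_total=n_total,
        n_evaluable=n_eval,
        fractions=fractions,
        percentages=percentages,
        coordinates=coords,
    )
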