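"""Bulk expression normalization, E/M signature derivation, metagenes and the
covariance-PCA cell-state space.

Samples here are bulk microarray profiles of clonal epithelial (E) or
mesenchymal (M) breast cell lines grown in adhesion, in suspension as
mammospheres, or replated after suspension.  E/M signatures are the top-k
most differentially expressed genes between clonal E and M lines; the state
space is a PCA (covariance matrix) of the signature-restricted expression
submatrix, with PC1 oriented along the E-to-M axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import NumericalDegeneracyError, SignatureMismatchError

CONDITIONS = ("adh", "MS", "re6", "re24", "re96", "re240", "other")
GROUPS = ("E", "M", "mixed", "unknown")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample annotations.

    ``values`` rows are gene ids, columns are sample ids.  ``annotations`` is
    indexed by sample id with columns ``cell_line``, ``condition`` and
    ``group``; missing annotations default to ``other``/``unknown``.
    ``log_scale`` marks values already on log2 scale; ``normalized`` is set
    only by :func:`normalize_arrays`.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    log_scale: bool = False
    normalized: bool = False

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                {"cell_line": "NA", "condition": "other", "group": "unknown"},
                index=self.values.columns,
            )
        if not self.annotations.index.equals(self.values.columns):
            missing = set(self.values.columns) - set(self.annotations.index)
            if missing:
                raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
            self.annotations = self.annotations.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneSignature:
    """Ordered gene list with a direction label (E or M) and a source tag."""

    label: str
    genes: tuple[str, ...]
    source: str = "derived"

    def __post_init__(self):
        if self.label not in ("E", "M"):
            raise ValueError(f"signature label must be 'E' or 'M', got {self.label!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature contains duplicate genes")
        if not self.genes:
            raise ValueError("signature is empty")

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def name(self) -> str:
        return f"{self.label}_{self.source}_{self.k}"


@dataclass
class MetageneScores:
    """Per-sample mean expression over a signature, plus missing-gene report."""

    scores: pd.Series
    n_missing: int
    missing_genes: tuple[str, ...]


@dataclass
class PCAModel:
    """Signature-space covariance PCA: loadings, centers, sample scores."""

    loadings: pd.DataFrame  # genes x components
    centers: pd.Series  # per-gene means used for centering
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    oriented: bool  # True once PC1 sign is fixed to the M direction

    def reconstruct(self) -> pd.DataFrame:
        """Centered submatrix approximation from the retained components
        (genes x samples)."""
        approx = self.scores.values @ self.loadings.values.T
        return pd.DataFrame(
            approx.T, index=self.loadings.index, columns=self.scores.index
        )


def normalize_arrays(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Two-step array normalization: central tendency, then relative.

    Central tendency: log2-transform (if not already log scale) and shift each
    sample so its median equals the global median of the log matrix.  Relative:
    subtract each gene's mean across samples.  The result is flagged
    ``normalized``.
    """
    if raw.normalized:
        raise ValueError("matrix is already normalized")
    vals = raw.values.astype(float)
    if not raw.log_scale:
        if (vals.values <= 0).any():
            n_bad = int((vals.values <= 0).sum())
            raise ValueError(
                f"{n_bad} non-positive intensities in linear-scale matrix; "
                "cannot log2-transform"
            )
        vals = np.log2(vals)
    global_median = float(np.median(vals.values))
    vals = vals + (global_median - vals.median(axis=0))
    vals = vals.sub(vals.mean(axis=1), axis=0)
    return ExpressionMatrix(
        values=vals,
        annotations=raw.annotations.copy(),
        log_scale=True,
        normalized=True,
    )


def rank_differential(
    norm: ExpressionMatrix,
    group_e: list[str],
    group_m: list[str],
) -> pd.DataFrame:
    """Per-gene Welch t statistic (E minus M), ranked descending.

    Returns a DataFrame indexed by gene with columns ``statistic``,
    ``mean_diff`` and ``rank`` (1 = most E-specific).  Ties in the statistic
    are broken by |mean difference| (larger first), then by gene id.
    Genes constant in both groups get statistic 0.
    """
    group_e, group_m = list(group_e), list(group_m)
    overlap = set(group_e) & set(group_m)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    unknown = (set(group_e) | set(group_m)) - set(norm.values.columns)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)}")
    if len(group_e) < 2 or len(group_m) < 2:
        raise ValueError("need >= 2 samples per group for Welch t")
    if not norm.normalized:
        raise ValueError("rank_differential requires a normalized matrix")

    e = norm.values[group_e].values
    m = norm.values[group_m].values
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(e, m, axis=1, equal_var=False)
    statistic = np.asarray(res.statistic, dtype=float)
    statistic[~np.isfinite(statistic)] = 0.0
    mean_diff = e.mean(axis=1) - m.mean(axis=1)

    table = pd.DataFrame(
        {"statistic": statistic, "mean_diff": mean_diff}, index=norm.values.index
    )
    table["_absdiff"] = np.abs(mean_diff)
    table = table.sort_values(
        by=["statistic", "_absdiff"],
        ascending=[False, False],
        kind="mergesort",
    )
    # within remaining ties, mergesort keeps gene-id order if we pre-sort by id
    table = (
        table.reset_index()
        .sort_values(by=["statistic", "_absdiff", "index"], ascending=[False, False, True])
        .set_index("index")
        .rename_axis(norm.values.index.name or "gene")
    )
    table = table.drop(columns="_absdiff")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def derive_signatures(
    ranked: pd.DataFrame, k: int, source: str = "derived"
) -> tuple[GeneSignature, GeneSignature]:
    """Top-k genes by statistic as the E signature, bottom-k as the M signature.

    The M signature is ordered most-M-specific first.  Requires 2k <= number
    of ranked genes so the two signatures are disjoint.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > len(ranked):
        raise ValueError(f"2k = {2 * k} exceeds number of ranked genes ({len(ranked)})")
    sig_e = GeneSignature("E", tuple(ranked.index[:k]), source=source)
    sig_m = GeneSignature("M", tuple(ranked.index[::-1][:k]), source=source)
    return sig_e, sig_m


def metagene_score(norm: ExpressionMatrix, sig: GeneSignature) -> MetageneScores:
    """Per-sample mean expression over the available signature genes."""
    present = [g for g in sig.genes if g in norm.values.index]
    missing = tuple(g for g in sig.genes if g not in norm.values.index)
    if not present:
        raise SignatureMismatchError(
            f"no gene of signature {sig.name} present in the matrix"
        )
    scores = norm.values.loc[present].mean(axis=0)
    scores.name = sig.name
    return MetageneScores(scores=scores, n_missing=len(missing), missing_genes=missing)


def state_space_pca(
    norm: ExpressionMatrix,
    sig_e: GeneSignature,
    sig_m: GeneSignature,
    n_components: int | None = 2,
) -> PCAModel:
    """PCA of the signature-restricted, gene-centered submatrix.

    Uses the covariance matrix of the sig_E union sig_M submatrix (genes as
    variables, samples as observations).  Zero-variance genes are dropped with
    a warning.  PC1's sign is fixed so the M metagene correlates positively
    with PC1 scores: epithelial samples sit at negative PC1, mesenchymal at
    positive PC1.
    """
    union: list[str] = []
    for g in tuple(sig_e.genes) + tuple(sig_m.genes):
        if g not in union:
            union.append(g)
    present = [g for g in union if g in norm.values.index]
    if len(present) < 2:
        raise SignatureMismatchError("fewer than 2 signature genes present in matrix")
    if norm.values.shape[1] < 3:
        raise ValueError("state_space_pca requires >= 3 samples")

    sub = norm.values.loc[present]
    variances = sub.var(axis=1, ddof=1)
    keep = variances > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance genes before PCA",
            stacklevel=2,
        )
    sub = sub.loc[keep]
    if sub.shape[0] < 2:
        raise NumericalDegeneracyError(
            "signature submatrix is (near) constant; PCA undefined"
        )

    X = sub.T.values  # samples x genes
    centers = pd.Series(X.mean(axis=0), index=sub.index, name="center")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_rank
    n_components = min(n_components, max_rank)
    if n_components < 1:
        raise NumericalDegeneracyError("not enough samples/genes for any component")

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components

    # orient PC1 toward the M direction using the M metagene on this submatrix
    m_present = [g for g in sig_m.genes if g in sub.index]
    if m_present:
        m_meta = sub.loc[m_present].mean(axis=0).values
        cov = float(np.cov(scores[:, 0], m_meta)[0, 1])
        if cov < 0:
            scores[:, 0] *= -1.0
            loadings[:, 0] *= -1.0

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=sub.index, columns=comp_names),
        centers=centers,
        scores=pd.DataFrame(scores, index=sub.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        oriented=True,
    )
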