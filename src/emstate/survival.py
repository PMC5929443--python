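"""Metagene survival analysis: intrinsic-subtype calls, Kaplan-Meier
estimation, logrank tests, two-group Cox hazard ratios and best-cutoff
dichotomization.

Tumors are first assigned to the four St. Gallen intrinsic subtypes from
bimodal marker expression: luminal A (ESR+, HER2-, MKI67 low), luminal B
(ESR+, HER2-, MKI67 high, or ESR+, HER2+), basal (ESR-, HER2-) and HER2+
(ESR-, HER2+).  A signature metagene (mean expression over the signature
genes) is dichotomized at the cutoff minimizing the logrank p over candidate
cutoffs in an interquantile window ("autoselect best cutoff"), and the
high-versus-low hazard ratio comes from a univariate Cox model on the group
indicator (Breslow tie handling).  The reported p is nominal: scanning
cutoffs makes it optimistic, and results carry a flag saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.mixture import GaussianMixture

from .bulk import GeneSignature
from .errors import (
    ParseError,
    ScanDomainError,
    StratumEmptyError,
    UndefinedStatisticError,
)

SUBTYPES = ("luminal_A", "luminal_B", "basal", "HER2pos")
MARKERS = ("ESR", "HER2", "MKI67")
ENDPOINTS = ("OS", "RFS")


@dataclass
class SurvivalCohort:
    """Patient table: id, follow-up time (months), event flag, marker and
    gene expression columns (log2 scale for genes, linear for markers)."""

    data: pd.DataFrame
    gene_columns: tuple[str, ...]
    endpoint: str = "OS"

    def __post_init__(self):
        required = ("patient_id", "time", "event") + MARKERS
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ParseError(f"cohort missing columns: {missing}")
        if (self.data["time"].values < 0).any():
            raise ValueError("negative follow-up times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        absent = [g for g in self.gene_columns if g not in self.data.columns]
        if absent:
            raise ParseError(f"gene columns absent from cohort: {absent[:5]}")

    @property
    def n_patients(self) -> int:
        return len(self.data)


@dataclass
class CoxResult:
    """Univariate two-group Cox fit (high vs low)."""

    hr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    estimable: bool
    n_iter: int = 0


@dataclass
class KMResult:
    """Best-cutoff dichotomization result for one signature/endpoint."""

    label: str
    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    cutoff: float
    n_high: int
    n_low: int
    estimable: bool = True
    #: nominal p is optimistic because the cutoff was selected to minimize it
    selection_optimism: bool = True
    #: permutation-adjusted p for the selected cutoff (None unless requested)
    p_adjusted: float | None = None


def call_subtypes(cohort: SurvivalCohort, random_state: int = 0) -> pd.DataFrame:
    """St. Gallen intrinsic-subtype calls from bimodal marker expression.

    ESR and HER2 are called +/- by a two-component Gaussian mixture on log2
    marker expression (posterior >= 0.5 for the higher-mean component =
    positive), falling back to a median split with a warning if the mixture
    degenerates.  MKI67 high/low is a median split within ESR+/HER2-
    patients.  Returns a DataFrame indexed like the cohort with boolean
    marker calls and the subtype.
    """
    if cohort.n_patients < 20:
        raise ValueError("subtype mixture calling requires >= 20 patients")
    df = cohort.data
    calls = {}
    for marker in ("ESR", "HER2"):
        x = df[marker].values.astype(float)
        if (x <= 0).any():
            raise ValueError(f"non-positive {marker} intensities; expected linear scale")
        calls[marker] = _bimodal_positive(np.log2(x), random_state, marker)
    esr_pos, her2_pos = calls["ESR"], calls["HER2"]

    lum_mask = esr_pos & ~her2_pos
    if lum_mask.sum() >= 2:
        mki_threshold = float(np.median(df.loc[lum_mask, "MKI67"].values))
    else:
        mki_threshold = float(np.median(df["MKI67"].values))
    mki_high = df["MKI67"].values > mki_threshold

    subtype = np.empty(len(df), dtype=object)
    subtype[esr_pos & ~her2_pos & ~mki_high] = "luminal_A"
    subtype[esr_pos & ~her2_pos & mki_high] = "luminal_B"
    subtype[esr_pos & her2_pos] = "luminal_B"
    subtype[~esr_pos & ~her2_pos] = "basal"
    subtype[~esr_pos & her2_pos] = "HER2pos"
    return pd.DataFrame(
        {
            "esr_pos": esr_pos,
            "her2_pos": her2_pos,
            "mki67_high": mki_high,
            "subtype": subtype,
        },
        index=df.index,
    )


def _bimodal_positive(
    log_x: np.ndarray, random_state: int, name: str
) -> np.ndarray:
    """Positive-component membership of a two-component Gaussian mixture."""
    gm = GaussianMixture(
        n_components=2, n_init=3, random_state=random_state
    ).fit(log_x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    sep = abs(means[1] - means[0]) / max(sds.mean(), 1e-12)
    if not gm.converged_ or sep < 1.0:
        warnings.warn(
            f"{name}: mixture degenerate (separation {sep:.2f} SD); "
            "falling back to median split",
            stacklevel=3,
        )
        return log_x > np.median(log_x)
    high = int(np.argmax(means))
    post = gm.predict_proba(log_x.reshape(-1, 1))[:, high]
    return post >= 0.5


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a step function as a DataFrame with columns ``time`` and
    ``survival`` (starting at time 0, survival 1; right-censoring handled).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("km_estimate requires >= 1 subject")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.values.astype(float), "survival": sf.iloc[:, 0].values}
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group logrank chi-square test (1 df), ties aggregated per time.

    Returns (statistic, p).  Identical groups give statistic 0, p = 1.  A
    zero-variance configuration (e.g. everything censored) raises
    UndefinedStatisticError.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    stat = _logrank_stat(ta, ea, tb, eb)
    return stat, float(stats.chi2.sf(stat, df=1))


def _logrank_stat(
    ta: np.ndarray, ea: np.ndarray, tb: np.ndarray, eb: np.ndarray
) -> float:
    """Vectorized logrank chi-square statistic."""
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if len(event_times) == 0:
        raise UndefinedStatisticError("no events in either group")
    # risk sets and event counts at each distinct event time (O(n log n))
    ta_sorted, tb_sorted = np.sort(ta), np.sort(tb)
    na = (len(ta) - np.searchsorted(ta_sorted, event_times, side="left")).astype(float)
    nb = (len(tb) - np.searchsorted(tb_sorted, event_times, side="left")).astype(float)
    k = len(event_times)
    da = np.bincount(np.searchsorted(event_times, ta[ea == 1]), minlength=k)
    db = np.bincount(np.searchsorted(event_times, tb[eb == 1]), minlength=k)
    n = na + nb
    d = (da + db).astype(float)
    expected_a = d * na / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d * (na / n) * (nb / n) * (n - d) / (n - 1)
    var = np.where(n > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        raise UndefinedStatisticError("zero logrank variance")
    observed_a = float(da.sum())
    return float((observed_a - expected_a.sum()) ** 2 / v)


def cox_two_group(
    times_high: Sequence[float],
    events_high: Sequence[int],
    times_low: Sequence[float],
    events_low: Sequence[int],
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> CoxResult:
    """Univariate Cox PH fit on a binary high/low indicator, Breslow ties.

    Newton-Raphson on the Breslow partial likelihood to gradient tolerance
    ``tol``; HR = exp(beta), CI = exp(beta +/- z * SE).  With no events in one
    group the likelihood is monotone: the result is flagged non-estimable
    with infinite bounds.
    """
    th = np.asarray(times_high, dtype=float)
    tl = np.asarray(times_low, dtype=float)
    eh = np.asarray(events_high, dtype=int)
    el = np.asarray(events_low, dtype=int)
    if eh.sum() + el.sum() == 0:
        raise ValueError("cox_two_group requires >= 1 event")
    if eh.sum() == 0 or el.sum() == 0:
        no_high_events = eh.sum() == 0
        return CoxResult(
            hr=0.0 if no_high_events else np.inf,
            ci_low=0.0,
            ci_high=np.inf,
            beta=-np.inf if no_high_events else np.inf,
            se=np.inf,
            estimable=False,
        )

    t = np.concatenate([th, tl])
    e = np.concatenate([eh, el])
    x = np.concatenate([np.ones(len(th)), np.zeros(len(tl))])
    event_times = np.unique(t[e == 1])
    # per distinct event time: events d_j, events-in-high s_j, risk counts
    d = np.array([(e[t == u] == 1).sum() for u in event_times], dtype=float)
    s = np.array(
        [((t == u) & (e == 1) & (x == 1)).sum() for u in event_times], dtype=float
    )
    r1 = (t[None, :] >= event_times[:, None])[:, x == 1].sum(axis=1).astype(float)
    r0 = (t[None, :] >= event_times[:, None])[:, x == 0].sum(axis=1).astype(float)

    beta = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eb = np.exp(beta)
        mu = r1 * eb / (r0 + r1 * eb)
        score = float((s - d * mu).sum())
        info = float((d * mu * (1 - mu)).sum())
        if info <= 0:
            return CoxResult(
                hr=np.exp(beta), ci_low=0.0, ci_high=np.inf,
                beta=beta, se=np.inf, estimable=False, n_iter=n_iter,
            )
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(score) < tol:
            break
    eb = np.exp(beta)
    mu = r1 * eb / (r0 + r1 * eb)
    info = float((d * mu * (1 - mu)).sum())
    se = 1.0 / np.sqrt(info)
    z = stats.norm.ppf(1 - alpha / 2)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        beta=float(beta),
        se=float(se),
        estimable=True,
        n_iter=n_iter,
    )


def best_cutoff_scan(
    scores: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    q_low: float = 0.25,
    q_high: float = 0.75,
    min_group_frac: float = 0.1,
    endpoint: str = "OS",
    label: str = "metagene",
    adjust_p_permutations: int = 0,
    random_state: int = 0,
) -> KMResult:
    """Autoselect-best-cutoff dichotomization of a metagene score.

    Candidate cutoffs are the unique score values within the
    [q_low, q_high] quantile window that leave both groups at least
    ``min_group_frac`` of the cohort (split: score > cutoff = high).  The
    cutoff minimizing the logrank p is selected (ties resolved toward the
    median score); HR and CI come from :func:`cox_two_group` at that cutoff.
    The reported p is nominal and flagged for selection optimism; with
    ``adjust_p_permutations`` > 0 a selection-corrected p is also computed
    by rerunning the scan on score-vs-outcome permutations (add-one
    estimator, so the adjusted p is never exactly 0).
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(scores)
    if not (len(times) == len(events) == n):
        raise ValueError("scores, times, events must have equal length")
    best = _scan_min_p(scores, times, events, q_low, q_high, min_group_frac)
    p, _, cutoff = best
    p_adjusted = None
    if adjust_p_permutations > 0:
        rng = np.random.default_rng(random_state)
        n_le = 0
        for _ in range(adjust_p_permutations):
            perm = rng.permutation(n)
            try:
                perm_best = _scan_min_p(
                    scores, times[perm], events[perm], q_low, q_high, min_group_frac
                )
            except ScanDomainError:
                continue
            n_le += perm_best[0] <= p
        p_adjusted = (1 + n_le) / (1 + adjust_p_permutations)
    high = scores > cutoff
    cox = cox_two_group(times[high], events[high], times[~high], events[~high])
    return KMResult(
        label=label,
        endpoint=endpoint,
        hr=cox.hr,
        ci_low=cox.ci_low,
        ci_high=cox.ci_high,
        p=float(p),
        cutoff=float(cutoff),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        estimable=cox.estimable,
        selection_optimism=True,
        p_adjusted=p_adjusted,
    )


def _scan_min_p(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    q_low: float,
    q_high: float,
    min_group_frac: float,
) -> tuple[float, float, float]:
    """Minimum logrank p over admissible cutoffs: (p, |c - median|, c)."""
    n = len(scores)
    lo, hi = np.quantile(scores, [q_low, q_high])
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    candidates = [
        c
        for c in np.unique(scores)
        if lo <= c <= hi
        and (scores > c).sum() >= min_n
        and (scores <= c).sum() >= min_n
    ]
    if not candidates:
        raise ScanDomainError(
            "no admissible cutoff: scores may be (near-)constant or the "
            "group-size constraint too strict"
        )
    median = float(np.median(scores))
    best: tuple[float, float, float] | None = None
    for c in candidates:
        high = scores > c
        try:
            _, p = logrank_test(times[high], events[high], times[~high], events[~high])
        except UndefinedStatisticError:
            continue
        key = (p, abs(c - median), float(c))
        if best is None or key < best:
            best = key
    if best is None:
        raise ScanDomainError("logrank undefined at every candidate cutoff")
    return best


def metagene(
    cohort: SurvivalCohort,
    signature: GeneSignature | Iterable[GeneSignature],
) -> pd.Series:
    """Per-patient mean expression over the signature genes present.

    A composite (e.g. E plus M) signature is the mean over the union of the
    gene lists.
    """
    if isinstance(signature, GeneSignature):
        genes, name = list(signature.genes), signature.name
    else:
        sigs = list(signature)
        seen: list[str] = []
        for s in sigs:
            for g in s.genes:
                if g not in seen:
                    seen.append(g)
        genes = seen
        name = "+".join(s.name for s in sigs)
    present = [g for g in genes if g in cohort.data.columns]
    if not present:
        raise ParseError(f"no gene of signature {name} present in cohort")
    out = cohort.data[present].mean(axis=1)
    out.name = name
    return out


def signature_survival(
    cohort: SurvivalCohort,
    signatures: Sequence[GeneSignature | tuple[GeneSignature, ...]],
    endpoint: str = "OS",
    subtype_filter: str = "all",
    q_low: float = 0.25,
    q_high: float = 0.75,
    min_group_frac: float = 0.1,
    random_state: int = 0,
) -> pd.DataFrame:
    """Best-cutoff survival association for each signature, optionally within
    one intrinsic subtype.  Returns a forest-plot-ready table (one row per
    signature: label, endpoint, subtype, HR, CI, p, cutoff, group sizes)."""
    if subtype_filter not in ("all",) + SUBTYPES:
        raise ValueError(f"unknown subtype filter {subtype_filter!r}")
    df = cohort.data
    if subtype_filter != "all":
        calls = call_subtypes(cohort, random_state=random_state)
        mask = (calls["subtype"] == subtype_filter).values
        if mask.sum() == 0:
            available = calls["subtype"].value_counts().to_dict()
            raise StratumEmptyError(subtype_filter, available)
        df = df[mask]
        cohort = SurvivalCohort(
            data=df.reset_index(drop=True),
            gene_columns=cohort.gene_columns,
            endpoint=cohort.endpoint,
        )
    rows = []
    for sig in signatures:
        scores = metagene(cohort, sig)
        result = best_cutoff_scan(
            scores.values,
            cohort.data["time"].values,
            cohort.data["event"].values,
            q_low=q_low,
            q_high=q_high,
            min_group_frac=min_group_frac,
            endpoint=endpoint,
            label=str(scores.name),
        )
        rows.append(
            {
                "label": result.label,
                "endpoint": endpoint,
                "subtype": subtype_filter,
                "hr": result.hr,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "p": result.p,
                "cutoff": result.cutoff,
                "n_high": result.n_high,
                "n_low": result.n_low,
                "estimable": result.estimable,
            }
        )
    return pd.DataFrame(rows)
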