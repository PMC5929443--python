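"""CD24/CD44 quadrant gating, YFP stratification, fold-change and coculture
synergy statistics.

Quadrant thresholds are derived from a heterogeneous reference population
(parental HP cells) run alongside each experiment: per channel, intensities
are asinh-transformed and a two-component Gaussian mixture is fitted; the
threshold is the equal-posterior point between the components, with a
kernel-density valley fallback.  Events strictly above both thresholds are
CD24+/CD44+, etc.; a tie at a threshold counts as negative.

The synergy index compares an observed coculture read-out to the projected
additive effect: under the equal-total-seeding design (cocultures seeded 1:1
from E and M cells, compared against the same total number of monocultured
cells) the projection is the arithmetic mean of the two monoculture counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .errors import GatingDegeneracyError, ParseError

#: Default asinh cofactor for fluorescence intensities.
DEFAULT_COFACTOR = 150.0

QUADRANTS = ("CD24+/CD44-", "CD24-/CD44+", "CD24+/CD44+", "CD24-/CD44-")

REQUIRED_COLUMNS = ("CD24", "CD44")


@dataclass
class GateSpec:
    """Per-channel thresholds on the asinh(intensity / cofactor) scale."""

    cd24: float
    cd44: float
    yfp: float | None = None
    cofactor: float = DEFAULT_COFACTOR
    reference: str = "unspecified"

    def __post_init__(self):
        if not (np.isfinite(self.cd24) and np.isfinite(self.cd44)):
            raise ValueError("gate thresholds must be finite")


@dataclass
class QuadrantCounts:
    """Event counts and fractions per CD24/CD44 quadrant."""

    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {q: float("nan") for q in QUADRANTS}
        return {q: self.counts[q] / self.total for q in QUADRANTS}


@dataclass
class SynergyResult:
    """Observed coculture read-out versus the projected additive effect."""

    observed: float
    mono_e: float
    mono_m: float
    projected: float
    synergy_fold: float


def _validate_events(events: pd.DataFrame, need_yfp: bool = False) -> None:
    cols = REQUIRED_COLUMNS + (("YFP",) if need_yfp else ())
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise ParseError(f"event table missing columns: {missing}")
    for c in cols:
        if not np.isfinite(events[c].values).all():
            raise ValueError(f"non-finite intensities in channel {c}")


def transform(values: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """asinh intensity transform used throughout gating."""
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def _mixture_threshold(
    x: np.ndarray, random_state: int, min_separation: float
) -> float:
    """Equal-posterior cut between two Gaussian mixture components, with a
    KDE-valley fallback when the mixture degenerates."""
    gm = GaussianMixture(
        n_components=2, n_init=3, random_state=random_state, covariance_type="full"
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu1, mu2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]

    def log_posterior_diff(t: float) -> float:
        return (np.log(w1) + stats.norm.logpdf(t, mu1, s1)) - (
            np.log(w2) + stats.norm.logpdf(t, mu2, s2)
        )

    kde = stats.gaussian_kde(x)

    def is_valley(t: float, lo: float, hi: float) -> bool:
        # a real inter-cluster boundary sits in a density valley; a split of
        # a unimodal channel does not
        d_t, d_lo, d_hi = kde([t, lo, hi])
        return d_t < 0.9 * min(d_lo, d_hi)

    if mu2 - mu1 >= min_separation:
        try:
            if log_posterior_diff(mu1) > 0 > log_posterior_diff(mu2):
                t = float(brentq(log_posterior_diff, mu1, mu2, xtol=1e-10))
                if is_valley(t, mu1, mu2):
                    return t
        except ValueError:
            pass
    # fallback: kernel-density valley between the two largest modes
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    maxima = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    if len(maxima) >= 2:
        top2 = maxima[np.argsort(dens[maxima])[-2:]]
        lo, hi = sorted(grid[top2])
        if hi - lo >= min_separation:
            between = (grid > lo) & (grid < hi)
            valley = float(grid[between][np.argmin(dens[between])])
            if is_valley(valley, lo, hi):
                return valley
    raise GatingDegeneracyError(
        f"channel appears unimodal (mixture means {mu1:.3f}, {mu2:.3f})"
    )


def fit_quadrant_gates(
    reference: pd.DataFrame,
    cofactor: float = DEFAULT_COFACTOR,
    random_state: int = 0,
    min_separation: float = 0.3,
    reference_id: str | None = None,
) -> GateSpec:
    """Derive CD24/CD44 thresholds from a heterogeneous reference sample.

    Requires >= 100 reference events.  Deterministic for a given
    ``random_state`` (mixture initialization seed).
    """
    _validate_events(reference)
    if len(reference) < 100:
        raise ValueError(f"need >= 100 reference events, got {len(reference)}")
    thresholds = {}
    for channel in ("CD24", "CD44"):
        x = transform(reference[channel].values, cofactor)
        try:
            thresholds[channel] = _mixture_threshold(x, random_state, min_separation)
        except GatingDegeneracyError as err:
            raise GatingDegeneracyError(f"{channel}: {err}") from None
    if reference_id is None:
        ids = reference["sample_id"].unique() if "sample_id" in reference else []
        reference_id = str(ids[0]) if len(ids) else "unspecified"
    return GateSpec(
        cd24=thresholds["CD24"],
        cd44=thresholds["CD44"],
        cofactor=cofactor,
        reference=reference_id,
    )


def assign_quadrants(events: pd.DataFrame, gates: GateSpec) -> pd.Series:
    """Quadrant label per event (strictly above threshold = positive)."""
    cd24_pos = transform(events["CD24"].values, gates.cofactor) > gates.cd24
    cd44_pos = transform(events["CD44"].values, gates.cofactor) > gates.cd44
    labels = np.where(
        cd24_pos & ~cd44_pos,
        "CD24+/CD44-",
        np.where(
            ~cd24_pos & cd44_pos,
            "CD24-/CD44+",
            np.where(cd24_pos & cd44_pos, "CD24+/CD44+", "CD24-/CD44-"),
        ),
    )
    return pd.Series(labels, index=events.index, name="quadrant")


def apply_gates(events: pd.DataFrame, gates: GateSpec) -> QuadrantCounts:
    """Count events per quadrant; every event falls in exactly one quadrant."""
    _validate_events(events)
    if len(events) == 0:
        raise ValueError("empty event table")
    labels = assign_quadrants(events, gates)
    counts = {q: int((labels == q).sum()) for q in QUADRANTS}
    return QuadrantCounts(counts=counts, total=len(events))


def yfp_threshold_from_control(
    control: pd.DataFrame,
    percentile: float = 99.5,
    cofactor: float = DEFAULT_COFACTOR,
) -> float:
    """YFP positivity threshold: upper percentile of a non-transduced control."""
    _validate_events(control, need_yfp=True)
    if len(control) == 0:
        raise ValueError("empty control table")
    return float(np.percentile(transform(control["YFP"].values, cofactor), percentile))


def yfp_stratify(
    events: pd.DataFrame, gates: GateSpec
) -> dict[str, QuadrantCounts]:
    """Quadrant counts within the YFP+ and YFP- strata.

    The YFP threshold must be present in the gates (set from a control via
    :func:`yfp_threshold_from_control`).  Stratum totals sum to the total
    event count; an empty stratum yields zero counts.
    """
    _validate_events(events, need_yfp=True)
    if gates.yfp is None:
        raise ValueError("gates carry no YFP threshold; derive one from a control")
    yfp_pos = transform(events["YFP"].values, gates.cofactor) > gates.yfp
    out = {}
    for name, mask in (("YFP+", yfp_pos), ("YFP-", ~yfp_pos)):
        stratum = events[mask]
        if len(stratum) == 0:
            out[name] = QuadrantCounts(counts={q: 0 for q in QUADRANTS}, total=0)
        else:
            out[name] = apply_gates(stratum, gates)
    return out


def fold_change(count_a: float, count_b: float) -> float:
    """Ratio a/b, e.g. coculture versus monoculture cell numbers."""
    if count_b <= 0:
        raise ZeroDivisionError("fold_change denominator must be > 0")
    return count_a / count_b


def synergy_index(
    cocult_count: float,
    mono_e_count: float,
    mono_m_count: float,
    mono_e_weight: float = 0.5,
) -> SynergyResult:
    """Coculture read-out relative to the projected additive effect.

    Projection defaults to the arithmetic mean of the monoculture counts
    (equal-total-seeding design); ``mono_e_weight`` exposes alternative
    seeding ratios.
    """
    if mono_e_count + mono_m_count <= 0:
        raise ZeroDivisionError("both monoculture counts are zero")
    if not 0 <= mono_e_weight <= 1:
        raise ValueError("mono_e_weight must be in [0, 1]")
    projected = mono_e_weight * mono_e_count + (1 - mono_e_weight) * mono_m_count
    if projected <= 0:
        raise ZeroDivisionError("projected additive effect is zero")
    return SynergyResult(
        observed=float(cocult_count),
        mono_e=float(mono_e_count),
        mono_m=float(mono_m_count),
        projected=float(projected),
        synergy_fold=float(cocult_count / projected),
    )
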