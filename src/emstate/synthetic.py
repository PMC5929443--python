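"""Seeded generators for every input the pipeline consumes, with planted
ground truth for parameter-recovery tests.

Each generator takes a frozen config carrying an explicit seed and returns
(data, truth): the truth object labels every generated record (planted
differential genes, true cell class, true quadrant and YFP status, mixture
component membership, planted log hazard ratio) so that classifiers, gaters
and estimators can be tested for recovery.  No global random state is used;
the same config yields byte-identical output.

The generators emulate the study designs they stand in for: clonal E versus
M bulk profiles with an intermediate suspension state; single-cell qPCR
panels with dropout and mixed pure/hybrid populations plus 100-cell
reference aggregates; bivariate CD24/CD44 event clusters with YFP labels and
coculture synergy; and proportional-hazards survival cohorts with bimodal
subtype markers.  Distributional choices (noise SDs, cluster geometry) are
artifact conventions documented in the methods note, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .bulk import ExpressionMatrix
from .errors import ConfigurationError
from .scstate import CtTable, ScPanel, UNDETECTED_CT, DEFAULT_LOD
from .survival import SurvivalCohort

BULK_CONDITIONS = ("adh_E", "adh_M", "MS", "replate_from_E", "replate_from_M")

#: condition -> (condition label, group label) for sample annotations
_CONDITION_ANNOT = {
    "adh_E": ("adh", "E"),
    "adh_M": ("adh", "M"),
    "MS": ("MS", "mixed"),
    "replate_from_E": ("re24", "mixed"),
    "replate_from_M": ("re24", "M"),
}


# ---------------------------------------------------------------------------
# bulk arrays


@dataclass(frozen=True)
class BulkSimConfig:
    """Clonal E vs M bulk arrays with an intermediate suspension state.

    Planted E-up genes are higher in E samples, M-up genes higher in M
    samples, both by ``effect_size`` log2 units.  Mammosphere (MS) and
    replate-from-E samples mix the E and M archetype means with weight
    ``intermediate_weight`` on the E side; replate-from-M samples revert to
    the M archetype.
    """

    n_genes: int = 2000
    n_diff_e: int = 200
    n_diff_m: int = 200
    effect_size: float = 4.0
    noise_sd: float = 0.25
    n_replicates: int = 3
    conditions: tuple[str, ...] = BULK_CONDITIONS
    intermediate_weight: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_diff_e < 0 or self.n_diff_m < 0:
            raise ConfigurationError("planted gene counts must be >= 0")
        if self.n_diff_e + self.n_diff_m > self.n_genes:
            raise ConfigurationError("more planted genes than genes")
        if not 0 <= self.intermediate_weight <= 1:
            raise ConfigurationError("intermediate_weight must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.conditions) - set(BULK_CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions: {sorted(unknown)}")
        if not self.conditions:
            raise ConfigurationError("at least one condition required")


@dataclass
class BulkTruth:
    """Planted structure of a simulated bulk experiment."""

    e_up_genes: tuple[str, ...]
    m_up_genes: tuple[str, ...]
    sample_condition: dict[str, str]
    config: dict = field(repr=False, default_factory=dict)


def simulate_bulk_arrays(config: BulkSimConfig) -> tuple[ExpressionMatrix, BulkTruth]:
    """Linear-scale intensity matrix (genes x samples) plus planted truth."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    planted = rng.choice(config.n_genes, config.n_diff_e + config.n_diff_m, replace=False)
    e_up_idx = planted[: config.n_diff_e]
    m_up_idx = planted[config.n_diff_e:]

    base = rng.uniform(6.0, 12.0, config.n_genes)
    e_mean = base.copy()
    m_mean = base.copy()
    e_mean[e_up_idx] += config.effect_size
    m_mean[m_up_idx] += config.effect_size
    w = config.intermediate_weight
    ms_mean = w * e_mean + (1 - w) * m_mean
    condition_means: Mapping[str, np.ndarray] = {
        "adh_E": e_mean,
        "adh_M": m_mean,
        "MS": ms_mean,
        "replate_from_E": ms_mean,
        "replate_from_M": m_mean,
    }

    columns, data, sample_condition, annot_rows = [], [], {}, []
    for cond in config.conditions:
        for r in range(1, config.n_replicates + 1):
            sample = f"{cond}_r{r}"
            log2_vals = condition_means[cond] + rng.normal(
                0.0, config.noise_sd, config.n_genes
            )
            columns.append(sample)
            data.append(np.exp2(log2_vals))
            sample_condition[sample] = cond
            cond_label, group = _CONDITION_ANNOT[cond]
            annot_rows.append(
                {"cell_line": cond, "condition": cond_label, "group": group}
            )

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    annotations = pd.DataFrame(annot_rows, index=columns)
    matrix = ExpressionMatrix(values=values, annotations=annotations, log_scale=False)
    truth = BulkTruth(
        e_up_genes=tuple(np.array(genes)[np.sort(e_up_idx)]),
        m_up_genes=tuple(np.array(genes)[np.sort(m_up_idx)]),
        sample_condition=sample_condition,
        config=asdict(config),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# single-cell qPCR


@dataclass(frozen=True)
class ScSimConfig:
    """Single-cell Ct tables with planted pure-E / pure-M / hybrid classes.

    Expressed genes get Ct ~ Normal(mean_ct_on, ct_sd) (hybrid cells shifted
    by ``hybrid_attenuation`` cycles), clipped below the LOD; genes of the
    opposite panel are undetected (sentinel 999).  ``dropout_prob`` silences
    each expressed gene independently.  100-cell reference samples carry the
    on-state Ct shifted earlier by log2(100) ~= 6.64 cycles (PCR doubling per
    cycle) with small noise.
    """

    n_pure_e: int = 50
    n_pure_m: int = 50
    n_hybrid: int = 100
    panel: ScPanel = field(default_factory=ScPanel)
    lod: float = DEFAULT_LOD
    dropout_prob: float = 0.1
    mean_ct_on: float = 17.0
    ct_sd: float = 0.8
    hybrid_attenuation: float = 1.5
    n_ref_samples: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pure_e, self.n_pure_m, self.n_hybrid) < 0:
            raise ConfigurationError("cell counts must be >= 0")
        if self.n_pure_e + self.n_pure_m + self.n_hybrid == 0:
            raise ConfigurationError("at least one cell required")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError("dropout_prob must be in [0, 1]")
        if not self.mean_ct_on < self.lod:
            raise ConfigurationError("mean_ct_on must be below the LOD")
        if not self.panel.e_genes or not self.panel.m_genes:
            raise ConfigurationError("panel must be non-empty")
        if self.n_ref_samples < 1:
            raise ConfigurationError("need >= 1 reference sample per group")


@dataclass
class ScTruth:
    """True class per simulated cell."""

    cell_class: pd.Series  # cell id -> pure_E / pure_M / hybrid
    config: dict = field(repr=False, default_factory=dict)


def simulate_sc_ct_table(
    config: ScSimConfig,
) -> tuple[CtTable, CtTable, ScTruth]:
    """(single-cell CtTable, 100-cell reference CtTable, truth)."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    genes = list(panel.genes)
    n_e_genes, n_m_genes = len(panel.e_genes), len(panel.m_genes)

    rows, cell_ids, classes = [], [], []
    specs = (
        ("pure_E", config.n_pure_e, True, False),
        ("pure_M", config.n_pure_m, False, True),
        ("hybrid", config.n_hybrid, True, True),
    )
    for cls, n_cells, e_on, m_on in specs:
        for i in range(n_cells):
            shift = config.hybrid_attenuation if cls == "hybrid" else 0.0
            row = np.full(len(genes), UNDETECTED_CT)
            if e_on:
                ct = rng.normal(config.mean_ct_on + shift, config.ct_sd, n_e_genes)
                row[:n_e_genes] = np.clip(ct, 0.1, config.lod - 0.5)
            if m_on:
                ct = rng.normal(config.mean_ct_on + shift, config.ct_sd, n_m_genes)
                row[n_e_genes:] = np.clip(ct, 0.1, config.lod - 0.5)
            drop = rng.random(len(genes)) < config.dropout_prob
            row[drop] = UNDETECTED_CT
            rows.append(row)
            cell_ids.append(f"{cls}_{i:04d}")
            classes.append(cls)

    cells = CtTable(
        values=pd.DataFrame(rows, index=cell_ids, columns=genes),
        lod=config.lod,
        sample_kind="single_cell",
    )

    # 100-cell reference aggregates: E references express the E panel, M
    # references the M panel, ~6.64 cycles earlier than a single cell
    ref_shift = np.log2(100.0)
    ref_rows, ref_ids, ref_groups = [], [], []
    for group, on_slice in (("E", slice(0, n_e_genes)), ("M", slice(n_e_genes, None))):
        for i in range(config.n_ref_samples):
            row = np.full(len(genes), UNDETECTED_CT)
            n_on = len(row[on_slice])
            ct = rng.normal(config.mean_ct_on - ref_shift, 0.2, n_on)
            row[on_slice] = np.clip(ct, 0.1, config.lod - 0.5)
            ref_rows.append(row)
            ref_ids.append(f"ref{group}_{i:02d}")
            ref_groups.append(group)

    refs = CtTable(
        values=pd.DataFrame(ref_rows, index=ref_ids, columns=genes),
        lod=config.lod,
        sample_kind="ref_100cell",
        ref_groups=pd.Series(ref_groups, index=ref_ids, name="ref_group"),
    )
    truth = ScTruth(
        cell_class=pd.Series(classes, index=cell_ids, name="true_class"),
        config=asdict(config),
    )
    return cells, refs, truth


# ---------------------------------------------------------------------------
# flow cytometry


#: raw-intensity cluster centers per quadrant: (CD24 level, CD44 level)
_QUADRANT_LEVELS = {
    "CD24+/CD44-": ("high", "low"),
    "CD24-/CD44+": ("low", "high"),
    "CD24+/CD44+": ("high", "high"),
    "CD24-/CD44-": ("low", "low"),
}


@dataclass(frozen=True)
class ClusterSpec:
    """One planted event cluster: quadrant identity, size, YFP status."""

    quadrant: str
    n_events: int
    yfp_positive: bool = False

    def __post_init__(self):
        if self.quadrant not in _QUADRANT_LEVELS:
            raise ConfigurationError(f"unknown quadrant {self.quadrant!r}")
        if self.n_events < 0:
            raise ConfigurationError("cluster counts must be >= 0")


@dataclass(frozen=True)
class CytoSimConfig:
    """Bivariate log-normal CD24/CD44 event clusters with YFP labels.

    ``low_mean``/``high_mean`` are raw-intensity cluster medians shared by
    both channels; ``log_sd`` is the natural-log scale SD.  Both defaults sit
    well above the asinh cofactor so the transformed clusters are
    near-Gaussian; the planted per-channel threshold is the equal-posterior
    crossing of the two transformed components at the planted weights.
    """

    clusters: tuple[ClusterSpec, ...]
    low_mean: float = 600.0
    high_mean: float = 60000.0
    log_sd: float = 0.5
    yfp_neg_mean: float = 50.0
    yfp_pos_mean: float = 30000.0
    yfp_log_sd: float = 0.4
    cofactor: float = 150.0
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if not self.clusters or sum(c.n_events for c in self.clusters) == 0:
            raise ConfigurationError("all-zero event counts")
        for v in (self.low_mean, self.high_mean, self.yfp_neg_mean, self.yfp_pos_mean):
            if v <= 0:
                raise ConfigurationError("cluster means must be positive")
        if self.log_sd <= 0 or self.yfp_log_sd <= 0:
            raise ConfigurationError("log SDs must be positive")


@dataclass
class CytoTruth:
    """Per-event planted quadrant/YFP labels and summary fractions."""

    quadrant: pd.Series
    yfp_positive: pd.Series
    planted_fractions: dict[str, float]
    planted_thresholds: dict[str, float]  # asinh-scale boundary per channel
    config: dict = field(repr=False, default_factory=dict)


def simulate_event_table(config: CytoSimConfig) -> tuple[pd.DataFrame, CytoTruth]:
    """Event table (columns sample_id, CD24, CD44, YFP) plus planted truth."""
    rng = np.random.default_rng(config.seed)
    levels = {"low": np.log(config.low_mean), "high": np.log(config.high_mean)}
    cd24, cd44, yfp, quadrants, yfp_flags = [], [], [], [], []
    for cluster in config.clusters:
        lv24, lv44 = _QUADRANT_LEVELS[cluster.quadrant]
        n = cluster.n_events
        cd24.append(rng.lognormal(levels[lv24], config.log_sd, n))
        cd44.append(rng.lognormal(levels[lv44], config.log_sd, n))
        yfp_mean = config.yfp_pos_mean if cluster.yfp_positive else config.yfp_neg_mean
        yfp.append(rng.lognormal(np.log(yfp_mean), config.yfp_log_sd, n))
        quadrants.extend([cluster.quadrant] * n)
        yfp_flags.extend([cluster.yfp_positive] * n)

    events = pd.DataFrame(
        {
            "sample_id": config.sample_id,
            "CD24": np.concatenate(cd24),
            "CD44": np.concatenate(cd44),
            "YFP": np.concatenate(yfp),
        }
    )
    total = len(events)
    planted = {
        q: sum(c.n_events for c in config.clusters if c.quadrant == q) / total
        for q in _QUADRANT_LEVELS
    }
    truth = CytoTruth(
        quadrant=pd.Series(quadrants, name="quadrant"),
        yfp_positive=pd.Series(yfp_flags, name="yfp_positive"),
        planted_fractions=planted,
        planted_thresholds={
            ch: _planted_channel_threshold(config, ch) for ch in ("CD24", "CD44")
        },
        config=asdict(config),
    )
    return events, truth


def _planted_channel_threshold(config: CytoSimConfig, channel: str) -> float:
    """Equal-posterior crossing of the planted low/high components on the
    asinh scale, approximating each transformed cluster as Gaussian
    (exact in the log region of the asinh, where the defaults live)."""
    level_idx = 0 if channel == "CD24" else 1
    n_high = sum(
        c.n_events
        for c in config.clusters
        if _QUADRANT_LEVELS[c.quadrant][level_idx] == "high"
    )
    total = sum(c.n_events for c in config.clusters)
    w_high = n_high / total
    w_low = 1.0 - w_high
    t_low = float(np.arcsinh(config.low_mean / config.cofactor))
    t_high = float(np.arcsinh(config.high_mean / config.cofactor))
    if w_low == 0.0 or w_high == 0.0:
        return (t_low + t_high) / 2  # single-sided channel: no real boundary
    # equal-variance Gaussian discriminant on the transformed scale
    return float(
        (t_low + t_high) / 2
        + config.log_sd**2 * np.log(w_low / w_high) / (t_high - t_low)
    )


@dataclass(frozen=True)
class CocultureSimConfig:
    """Coculture synergy design on surviving-cell counts.

    Monocultures yield Poisson(n_mono_e) and Poisson(n_mono_m) surviving
    cells; the equal-seeding coculture yields Poisson(synergy_factor x
    projected additive count) where projected = (n_mono_e + n_mono_m) / 2.
    """

    n_mono_e: int = 200
    n_mono_m: int = 4000
    synergy_factor: float = 5.0
    e_fraction_cocult: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_mono_e < 0 or self.n_mono_m < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.n_mono_e + self.n_mono_m == 0:
            raise ConfigurationError("all-zero monoculture counts")
        if self.synergy_factor <= 0:
            raise ConfigurationError("synergy_factor must be > 0")
        if not 0 <= self.e_fraction_cocult <= 1:
            raise ConfigurationError("e_fraction_cocult must be in [0, 1]")


def simulate_coculture_events(
    config: CocultureSimConfig, cyto_template: CytoSimConfig | None = None
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Mono-E, mono-M and coculture event tables with planted synergy.

    Returns ({"mono_E": events, "mono_M": events, "cocult": events}, truth)
    where truth records the planted synergy factor and expected counts.
    Event intensities reuse the cluster geometry of ``cyto_template`` (its
    clusters field is ignored).
    """
    rng = np.random.default_rng(config.seed)
    if cyto_template is None:
        cyto_template = CytoSimConfig(
            clusters=(ClusterSpec("CD24+/CD44-", 1),), seed=config.seed
        )
    n_e = int(rng.poisson(config.n_mono_e))
    n_m = int(rng.poisson(config.n_mono_m))
    projected = 0.5 * (config.n_mono_e + config.n_mono_m)
    n_cocult = int(rng.poisson(config.synergy_factor * projected))
    n_cocult_e = int(round(config.e_fraction_cocult * n_cocult))

    def build(sample_id: str, clusters: tuple[ClusterSpec, ...], seed: int):
        cfg_dict = asdict(cyto_template)
        cfg_dict.update(clusters=clusters, sample_id=sample_id, seed=seed)
        events, _ = simulate_event_table(CytoSimConfig(**cfg_dict))
        return events

    sub = rng.integers(0, 2**31 - 1, 3)
    tables = {
        "mono_E": build(
            "mono_E", (ClusterSpec("CD24-/CD44+", max(n_e, 1)),), int(sub[0])
        ),
        "mono_M": build(
            "mono_M", (ClusterSpec("CD24-/CD44+", max(n_m, 1)),), int(sub[1])
        ),
        "cocult": build(
            "cocult",
            (
                ClusterSpec("CD24+/CD44-", n_cocult_e),
                ClusterSpec("CD24-/CD44+", n_cocult - n_cocult_e),
            ),
            int(sub[2]),
        ),
    }
    truth = {
        "synergy_factor": config.synergy_factor,
        "projected_additive": projected,
        "expected_cocult": config.synergy_factor * projected,
        "config": asdict(config),
    }
    return tables, truth


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass(frozen=True)
class MarkerMix:
    """Two-component log2-scale marker mixture (negative and positive)."""

    low_mean: float = 4.0
    high_mean: float = 9.0
    sd: float = 0.7
    p_high: float = 0.5

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError("marker sd must be > 0")
        if not 0 <= self.p_high <= 1:
            raise ConfigurationError("p_high must be in [0, 1]")


@dataclass(frozen=True)
class SurvSimConfig:
    """Proportional-hazards cohort with a planted metagene effect.

    Event times are exponential with hazard = baseline_hazard *
    exp(log_hr * metagene), metagene ~ N(0, 1); censoring is independent
    exponential at ``censoring_rate`` plus administrative censoring at
    ``max_followup`` months.  Signature gene columns are the metagene plus
    N(0, gene_noise_sd) noise; ESR/HER2/MKI67 markers are drawn from
    two-component log2-scale mixtures with known memberships.
    """

    n_patients: int = 600
    log_hr: float = 0.0
    baseline_hazard: float = 0.01  # events per month
    censoring_rate: float = 0.005
    max_followup: float = 240.0
    n_signature_genes: int = 10
    gene_noise_sd: float = 0.5
    esr: MarkerMix = field(default_factory=lambda: MarkerMix(p_high=0.6))
    her2: MarkerMix = field(default_factory=lambda: MarkerMix(p_high=0.25))
    mki67: MarkerMix = field(default_factory=lambda: MarkerMix(high_mean=8.0))
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ConfigurationError("rates must be > 0")
        if self.max_followup <= 0:
            raise ConfigurationError("max_followup must be > 0")
        if self.n_signature_genes < 1:
            raise ConfigurationError("need >= 1 signature gene")
        if self.gene_noise_sd < 0:
            raise ConfigurationError("gene_noise_sd must be >= 0")


@dataclass
class SurvTruth:
    """Planted cohort structure: metagene, effect size, marker memberships."""

    metagene: pd.Series
    log_hr: float
    marker_high: pd.DataFrame  # boolean membership per marker
    gene_names: tuple[str, ...]
    config: dict = field(repr=False, default_factory=dict)


def simulate_survival_cohort(
    config: SurvSimConfig,
) -> tuple[SurvivalCohort, SurvTruth]:
    """(SurvivalCohort, truth) with exponential PH event times."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    z = rng.standard_normal(n)
    hazard = config.baseline_hazard * np.exp(config.log_hr * z)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    t_cens = np.minimum(t_cens, config.max_followup)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    gene_names = tuple(f"SIG{i:03d}" for i in range(config.n_signature_genes))
    genes = {
        g: z + rng.normal(0.0, config.gene_noise_sd, n) for g in gene_names
    }

    marker_high = {}
    markers = {}
    for name, mix in (("ESR", config.esr), ("HER2", config.her2), ("MKI67", config.mki67)):
        high = rng.random(n) < mix.p_high
        log2_val = np.where(
            high,
            rng.normal(mix.high_mean, mix.sd, n),
            rng.normal(mix.low_mean, mix.sd, n),
        )
        markers[name] = np.exp2(log2_val)
        marker_high[name] = high

    ids = [f"P{i:05d}" for i in range(n)]
    data = pd.DataFrame({"patient_id": ids, "time": time, "event": event})
    for name in ("ESR", "HER2", "MKI67"):
        data[name] = markers[name]
    for g in gene_names:
        data[g] = genes[g]

    cohort = SurvivalCohort(data=data, gene_columns=gene_names)
    truth = SurvTruth(
        metagene=pd.Series(z, index=ids, name="metagene"),
        log_hr=config.log_hr,
        marker_high=pd.DataFrame(marker_high, index=ids),
        gene_names=gene_names,
        config=asdict(config),
    )
    return cohort, truth
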