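# Methods

This note records the models implemented in `emstate`, the conventions
chosen where the underlying procedures are underdetermined, what the
synthetic generators do and do not emulate, and the numerical details that
matter for reproducing results.

## Bulk normalization and signature derivation

Raw array intensities are assumed strictly positive on the linear scale.
Normalization is two-step: (i) *central tendency* — log2 transform, then
shift each sample so its median equals the global median of the log matrix;
(ii) *relative* — subtract each gene's mean across samples. The exact
algorithm behind these normalization names in commercial array software is
not public; median scaling followed by gene-mean centering is this
package's normative reading, and it makes the result exactly invariant to
per-sample scale factors (tested).

Differential ranking between clonal E and M lines uses the Welch *t*
statistic (E − M), a robust default for small replicate groups with
possibly unequal variances. "Most differentially expressed" is therefore
operationalized as largest |t|, with ties broken by |mean difference| and
then gene id so the ranking is fully deterministic. Genes constant in both
groups get statistic 0. The E signature is the top *k* genes, the M
signature the bottom *k* (most-M-specific first); k = 150 by default, with
24 and 50 as the other conventional sizes. Signatures are disjoint by
construction (2k ≤ number of genes is enforced).

A *metagene* is the mean normalized expression of a signature's available
genes; missing genes are counted and reported, never imputed.

The E/M state space is a PCA of the sample-by-gene submatrix restricted to
sig_E ∪ sig_M, centered per gene, using the covariance (not correlation)
matrix — genes keep their natural scale. Zero-variance genes are dropped
with a warning; an all-constant submatrix is a hard error. Because PCA
signs are arbitrary, PC1 is oriented so that the M metagene covaries
positively with it: E samples score negative, M samples positive, and
intermediate (suspension-derived) samples fall between the clusters. With
the default generator (intermediate weight 0.5) the mammosphere cluster
lands at ≈ 0.5 of the E→M distance on PC1.

## Single-cell qPCR scoring

Marker panels default to the 9 epithelial genes (CDH1, EPCAM, KRT5, LCN2,
S100A8, S100P, SLPI, TP63, TNFSF10) and 11 mesenchymal genes (ABCA6, AR,
CDH2, DCN, FN1, PCOLCE, SNAI1, VIM, WNT5A, ZEB1, ZEB2).

Conventions, each configurable:

- **LOD** defaults to 24 cycles (a common microfluidic-qPCR convention; the
  platform protocol does not fix one). Detected genes (Ct < LOD) linearize
  to 2^(LOD − Ct); undetected genes carry the sentinel Ct 999 and linearize
  to 0.
- **Reference normalization**: each gene is divided by (reference maximum /
  100), i.e. the per-cell equivalent of the best 100-cell reference of the
  matching type (E genes → E references, M genes → M references). A cell
  expressing a gene at one reference-cell equivalent scores 1. The literal
  alternative reading (divide the cell value by 100 × max) differs only by
  a constant factor of 10⁴ and cannot change any classification at the
  default thresholds; the chosen reading keeps scores on an interpretable
  scale. The divisor (100) is a parameter.
- **Classification**: E and M scores are panel means of normalized values.
  τ_E = τ_M = 0 by default, i.e. any detected panel gene counts — matching
  the "exclusively expressing" semantics of pure-state calls. Cells above
  both thresholds are hybrid E/M; above neither, not evaluable.
  "Evaluable" = at least one detected panel gene (`min_genes_detected`,
  configurable).
- **Report percentages** are computed over evaluable cells and rounded half
  away from zero (11/19 → 58%, 4/19 → 21%, 1/20 → 5%).

## Cytometry gating and synergy

Events are analyzed on the asinh(intensity / cofactor) scale, cofactor 150
(standard practice for non-compensated fluorescence tables; FCS parsing and
compensation are out of scope — inputs are pre-extracted CSV intensity
tables). Per channel, quadrant thresholds come from a heterogeneous
reference population: a two-component Gaussian mixture is fitted
(deterministic given its init seed) and the threshold is the
equal-posterior point between the components. The cut must sit in a real
density valley (KDE density at the cut < 0.9 × the density at both
component centers); otherwise a KDE-valley fallback between the two largest
modes is tried, and if that also fails the channel is reported as
degenerate/unimodal rather than silently gated. Events strictly above a
threshold are positive; a tie is negative. The YFP lineage gate is the
99.5th percentile of a non-transduced control (controls are expected
unimodal, so no mixture is fitted); with a percentile gate, ~0.5% of truly
negative events leak into the positive stratum by construction.

The synergy index for cocultures seeded 1:1 from E and M cells and
compared against the same total number of monocultured cells is
observed / projected, with projected = (monoE + monoM)/2. The equal-weight
projection follows from the equal-total-seeding design; other seeding
ratios are exposed via a weight parameter. The index is scale-invariant.

## Survival analysis

**Subtypes.** ESR and HER2 are called ± by a two-component Gaussian mixture
on log2 marker expression (positive = posterior ≥ 0.5 for the higher-mean
component), falling back to a median split with a warning when the fitted
components are separated by less than one pooled SD. MKI67 high/low is a
median split within ESR+/HER2− patients. Mapping: ESR+/HER2−/MKI67low →
luminal A; ESR+/HER2−/MKI67high or ESR+/HER2+ → luminal B; ESR−/HER2− →
basal; ESR−/HER2+ → HER2+. The mapping is total and deterministic given the
marker calls; the exact bimodality procedure of the online survival tool
this emulates is unpublished, so the mixture/median rule is this package's
convention.

**Estimators.** Kaplan–Meier curves use lifelines' product-limit fitter.
The two-group logrank test aggregates ties at distinct event times and uses
the hypergeometric variance with the (n−d)/(n−1) correction; it is
implemented vectorized in-house because the best-cutoff scan evaluates it
hundreds of times per signature, and is validated in the test suite against
lifelines and against an exhaustive permutation oracle on 10-subject toys
(the analytic χ² is asymptotic; agreement is asserted to within 0.1 in p).
The two-group Cox model is a univariate Newton–Raphson on the Breslow
partial likelihood (gradient tolerance 1e−8, step clipping at ±5), with
HR = exp(β) and CI = exp(β ± 1.96·SE); Breslow ties were chosen because
the grid-search oracle is simplest to state for them, and the in-house fit
is cross-checked against lifelines (Efron) on tie-free data where the two
coincide. A group with zero events yields a monotone likelihood; the
result is flagged non-estimable with infinite bounds instead of a
pseudo-converged number.

**Best cutoff.** Candidate cutoffs are the unique metagene values within
the [0.25, 0.75] quantile window leaving each group ≥ 10% of the cohort
(split: score > cutoff = high). The cutoff minimizing the logrank *p* is
selected, ties resolved toward the median. The reported *p* is nominal, as
in the emulated tool, and every result carries a `selection_optimism`
flag: under a planted null the scan reaches p < 0.05 in far more than 5%
of replicates (asserted as a property test at n = 600 over 200
replicates — empirically roughly, an order of magnitude above the nominal
rate). An optional selection-corrected p (`adjust_p_permutations`) reruns
the scan on score-versus-outcome permutations and reports the add-one
permutation estimate of how often a null scan beats the observed minimum
p. A composite E+M signature metagene is the mean over the union of
the gene lists (union-mean rather than mean-of-metagenes; the two differ
only when the lists overlap or differ in length, and the alternative is a
one-line change at the `metagene` call site).

## Synthetic data: what it emulates and what it does not

No quantitative noise model is published for any of the four assays, so all
generator distributions are artifact choices, fixed once:

- **Bulk** (`BulkSimConfig`): gene baselines uniform on log2 [6, 12];
  planted E-up/M-up genes shifted by 4 log2 units (clear clonal E-vs-M
  separation); replicate noise SD 0.25 log2 units; 3 replicates per
  condition; mammosphere and replate-from-E samples mix the archetype means
  at weight 0.5, replate-from-M samples revert to the M archetype —
  encoding the observed asymmetry of plasticity (E lines reach a stable
  intermediate state, M lines revert).
- **Single cell** (`ScSimConfig`): on-state Ct ~ N(17, 0.8) cycles, hybrid
  cells attenuated by +1.5 cycles, LOD 24, dropout 10% per gene per cell,
  off-panel genes at the sentinel; 100-cell references at the on-state Ct
  − log2(100) ≈ 6.64 cycles (PCR doubles per cycle, so 100× input crosses
  threshold ~6.64 cycles earlier) with SD 0.2.
- **Cytometry** (`CytoSimConfig`): per-quadrant bivariate lognormal
  clusters with raw-intensity medians 600 (negative) and 60 000 (positive)
  and ln-scale SD 0.5 — both well above the asinh cofactor, so transformed
  clusters are near-Gaussian and the planted per-channel boundary (the
  equal-posterior crossing at the planted weights) is well defined; YFP
  medians 50 / 30 000. Coculture counts are Poisson around
  synergy_factor × projected-additive.
- **Survival** (`SurvSimConfig`): metagene z ~ N(0,1); event times
  exponential with hazard 0.01·exp(logHR·z) per month; independent
  exponential censoring (rate 0.005) capped at 240 months of follow-up;
  signature genes are z plus N(0, 0.5) noise; markers are two-component
  log2-scale mixtures (means 4 vs 9, SD 0.7; positive fractions 0.6 ESR,
  0.25 HER2, 0.5 MKI67 — roughly clinical marker prevalences).

Not emulated: PCR chemistry and preamplification bias, array probe
effects and batch structure, cytometer spillover/compensation and doublets,
non-proportional hazards, and correlated gene–gene noise. Passing recovery
tests therefore shows the estimators are correct under the stated
generative models, not that they are robust to every artifact of real
assays.

Every generator draws from one `numpy` Generator seeded per call; identical
config ⇒ byte-identical output, and every simulated record is labeled in a
truth object (planted genes, true cell class, quadrant and YFP status,
mixture memberships, planted log-HR).

## Problem sizes and degenerate inputs

Default analysis sizes — 600-gene bulk matrices with 200 + 200 planted
genes, 200-cell single-cell tables, 10 000-event cytometry samples, and
600-patient cohorts (50 replicates for HR recovery, 200 for the null
calibration of the cutoff scan) — were chosen as the smallest sizes at
which the recovery tolerances quoted in the tests are comfortably stable
across seeds; the whole suite plus the acceptance script completes in
about a minute.

Degenerate inputs fail loudly and specifically: non-positive linear
intensities, duplicate gene ids and ragged rows (with file/line), missing
reference groups, unimodal gating channels, constant metagenes in the
cutoff scan, empty subtype strata (listing the available strata), and
zero-variance PCA submatrices.

## Known limitations

- Real patient-cohort hazard ratios depend on a proprietary external
  database and probe-set mapping; this package reproduces the analysis
  structure and validates it by parameter recovery on synthetic cohorts
  only.
- Gene identifiers are taken at face value (no probe-level processing,
  id translation, or cross-platform mapping).
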