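# emstate

Analysis toolkit for epithelial–mesenchymal (E/M) cell states in breast
cancer model systems, for computational biologists studying EMT
heterogeneity and its clinical correlates. It covers four linked analyses:

1. **Bulk signatures and state space** — normalize expression arrays from
   clonal E and M cell lines (median scaling, then per-gene centering), rank
   genes by a Welch *t* statistic between E and M clones, take the top-*k*
   genes in each direction as E/M signatures (k = 150 by default), and
   project samples into a covariance-matrix PCA of the signature submatrix.
   PC1 is oriented so the mesenchymal metagene increases with it: adherent E
   clones sit at negative PC1, M clones at positive PC1, and suspension
   (mammosphere) cultures in between.
2. **Single-cell qPCR E/M scoring** — linearize Ct values as
   2^(LOD − Ct) (0 if undetected), scale each marker gene to the per-cell
   equivalent of its maximum in simultaneously run 100-cell reference
   samples (E genes against E references, M genes against M references),
   average the 9 E-panel and 11 M-panel genes into per-cell E and M scores,
   and classify each cell as **E**, **M**, **hybrid E/M** (both panels above
   threshold) or **not evaluable**.
3. **Quadrant cytometry and coculture synergy** — derive CD24/CD44
   thresholds from a heterogeneous reference sample (asinh transform,
   two-component Gaussian mixture, equal-posterior cut with a KDE-valley
   fallback), count events per CD24±/CD44± quadrant, stratify by a YFP
   lineage label, and quantify coculture synergy as
   observed / projected-additive, where the projection under equal total
   seeding is the mean of the two monoculture counts.
4. **Metagene survival analysis** — call St. Gallen intrinsic subtypes
   (luminal A/B, basal, HER2+) from bimodal ESR/HER2/MKI67 expression,
   compute signature metagenes (mean expression), dichotomize at the
   cutoff minimizing the logrank *p* within an interquantile window
   ("autoselect best cutoff"), and report the two-group Cox hazard ratio
   with 95% CI. The scanned *p* is nominal and flagged as
   selection-optimistic.

A `synthetic` module generates every input with planted ground truth
(differential genes, cell classes, quadrant memberships, hazard ratios), so
all estimators are tested for parameter recovery end to end.

## Worked example

```python
import emstate as es

# classify a simulated single-cell population with 58% planted hybrids
cfg = es.ScSimConfig(n_pure_e=42, n_pure_m=42, n_hybrid=116,
                     dropout_prob=0.1, seed=7)
cells, refs, truth = es.simulate_sc_ct_table(cfg)
norm = es.reference_normalize(es.ct_to_linear(cells), es.ct_to_linear(refs),
                              refs.ref_groups, cfg.panel)
calls = es.classify_cells(es.cell_scores(norm, cfg.panel))
summary = es.population_summary(calls)
print("counts:", summary.counts)
print("percent of evaluable:", summary.percentages)

# survival: planted harmful metagene, best-cutoff dichotomization
cohort, t = es.simulate_survival_cohort(
    es.SurvSimConfig(n_patients=600, log_hr=0.5, seed=1))
sig = es.GeneSignature("M", t.gene_names, source="sim")
res = es.best_cutoff_scan(es.metagene(cohort, sig).values,
                          cohort.data["time"].values,
                          cohort.data["event"].values)
print(f"HR = {res.hr:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"logrank p = {res.p:.2e}, cutoff = {res.cutoff:.3f}, "
      f"groups {res.n_high}/{res.n_low}")
```

Output:

```
counts: {'E': 42, 'M': 42, 'hybrid': 116, 'not_evaluable': 0}
percent of evaluable: {'E': 21, 'M': 21, 'hybrid': 58}
HR = 2.20 (95% CI 1.77-2.73), logrank p = 4.58e-13, cutoff = 0.473, groups 176/424
```

The classifier recovers the planted class mix exactly despite 10% gene
dropout (58% hybrid, 21% pure E, 21% pure M of the evaluable cells), and
the best-cutoff scan on a cohort with a planted positive log hazard ratio
reports HR > 1 — note the nominal *p* is optimistic because the cutoff was
chosen to minimize it (`res.selection_optimism`).

The same stages are exposed on the command line:

```bash
emstate simulate sc --seed 7 --out sim/
emstate scstate --ct sim/sc_cells.csv --refs sim/sc_refs.csv --out calls.tsv
emstate synergy --cocult 60 --mono-e 10 --mono-m 30
emstate run --seed 5 --out run/        # full pipeline + manifest.json
```

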