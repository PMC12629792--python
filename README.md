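# pdackit

Exploratory biomarker analyses for metastatic pancreatic ductal
adenocarcinoma (mPDAC) trial cohorts, built as a tested, reusable
pipeline:

* **ctDNA kinetics** — circulating KRAS G12 mutant-allele fraction
  (`%MAF = 100 · mutant copies / total copies`) tracked against tumor
  burden (sum of longest diameters, SLD). Per patient the coupling is
  exponential, `log10(%MAF) = α + β·SLD`, fitted by OLS on time-matched
  pairs; the fits translate a RECIST 30% SLD reduction into an
  equivalent %MAF reduction, `100·(1 − 10^(−0.3·β·SLD₀))`.
* **Molecular calls** — ctKRAS *clearance* (%MAF at or below the
  wild-type-derived threshold, mean + 3 sd, within 225 days),
  *mResponse* (≥90% reduction from baseline within 70 days) and
  *mProgression* (≥10% increase from a previous measurement within
  225 days), plus confusion-matrix evaluation against radiological
  RECIST v1.1 labels and lead-time statistics.
* **Molecular subtyping** — classical vs basal-like classification
  (z-score → PCA → K-means with a classical-marker orientation rule)
  and single-sample gene-set scoring (ssGSEA, rank-weighted ECDF
  difference) with median stratification.
* **Association screens** — Fisher exact screens with Benjamini-Hochberg
  FDR, Kaplan-Meier medians, classic and Gehan-Breslow weighted
  log-rank tests, Cox proportional-hazards fits (Breslow ties,
  interactions), immune fold-change analysis with a normality-gated
  t-test/Wilcoxon branch, variant filters, TMB/MSI classification, a
  tissue-vs-ctDNA KRAS consensus rule, and a pairwise confounding
  screen.
* **Synthetic cohorts** — a seeded simulator generating SLD
  trajectories, coupled ctDNA series with a detection floor, RECIST
  labels, two-subtype expression, immune panels and survival, so every
  stage is testable without patient data.

## Worked example

Simulate a 60-patient cohort and run the full pipeline:

```bash
pdackit simulate --out demo/cohort --seed 7
pdackit run-all --cohort demo/cohort --out demo/results --seed 7
```

or equivalently in Python:

```python
from pdackit.simulate import CohortConfig, simulate_cohort
from pdackit.pipeline import run_full_analysis, PipelineConfig

bundle = simulate_cohort(CohortConfig(n_patients=60, seed=7))
summary = run_full_analysis(bundle, PipelineConfig(seed=7))
```

Selected entries of the summary this prints:

```json
{
  "molecular_call_counts": {"n_evaluable": 57, "cleared": 16,
                            "mresponse": 18, "mprogression": 48},
  "mresponse_evaluation": {"tp": 18, "fn": 7, "fp": 0, "tn": 32,
                           "accuracy": 87.7, "sensitivity": 72.0,
                           "specificity": 100.0},
  "sld30_maf_reduction": {"mean": 78.66, "sd": 19.81, "n": 29},
  "maf_sld_correlation": {"pearson_r_absolute": 0.815, "n_pairs": 192},
  "subtype_counts": {"classical": 34, "basal-like": 26},
  "clearance_survival": {"km_median_by_stratum":
      {"not_cleared": 294.0, "cleared": 458.2},
      "logrank_p": 0.217, "gehan_p": 0.199}
}
```

Reading it: 57 of 60 patients had an evaluable mutant ctDNA series; 18
met the mResponse definition, and treating mResponse as a predictor of
confirmed radiological response gives 72.0% sensitivity and 100%
specificity on this cohort. The per-patient exponential fits translate
a 30% SLD reduction into a 78.7% (±19.8) %MAF reduction, and pooled SLD
vs log10(%MAF) correlate at r = 0.81 — the coupling the simulator
injects and the kinetics module is designed to recover. Patients who
cleared ctKRAS have a longer median overall survival (458 vs 294 days);
at n=60 the log-rank test does not reach significance.

Each stage is also exposed separately: `pdackit ctdna call`,
`pdackit ctdna evaluate`, `pdackit subtype`, `pdackit associate`
(see `--help` for options).

## Layout

```
src/pdackit/
  simulate.py      synthetic cohort generator (seeded, per-patient streams)
  kinetics.py      %MAF computation, matching, exponential fits, callers
  subtypes.py      z-score/PCA/K-means subtyping, ssGSEA, median strata
  associations.py  Fisher/BH/KM/log-rank/Cox/fold-change/variant rules
  io.py            schema-validated CSV/TSV/GMT I/O
  pipeline.py      end-to-end orchestration with exclusion accounting
  cli.py           click command-line interface
docs/methods.md    model assumptions, parameter choices, limitations
```
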