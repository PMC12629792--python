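# Methods

## The coupling model

The central quantity is the circulating KRAS G12 mutant-allele fraction
(%MAF), the mutant copy concentration divided by the total cell-free
DNA copy concentration, as a percentage. Tumor burden is the RECIST sum
of longest diameters (SLD, mm). The working model is exponential
coupling,

    %MAF(t) = 10^(α + β · SLD(t) + ε),   ε ~ N(0, σ²),

so log10(%MAF) is linear in SLD. Per patient, α (log10 %MAF at zero
burden) and β (per-mm slope) are estimated by ordinary least squares on
time-matched (SLD, %MAF) pairs; patients need at least three usable
pairs, and pairs with undetected (zero) %MAF are excluded unless a
pseudo-count is configured. The fit quality is the OLS R². The model's
practical use is threshold translation: an SLD reduction of 30% from
baseline SLD₀ multiplies %MAF by 10^(−0.3·β·SLD₀), giving the per-patient
%MAF reduction equivalent to a RECIST partial response, whose cohort
mean motivates the 90% cut used by the molecular response definition.

Matching pairs each CT-scan SLD value with the temporally closest ctDNA
draw. Ties break toward the earlier draw (no look-ahead); pairs more
than `max_gap_days` apart are dropped. The default gap cap of 21 days
is roughly the reported mean matching gap plus two standard deviations.

## Molecular calls

All calls anchor to a per-patient baseline: the latest measurement at
day ≤ 0, else the first available measurement (with a warning). The
definitions are:

* **clearance** — %MAF at or below the clearance threshold at any
  on-treatment time point within the first 225 days. The threshold is
  the mean plus three sample standard deviations (ddof = 1) of %MAF
  measurements from KRAS G12 wild-type patients — a specificity bound on
  assay background. All wild-type timepoints are used, not baseline
  only; with a noise-free wild-type panel the threshold degenerates to
  0, which the detection floor makes attainable. Patients whose baseline
  is already at or below the threshold are not evaluable.
* **mResponse** — relative %MAF at or below 0.10 of baseline (≥90%
  reduction) within the first 70 days.
* **mProgression** — a measurement at least 1.10 times any earlier
  positive measurement within the first 225 days. The "10% increase" is
  read as relative; an `absolute_points` mode (≥10 percentage points of
  %MAF) is available behind a config switch because the phrasing admits
  both readings.

Calls are monotone in their thresholds (relaxing a cut can only turn a
negative call positive) and idempotent. Evaluation against radiology
uses confirmed RECIST PR/CR as the positive response label and RECIST
PD at any assessment as the progression label; metrics are reported at
one decimal with halves rounded away from zero, the convention of
clinical tables. Lead time is radiological day minus molecular day
(positive when the blood signal came first), summarized as mean ± sd
over patients with both events.

RECIST v1.1 labelling from an SLD series: PR at ≥30% drop from
baseline, CR at SLD = 0, PD at ≥20% rise over the running nadir with a
≥5 mm absolute rise; responses require reconfirmation at least 28 days
later (configurable), and the response day is the first day the
criterion held.

## Subtyping and gene-set scores

Classification into classical and basal-like transcriptomic subtypes
follows the standard workflow: z-score the signature genes across
samples (ddof = 1, zero-variance genes dropped), project samples onto
the first 2 principal components (the dimensionality is configurable;
2 is the default because the published analyses cluster in a plotted
PCA plane), K-means with k = 2, k-means++ initialization, 50 restarts
and a fixed seed. Clusters carry no labels of their own, so the cluster
whose samples have the higher mean z-score over the classical markers
is called "classical" — an explicit convention. Patients with several
biopsies keep per-sample labels; a first-biopsy collapse is provided
for survival joins.

ssGSEA scores a gene set in one sample by ranking genes by expression
(highest first, ties by stable input order) and accumulating the
difference between the in-set ECDF weighted by rank^α (α = 0.25) and
the unweighted out-of-set ECDF. Scores are dichotomized strictly at the
cohort median (high iff score > median, ties low). Survival effects of
scores are tested with the score as a continuous Cox covariate; the
median strata are used for Kaplan-Meier display.

## Survival and screening machinery

Kaplan-Meier estimation, medians and Greenwood-based confidence
intervals come from lifelines. The weighted log-rank statistic is
implemented directly: at each event time the observed-minus-expected
vector under the hypergeometric null accumulates with weight 1
(classic log-rank) or the total number at risk (Gehan-Breslow
generalized Wilcoxon, which up-weights early event times and is the
appropriate test when hazards differ early and converge later). Cox
models use the partial likelihood with Breslow tie handling via
statsmodels, with formula support for categorical reference levels and
pairwise interactions; possible separation is flagged per term, not
raised. Fisher's exact test uses the "sum of hypergeometric
probabilities ≤ observed" two-sided convention and reports the sample
odds ratio; a zero margin yields p = 1 with an undefined odds ratio.
Benjamini-Hochberg adjustment is the step-up procedure with
monotonicity enforcement, applied within each screening family.

Variant filtering mirrors targeted-panel practice: the somatic filter
drops variants with frequency > 0.01 in any of the 1000 Genomes, ESP or
gnomAD populations and keeps IMPACT MODERATE/HIGH. The DNA-damage-repair
germline filter (BRCA1/BRCA2/PALB2) keeps HIGH-impact variants with
population frequency ≥ 0.01 — the surprising frequency direction is
applied verbatim as published, with `strict_paper=False` switching to
the conventional rare-variant direction. Missing population frequencies
are unobserved, not disqualifying. TMB is split at the cohort median
(ties low); MSI calls use a 20% unstable-loci score. The confounding
screen routes numeric-numeric pairs to Pearson, categorical pairs to
Fisher (2×2 with any expected count < 5) or chi-square, and mixed pairs
to one-way ANOVA.

## The synthetic cohort

The generator emulates the statistical structure the analyses assume,
not raw assays (no sequencing reads, droplets or cytometry events):

* SLD is single-phase exponential per patient,
  `SLD(t) = SLD₀·e^(r·t)`, with r drawn around −0.012/day for
  responders and +0.004/day for non-responders (jitter sd 0.004/day);
  an optional two-phase decay-then-regrowth mode exercises progression
  calls. Baseline SLD is lognormal with median 70 mm (log-sd 0.4).
  Patients discontinue at radiological progression: series truncate at
  the PD visit, as trial sampling does.
* %MAF follows the coupling model with β ~ N(0.035, 0.008) per mm and
  α ~ N(−2.45, 0.4), putting a typical baseline at 1% MAF and placing a
  30% SLD reduction in the deep (~70–85%) MAF-reduction regime; noise
  sd 0.15 on log10; detection floor 0.01% recorded as explicit zeros.
  Wild-type patients get folded-normal background (sd 0.004%).
* Visits: ctDNA every 14 days, CT scans every 56 days, to day 280; all
  series share day 0 as baseline.
* Response probability 0.42; genotype probabilities
  G12D/G12V/G12R/WT = 0.40/0.40/0.13/0.07 — the regime of a first-line
  mPDAC cohort.
* Survival is exponential with responder hazard multiplier 0.4 and base
  medians of 300 (OS) and 150 (PFS) days for non-responders, so cohort
  medians land near 15 and 7.5 months; PFS is the minimum of the
  progression and death times; administrative censoring at day 720.
* Expression has two balanced subtypes with 25 markers each shifted by
  3 noise-sd, plus 200 background genes. The immune panel covers the
  four sampling days around the priming dose with configurable
  multiplicative post-dose effects (default: ×2 on Ki67+ T cells in
  responders).

Reproducibility: one `SeedSequence` per cohort spawns one stream per
patient by counter plus cohort-level streams, so output is
byte-identical per seed and independent of iteration order.

What passing tests on these cohorts do *not* show about real data: the
generator has no inter-lesion structure (SLD is simulated directly),
no visit nonadherence or assay batch effects, exponential rather than
realistic tumor-growth laws, and label noise only where injected — so
recovery rates here are upper bounds on what heterogeneous clinical
data would give.

## Numerical choices and edge cases

* One-decimal percentages round halves away from zero (`round_half_away`),
  matching clinical reporting; Python's banker's rounding would report
  76.65 → 76.6.
* OLS fits require ≥3 points and nonzero SLD variance; saturated
  (100%) MAF values are kept in calls but carry no slope information.
* K-means determinism comes from a fixed seed plus 50 restarts; on
  enumerable instances (n ≤ 8) it attains the global best-SSE
  partition in tests.
* Exact-test p-values are discrete: under a null their distribution is
  superuniform (P(p ≤ a) ≤ a), so uniformity diagnostics are reserved
  for the continuous tests (Pearson, ANOVA); the Fisher screen's null
  rejection rate sits at or slightly below the nominal 5%.
* Degenerate inputs fail loudly with typed errors (`SchemaError`,
  `BaselineError`, `InsufficientDataError`) carrying row/column context;
  exclusions are logged once per patient and stage with a
  machine-readable reason.

## Known limitations

* The clearance threshold uses all wild-type timepoints; whether the
  original analysis used baseline only is not stated, and the choice
  shifts the threshold by at most the wild-type within-patient drift.
* The exact functional form of the published per-patient exponential
  models (log base, weighting) is not stated; OLS on log10 matches the
  plotted axes and is adopted.
* Cox tie handling is Breslow; with heavily tied data Efron would
  differ in the third decimal of log-HRs.
* ssGSEA normalization differs across published implementations; the
  optional normalization here is cohort min-max rescaling of scores.
* The simulator's problem sizes used in tests and the acceptance script
  (cohorts of 100–500 patients, 20–100 replicate seeds) are the sizes
  at which the checked statistical properties stabilize; all are
  configurable.
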