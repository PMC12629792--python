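"""Feature-endpoint screening and survival statistics.

Fisher-exact screens over binary alteration matrices, Benjamini-Hochberg
FDR, Kaplan-Meier estimation, weighted log-rank tests (classic and
Gehan-Breslow), Cox proportional-hazards fits with interactions
(Breslow tie handling), immune fold-change analysis with normality-gated
group comparison, K-means sample clustering, somatic/germline variant
filtering, TMB/MSI classification, tissue-vs-ctDNA KRAS consensus, and a
pairwise confounding screen.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

from ._util import InsufficientDataError, PdackitError, logger

DDR_GENES = ("BRCA1", "BRCA2", "PALB2")
POPULATION_MAF_COLS = ("maf_1000g", "maf_esp", "maf_gnomad")


# ---------------------------------------------------------------------------
# exact tests and FDR

def fisher_exact_test(table: Sequence[Sequence[int]]) -> dict[str, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums the hypergeometric probabilities of all tables
    (with the observed margins) no more probable than the observed one.
    The reported odds ratio is the sample (cross-product) estimate; with
    a zero margin the table carries no information, so p = 1 and the
    odds ratio is undefined (NaN).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0) or t.sum() == 0:
        raise PdackitError("need a nonnegative 2x2 table with positive total")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return {"odds_ratio": float("nan"), "p_two_sided": 1.0}
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    sample_or = float("inf") if b * c == 0 else a * d / (b * c)
    return {"odds_ratio": float(sample_or), "p_two_sided": float(p)}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise PdackitError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_screen(
    features: pd.DataFrame,
    endpoints: pd.DataFrame,
    min_altered: int = 3,
) -> pd.DataFrame:
    """One Fisher test per (binary feature, binary endpoint).

    Features altered in fewer than ``min_altered`` samples are excluded
    (logged); constant endpoints are skipped with a warning. Raw p and
    BH q (adjusted within each endpoint's family) are reported.
    """
    rows = []
    for fname in features.columns:
        f = features[fname].astype(bool)
        if int(f.sum()) < min_altered:
            logger.info("feature %s excluded: altered in %d < %d samples", fname, int(f.sum()), min_altered)
            continue
        for ename in endpoints.columns:
            e = endpoints[ename].astype(bool)
            if e.nunique() < 2:
                warnings.warn(f"endpoint {ename} is constant; skipped", stacklevel=2)
                continue
            table = [
                [int((f & e).sum()), int((f & ~e).sum())],
                [int((~f & e).sum()), int((~f & ~e).sum())],
            ]
            res = fisher_exact_test(table)
            rows.append(
                {
                    "feature": fname,
                    "endpoint": ename,
                    "statistic_kind": "fisher_p",
                    "estimate": res["odds_ratio"],
                    "p": res["p_two_sided"],
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = np.nan
        for ename, idx in out.groupby("endpoint").groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# survival machinery

def km_estimate(time: Sequence[float], event: Sequence[int]) -> dict:
    """Product-limit survival curve with median and 95% CI (Greenwood
    variance, log-log transform; the lifelines default)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    if event.sum() == 0:
        median = float("nan")
        ci_low = ci_high = float("nan")
    else:
        median = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        ci_low, ci_high = (float(ci.iloc[0, 0]), float(ci.iloc[0, 1]))
    sf = kmf.survival_function_.iloc[:, 0]
    return {
        "median": median,
        "median_ci": (ci_low, ci_high),
        "survival_function": pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.to_numpy()}),
    }


def weighted_logrank_test(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
    weights: str = "logrank",
) -> dict[str, float]:
    """K-sample weighted log-rank test.

    ``weights='logrank'`` gives the classic test (weight 1 at every event
    time); ``weights='gehan'`` gives the Gehan-Breslow generalized
    Wilcoxon (weight = total number at risk), which up-weights early
    event times. The statistic is the weighted observed-minus-expected
    vector with its hypergeometric covariance; two-sided p from a
    chi-square with k-1 degrees of freedom.
    """
    if weights not in ("logrank", "gehan"):
        raise PdackitError(f"unknown weights {weights!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    if k < 2:
        raise PdackitError("need at least two groups")
    if event.sum() == 0:
        raise InsufficientDataError("need at least one event")
    event_times = np.unique(time[event == 1])
    U = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = float(at_risk.sum())
        d = float(((time == t) & (event == 1)).sum())
        if n <= 1:
            continue
        w = n if weights == "gehan" else 1.0
        n_j = np.array([(at_risk & (group == g)).sum() for g in labels], dtype=float)
        d_j = np.array(
            [((time == t) & (event == 1) & (group == g)).sum() for g in labels], dtype=float
        )
        U += w * (d_j - d * n_j / n)
        frac = n_j / n
        hyper = d * (n - d) / (n - 1)
        V += w**2 * hyper * (np.diag(frac) - np.outer(frac, frac))
    U_r, V_r = U[:-1], V[:-1, :-1]
    chi2 = float(U_r @ np.linalg.pinv(V_r) @ U_r)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return {"chi2": chi2, "p": p, "df": k - 1}


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    formula: str,
) -> pd.DataFrame:
    """Cox proportional-hazards fit via partial likelihood (Breslow ties).

    ``formula`` is a patsy right-hand side, so categorical terms with an
    explicit reference level (``C(geno, Treatment('G12V'))``) and
    pairwise interactions (``a * b``) are supported. Returns one row per
    term with HR, Wald 95% CI and p. Separation (monotone likelihood) is
    flagged per term rather than raised.
    """
    if data[event_col].sum() == 0:
        raise InsufficientDataError("need at least one event")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg.from_formula(
            f"{duration_col} ~ {formula}",
            data=data,
            status=data[event_col].to_numpy(),
            ties="breslow",
        )
        res = model.fit(disp=False)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    flagged = (np.abs(params) > 10) | ~np.isfinite(bse)
    if flagged.any():
        warnings.warn("possible separation/monotone likelihood in Cox fit", stacklevel=2)
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "term": list(res.model.exog_names),
            "coef": params,
            "hr": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p": pvals,
            "flagged": flagged,
        }
    )


# ---------------------------------------------------------------------------
# immune panel analysis

def fold_change_table(
    immune: pd.DataFrame, baseline_day: str, target_day: str
) -> pd.DataFrame:
    """Per-(patient, population) fold change between two sampling days.

    FC = value(target) / value(baseline); rows with a missing timepoint
    or a zero baseline are excluded (logged).
    """
    wide = immune.pivot_table(
        index=["patient_id", "population"], columns="day", values="frequency", aggfunc="first"
    )
    for col in (baseline_day, target_day):
        if col not in wide.columns:
            raise PdackitError(f"day {col!r} absent from immune panel")
    rows = []
    for (pid, pop), r in wide.iterrows():
        base, target = r.get(baseline_day), r.get(target_day)
        if pd.isna(base) or pd.isna(target):
            logger.info("fold change excluded for (%s, %s): missing timepoint", pid, pop)
            continue
        if base <= 0:
            logger.info("fold change excluded for (%s, %s): zero baseline", pid, pop)
            continue
        rows.append({"patient_id": pid, "population": pop, "fold_change": float(target / base)})
    return pd.DataFrame(rows)


def normality_gated_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha_normality: float = 0.05,
) -> dict:
    """Two-group comparison gated on Shapiro-Wilk normality.

    If both groups look normal (Shapiro p >= alpha in each), a two-sample
    t-test is used; otherwise the Wilcoxon rank-sum (Mann-Whitney) test.
    Returns which branch fired together with the two-sided p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need n >= 3 per group")
    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    if sw_a >= alpha_normality and sw_b >= alpha_normality:
        test_used = "t-test"
        p = float(stats.ttest_ind(a, b).pvalue)
    else:
        test_used = "wilcoxon"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {"test_used": test_used, "p": p, "shapiro_p_a": float(sw_a), "shapiro_p_b": float(sw_b)}


def kmeans_cluster_samples(
    fc_matrix: pd.DataFrame | np.ndarray, k: int = 2, seed: int = 0
) -> np.ndarray:
    """K-means labels for samples (rows); k-means++ with 50 restarts."""
    X = np.asarray(fc_matrix, dtype=float)
    if not np.all(np.isfinite(X)):
        raise PdackitError("fc_matrix must be finite")
    if k > X.shape[0]:
        raise PdackitError("k cannot exceed the number of samples")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(X)
    return km.labels_


# ---------------------------------------------------------------------------
# variant-level rules

def filter_somatic_variants(
    variants: pd.DataFrame, mode: str = "somatic", strict_paper: bool = True
) -> pd.DataFrame:
    """Population-frequency / impact filters for targeted-panel variants.

    ``somatic``: drop variants with frequency > 0.01 in any of the 1000
    Genomes, ESP or gnomAD populations (germline-likely) and keep only
    IMPACT MODERATE or HIGH.

    ``ddr_germline`` (BRCA1/BRCA2/PALB2 only): the published rule keeps
    variants with population frequency >= 0.01 and IMPACT HIGH — the
    frequency direction is the mirror image of the somatic filter. That
    rule is applied verbatim when ``strict_paper`` is True; with
    ``strict_paper=False`` the conventional rare-variant direction
    (frequency <= 0.01) is used instead.

    Missing population frequencies are treated as unobserved: the record
    is kept with respect to that population, with a warning.
    """
    if mode not in ("somatic", "ddr_germline"):
        raise PdackitError(f"unknown mode {mode!r}")
    df = variants.copy()
    mafs = df.reindex(columns=list(POPULATION_MAF_COLS))
    if mafs.isna().any().any():
        warnings.warn("missing population frequencies treated as unobserved", stacklevel=2)
    impact = df["impact"].astype(str).str.upper()
    if mode == "somatic":
        common_any = (mafs > 0.01).any(axis=1)  # NaN compares False -> unobserved kept
        keep = ~common_any & impact.isin(["MODERATE", "HIGH"])
    else:
        df_genes = df["gene"].astype(str).str.upper()
        in_ddr = df_genes.isin(DDR_GENES)
        if strict_paper:
            rare_any = (mafs < 0.01).any(axis=1)
            keep = in_ddr & ~rare_any & (impact == "HIGH")
        else:
            common_any = (mafs > 0.01).any(axis=1)
            keep = in_ddr & ~common_any & (impact == "HIGH")
    return df[keep].reset_index(drop=True)


def classify_tmb_msi(
    tmb: Sequence[float], msi_score: Sequence[float], tmb_median: float | None = None
) -> pd.DataFrame:
    """TMB high/low at the cohort median (strict >; ties are low) and
    MSI vs MSS at a 20% unstable-loci score (MSI iff >= 20)."""
    tmb = np.asarray(tmb, dtype=float)
    msi = np.asarray(msi_score, dtype=float)
    if np.any(tmb < 0) or np.any((msi < 0) | (msi > 100)):
        raise PdackitError("tmb must be >= 0 and msi_score in [0, 100]")
    med = float(np.median(tmb)) if tmb_median is None else float(tmb_median)
    return pd.DataFrame(
        {
            "tmb": tmb,
            "msi_score": msi,
            "tmb_class": np.where(tmb > med, "high", "low"),
            "msi_class": np.where(msi >= 20.0, "MSI", "MSS"),
            "tmb_median": med,
        }
    )


def consensus_kras(tissue_call: str | None, ctdna_call: str | None) -> str:
    """Harmonize tissue-sequencing and ctDNA KRAS G12 calls.

    Agreement returns the shared call; a single available source wins;
    disagreement returns "conflict" (flagged for manual review, never
    silently resolved); two missing sources return "undetermined".
    """

    def _missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x)) or x == ""

    t_missing, c_missing = _missing(tissue_call), _missing(ctdna_call)
    if t_missing and c_missing:
        return "undetermined"
    if t_missing:
        return str(ctdna_call)
    if c_missing:
        return str(tissue_call)
    return str(tissue_call) if tissue_call == ctdna_call else "conflict"


# ---------------------------------------------------------------------------
# confounding screen

def confounding_screen(
    covariates: pd.DataFrame, types: Mapping[str, str]
) -> pd.DataFrame:
    """Pairwise association screen across cohort covariates.

    numeric-numeric pairs use Pearson correlation; categorical pairs use
    Fisher's exact test when the table is 2x2 with any expected count
    below 5, else chi-square; categorical-numeric pairs use one-way
    ANOVA. p-values are BH-adjusted across the screen. Covariates with a
    single level are skipped with a log entry.
    """
    cols = [c for c in covariates.columns if c in types]
    usable = []
    for c in cols:
        if covariates[c].nunique(dropna=True) < 2:
            logger.info("covariate %s skipped: single level", c)
            continue
        usable.append(c)
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            pair = covariates[[a, b]].dropna()
            ta, tb = types[a], types[b]
            if ta == "numeric" and tb == "numeric":
                r, p = stats.pearsonr(pair[a], pair[b])
                test, estimate = "pearson", float(r)
            elif ta != "numeric" and tb != "numeric":
                table = pd.crosstab(pair[a], pair[b]).to_numpy()
                expected = stats.contingency.expected_freq(table)
                if table.shape == (2, 2) and (expected < 5).any():
                    res = fisher_exact_test(table)
                    test, estimate, p = "fisher", res["odds_ratio"], res["p_two_sided"]
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table)
                    test, estimate = "chi2", float(chi2)
            else:
                cat, num = (a, b) if ta != "numeric" else (b, a)
                groups = [g[num].to_numpy(dtype=float) for _, g in pair.groupby(cat, observed=True)]
                stat, p = stats.f_oneway(*groups)
                test, estimate = "anova", float(stat)
            rows.append({"covariate_a": a, "covariate_b": b, "test": test, "estimate": estimate, "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
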