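"""Circulating-tumor-DNA (ctKRAS) kinetics and molecular response calling.

Implements the longitudinal %MAF analysis chain: %MAF computation from
droplet-PCR copy concentrations, per-patient standardization to baseline,
nearest-in-time matching of tumor-burden (SLD) and ctDNA measurements,
per-patient exponential models ``log10(%MAF) = alpha + beta * SLD``,
translation of a RECIST-style 30% SLD reduction into an equivalent %MAF
reduction, the ctKRAS clearance threshold (wild-type mean + 3 sd), the
clearance / molecular-response (mResponse) / molecular-progression
(mProgression) callers, lead-time computation, and confusion-matrix
evaluation of a molecular call against the radiological label.

Conventions: days are relative to the first dose; the baseline
measurement of a series is the latest one at day <= 0 (if none exists the
first measurement is used with a warning). Undetected %MAF is an explicit
0 with ``detected=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import BaselineError, InsufficientDataError, PdackitError, logger, round_half_away


@dataclass(frozen=True)
class MolecularCallConfig:
    """Thresholds and windows for the molecular callers.

    Defaults are the published definitions: mResponse = >=90% reduction
    from baseline in %MAF within the first 70 days; mProgression = >=10%
    increase from any previous measurement within the first 225 days;
    clearance = %MAF at or below the wild-type-derived threshold within
    the first 225 days.
    """

    mresponse_reduction: float = 0.90
    mresponse_window_days: float = 70.0
    mprogression_increase: float = 0.10
    mprogression_mode: str = "relative"  # or "absolute_points"
    mprogression_window_days: float = 225.0
    clearance_window_days: float = 225.0
    clearance_threshold: float = 0.0  # %MAF; typically from compute_clearance_threshold

    def __post_init__(self) -> None:
        if not (0.0 < self.mresponse_reduction <= 1.0):
            raise PdackitError("mresponse_reduction must be in (0, 1]")
        if self.mprogression_mode not in ("relative", "absolute_points"):
            raise PdackitError("mprogression_mode must be 'relative' or 'absolute_points'")
        for w in (
            self.mresponse_window_days,
            self.mprogression_window_days,
            self.clearance_window_days,
        ):
            if w <= 0:
                raise PdackitError("call windows must be positive")


@dataclass
class ExponentialFit:
    """Per-patient OLS of log10(%MAF) on SLD (mm)."""

    patient_id: str
    alpha: float  # intercept, log10(%MAF)
    beta: float  # slope per mm
    r2: float
    n_points: int


@dataclass
class MolecularCalls:
    patient_id: str
    cleared: bool | None  # None = not evaluable
    first_clearance_day: float | None
    mresponse: bool | None
    first_mresponse_day: float | None
    mprogression: bool | None
    first_mprogression_day: float | None
    config: MolecularCallConfig = field(repr=False, default=None)


@dataclass
class PredictorEvaluation:
    """Confusion-matrix metrics of a molecular call vs a radiological label.

    Percentages are reported at one decimal, rounding halves away from
    zero (the convention of clinical tables)."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    def rounded(self) -> dict[str, float]:
        return {
            "accuracy": round_half_away(self.accuracy, 1),
            "sensitivity": round_half_away(self.sensitivity, 1),
            "specificity": round_half_away(self.specificity, 1),
        }


def compute_maf(mutant_conc: float, total_conc: float) -> float:
    """%MAF: mutant copy concentration over total, as a percentage."""
    mutant = np.asarray(mutant_conc, dtype=float)
    total = np.asarray(total_conc, dtype=float)
    if np.any((total <= 0) & (mutant > 0)):
        raise PdackitError("total_conc must be positive when mutant_conc > 0")
    if np.any(mutant < 0):
        raise PdackitError("mutant_conc must be nonnegative")
    if np.any(mutant > total):
        raise PdackitError("mutant_conc cannot exceed total_conc")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * mutant / total, 0.0)
    return float(out) if out.ndim == 0 else out


def baseline_value(series: pd.DataFrame, value_col: str) -> float:
    """Baseline anchor: latest measurement at day <= 0, else the first
    on-treatment measurement (with a warning)."""
    df = series.sort_values("day")
    pre = df[df["day"] <= 0]
    if not pre.empty:
        return float(pre.iloc[-1][value_col])
    if df.empty:
        raise BaselineError("series is empty")
    logger.warning(
        "no measurement at day <= 0 for patient %s; using first on-treatment value as baseline",
        df.iloc[0].get("patient_id", "?"),
    )
    return float(df.iloc[0][value_col])


def standardize_series(series: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Express a per-patient series relative to its baseline.

    ``kind='maf'`` divides %MAF by the baseline (baseline = 1);
    ``kind='sld'`` reports SLD as a percentage of baseline (baseline =
    100). A zero or missing baseline is an exclusion error.
    """
    if kind == "maf":
        col, out_col, scale = "maf_pct", "maf_rel", 1.0
    elif kind == "sld":
        col, out_col, scale = "sld_mm", "sld_rel_pct", 100.0
    else:
        raise PdackitError(f"unknown kind {kind!r}")
    base = baseline_value(series, col)
    if base <= 0:
        raise BaselineError(f"baseline {col} must be positive, got {base}")
    out = series.copy()
    out[out_col] = out[col] / base * scale
    return out


def match_timepoints(
    sld_series: pd.DataFrame,
    maf_series: pd.DataFrame,
    max_gap_days: float = 21.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pair each SLD measurement with the temporally closest %MAF one.

    Ties break toward the earlier %MAF measurement (no look-ahead).
    Pairs with a gap above ``max_gap_days`` are dropped. Returns the
    pair table plus the mean/sd of the retained gaps.
    """
    if sld_series.empty or maf_series.empty:
        return pd.DataFrame(), {"mean_gap_days": float("nan"), "sd_gap_days": float("nan"), "n_pairs": 0}
    sld = standardize_series(sld_series, "sld")
    maf = standardize_series(maf_series, "maf").sort_values("day").reset_index(drop=True)
    rows = []
    for _, s in sld.sort_values("day").iterrows():
        gaps = (maf["day"] - s["day"]).abs()
        best = gaps.min()
        if best > max_gap_days:
            continue
        # idxmin on the sorted frame returns the earliest day among ties
        m = maf.loc[gaps.idxmin()]
        rows.append(
            {
                "patient_id": s.get("patient_id", m.get("patient_id", "?")),
                "sld_day": float(s["day"]),
                "maf_day": float(m["day"]),
                "sld_mm": float(s["sld_mm"]),
                "maf_pct": float(m["maf_pct"]),
                "detected": bool(m.get("detected", m["maf_pct"] > 0)),
                "sld_rel_pct": float(s["sld_rel_pct"]),
                "maf_rel": float(m["maf_rel"]),
                "gap_days": float(best),
            }
        )
    pairs = pd.DataFrame(rows)
    gaps = pairs["gap_days"] if not pairs.empty else pd.Series(dtype=float)
    summary = {
        "mean_gap_days": float(gaps.mean()) if len(gaps) else float("nan"),
        "sd_gap_days": float(gaps.std(ddof=1)) if len(gaps) > 1 else float("nan"),
        "n_pairs": int(len(pairs)),
    }
    return pairs, summary


def fit_patient_exponential(
    pairs: pd.DataFrame, pseudo_maf: float = 0.0
) -> ExponentialFit | None:
    """OLS of log10(%MAF + pseudo_maf) on SLD over a patient's pairs.

    Pairs with undetected (zero) %MAF are excluded unless the pseudo
    count makes them positive. Returns None for patients with fewer than
    three usable points (excluded from model-based steps).
    """
    if pairs.empty:
        return None
    maf = pairs["maf_pct"].to_numpy(dtype=float) + pseudo_maf
    keep = maf > 0
    if "detected" in pairs and pseudo_maf == 0:
        keep &= pairs["detected"].to_numpy(dtype=bool)
    x = pairs["sld_mm"].to_numpy(dtype=float)[keep]
    y = np.log10(maf[keep])
    if len(x) < 3:
        return None
    if np.ptp(x) == 0:
        raise PdackitError("SLD has zero variance; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    pid = str(pairs["patient_id"].iloc[0]) if "patient_id" in pairs else "?"
    return ExponentialFit(
        patient_id=pid, alpha=float(res.intercept), beta=float(res.slope), r2=r2, n_points=int(len(x))
    )


def translate_sld_threshold(
    fits: Sequence[ExponentialFit],
    baselines: Mapping[str, float],
    sld_reduction: float = 0.30,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """%MAF reduction equivalent to a fractional SLD reduction.

    For a patient with slope ``beta`` and baseline SLD0, an SLD drop of
    ``sld_reduction * SLD0`` multiplies %MAF by
    ``10**(-beta * sld_reduction * SLD0)``; the equivalent reduction is
    one minus that ratio, as a percentage. Returns per-patient values and
    the cohort mean/sd (the quantity used to motivate the 90% mResponse
    cut).
    """
    rows = []
    for fit in fits:
        sld0 = baselines.get(fit.patient_id)
        if sld0 is None or sld0 <= 0:
            logger.info("patient %s skipped in threshold translation: no baseline SLD", fit.patient_id)
            continue
        ratio = 10.0 ** (fit.beta * (-sld_reduction * sld0))
        rows.append(
            {"patient_id": fit.patient_id, "maf_reduction_pct": 100.0 * (1.0 - ratio)}
        )
    table = pd.DataFrame(rows)
    vals = table["maf_reduction_pct"] if not table.empty else pd.Series(dtype=float)
    summary = {
        "mean": float(vals.mean()) if len(vals) else float("nan"),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "n": int(len(vals)),
    }
    return table, summary


def compute_clearance_threshold(wt_measurements: Sequence[float]) -> float:
    """Clearance threshold: mean of wild-type %MAF plus three sample sd."""
    vals = np.asarray(wt_measurements, dtype=float)
    if len(vals) < 2:
        raise InsufficientDataError("need >= 2 wild-type measurements")
    return float(vals.mean() + 3.0 * vals.std(ddof=1))


def call_clearance(
    series: pd.DataFrame, config: MolecularCallConfig
) -> tuple[bool | None, float | None]:
    """ctKRAS clearance: %MAF at or below the threshold at any
    on-treatment time point within the clearance window.

    Patients whose baseline is already at or below the threshold are not
    evaluable (returns ``(None, None)``)."""
    base = baseline_value(series, "maf_pct")
    if base <= config.clearance_threshold:
        return None, None
    on_tx = series[(series["day"] > 0)].sort_values("day")
    hits = on_tx[
        (on_tx["maf_pct"] <= config.clearance_threshold)
        & (on_tx["day"] <= config.clearance_window_days)
    ]
    if hits.empty:
        return False, None
    return True, float(hits.iloc[0]["day"])


def call_mresponse(
    series: pd.DataFrame, config: MolecularCallConfig
) -> tuple[bool | None, float | None]:
    """mResponse: reduction from baseline of at least
    ``mresponse_reduction`` within ``mresponse_window_days``."""
    try:
        std = standardize_series(series, "maf")
    except BaselineError:
        return None, None
    on_tx = std[std["day"] > 0].sort_values("day")
    hits = on_tx[
        (on_tx["maf_rel"] <= 1.0 - config.mresponse_reduction)
        & (on_tx["day"] <= config.mresponse_window_days)
    ]
    if hits.empty:
        return False, None
    return True, float(hits.iloc[0]["day"])


def call_mprogression(
    series: pd.DataFrame, config: MolecularCallConfig
) -> tuple[bool | None, float | None]:
    """mProgression: increase of at least ``mprogression_increase`` from
    any previous measurement, within the progression window.

    Default mode is relative (value >= 1.10 x an earlier positive value);
    ``absolute_points`` instead requires an increase of >= 10 percentage
    points of %MAF.
    """
    window = series[series["day"] <= config.mprogression_window_days].sort_values("day")
    if len(window) < 2:
        return None, None
    days = window["day"].to_numpy(dtype=float)
    vals = window["maf_pct"].to_numpy(dtype=float)
    for i in range(1, len(vals)):
        prev = vals[:i]
        if config.mprogression_mode == "relative":
            ref = prev[prev > 0]
            trigger = ref.size and np.any(vals[i] >= (1.0 + config.mprogression_increase) * ref)
        else:
            trigger = np.any(vals[i] - prev >= 100.0 * config.mprogression_increase)
        if trigger:
            return True, float(days[i])
    return False, None


def call_patient(series: pd.DataFrame, config: MolecularCallConfig) -> MolecularCalls:
    """All three molecular calls for one patient's ctDNA series."""
    pid = str(series["patient_id"].iloc[0]) if "patient_id" in series else "?"
    cleared, clear_day = call_clearance(series, config)
    mresp, mresp_day = call_mresponse(series, config)
    mprog, mprog_day = call_mprogression(series, config)
    return MolecularCalls(
        patient_id=pid,
        cleared=cleared,
        first_clearance_day=clear_day,
        mresponse=mresp,
        first_mresponse_day=mresp_day,
        mprogression=mprog,
        first_mprogression_day=mprog_day,
        config=config,
    )


def evaluate_predictor(
    molecular: Sequence[bool], radiological: Sequence[bool]
) -> PredictorEvaluation:
    """Confusion matrix of a molecular call against the radiological label."""
    mol = np.asarray(molecular, dtype=bool)
    rad = np.asarray(radiological, dtype=bool)
    if mol.shape != rad.shape:
        raise PdackitError("molecular and radiological labels must cover the same patients")
    return PredictorEvaluation(
        tp=int(np.sum(mol & rad)),
        fn=int(np.sum(~mol & rad)),
        fp=int(np.sum(mol & ~rad)),
        tn=int(np.sum(~mol & ~rad)),
    )


def compute_lead_time(molecular_day: float, radiological_day: float) -> float:
    """Days by which the molecular call precedes the radiological one
    (positive = molecular earlier; negative allowed)."""
    return float(radiological_day) - float(molecular_day)


def lead_time_summary(
    molecular_days: Sequence[float | None], radiological_days: Sequence[float | None]
) -> dict[str, float]:
    """Cohort mean +/- sd of lead time over patients with both events."""
    leads = [
        compute_lead_time(m, r)
        for m, r in zip(molecular_days, radiological_days)
        if m is not None and r is not None and not (pd.isna(m) or pd.isna(r))
    ]
    arr = np.asarray(leads, dtype=float)
    return {
        "n": int(arr.size),
        "mean_days": float(arr.mean()) if arr.size else float("nan"),
        "sd_days": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        "lead_times": leads,
    }


def correlate_maf_sld(pairs: pd.DataFrame) -> dict[str, float]:
    """Pearson correlations of tumor burden with ctDNA on two scales:
    absolute (SLD vs log10 %MAF, detected pairs) and relative to baseline
    (%SLD vs %MAF ratio)."""
    det = pairs[(pairs["maf_pct"] > 0)]
    if len(det) < 3:
        raise InsufficientDataError("need >= 3 detected pairs")
    x = det["sld_mm"].to_numpy(dtype=float)
    y = np.log10(det["maf_pct"].to_numpy(dtype=float))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PdackitError("zero variance in correlation input")
    r_abs, p_abs = stats.pearsonr(x, y)
    r_rel, p_rel = stats.pearsonr(
        det["sld_rel_pct"].to_numpy(dtype=float), det["maf_rel"].to_numpy(dtype=float)
    )
    return {
        "pearson_r_absolute": float(r_abs),
        "p_absolute": float(p_abs),
        "pearson_r_relative": float(r_rel),
        "p_relative": float(p_rel),
        "n_pairs": int(len(det)),
    }
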