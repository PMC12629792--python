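"""End-to-end orchestration: calls -> subtyping -> association screens.

``run_full_analysis`` reproduces the exploratory biomarker flow on any
conforming cohort bundle: compute the wild-type-derived clearance
threshold, make per-patient molecular calls, fit the per-patient
exponential coupling models and translate the 30%-SLD threshold, derive
RECIST labels, evaluate the molecular calls as predictors of the
radiological ones (with lead times), classify molecular subtypes and
score gene sets, and run the survival/association screens. Every patient
excluded at any stage appears exactly once in the exclusion log with a
machine-readable reason; inputs are never mutated.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._util import BaselineError, InsufficientDataError, PdackitError, logger
from . import associations as assoc
from . import kinetics as kin
from . import subtypes as sub
from .simulate import CohortBundle, derive_recist_labels


@dataclass
class PipelineConfig:
    call_config: kin.MolecularCallConfig = field(default_factory=kin.MolecularCallConfig)
    max_gap_days: float = 21.0
    pseudo_maf: float = 0.0
    n_pcs: int = 2
    k: int = 2
    seed: int = 0
    fdr_level: float = 0.05
    min_altered_samples: int = 3


def _recist_by_patient(sld: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, df in sld.groupby("patient_id"):
        try:
            r = derive_recist_labels(df)
        except BaselineError:
            rows.append({"patient_id": pid, "bor": None, "response_day": None, "progression_day": None})
            continue
        rows.append(
            {
                "patient_id": pid,
                "bor": r.bor,
                "response_day": r.response_day,
                "progression_day": r.progression_day,
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(
    bundle: CohortBundle,
    config: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> dict:
    """Run the full analysis; returns the summary dict (also written as
    JSON alongside the result tables when ``out_dir`` is given)."""
    cfg = config or PipelineConfig()
    exclusions: list[dict] = []
    summary: dict = {"seed": cfg.seed}

    patients = bundle.patients
    ctdna = bundle.ctdna
    has_ctdna = ctdna is not None and len(ctdna) > 0

    recist = _recist_by_patient(bundle.sld)
    summary["recist_counts"] = recist["bor"].value_counts(dropna=True).to_dict()

    calls_df = pd.DataFrame()
    pairs_all = pd.DataFrame()
    fits_rows = []
    if has_ctdna:
        genotypes = patients.set_index("patient_id")["genotype"]
        wt_ids = genotypes[genotypes == "WT"].index
        wt_maf = ctdna[ctdna["patient_id"].isin(wt_ids)]["maf_pct"]
        try:
            threshold = kin.compute_clearance_threshold(wt_maf.to_numpy())
        except InsufficientDataError:
            threshold = 0.0
            logger.warning("fewer than two wild-type measurements; clearance threshold set to 0")
        call_config = kin.MolecularCallConfig(
            **{**asdict(cfg.call_config), "clearance_threshold": threshold}
        )
        summary["clearance_threshold_pct"] = threshold

        call_rows = []
        baselines: dict[str, float] = {}
        for pid, series in ctdna.groupby("patient_id"):
            if genotypes.get(pid) == "WT":
                exclusions.append({"patient_id": pid, "stage": "ctdna_calls", "reason": "kras_wild_type"})
                continue
            series = series.sort_values("day")
            if series["maf_pct"].iloc[0] <= 0 or len(series) < 2:
                exclusions.append(
                    {"patient_id": pid, "stage": "ctdna_calls", "reason": "no_detected_baseline_or_single_point"}
                )
                continue
            mc = kin.call_patient(series, call_config)
            call_rows.append(
                {
                    "patient_id": pid,
                    "cleared": mc.cleared,
                    "first_clearance_day": mc.first_clearance_day,
                    "mresponse": mc.mresponse,
                    "first_mresponse_day": mc.first_mresponse_day,
                    "mprogression": mc.mprogression,
                    "first_mprogression_day": mc.first_mprogression_day,
                }
            )
            sld_p = bundle.sld[bundle.sld["patient_id"] == pid]
            if not sld_p.empty:
                pairs, _ = kin.match_timepoints(sld_p, series, cfg.max_gap_days)
                if not pairs.empty:
                    pairs_all = pd.concat([pairs_all, pairs], ignore_index=True)
                fit = kin.fit_patient_exponential(pairs, cfg.pseudo_maf)
                if fit is not None:
                    fits_rows.append(fit)
                    baselines[pid] = kin.baseline_value(sld_p, "sld_mm")
                else:
                    exclusions.append(
                        {"patient_id": pid, "stage": "exponential_fit", "reason": "fewer_than_three_points"}
                    )
        calls_df = pd.DataFrame(call_rows)
        if not calls_df.empty:
            summary["molecular_call_counts"] = {
                "n_evaluable": int(len(calls_df)),
                "cleared": int(calls_df["cleared"].fillna(False).sum()),
                "mresponse": int(calls_df["mresponse"].fillna(False).sum()),
                "mprogression": int(calls_df["mprogression"].fillna(False).sum()),
            }
        _, translation = kin.translate_sld_threshold(fits_rows, baselines)
        summary["sld30_maf_reduction"] = translation
        if len(pairs_all) >= 3:
            try:
                summary["maf_sld_correlation"] = kin.correlate_maf_sld(pairs_all)
            except (PdackitError, InsufficientDataError):
                pass

        # predictor evaluation vs RECIST
        merged = calls_df.merge(recist, on="patient_id", how="inner")
        merged = merged[merged["bor"].notna()]
        if not merged.empty:
            rad_resp = merged["bor"].isin(["PR", "CR"])
            mol_resp = merged["mresponse"].fillna(False).astype(bool)
            ev = kin.evaluate_predictor(mol_resp, rad_resp)
            summary["mresponse_evaluation"] = {
                "tp": ev.tp, "fn": ev.fn, "fp": ev.fp, "tn": ev.tn, **ev.rounded()
            }
            resp = merged[mol_resp & rad_resp]
            summary["mresponse_lead_time"] = {
                k: v
                for k, v in kin.lead_time_summary(
                    resp["first_mresponse_day"], resp["response_day"]
                ).items()
                if k != "lead_times"
            }
            rad_prog = merged["progression_day"].notna()
            mol_prog = merged["mprogression"].fillna(False).astype(bool)
            evp = kin.evaluate_predictor(mol_prog, rad_prog)
            summary["mprogression_evaluation"] = {
                "tp": evp.tp, "fn": evp.fn, "fp": evp.fp, "tn": evp.tn, **evp.rounded()
            }
            prog = merged[mol_prog & rad_prog]
            summary["mprogression_lead_time"] = {
                k: v
                for k, v in kin.lead_time_summary(
                    prog["first_mprogression_day"], prog["progression_day"]
                ).items()
                if k != "lead_times"
            }
    else:
        summary["ctdna_stages"] = "skipped: no ctDNA table"

    # subtype classification + gene-set scoring
    subtype_df = pd.DataFrame()
    has_expr = bundle.expression is not None and len(bundle.expression) > 0
    if has_expr and bundle.gene_sets:
        classical = bundle.gene_sets.get("classical_markers", [])
        basal = bundle.gene_sets.get("basal_markers", [])
        if classical and basal:
            subtype_df = sub.classify_molecular_subtype(
                bundle.expression, classical, basal, n_pcs=cfg.n_pcs, k=cfg.k, seed=cfg.seed
            )
            summary["subtype_counts"] = subtype_df["subtype"].value_counts().to_dict()
        scores = sub.ssgsea_scores(bundle.expression, bundle.gene_sets)
        strata_summaries = {}
        surv = bundle.survival.set_index("patient_id") if len(bundle.survival) else None
        for set_name, sdf in scores.groupby("set_name"):
            sdf = sdf.set_index("sample_id")
            strata = sub.stratify_by_median(sdf["score"])
            if surv is not None:
                joined = surv.join(sdf["score"]).join(strata.rename("stratum")).dropna(subset=["score"])
                if len(joined) >= 2 and joined["OS_event"].sum() > 0:
                    km_by = {
                        s: assoc.km_estimate(g["OS_days"], g["OS_event"])["median"]
                        for s, g in joined.groupby("stratum")
                    }
                    try:
                        cox = assoc.cox_fit(joined.reset_index(), "OS_days", "OS_event", "score")
                        hr = float(cox["hr"].iloc[0])
                        p = float(cox["p"].iloc[0])
                    except (PdackitError, InsufficientDataError):
                        hr = p = float("nan")
                    strata_summaries[set_name] = {"km_median_by_stratum": km_by, "cox_hr": hr, "cox_p": p}
        if strata_summaries:
            summary["gene_set_survival"] = strata_summaries
    else:
        summary["subtype_stages"] = "skipped: no expression matrix or gene sets"

    # association screens on genotype features
    if len(bundle.survival):
        surv = bundle.survival.merge(patients, on="patient_id")
        features = pd.get_dummies(surv["genotype"], prefix="KRAS").astype(bool)
        endpoints = pd.DataFrame(
            {
                "OS_12": (surv["OS_days"] > 365) | ((surv["OS_days"] <= 365) & (surv["OS_event"] == 0)),
                "PFS_12": (surv["PFS_days"] > 365) | ((surv["PFS_days"] <= 365) & (surv["PFS_event"] == 0)),
            }
        )
        screen = assoc.fisher_screen(features, endpoints, cfg.min_altered_samples)
        if not screen.empty:
            top = screen.nsmallest(5, "p")
            summary["top_associations"] = top[["feature", "endpoint", "estimate", "p", "q"]].to_dict("records")

        if has_ctdna and not calls_df.empty:
            j = surv.merge(calls_df[["patient_id", "cleared"]], on="patient_id").dropna(subset=["cleared"])
            if j["cleared"].nunique() == 2 and j["OS_event"].sum() > 0:
                med = {
                    ("cleared" if c else "not_cleared"): assoc.km_estimate(g["OS_days"], g["OS_event"])["median"]
                    for c, g in j.groupby("cleared")
                }
                lr = assoc.weighted_logrank_test(j["OS_days"], j["OS_event"], j["cleared"], "logrank")
                gb = assoc.weighted_logrank_test(j["OS_days"], j["OS_event"], j["cleared"], "gehan")
                summary["clearance_survival"] = {
                    "km_median_by_stratum": med,
                    "logrank_p": lr["p"],
                    "gehan_p": gb["p"],
                }

    summary["exclusions"] = exclusions

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        if not calls_df.empty:
            calls_df.to_csv(os.path.join(out_dir, "calls.csv"), index=False)
        if not pairs_all.empty:
            pairs_all.to_csv(os.path.join(out_dir, "pairs.csv"), index=False)
        if fits_rows:
            pd.DataFrame([f.__dict__ for f in fits_rows]).to_csv(
                os.path.join(out_dir, "fits.csv"), index=False
            )
        if not subtype_df.empty:
            subtype_df.to_csv(os.path.join(out_dir, "subtypes.csv"), index=False)
        recist.to_csv(os.path.join(out_dir, "recist.csv"), index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
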