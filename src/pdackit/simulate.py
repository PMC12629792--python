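"""Synthetic cohort generator for ctDNA/tumor-burden biomarker analyses.

Generates cohorts with the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without patient data:

* per-patient tumor burden (sum of longest diameters, SLD) following
  single-phase exponential decay or growth, with an optional two-phase
  decay-then-regrowth mode;
* circulating KRAS mutant-allele fraction (%MAF) coupled exponentially to
  SLD — ``%MAF = 10**(alpha + beta * SLD + noise)`` — with a detection
  floor below which measurements read 0;
* RECIST v1.1 response labels derived from the SLD series;
* exponential survival times whose hazard depends on responder status;
* a two-subtype (classical / basal-like) expression matrix with shifted
  marker genes;
* a longitudinal immune panel with treatment-induced fold changes.

Reproducibility: one ``numpy.random.SeedSequence`` per cohort, spawned
into one child stream per patient (by patient counter) plus dedicated
cohort-level streams, so output is byte-identical for a given config and
independent of patient iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import BaselineError, PdackitError

GENOTYPES = ("G12D", "G12V", "G12R", "WT")
IMMUNE_DAYS = ("C1D1", "C1D2", "C1D8", "C2D1")
DEFAULT_IMMUNE_POPULATIONS = (
    "Ki67+ T cells",
    "Ki67+ NK cells",
    "CD54+ B cells",
    "Total B cells",
    "Classical monocytes",
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the regime of a first-line metastatic PDAC trial
    cohort: ~42% radiological responders, baseline SLD lognormal with
    median ~70 mm, log10(%MAF) coupled to SLD with slope ~0.035/mm (so a
    30% SLD reduction translates into an ~80% %MAF reduction for a
    typical patient), biweekly ctDNA sampling and 8-weekly CT scans over
    280 days, and exponential survival with responder hazard multiplier
    0.4 chosen so the cohort medians land near 15 (OS) and 7.5 (PFS)
    months.
    """

    n_patients: int = 150
    genotype_probs: Mapping[str, float] = field(
        default_factory=lambda: {"G12D": 0.40, "G12V": 0.40, "G12R": 0.13, "WT": 0.07}
    )
    # lognormal parameters of baseline SLD in mm: exp(mean) is the median
    baseline_sld_mm: tuple[float, float] = (math.log(70.0), 0.4)
    growth_rate_responder: float = -0.012  # per-day fractional SLD change
    growth_rate_progressor: float = 0.004
    growth_rate_sd: float = 0.004  # per-patient jitter around the group rate
    response_prob: float = 0.42
    coupling_slope_beta: float = 0.035  # log10(%MAF) per mm SLD
    coupling_slope_sd: float = 0.008
    # shared coupling intercept with per-patient scatter: a typical 70 mm
    # baseline gives 10**(-2.45 + 0.035*70) = 1% baseline MAF, and %MAF
    # scales with tumor burden across patients (strong pooled correlation)
    coupling_intercept_log10: float = -2.45
    coupling_intercept_sd: float = 0.4
    maf_noise_sd: float = 0.15  # additive on log10(%MAF)
    detection_floor_pct: float = 0.01
    wt_background_maf_sd: float = 0.004  # residual %MAF signal in KRAS-WT plasma
    visit_days: tuple[int, ...] = tuple(range(0, 281, 14))  # ctDNA draws
    sld_visit_days: tuple[int, ...] = (0, 56, 112, 168, 224, 280)  # CT scans
    survival_link: Mapping[str, float] = field(
        default_factory=lambda: {"responder": 0.4, "non_responder": 1.0}
    )
    os_base_hazard: float = math.log(2) / 300.0  # per day, non-responders
    pfs_base_hazard: float = math.log(2) / 150.0
    admin_censor_day: float = 720.0
    two_phase: bool = False  # decay-then-regrowth SLD mode
    switch_day: float = 180.0
    regrowth_rate: float = 0.006
    expression_effect_size: float = 3.0  # marker shift in units of noise sd
    n_marker_genes: int = 25  # per subtype signature
    n_background_genes: int = 200
    immune_effect_map: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"Ki67+ T cells": {"responder": 2.0}}
    )
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.genotype_probs.get(g, 0.0) for g in GENOTYPES)
        if abs(total - 1.0) > 1e-9:
            raise PdackitError(f"genotype_probs must sum to 1, got {total!r}")
        if any(p < 0 for p in self.genotype_probs.values()):
            raise PdackitError("genotype_probs must be nonnegative")
        if self.n_patients <= 0:
            raise PdackitError("n_patients must be positive")
        if self.detection_floor_pct < 0:
            raise PdackitError("detection_floor_pct must be >= 0")
        if self.maf_noise_sd < 0:
            raise PdackitError("maf_noise_sd must be >= 0")
        if len(self.visit_days) == 0 or len(self.sld_visit_days) == 0:
            raise PdackitError("visit schedules must be nonempty")
        for days in (self.visit_days, self.sld_visit_days):
            if days[0] != 0:
                raise PdackitError("first visit day must be 0 (baseline)")
            if any(b <= a for a, b in zip(days, days[1:])):
                raise PdackitError("visit days must be strictly increasing")
        if any(h <= 0 for h in self.survival_link.values()):
            raise PdackitError("survival_link multipliers must be positive")
        if self.os_base_hazard <= 0 or self.pfs_base_hazard <= 0:
            raise PdackitError("base hazards must be positive")


@dataclass
class PatientTruth:
    """Generative ground truth retained for recovery tests."""

    patient_id: str
    genotype: str
    is_responder: bool
    baseline_sld: float
    growth_rate: float
    true_alpha: float  # log10(%MAF) intercept
    true_beta: float  # log10(%MAF) slope per mm SLD


@dataclass
class RecistAssessment:
    """RECIST v1.1 call derived from an SLD series."""

    bor: str  # one of CR, PR, SD, PD
    response_day: float | None  # first day the (confirmed) response criterion held
    progression_day: float | None


@dataclass
class CohortBundle:
    """All tables of a simulated cohort, cross-keyed by patient_id."""

    patients: pd.DataFrame
    sld: pd.DataFrame
    ctdna: pd.DataFrame
    immune: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    gene_sets: dict[str, list[str]]
    config: CohortConfig


def simulate_sld_trajectory(
    patient: PatientTruth,
    visit_days: Sequence[float],
    *,
    two_phase: bool = False,
    switch_day: float = 180.0,
    regrowth_rate: float = 0.006,
) -> pd.DataFrame:
    """SLD(day) = baseline * exp(rate * day), optionally regrowing after
    ``switch_day`` (two-phase mode, used to exercise progression calls)."""
    days = np.asarray(visit_days, dtype=float)
    if np.any(days < 0):
        raise PdackitError("visit days must be nonnegative")
    if patient.baseline_sld <= 0:
        raise PdackitError("baseline_sld must be positive")
    sld = patient.baseline_sld * np.exp(patient.growth_rate * days)
    if two_phase:
        after = days > switch_day
        sld_switch = patient.baseline_sld * math.exp(patient.growth_rate * switch_day)
        sld[after] = sld_switch * np.exp(regrowth_rate * (days[after] - switch_day))
    return pd.DataFrame(
        {"patient_id": patient.patient_id, "day": days, "sld_mm": sld}
    )


def simulate_ctdna_from_sld(
    sld: pd.DataFrame,
    true_beta: float,
    intercept: float,
    noise_sd: float,
    detection_floor: float,
    rng: np.random.Generator,
    *,
    total_conc_median: float = 5000.0,
    total_conc_sigma: float = 0.5,
) -> pd.DataFrame:
    """%MAF = 10**(intercept + beta * SLD + eps), eps ~ N(0, noise_sd).

    Values below ``detection_floor`` are recorded as 0 with
    ``detected=False`` (explicit zeros, so clearance logic can see them).
    Copy concentrations are back-calculated from a lognormal total cfDNA
    concentration so the %MAF identity holds exactly.
    """
    if noise_sd < 0:
        raise PdackitError("noise_sd must be >= 0")
    if sld.empty:
        raise PdackitError("sld series must be nonempty")
    days = sld["day"].to_numpy(dtype=float)
    eps = rng.normal(0.0, noise_sd, size=len(days)) if noise_sd > 0 else 0.0
    # exponent clipped at 2: %MAF cannot exceed 100%
    maf = 10.0 ** np.minimum(intercept + true_beta * sld["sld_mm"].to_numpy() + eps, 2.0)
    detected = maf >= detection_floor
    maf = np.where(detected, maf, 0.0)
    total = total_conc_median * np.exp(rng.normal(0.0, total_conc_sigma, len(days)))
    # grouping keeps mutant <= total exactly at the 100% cap
    mutant = total * (maf / 100.0)
    return pd.DataFrame(
        {
            "patient_id": sld["patient_id"].to_numpy(),
            "day": days,
            "mutant_conc": mutant,
            "total_conc": total,
            "maf_pct": maf,
            "detected": detected,
        }
    )


def derive_recist_labels(
    sld: pd.DataFrame, confirmation_days: float = 28.0
) -> RecistAssessment:
    """Apply RECIST v1.1 rules to a single-patient SLD series.

    PR: SLD drop >= 30% from baseline; CR: SLD = 0; PD: SLD rise >= 20%
    over the nadir AND >= 5 mm absolute. A response counts only when the
    criterion holds again at least ``confirmation_days`` later;
    ``response_day`` is the first day the criterion was met.
    """
    df = sld.sort_values("day")
    base_rows = df[df["day"] <= 0]
    if base_rows.empty:
        raise BaselineError("RECIST derivation requires a baseline (day <= 0)")
    baseline = float(base_rows.iloc[-1]["sld_mm"])
    on_tx = df[df["day"] > 0]
    days = on_tx["day"].to_numpy(dtype=float)
    vals = on_tx["sld_mm"].to_numpy(dtype=float)

    is_pr = vals <= 0.7 * baseline
    is_cr = vals == 0.0

    # nadir over baseline and all strictly earlier on-treatment visits
    prior_min = np.minimum.accumulate(np.concatenate([[baseline], vals]))[:-1]
    is_pd = (vals >= 1.2 * prior_min) & (vals - prior_min >= 5.0)

    def _first_confirmed(flags: np.ndarray) -> float | None:
        idx = np.flatnonzero(flags)
        for i in idx:
            later = idx[days[idx] >= days[i] + confirmation_days]
            if later.size:
                return float(days[i])
        return None

    cr_day = _first_confirmed(is_cr)
    pr_day = _first_confirmed(is_pr)
    pd_idx = np.flatnonzero(is_pd)
    progression_day = float(days[pd_idx[0]]) if pd_idx.size else None

    if cr_day is not None:
        bor, response_day = "CR", cr_day
    elif pr_day is not None:
        bor, response_day = "PR", pr_day
    else:
        response_day = None
        # SD if any non-PD on-treatment assessment precedes progression
        non_pd_days = days[~is_pd]
        if progression_day is None:
            bor = "SD" if len(days) else "PD"
        elif non_pd_days.size and non_pd_days[0] < progression_day:
            bor = "SD"
        else:
            bor = "PD"
    return RecistAssessment(bor=bor, response_day=response_day, progression_day=progression_day)


def simulate_survival(
    truth: pd.DataFrame,
    survival_link: Mapping[str, float],
    admin_censor_day: float,
    rng: np.random.Generator,
    *,
    os_base_hazard: float = math.log(2) / 300.0,
    pfs_base_hazard: float = math.log(2) / 150.0,
) -> pd.DataFrame:
    """Exponential OS/PFS with responder-dependent hazard multipliers.

    PFS is the minimum of an exponential progression time and OS, so
    PFS <= OS holds per patient; both are administratively censored at
    ``admin_censor_day``.
    """
    if any(h <= 0 for h in survival_link.values()):
        raise PdackitError("survival_link multipliers must be positive")
    if os_base_hazard <= 0 or pfs_base_hazard <= 0:
        raise PdackitError("hazards must be positive")
    rows = []
    for _, p in truth.iterrows():
        mult = survival_link["responder" if p["is_responder"] else "non_responder"]
        os_t = rng.exponential(1.0 / (os_base_hazard * mult))
        prog_t = rng.exponential(1.0 / (pfs_base_hazard * mult))
        pfs_t = min(prog_t, os_t)
        os_days = min(os_t, admin_censor_day)
        pfs_days = min(pfs_t, admin_censor_day)
        rows.append(
            {
                "patient_id": p["patient_id"],
                "OS_days": os_days,
                "OS_event": int(os_t <= admin_censor_day),
                "PFS_days": pfs_days,
                "PFS_event": int(pfs_t <= admin_censor_day),
            }
        )
    return pd.DataFrame(rows)


def default_gene_sets(n_marker: int = 25) -> dict[str, list[str]]:
    """Disjoint synthetic classical/basal marker lists (stand-ins for the
    published Moffitt-style signatures, which are external inputs)."""
    return {
        "classical_markers": [f"CLA{i:03d}" for i in range(n_marker)],
        "basal_markers": [f"BAS{i:03d}" for i in range(n_marker)],
    }


def simulate_expression_matrix(
    n_samples: int,
    subtype_labels: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    effect_size: float,
    rng: np.random.Generator,
    *,
    n_background_genes: int = 200,
    sample_ids: Sequence[str] | None = None,
    mode: str = "vst",
) -> pd.DataFrame:
    """Two-subtype expression matrix (genes x samples).

    Marker genes are shifted by ``effect_size`` (in noise-sd units) in
    samples of their subtype; background genes are iid noise. In ``tpm``
    mode values are exponentiated so the matrix is strictly positive.
    """
    classical = list(gene_sets["classical_markers"])
    basal = list(gene_sets["basal_markers"])
    if set(classical) & set(basal):
        raise PdackitError("classical and basal marker lists must be disjoint")
    if len(subtype_labels) != n_samples:
        raise PdackitError("subtype_labels length must equal n_samples")
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    labels = np.asarray(subtype_labels)
    genes = classical + basal + [f"BG{i:04d}" for i in range(n_background_genes)]
    values = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    values[: len(classical), labels == "classical"] += effect_size
    values[len(classical) : len(classical) + len(basal), labels == "basal-like"] += effect_size
    if mode == "tpm":
        values = np.exp(values)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)


def simulate_immune_panel(
    patients: pd.DataFrame,
    populations: Sequence[str],
    effect_map: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
    *,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Long-format immune panel over the sampling days C1D1..C2D1.

    ``effect_map`` maps population -> {stratum -> multiplier}, with
    strata ``responder``/``non_responder``/``all``; the multiplier is
    applied to post-dose (after C1D1) values of matching patients.
    Frequencies are percentages clipped to [0, 100].
    """
    for pop, strata in effect_map.items():
        if pop not in populations:
            raise PdackitError(f"effect_map population {pop!r} not simulated")
        for s in strata:
            if s not in ("responder", "non_responder", "all"):
                raise PdackitError(f"unknown stratum {s!r} in effect_map")
    rows = []
    for _, p in patients.iterrows():
        stratum = "responder" if p["is_responder"] else "non_responder"
        for pop in populations:
            baseline = float(np.clip(np.exp(rng.normal(math.log(5.0), 0.6)), 0.01, 100.0))
            mult = effect_map.get(pop, {})
            eff = mult.get(stratum, mult.get("all", 1.0))
            for day in IMMUNE_DAYS:
                value = baseline
                if day != "C1D1":
                    value = baseline * eff * math.exp(rng.normal(0.0, noise_sd))
                rows.append(
                    {
                        "patient_id": p["patient_id"],
                        "day": day,
                        "population": pop,
                        "frequency": float(np.clip(value, 0.0, 100.0)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_predictor_labels(
    truth_flags: Sequence[bool],
    sensitivity: float,
    specificity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Molecular-call flags with a set concordance to a truth label.

    Positives are called with probability ``sensitivity``; negatives are
    called negative with probability ``specificity``. Used to test that
    the evaluation module recovers the generative operating point.
    """
    truth = np.asarray(truth_flags, dtype=bool)
    u = rng.random(truth.shape)
    return np.where(truth, u < sensitivity, u >= specificity)


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort bundle per the config; deterministic in the seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    # one stream per patient (by counter) + cohort-level streams
    children = ss.spawn(config.n_patients + 2)
    expr_rng = np.random.default_rng(children[config.n_patients])
    cohort_rng = np.random.default_rng(children[config.n_patients + 1])

    probs = np.array([config.genotype_probs.get(g, 0.0) for g in GENOTYPES])
    mu_sld, sd_sld = config.baseline_sld_mm

    truths: list[PatientTruth] = []
    sld_frames, ct_frames = [], []
    patient_rows = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i:04d}"
        genotype = GENOTYPES[rng.choice(len(GENOTYPES), p=probs)]
        is_resp = bool(rng.random() < config.response_prob)
        base_rate = (
            config.growth_rate_responder if is_resp else config.growth_rate_progressor
        )
        rate = base_rate + rng.normal(0.0, config.growth_rate_sd)
        baseline_sld = float(np.exp(rng.normal(mu_sld, sd_sld)))
        beta = max(config.coupling_slope_beta + rng.normal(0.0, config.coupling_slope_sd), 1e-3)
        alpha = rng.normal(config.coupling_intercept_log10, config.coupling_intercept_sd)
        truth = PatientTruth(
            patient_id=pid,
            genotype=genotype,
            is_responder=is_resp,
            baseline_sld=baseline_sld,
            growth_rate=rate,
            true_alpha=alpha,
            true_beta=beta,
        )
        truths.append(truth)

        sld_df = simulate_sld_trajectory(
            truth,
            config.sld_visit_days,
            two_phase=config.two_phase,
            switch_day=config.switch_day,
            regrowth_rate=config.regrowth_rate,
        )
        sld_frames.append(sld_df)

        # ctDNA drawn on its own (denser) schedule from the same trajectory
        ct_sld = simulate_sld_trajectory(
            truth,
            config.visit_days,
            two_phase=config.two_phase,
            switch_day=config.switch_day,
            regrowth_rate=config.regrowth_rate,
        )
        if genotype == "WT":
            days = ct_sld["day"].to_numpy(dtype=float)
            maf = np.abs(rng.normal(0.0, config.wt_background_maf_sd, len(days)))
            detected = maf >= config.detection_floor_pct
            maf = np.where(detected, maf, 0.0)
            total = 5000.0 * np.exp(rng.normal(0.0, 0.5, len(days)))
            ct_df = pd.DataFrame(
                {
                    "patient_id": pid,
                    "day": days,
                    "mutant_conc": total * (maf / 100.0),
                    "total_conc": total,
                    "maf_pct": maf,
                    "detected": detected,
                }
            )
        else:
            ct_df = simulate_ctdna_from_sld(
                ct_sld,
                truth.true_beta,
                truth.true_alpha,
                config.maf_noise_sd,
                config.detection_floor_pct,
                rng,
            )
        ct_frames.append(ct_df)

        recist = derive_recist_labels(sld_df)
        if recist.progression_day is not None:
            # patients discontinue at radiological progression: no further
            # scans or blood draws after the PD visit
            sld_df = sld_df[sld_df["day"] <= recist.progression_day]
            ct_df = ct_df[ct_df["day"] <= recist.progression_day]
            sld_frames[-1] = sld_df
            ct_frames[-1] = ct_df
        patient_rows.append(
            {
                "patient_id": pid,
                "genotype": genotype,
                "is_responder": is_resp,
                "bor": recist.bor,
                "response_day": recist.response_day,
                "progression_day": recist.progression_day,
            }
        )

    patients = pd.DataFrame(patient_rows)
    truth_df = pd.DataFrame([t.__dict__ for t in truths])

    survival = simulate_survival(
        truth_df,
        config.survival_link,
        config.admin_censor_day,
        cohort_rng,
        os_base_hazard=config.os_base_hazard,
        pfs_base_hazard=config.pfs_base_hazard,
    )

    gene_sets = default_gene_sets(config.n_marker_genes)
    subtype_labels = np.where(
        cohort_rng.random(config.n_patients) < 0.5, "classical", "basal-like"
    )
    expression = simulate_expression_matrix(
        config.n_patients,
        subtype_labels,
        gene_sets,
        config.expression_effect_size,
        expr_rng,
        n_background_genes=config.n_background_genes,
        sample_ids=patients["patient_id"].tolist(),
    )
    truth_df["true_subtype"] = subtype_labels

    immune = simulate_immune_panel(
        patients, DEFAULT_IMMUNE_POPULATIONS, config.immune_effect_map, cohort_rng
    )

    return CohortBundle(
        patients=patients,
        sld=pd.concat(sld_frames, ignore_index=True),
        ctdna=pd.concat(ct_frames, ignore_index=True),
        immune=immune,
        survival=survival,
        truth=truth_df,
        expression=expression,
        gene_sets=gene_sets,
        config=config,
    )


def null_config(**overrides) -> CohortConfig:
    """Config with every injected effect switched off (null calibration)."""
    base = CohortConfig(
        growth_rate_responder=0.0,
        growth_rate_progressor=0.0,
        growth_rate_sd=0.0,
        survival_link={"responder": 1.0, "non_responder": 1.0},
        expression_effect_size=0.0,
        immune_effect_map={},
    )
    return replace(base, **overrides)
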