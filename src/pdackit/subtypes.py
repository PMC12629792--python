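"""Transcriptomic subtyping (classical vs basal-like) and gene-set scoring.

The subtype caller reproduces the standard PDAC workflow: z-score the
signature genes across samples, project into PCA space, K-means with k=2,
then map clusters to labels by mean classical-marker z-score. Gene-set
activity is scored per sample with ssGSEA (rank-weighted ECDF difference,
Barbie-style) and dichotomised at the cohort median (high: > median).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._util import InsufficientDataError, PdackitError, logger

N_KMEANS_RESTARTS = 50


def zscore_transform(
    matrix: pd.DataFrame, gene_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene z-score across samples (ddof=1).

    Restricted to ``gene_subset`` when given; genes absent from the
    matrix are logged and skipped, zero-variance genes are dropped with a
    warning.
    """
    if gene_subset is not None:
        present = [g for g in gene_subset if g in matrix.index]
        missing = sorted(set(gene_subset) - set(present))
        if missing:
            logger.info("%d signature genes absent from matrix: %s", len(missing), missing[:5])
        matrix = matrix.loc[present]
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes", stacklevel=2)
    values = values[keep]
    sd = sd[keep]
    mean = values.mean(axis=1, keepdims=True)
    z = (values - mean) / sd[:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def classify_molecular_subtype(
    matrix: pd.DataFrame,
    classical_genes: Sequence[str],
    basal_genes: Sequence[str],
    n_pcs: int = 2,
    k: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign classical / basal-like labels by K-means in PCA space.

    The signature genes (union of both lists) are z-scored, projected on
    the first ``n_pcs`` principal components, and clustered with k-means
    (k=2, k-means++ with 50 restarts, fixed seed). The cluster whose
    samples have the higher mean z-score over the classical markers is
    labelled "classical".
    """
    if matrix.shape[1] < k:
        raise InsufficientDataError(f"need >= {k} samples")
    signature = list(dict.fromkeys(list(classical_genes) + list(basal_genes)))
    z = zscore_transform(matrix, signature)
    if z.shape[0] < 2:
        raise InsufficientDataError("need >= 2 signature genes present in the matrix")
    n_pcs_eff = min(n_pcs, z.shape[0], z.shape[1])
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n_pcs_eff}", stacklevel=2)
    X = z.to_numpy(dtype=float).T  # samples x genes
    pcs = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=N_KMEANS_RESTARTS, random_state=seed).fit(pcs)
    labels = km.labels_

    classical_present = [g for g in classical_genes if g in z.index]
    if not classical_present:
        raise PdackitError("no classical marker genes present; cannot orient clusters")
    classical_score = z.loc[classical_present].mean(axis=0).to_numpy()
    cluster_means = [classical_score[labels == c].mean() for c in range(k)]
    classical_cluster = int(np.argmax(cluster_means))

    out = pd.DataFrame(
        {
            "sample_id": z.columns,
            "subtype": np.where(labels == classical_cluster, "classical", "basal-like"),
            "cluster_index": labels,
        }
    )
    for j in range(n_pcs_eff):
        out[f"PC{j + 1}"] = pcs[:, j]
    return out


def ssgsea_scores(
    matrix: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample GSEA enrichment scores (rank-weighted ECDF difference).

    Per sample, genes are ranked by expression (highest expression gets
    the largest rank, ties resolved by stable input order); walking down
    the ranked list, the score accumulates the difference between the
    in-set ECDF weighted by rank**alpha and the unweighted out-of-set
    ECDF. With ``normalize=True`` scores are rescaled by the cohort-wide
    max minus min.

    Sets with no gene in the matrix get an undefined (NaN) score, logged.
    """
    n_genes = matrix.shape[0]
    values = matrix.to_numpy(dtype=float)
    gene_index = pd.Index(matrix.index)
    rows = []
    for sample_pos, sample in enumerate(matrix.columns):
        expr = values[:, sample_pos]
        if np.ptp(expr) == 0:
            warnings.warn(f"all-tied expression in sample {sample}; ranks follow input order", stacklevel=2)
        # stable descending order: highest expression first
        order = np.argsort(-expr, kind="stable")
        # rank n_genes for the top gene down to 1
        ranks_desc = np.arange(n_genes, 0, -1, dtype=float)
        for set_name, genes in gene_sets.items():
            in_set_mask = np.asarray(gene_index.isin(set(genes)))[order]
            n_in = int(in_set_mask.sum())
            if n_in == 0:
                logger.info("gene set %s has no overlap with the matrix; score undefined", set_name)
                rows.append({"sample_id": sample, "set_name": set_name, "score": float("nan")})
                continue
            weights = np.where(in_set_mask, ranks_desc**alpha, 0.0)
            ecdf_in = np.cumsum(weights) / weights.sum()
            ecdf_out = np.cumsum(~in_set_mask) / float(n_genes - n_in)
            rows.append(
                {
                    "sample_id": sample,
                    "set_name": set_name,
                    "score": float(np.sum(ecdf_in - ecdf_out)),
                }
            )
    scores = pd.DataFrame(rows)
    if normalize:
        span = scores["score"].max() - scores["score"].min()
        if span > 0:
            scores["score"] = scores["score"] / span
    return scores


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """High/low strata at the cohort median: high iff score > median
    (strict; values equal to the median are low)."""
    if len(scores) < 2:
        raise InsufficientDataError("need >= 2 samples to stratify")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index)


def collapse_to_patients(
    assignments: pd.DataFrame, sample_to_patient: Mapping[str, str]
) -> pd.DataFrame:
    """First-biopsy collapse for survival joins: when a patient has
    several classified samples, keep the first by sample ID order."""
    df = assignments.copy()
    df["patient_id"] = df["sample_id"].map(sample_to_patient)
    df = df.sort_values("sample_id").drop_duplicates("patient_id", keep="first")
    return df.reset_index(drop=True)
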