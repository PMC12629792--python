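"""Cohort table I/O: schema-validated CSV/TSV loading, GMT parsing, bundle writing."""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import SchemaError, logger
from .kinetics import compute_maf
from .simulate import CohortBundle

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "genotype"],
    "sld": ["patient_id", "day", "sld_mm"],
    "ctdna": ["patient_id", "day", "mutant_conc", "total_conc"],
    "immune": ["patient_id", "day", "population", "frequency"],
    "survival": ["patient_id", "OS_days", "OS_event", "PFS_days", "PFS_event"],
}
KEY_COLUMNS = {
    "patients": ["patient_id"],
    "sld": ["patient_id", "day"],
    "ctdna": ["patient_id", "day"],
    "immune": ["patient_id", "day", "population"],
    "survival": ["patient_id"],
}
NUMERIC_COLUMNS = {
    "sld": ["day", "sld_mm"],
    "ctdna": ["day", "mutant_conc", "total_conc"],
    "immune": ["frequency"],
    "survival": ["OS_days", "OS_event", "PFS_days", "PFS_event"],
}


def _validate(name: str, df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column {col!r}")
    for col in NUMERIC_COLUMNS.get(name, []):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{name}: non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row + 2}"
            )
        df[col] = coerced
    keys = KEY_COLUMNS[name]
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise SchemaError(
            f"{name}: duplicate key {tuple(df.loc[df.index[row], keys])} at row {row + 2}"
        )
    return df


def load_table(path: str, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _validate(name, df)
    logger.info("%s: loaded %d rows from %s", name, len(df), path)
    return df


def load_expression(path: str) -> pd.DataFrame:
    """genes x samples TSV, first column gene IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise SchemaError("expression: duplicate gene IDs")
    if df.columns.duplicated().any():
        raise SchemaError("expression: duplicate sample IDs")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise SchemaError("expression: non-finite values")
    return df


def parse_gmt(path: str) -> dict[str, list[str]]:
    """Standard GMT dialect: name <tab> description <tab> gene IDs.

    Duplicate genes within a set are removed with a warning; a line with
    fewer than three fields is a parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"gmt: malformed line {lineno}: expected >= 3 tab-separated fields")
            name, _desc, genes = fields[0], fields[1], fields[2:]
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < len([g for g in genes if g]):
                logger.warning("gmt: duplicated genes in set %s deduplicated", name)
            sets[name] = unique
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def load_cohort(directory: str) -> CohortBundle:
    """Load a cohort bundle from a directory of tables.

    Required: patients.csv, sld.csv, ctdna.csv, survival.csv. Optional:
    immune.csv, truth.csv, expression.tsv, genesets.gmt. The ctDNA table
    gains a ``maf_pct`` column (recomputed when absent; checked against
    the copy concentrations when present) and a ``detected`` flag.
    """
    def p(name: str) -> str:
        return os.path.join(directory, name)

    patients = load_table(p("patients.csv"), "patients")
    sld = load_table(p("sld.csv"), "sld")
    ctdna = load_table(p("ctdna.csv"), "ctdna")
    survival = load_table(p("survival.csv"), "survival")
    immune = (
        load_table(p("immune.csv"), "immune") if os.path.exists(p("immune.csv")) else pd.DataFrame()
    )
    truth = pd.read_csv(p("truth.csv")) if os.path.exists(p("truth.csv")) else pd.DataFrame()

    maf = compute_maf(ctdna["mutant_conc"].to_numpy(), ctdna["total_conc"].to_numpy())
    if "maf_pct" in ctdna.columns:
        given = ctdna["maf_pct"].to_numpy(dtype=float)
        if np.any(np.abs(given - maf) > 1e-9):
            raise SchemaError("ctdna: maf_pct inconsistent with copy concentrations")
    ctdna["maf_pct"] = maf
    if "detected" not in ctdna.columns:
        ctdna["detected"] = ctdna["maf_pct"] > 0
    else:
        ctdna["detected"] = ctdna["detected"].astype(bool)

    known = set(patients["patient_id"])
    for name, df in (("sld", sld), ("ctdna", ctdna), ("survival", survival)):
        unknown = set(df["patient_id"]) - known
        if unknown:
            raise SchemaError(f"{name}: patient_ids not in patients.csv: {sorted(unknown)[:5]}")

    expression = (
        load_expression(p("expression.tsv")) if os.path.exists(p("expression.tsv")) else pd.DataFrame()
    )
    gene_sets = parse_gmt(p("genesets.gmt")) if os.path.exists(p("genesets.gmt")) else {}

    return CohortBundle(
        patients=patients,
        sld=sld,
        ctdna=ctdna,
        immune=immune,
        survival=survival,
        truth=truth,
        expression=expression,
        gene_sets=gene_sets,
        config=None,
    )


def write_cohort(bundle: CohortBundle, directory: str) -> None:
    """Write the bundle as the standard directory of text tables."""
    os.makedirs(directory, exist_ok=True)
    for name in ("patients", "sld", "ctdna", "immune", "survival", "truth"):
        df = getattr(bundle, name)
        if df is not None and len(df):
            df.to_csv(os.path.join(directory, f"{name}.csv"), index=False)
    if bundle.expression is not None and len(bundle.expression):
        bundle.expression.to_csv(os.path.join(directory, "expression.tsv"), sep="\t")
    if bundle.gene_sets:
        write_gmt(bundle.gene_sets, os.path.join(directory, "genesets.gmt"))
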