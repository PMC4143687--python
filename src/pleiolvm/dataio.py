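"""Readers, writers and phenotype preprocessing.

File formats (all plain text):

* phenotype long table — CSV with header ``family_id, individual_id, visit,
  age, <phenotype columns>, <covariate columns>`` (one row per visit);
* genotype table — CSV with header ``individual_id, snp_id, dosage`` (additive
  minor-allele counts 0/1/2);
* truth sidecar — JSON holding the generating parameters and latent arrays
  (written by the simulator only).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LongFamilyDataset
from .model import ThetaState

logger = logging.getLogger("pleiolvm")

__all__ = [
    "adjust_for_medication",
    "code_genotype_additive",
    "write_dataset",
    "load_dataset",
]


def adjust_for_medication(sbp, dbp, on_medication):
    """Medication adjustment for treated blood pressures: +15 SBP, +10 DBP.

    Accepts scalars or arrays; a missing (NaN) medication flag leaves the
    record unchanged and logs a warning.  Applied per visit, so an individual
    treated at some visits only is adjusted only at those visits.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(on_medication, dtype=float)
    missing = np.isnan(med)
    if np.any(missing):
        logger.warning(
            "medication flag missing for %d record(s); passed through unadjusted",
            int(np.sum(missing)),
        )
    on = (med == 1) & ~missing
    sbp_adj = np.where(on, sbp + 15.0, sbp)
    dbp_adj = np.where(on, dbp + 10.0, dbp)
    if sbp_adj.ndim == 0:
        return float(sbp_adj), float(dbp_adj)
    return sbp_adj, dbp_adj


def code_genotype_additive(genotypes, minor_allele: str | None = None,
                           snp_id: str = "?"):
    """Additive coding: count of minor alleles in {0, 1, 2}.

    ``genotypes`` may already be numeric dosages (validated and passed through)
    or allele-pair strings such as ``"AG"``, ``"A/G"`` or ``"A|G"``, in which
    case ``minor_allele`` is required.  Missing values stay missing.
    """
    arr = np.asarray(genotypes)
    if arr.dtype.kind in "if":
        vals = arr.astype(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not np.all(ok):
            raise ValueError(f"SNP {snp_id}: dosages must be 0, 1, 2 or missing")
        return vals if vals.ndim else float(vals)
    if minor_allele is None:
        raise ValueError(f"SNP {snp_id}: minor_allele is required for allele-pair genotypes")
    scalar = arr.ndim == 0
    out = np.full(arr.size if not scalar else 1, np.nan)
    flat = np.atleast_1d(arr)
    alleles_seen: set[str] = set()
    for i, g in enumerate(flat):
        if g is None or (isinstance(g, float) and np.isnan(g)) or g == "":
            continue
        pair = [c for c in str(g) if c.isalpha()]
        if len(pair) != 2:
            raise ValueError(f"SNP {snp_id}: cannot parse genotype {g!r}")
        alleles_seen.update(pair)
        out[i] = sum(1 for c in pair if c == minor_allele)
    if len(alleles_seen) > 2:
        raise ValueError(
            f"SNP {snp_id}: more than two alleles observed ({sorted(alleles_seen)}); "
            "only biallelic sites are supported"
        )
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# dataset round trip
# ---------------------------------------------------------------------------


def write_dataset(dataset: LongFamilyDataset, outdir, snp_columns=("snp",)) -> dict[str, Path]:
    """Write phenotype, genotype and (optional) truth files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    non_snp = [c for c in dataset.covariates.columns if c not in snp_columns]
    pheno = pd.concat(
        [dataset.meta.reset_index(drop=True),
         dataset.phenotypes.reset_index(drop=True),
         dataset.covariates[non_snp].reset_index(drop=True)],
        axis=1,
    )
    paths["phenotypes"] = outdir / "phenotypes.csv"
    pheno.to_csv(paths["phenotypes"], index=False)

    geno_rows = []
    first = dataset.meta.groupby("individual_id", sort=False).head(1).index
    for snp in snp_columns:
        if snp not in dataset.covariates.columns:
            continue
        for i in first:
            geno_rows.append({
                "individual_id": dataset.meta.loc[i, "individual_id"],
                "snp_id": snp,
                "dosage": dataset.covariates.loc[i, snp],
            })
    paths["genotypes"] = outdir / "genotypes.csv"
    pd.DataFrame(geno_rows, columns=["individual_id", "snp_id", "dosage"]).to_csv(
        paths["genotypes"], index=False
    )

    if dataset.truth is not None:
        truth = dataset.truth
        theta: ThetaState = truth["theta"]
        latent = truth["latent"]
        payload = {
            "theta": {
                "beta0": theta.beta0.tolist(), "beta": theta.beta.tolist(),
                "alpha": theta.alpha.tolist(), "lam": theta.lam.tolist(),
                "tau2": theta.tau2.tolist(), "sigma2": theta.sigma2.tolist(),
                "sigma_a2": theta.sigma_a2, "sigma_d2": theta.sigma_d2,
            },
            "latent": {
                "U": latent.U.tolist(), "a": latent.a.tolist(),
                "d": latent.d.tolist(), "b": latent.b.tolist(),
            },
            "spec": truth["spec"].to_dict() if "spec" in truth else None,
        }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(payload))
    return paths


def load_dataset(phenotype_csv, genotype_csv=None, phenotype_names=None,
                 covariate_names=None, on_missing_genotype: str = "drop") -> LongFamilyDataset:
    """Load a long-format dataset from the CSV files written by this package.

    Rows with no phenotype value at all are dropped (count logged); visit
    indices are rebuilt consecutively per individual; individuals present in
    the phenotype file but absent from the genotype file are dropped or raise
    depending on ``on_missing_genotype`` ("drop" | "fail").
    """
    df = pd.read_csv(phenotype_csv)
    for col in ("family_id", "individual_id", "visit"):
        if col not in df.columns:
            raise ValueError(f"phenotype file missing required column {col!r}")
    reserved = {"family_id", "individual_id", "visit", "age"}
    other = [c for c in df.columns if c not in reserved]
    if phenotype_names is None:
        raise ValueError("phenotype_names must name the phenotype columns")
    phenotype_names = list(phenotype_names)
    missing = [c for c in phenotype_names if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype columns not found in file: {missing}")
    if covariate_names is None:
        covariate_names = [c for c in other if c not in phenotype_names]
    covariate_names = list(covariate_names)
    if "age" in df.columns and "age" not in covariate_names and "age" not in phenotype_names:
        covariate_names = covariate_names + ["age"]

    no_pheno = df[phenotype_names].isna().all(axis=1)
    if no_pheno.any():
        logger.info("dropping %d record(s) with no phenotype at all", int(no_pheno.sum()))
        df = df.loc[~no_pheno]

    snp_cols: list[str] = []
    if genotype_csv is not None:
        geno = pd.read_csv(genotype_csv)
        for col in ("individual_id", "snp_id", "dosage"):
            if col not in geno.columns:
                raise ValueError(f"genotype file missing required column {col!r}")
        wide = geno.pivot_table(index="individual_id", columns="snp_id",
                                values="dosage", aggfunc="first")
        snp_cols = list(wide.columns)
        absent = ~df["individual_id"].isin(wide.index)
        if absent.any():
            msg = (f"{df.loc[absent, 'individual_id'].nunique()} individual(s) in the "
                   f"phenotype file have no genotype record")
            if on_missing_genotype == "fail":
                raise ValueError(msg)
            logger.warning("%s; dropped", msg)
            df = df.loc[~absent]
        for snp in snp_cols:
            df[snp] = df["individual_id"].map(wide[snp])
            code_genotype_additive(df[snp].to_numpy(), snp_id=snp)  # validation
        covariate_names = covariate_names + [c for c in snp_cols if c not in covariate_names]

    df = df.sort_values(["family_id", "individual_id", "visit"],
                        kind="stable").reset_index(drop=True)
    df["visit"] = df.groupby(["family_id", "individual_id"]).cumcount() + 1

    meta_cols = ["family_id", "individual_id", "visit"] + (["age"] if "age" in df.columns else [])
    ds = LongFamilyDataset(
        meta=df[meta_cols].copy(),
        phenotypes=df[phenotype_names].copy(),
        covariates=df[[c for c in covariate_names if c in df.columns]].copy(),
    )
    logger.info("loaded dataset: %s", ds.summary())
    return ds
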