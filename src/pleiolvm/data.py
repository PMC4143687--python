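"""Long-format longitudinal family dataset and its fitting view.

A :class:`LongFamilyDataset` stores one row per (family, individual, visit)
record: phenotype values (continuous and/or binary), covariate values (both
roles, including the SNP dosage), and the indexing columns.  The partition of
covariates into direct (W) and indirect (X) is a property of a
:class:`~pleiolvm.model.ModelSpec`, not of the data, so the same dataset can be
fit under every cell of a covariate-placement model grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSpec

__all__ = ["LongFamilyDataset", "FitData"]

META_COLUMNS = ("family_id", "individual_id", "visit")


@dataclass
class FitData:
    """Numpy view of a dataset under a fixed ModelSpec, ready for the sampler.

    Missing phenotype cells are carried as NaN with companion boolean masks;
    ``fam_idx`` / ``ind_idx`` map records to family / individual codes and
    ``ind_fam`` maps individual codes to family codes.
    """

    spec: ModelSpec
    y_cont: np.ndarray      # (n, J1) float, NaN = missing
    cont_mask: np.ndarray   # (n, J1) bool, True = observed
    y_bin: np.ndarray       # (n, J2) float in {0,1,NaN}
    bin_mask: np.ndarray    # (n, J2) bool
    W: np.ndarray           # (n, p1)
    X: np.ndarray           # (n, p2)
    fam_idx: np.ndarray     # (n,) int codes 0..C-1
    ind_idx: np.ndarray     # (n,) int codes 0..M-1
    ind_fam: np.ndarray     # (M,) family code of each individual

    def __post_init__(self) -> None:
        self.n = len(self.fam_idx)
        self.C = int(self.fam_idx.max()) + 1 if self.n else 0
        self.M = len(self.ind_fam)
        self.n_records_per_family = np.bincount(self.fam_idx, minlength=self.C)
        self.n_records_per_individual = np.bincount(self.ind_idx, minlength=self.M)
        # NaN-free copies for residual arithmetic (masks carry the missingness)
        self.y_cont_filled = np.where(self.cont_mask, np.nan_to_num(self.y_cont), 0.0)
        self.y_bin_filled = np.where(self.bin_mask, np.nan_to_num(self.y_bin), 0.0)


class LongFamilyDataset:
    """Observed longitudinal family data in long format.

    Parameters
    ----------
    meta
        DataFrame with columns family_id, individual_id, visit (1-based,
        consecutive within individual) and optionally age or other bookkeeping.
    phenotypes
        DataFrame (same row order) with one column per phenotype; NaN = missing.
    covariates
        DataFrame (same row order) with one column per covariate, including the
        SNP dosage column (values in {0, 1, 2}).
    truth
        Optional generating truth (ThetaState, latent arrays) kept by the
        simulator for recovery tests.
    """

    def __init__(self, meta: pd.DataFrame, phenotypes: pd.DataFrame,
                 covariates: pd.DataFrame, truth: dict | None = None) -> None:
        if not all(c in meta.columns for c in META_COLUMNS):
            raise ValueError(f"meta must contain columns {META_COLUMNS}")
        if not (len(meta) == len(phenotypes) == len(covariates)):
            raise ValueError("meta, phenotypes and covariates must have equal length")
        self.meta = meta.reset_index(drop=True)
        self.phenotypes = phenotypes.reset_index(drop=True)
        self.covariates = covariates.reset_index(drop=True)
        self.truth = truth
        self._validate()

    # -- structure ----------------------------------------------------------
    def _validate(self) -> None:
        key = self.meta[["family_id", "individual_id"]].astype(str).agg("|".join, axis=1)
        for ind, grp in self.meta.groupby(key.values, sort=False):
            visits = np.sort(grp["visit"].to_numpy())
            if not np.array_equal(visits, np.arange(1, len(visits) + 1)):
                raise ValueError(
                    f"visit indices for individual {ind} must be consecutive from 1, got {visits}"
                )

    @property
    def n_records(self) -> int:
        return len(self.meta)

    @property
    def n_families(self) -> int:
        return self.meta["family_id"].nunique()

    @property
    def n_individuals(self) -> int:
        return len(self.meta.groupby(["family_id", "individual_id"]).size())

    def visit_histogram(self) -> pd.Series:
        """Number of individuals having 1, 2, ... visits."""
        per_ind = self.meta.groupby(["family_id", "individual_id"])["visit"].max()
        return per_ind.value_counts().sort_index()

    def family_sizes(self) -> pd.Series:
        per_fam = self.meta.groupby("family_id")["individual_id"].nunique()
        return per_fam

    def summary(self) -> str:
        hist = self.visit_histogram()
        sizes = self.family_sizes()
        hist_txt = ", ".join(f"{int(c)} with {int(v)}" for v, c in hist.items())
        return (
            f"{self.n_records} records; {self.n_individuals} individuals in "
            f"{self.n_families} families (sizes {int(sizes.min())}-{int(sizes.max())}); "
            f"visit counts: {hist_txt}"
        )

    # -- fitting view -------------------------------------------------------
    def design(self, spec: ModelSpec) -> FitData:
        """Build the numpy fitting view for one ModelSpec."""
        for name in spec.phenotypes:
            if name not in self.phenotypes.columns:
                raise KeyError(f"phenotype {name!r} not found in dataset")
        for name in spec.direct_covariates + spec.indirect_covariates:
            if name not in self.covariates.columns:
                raise KeyError(f"covariate {name!r} not found in dataset")

        fam_codes, fam_idx = np.unique(self.meta["family_id"].to_numpy(), return_inverse=True)
        ind_key = (
            self.meta["family_id"].astype(str) + "|" + self.meta["individual_id"].astype(str)
        ).to_numpy()
        # stable individual order: order of first appearance
        _, first, ind_idx = np.unique(ind_key, return_index=True, return_inverse=True)
        order = np.argsort(np.argsort(first))
        ind_idx = order[ind_idx]
        M = len(first)
        ind_fam = np.zeros(M, dtype=int)
        ind_fam[ind_idx] = fam_idx

        n = self.n_records
        y_cont = (
            self.phenotypes[list(spec.continuous_phenotypes)].to_numpy(dtype=float)
            if spec.J1 else np.zeros((n, 0))
        )
        y_bin = (
            self.phenotypes[list(spec.binary_phenotypes)].to_numpy(dtype=float)
            if spec.J2 else np.zeros((n, 0))
        )
        bad = y_bin[~np.isnan(y_bin)]
        if bad.size and not np.all(np.isin(bad, (0.0, 1.0))):
            raise ValueError("binary phenotype values must be 0, 1 or missing")
        W = (
            self.covariates[list(spec.direct_covariates)].to_numpy(dtype=float)
            if spec.p1 else np.zeros((n, 0))
        )
        X = (
            self.covariates[list(spec.indirect_covariates)].to_numpy(dtype=float)
            if spec.p2 else np.zeros((n, 0))
        )
        if spec.snp_name is not None:
            snp = self.covariates[spec.snp_name].to_numpy(dtype=float)
            ok = np.isnan(snp) | np.isin(snp, (0.0, 1.0, 2.0))
            if not np.all(ok):
                raise ValueError(f"SNP column {spec.snp_name!r} must contain dosages 0/1/2")
        return FitData(
            spec=spec,
            y_cont=y_cont,
            cont_mask=~np.isnan(y_cont),
            y_bin=y_bin,
            bin_mask=~np.isnan(y_bin),
            W=np.nan_to_num(W),
            X=np.nan_to_num(X),
            fam_idx=fam_idx.astype(int),
            ind_idx=ind_idx.astype(int),
            ind_fam=ind_fam,
        )

    def equals(self, other: "LongFamilyDataset") -> bool:
        try:
            pd.testing.assert_frame_equal(self.meta, other.meta, check_dtype=False)
            pd.testing.assert_frame_equal(self.phenotypes, other.phenotypes, check_dtype=False)
            pd.testing.assert_frame_equal(self.covariates, other.covariates, check_dtype=False)
        except AssertionError:
            return False
        return True
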