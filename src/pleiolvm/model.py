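"""Model containers, priors and density evaluations for the latent-variable model.

The model links J observed phenotypes (J1 continuous, J - J1 binary), measured
repeatedly on members of families, to a scalar latent severity U:

    continuous:  y_citj = beta0_j + W_cit' beta_j + lam_j * U_cit + b_cij + e_citj,
                 e_citj ~ N(0, sigma_j^2)
    binary:      eta_citj = beta0_j + W_cit' beta_j + lam_j * U_cit + b_cij + e_citj,
                 e_citj ~ N(0, 1),  y_citj = 1{eta_citj > 0}   (probit link)
    structural:  U_cit = X_cit' alpha + a_c + d_ci + eps_cit,  eps_cit ~ N(0, 1)

with a_c ~ N(0, sigma_a2) (family), d_ci ~ N(0, sigma_d2) (individual, serial),
b_cij ~ N(0, tau_j^2) (individual-by-phenotype).  The residual variance of the
structural equation is fixed at 1 to set the latent scale; the sign is fixed by
constraining the first loading lam_1 > 0.  Direct covariates W act on phenotypes
individually; indirect covariates X act only through U, so a genetic covariate in
X with a nonzero coefficient is pleiotropic by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, ndtr

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "ThetaState",
    "LatentState",
    "folded_t_logpdf",
    "loglik_complete",
    "logprior",
    "loglik_observed_pointwise",
    "loglik_marginal_u_pointwise",
    "loglik_subject_pointwise",
    "loglik_family_pointwise",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which phenotypes are modelled and how covariates are partitioned.

    ``direct_covariates`` enter the measurement equations (W); the
    ``indirect_covariates`` enter the structural equation for U (X).  The two
    sets must be disjoint for the model to be identified.  ``snp_name`` marks
    the indirect covariate whose coefficient carries the pleiotropy test.
    """

    continuous_phenotypes: tuple[str, ...]
    binary_phenotypes: tuple[str, ...] = ()
    direct_covariates: tuple[str, ...] = ()
    indirect_covariates: tuple[str, ...] = ()
    snp_name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "continuous_phenotypes", tuple(self.continuous_phenotypes))
        object.__setattr__(self, "binary_phenotypes", tuple(self.binary_phenotypes))
        object.__setattr__(self, "direct_covariates", tuple(self.direct_covariates))
        object.__setattr__(self, "indirect_covariates", tuple(self.indirect_covariates))
        overlap = set(self.direct_covariates) & set(self.indirect_covariates)
        if overlap:
            raise ValueError(
                f"direct and indirect covariate sets must be disjoint; shared: {sorted(overlap)}"
            )
        if self.J < 1:
            raise ValueError("at least one phenotype is required")
        dup = [p for p in self.continuous_phenotypes if p in self.binary_phenotypes]
        if dup:
            raise ValueError(f"phenotype listed as both continuous and binary: {dup}")

    # -- dimensions ---------------------------------------------------------
    @property
    def phenotypes(self) -> tuple[str, ...]:
        return self.continuous_phenotypes + self.binary_phenotypes

    @property
    def J(self) -> int:
        return len(self.continuous_phenotypes) + len(self.binary_phenotypes)

    @property
    def J1(self) -> int:
        return len(self.continuous_phenotypes)

    @property
    def J2(self) -> int:
        return len(self.binary_phenotypes)

    @property
    def p1(self) -> int:
        return len(self.direct_covariates)

    @property
    def p2(self) -> int:
        return len(self.indirect_covariates)

    def validate_for_pleiotropy(self) -> None:
        """Checks required before a SNP-level pleiotropy test is meaningful."""
        if self.J < 2:
            raise ValueError("pleiotropy requires at least 2 phenotypes (J >= 2)")
        if self.snp_name is None:
            raise ValueError("snp_name must be set for a pleiotropy test")
        if self.snp_name not in self.indirect_covariates:
            raise ValueError(
                f"snp_name {self.snp_name!r} must be one of the indirect covariates "
                f"{self.indirect_covariates}"
            )

    def with_roles(
        self, direct: Sequence[str], indirect: Sequence[str]
    ) -> "ModelSpec":
        """Same phenotypes, new direct/indirect partition (one model-grid cell)."""
        snp = self.snp_name if self.snp_name in tuple(indirect) else None
        return ModelSpec(
            self.continuous_phenotypes,
            self.binary_phenotypes,
            tuple(direct),
            tuple(indirect),
            snp_name=snp,
        )

    def to_dict(self) -> dict:
        return {
            "continuous_phenotypes": list(self.continuous_phenotypes),
            "binary_phenotypes": list(self.binary_phenotypes),
            "direct_covariates": list(self.direct_covariates),
            "indirect_covariates": list(self.indirect_covariates),
            "snp_name": self.snp_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            tuple(d["continuous_phenotypes"]),
            tuple(d.get("binary_phenotypes", ())),
            tuple(d.get("direct_covariates", ())),
            tuple(d.get("indirect_covariates", ())),
            d.get("snp_name"),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the model parameters.

    * loadings lam_j: folded-t with ``loading_df`` degrees of freedom (default 3)
      and scale ``loading_scale`` on the magnitude; the sign of lam_1 is fixed
      positive, the other signs are free.
    * beta_j: N(0, beta_scale^2 I); alpha: N(0, alpha_scale^2 I) (defaults are
      the standard-normal priors); intercepts beta0_j: N(0, beta0_scale^2) with
      a default scale of 100, weak across typical phenotype scales (a tight
      intercept prior biases the latent mean into the indirect coefficients).
    * variance components: conjugate inverse-gamma IG(ig_shape, ig_scale),
      default IG(0.01, 0.01) (vague).
    """

    loading_df: float = 3.0
    loading_scale: float = 1.0
    beta_scale: float = 1.0
    alpha_scale: float = 1.0
    beta0_scale: float = 100.0
    ig_shape: float = 0.01
    ig_scale: float = 0.01

    def __post_init__(self) -> None:
        for name in ("loading_df", "loading_scale", "beta_scale", "alpha_scale",
                     "beta0_scale", "ig_shape", "ig_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PriorSpec.{name} must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# parameter / latent state
# ---------------------------------------------------------------------------


@dataclass
class ThetaState:
    """One full parameter state Theta.

    Shapes: beta0 (J,), beta (J, p1), alpha (p2,), lam (J,), tau2 (J,),
    sigma2 (J1,), sigma_a2 and sigma_d2 scalars.  The structural residual
    variance is a model constant (1), not a field.
    """

    beta0: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    lam: np.ndarray
    tau2: np.ndarray
    sigma2: np.ndarray
    sigma_a2: float
    sigma_d2: float

    def __post_init__(self) -> None:
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.tau2 = np.atleast_1d(np.asarray(self.tau2, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.sigma_a2 = float(self.sigma_a2)
        self.sigma_d2 = float(self.sigma_d2)

    def validate(self, spec: ModelSpec | None = None) -> None:
        for name in ("tau2", "sigma2"):
            v = getattr(self, name)
            if np.any(v <= 0):
                raise ValueError(f"ThetaState.{name} must be strictly positive")
        if self.sigma_a2 <= 0:
            raise ValueError("ThetaState.sigma_a2 must be strictly positive")
        if self.sigma_d2 <= 0:
            raise ValueError("ThetaState.sigma_d2 must be strictly positive")
        if spec is not None:
            J, J1, p1, p2 = spec.J, spec.J1, spec.p1, spec.p2
            checks = {
                "beta0": (self.beta0.shape, (J,)),
                "beta": (self.beta.shape, (J, p1)),
                "alpha": (self.alpha.shape, (p2,)),
                "lam": (self.lam.shape, (J,)),
                "tau2": (self.tau2.shape, (J,)),
                "sigma2": (self.sigma2.shape, (J1,)),
            }
            for name, (got, want) in checks.items():
                if got != want:
                    raise ValueError(
                        f"ThetaState.{name} has shape {got}, expected {want} for this ModelSpec"
                    )

    def copy(self) -> "ThetaState":
        return ThetaState(
            self.beta0.copy(), self.beta.copy(), self.alpha.copy(), self.lam.copy(),
            self.tau2.copy(), self.sigma2.copy(), self.sigma_a2, self.sigma_d2,
        )

    def flat(self, spec: ModelSpec) -> dict[str, float]:
        """Named scalar view, e.g. ``lam[sbp]``, ``beta[sbp,sex]``, ``alpha[age]``."""
        out: dict[str, float] = {}
        for j, p in enumerate(spec.phenotypes):
            out[f"lam[{p}]"] = float(self.lam[j])
        for j, p in enumerate(spec.phenotypes):
            out[f"beta0[{p}]"] = float(self.beta0[j])
        for j, p in enumerate(spec.phenotypes):
            for k, w in enumerate(spec.direct_covariates):
                out[f"beta[{p},{w}]"] = float(self.beta[j, k])
        for k, x in enumerate(spec.indirect_covariates):
            out[f"alpha[{x}]"] = float(self.alpha[k])
        for j, p in enumerate(spec.phenotypes):
            out[f"tau2[{p}]"] = float(self.tau2[j])
        for j, p in enumerate(spec.continuous_phenotypes):
            out[f"sigma2[{p}]"] = float(self.sigma2[j])
        out["sigma_a2"] = self.sigma_a2
        out["sigma_d2"] = self.sigma_d2
        return out


@dataclass
class LatentState:
    """All latent quantities: U (n,), a (C,), d (M,), b (M, J), eta_bin (n, J2)."""

    U: np.ndarray
    a: np.ndarray
    d: np.ndarray
    b: np.ndarray
    eta_bin: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.eta_bin = np.asarray(self.eta_bin, dtype=float)
        if self.eta_bin.ndim == 1:
            self.eta_bin = self.eta_bin.reshape(len(self.U), -1)

    def copy(self) -> "LatentState":
        return LatentState(self.U.copy(), self.a.copy(), self.d.copy(),
                           self.b.copy(), self.eta_bin.copy())


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def folded_t_logpdf(x, df: float, scale: float = 1.0):
    """Log density of the folded Student-t evaluated at the magnitude |x|.

    density(m) = 2 * t_df(m / scale) / scale for m >= 0.
    """
    x = np.abs(np.asarray(x, dtype=float))
    return np.log(2.0) + stats.t.logpdf(x / scale, df) - np.log(scale)


def _measurement_means(theta: ThetaState, latent: LatentState, fit) -> np.ndarray:
    """(n, J) matrix of measurement-equation means beta0 + W'beta + lam*U + b."""
    n = fit.n
    mean = (
        theta.beta0[None, :]
        + (fit.W @ theta.beta.T if fit.W.shape[1] else np.zeros((n, theta.beta0.size)))
        + theta.lam[None, :] * latent.U[:, None]
        + latent.b[fit.ind_idx, :]
    )
    return mean


def _structural_mean(theta: ThetaState, latent: LatentState, fit) -> np.ndarray:
    xa = fit.X @ theta.alpha if fit.X.shape[1] else np.zeros(fit.n)
    return xa + latent.a[fit.fam_idx] + latent.d[fit.ind_idx]


def _as_fit(data, spec: ModelSpec | None):
    from .data import FitData, LongFamilyDataset

    if isinstance(data, FitData):
        return data
    if isinstance(data, LongFamilyDataset):
        if spec is None:
            raise ValueError("a ModelSpec is required when passing a LongFamilyDataset")
        return data.design(spec)
    raise TypeError(f"expected FitData or LongFamilyDataset, got {type(data).__name__}")


def loglik_complete(theta: ThetaState, latent: LatentState, data, spec: ModelSpec | None = None) -> float:
    """Complete-data log likelihood: observed y, augmented eta, latent U and effects.

    Sums Normal log densities of (i) continuous y around their measurement means
    with variances sigma_j^2, (ii) augmented probit variables eta around their
    measurement means with unit variance, (iii) U around the structural mean with
    unit variance, and (iv) a, d, b around zero with their variance components.
    """
    fit = _as_fit(data, spec)
    spec = fit.spec
    theta.validate(spec)
    mean = _measurement_means(theta, latent, fit)
    total = 0.0
    if spec.J1:
        mu = mean[:, : spec.J1]
        resid = fit.y_cont - mu
        var = theta.sigma2[None, :]
        terms = -0.5 * (_LOG_2PI + np.log(var) + resid**2 / var)
        total += float(np.sum(terms[fit.cont_mask]))
    if spec.J2:
        mu = mean[:, spec.J1:]
        resid = latent.eta_bin - mu
        terms = -0.5 * (_LOG_2PI + resid**2)
        total += float(np.sum(terms[fit.bin_mask]))
    # structural
    resid_u = latent.U - _structural_mean(theta, latent, fit)
    total += float(np.sum(-0.5 * (_LOG_2PI + resid_u**2)))
    # random effects
    total += float(np.sum(stats.norm.logpdf(latent.a, scale=np.sqrt(theta.sigma_a2))))
    total += float(np.sum(stats.norm.logpdf(latent.d, scale=np.sqrt(theta.sigma_d2))))
    total += float(
        np.sum(stats.norm.logpdf(latent.b, scale=np.sqrt(theta.tau2)[None, :]))
    )
    return total


def logprior(theta: ThetaState, priors: PriorSpec, spec: ModelSpec | None = None,
             return_blocks: bool = False):
    """Log prior density of Theta under `priors`.

    Folded-t on the loading magnitudes, Gaussian blocks for beta0 / beta / alpha,
    inverse-gamma for every variance component.
    """
    theta.validate(spec)
    blocks: dict[str, float] = {}
    blocks["lam"] = float(np.sum(folded_t_logpdf(theta.lam, priors.loading_df,
                                                 priors.loading_scale)))
    blocks["beta0"] = float(np.sum(stats.norm.logpdf(theta.beta0, scale=priors.beta0_scale)))
    blocks["beta"] = float(np.sum(stats.norm.logpdf(theta.beta, scale=priors.beta_scale)))
    blocks["alpha"] = float(np.sum(stats.norm.logpdf(theta.alpha, scale=priors.alpha_scale)))
    ig = stats.invgamma(priors.ig_shape, scale=priors.ig_scale)
    blocks["variances"] = float(
        np.sum(ig.logpdf(theta.tau2)) + np.sum(ig.logpdf(theta.sigma2))
        + ig.logpdf(theta.sigma_a2) + ig.logpdf(theta.sigma_d2)
    )
    total = float(sum(blocks.values()))
    if return_blocks:
        return total, blocks
    return total


def loglik_observed_pointwise(theta: ThetaState, latent: LatentState, data,
                              spec: ModelSpec | None = None) -> np.ndarray:
    """Per-record observed-data log likelihood conditional on U and b.

    Continuous cells contribute Normal log densities; binary cells contribute
    log Phi(m) or log(1 - Phi(m)) with the probit residual e integrated out of
    the augmented representation.  Missing cells contribute zero.
    """
    fit = _as_fit(data, spec)
    spec = fit.spec
    mean = _measurement_means(theta, latent, fit)
    out = np.zeros(fit.n)
    if spec.J1:
        mu = mean[:, : spec.J1]
        var = theta.sigma2[None, :]
        terms = -0.5 * (_LOG_2PI + np.log(var) + (fit.y_cont - mu) ** 2 / var)
        out += np.sum(np.where(fit.cont_mask, terms, 0.0), axis=1)
    if spec.J2:
        mu = mean[:, spec.J1:]
        y = fit.y_bin
        terms = np.where(y == 1, log_ndtr(mu), log_ndtr(-mu))
        out += np.sum(np.where(fit.bin_mask, terms, 0.0), axis=1)
    return out


def loglik_subject_pointwise(theta: ThetaState, latent: LatentState, data,
                             spec: ModelSpec | None = None) -> np.ndarray:
    """Per-individual log likelihood conditional on (a, d) only.

    The latent factor U, the individual-by-phenotype effects b and the
    measurement noise are all integrated out analytically: given (a_c, d_ci)
    the T_ci x J1 block of continuous phenotypes is multivariate normal with
    mean mu_tj = beta0_j + W't beta_j + lam_j (X't alpha + a_c + d_ci) and
    covariance lam_j lam_j' [t = t'] + tau_j^2 [j = j'] + sigma_j^2 [both].
    This is the focus that can see covariate placement: misfit of an
    individual-constant covariate cannot hide in b here.  Only defined for
    all-continuous phenotype sets.
    """
    fit = _as_fit(data, spec)
    spec = fit.spec
    if spec.J2:
        raise ValueError(
            "the subject-level (U, b)-marginal likelihood is analytic only for "
            "continuous phenotypes; use loglik_marginal_u_pointwise for models "
            "with binary phenotypes"
        )
    J1 = spec.J1
    lam, tau2, sigma2 = theta.lam, theta.tau2, theta.sigma2
    m_u = (fit.X @ theta.alpha if fit.X.shape[1] else np.zeros(fit.n)) \
        + latent.a[fit.fam_idx] + latent.d[fit.ind_idx]
    mu = (
        theta.beta0[None, :]
        + (fit.W @ theta.beta.T if fit.W.shape[1] else 0.0)
        + lam[None, :] * m_u[:, None]
    )  # (n, J1)
    resid = fit.y_cont - mu  # NaN at missing cells

    order = np.argsort(fit.ind_idx, kind="stable")
    counts = fit.n_records_per_individual
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    out = np.zeros(fit.M)
    has_missing = ~fit.cont_mask.all(axis=1)
    miss_by_ind = np.bincount(fit.ind_idx, weights=has_missing.astype(float),
                              minlength=fit.M) > 0
    base_cov = np.outer(lam, lam) + np.diag(sigma2)  # per-visit block

    for T in np.unique(counts):
        group = np.flatnonzero((counts == T) & ~miss_by_ind)
        if len(group) == 0:
            continue
        pos = starts[group][:, None] + np.arange(T)[None, :]
        rec = order[pos]                       # (g, T) record indices
        r = resid[rec].reshape(len(group), T * J1)
        cov = np.kron(np.eye(T), base_cov) + np.kron(np.ones((T, T)), np.diag(tau2))
        L = np.linalg.cholesky(cov)
        z = np.linalg.solve(L, r.T)            # (TJ1, g)
        k = T * J1
        out[group] = -0.5 * (k * _LOG_2PI + np.sum(z * z, axis=0)) \
            - np.sum(np.log(np.diag(L)))

    # individuals with missing cells: same block density on the observed subset
    for m in np.flatnonzero(miss_by_ind):
        rec = order[starts[m]: starts[m] + counts[m]]
        mask = fit.cont_mask[rec].ravel()
        if not mask.any():
            continue
        r = resid[rec].ravel()[mask]
        T = counts[m]
        cov = (np.kron(np.eye(T), base_cov)
               + np.kron(np.ones((T, T)), np.diag(tau2)))[np.ix_(mask, mask)]
        L = np.linalg.cholesky(cov)
        z = np.linalg.solve(L, r)
        out[m] = -0.5 * (mask.sum() * _LOG_2PI + z @ z) - np.sum(np.log(np.diag(L)))
    return out


def loglik_family_pointwise(theta: ThetaState, data,
                            spec: ModelSpec | None = None) -> np.ndarray:
    """Per-family marginal log likelihood: every latent quantity integrated out.

    For an all-continuous phenotype set the family/individual severity effects
    (a, d), the latent factor U, the individual-by-phenotype effects b and the
    measurement noise are jointly Gaussian, so the stacked phenotype vector of
    one family is multivariate normal with mean mu_tj = beta0_j + W't beta_j +
    lam_j X't alpha and covariance

        lam_j lam_j' (sigma_a^2 + sigma_d^2 [i = i'] + [rec = rec'])
        + tau_j^2 [j = j'][i = i'] + sigma_j^2 [j = j'][rec = rec'].

    This is the fully marginal likelihood in theta alone, the natural focus
    for comparing covariate placements: its deviance has the least Monte-Carlo
    noise (no latent draws enter) and its effective parameter count is the
    number of identified model parameters.  Only defined when there are no
    binary phenotypes.

    The family covariance splits as a block-diagonal part (one block per
    individual, from b, e and the visit-level part of U) plus a low-rank part
    from (a, d); the evaluation uses that Woodbury structure, with the
    rank-(individuals + 1) capacity matrix reduced to scalars by its
    arrowhead form, so the cost is linear in family size.
    """
    fit = _as_fit(data, spec)
    spec = fit.spec
    if spec.J2:
        raise ValueError(
            "the fully marginal family likelihood is analytic only for "
            "continuous phenotypes; use loglik_marginal_u_pointwise for "
            "models with binary phenotypes"
        )
    lam, tau2, sigma2 = theta.lam, theta.tau2, theta.sigma2
    sa2, sd2 = float(theta.sigma_a2), float(theta.sigma_d2)
    mu = (
        theta.beta0[None, :]
        + (fit.W @ theta.beta.T if fit.W.shape[1] else 0.0)
        + lam[None, :] * ((fit.X @ theta.alpha)[:, None] if fit.X.shape[1] else 0.0)
    )
    resid = np.where(fit.cont_mask, fit.y_cont - mu, 0.0)
    lamlam = np.outer(lam, lam)
    J = spec.J1
    M = fit.M

    # records grouped by individual (stable sort keeps visit order)
    order = np.argsort(fit.ind_idx, kind="stable")
    counts = np.bincount(fit.ind_idx, minlength=M)
    starts = np.cumsum(counts) - counts

    # per-individual reductions against the block A_i = 1 1' (x) T
    # + I (x) (D + lam lam'): q = v'A^-1 v with v the stacked loadings,
    # u = v'A^-1 r, rar = r'A^-1 r, ld = log det A, nobs = observed cells
    q = np.zeros(M)
    u = np.zeros(M)
    rar = np.zeros(M)
    ld = np.zeros(M)
    nobs = np.zeros(M)

    complete = np.ones(M, dtype=bool)
    np.logical_and.at(complete, fit.ind_idx, fit.cont_mask.all(axis=1))

    for v in np.unique(counts):
        if v == 0:
            continue
        inds = np.flatnonzero((counts == v) & complete)
        if inds.size:
            recs = order[starts[inds][:, None] + np.arange(v)]  # (n_g, v)
            r_stack = resid[recs].reshape(len(inds), v * J)
            block = (np.kron(np.ones((v, v)), np.diag(tau2))
                     + np.kron(np.eye(v), np.diag(sigma2) + lamlam))
            cf = cho_factor(block, lower=True)
            vlam = np.tile(lam, v)
            w = cho_solve(cf, vlam)
            g_stack = cho_solve(cf, r_stack.T).T
            q[inds] = vlam @ w
            u[inds] = g_stack @ vlam
            rar[inds] = np.einsum("ij,ij->i", r_stack, g_stack)
            ld[inds] = 2.0 * np.sum(np.log(np.diag(cf[0])))
            nobs[inds] = v * J
        for i in np.flatnonzero((counts == v) & ~complete):
            recs = order[starts[i]:starts[i] + v]
            keep = fit.cont_mask[recs].ravel()
            if not keep.any():
                continue
            block = (np.kron(np.ones((v, v)), np.diag(tau2))
                     + np.kron(np.eye(v), np.diag(sigma2) + lamlam))
            cf = cho_factor(block[np.ix_(keep, keep)], lower=True)
            vlam = np.tile(lam, v)[keep]
            r_i = resid[recs].ravel()[keep]
            w = cho_solve(cf, vlam)
            g_i = cho_solve(cf, r_i)
            q[i] = vlam @ w
            u[i] = g_i @ vlam
            rar[i] = r_i @ g_i
            ld[i] = 2.0 * np.sum(np.log(np.diag(cf[0])))
            nobs[i] = keep.sum()

    # Woodbury capacity C = I + F'A^-1 F for F = [sqrt(sa2) 1 (x) lam,
    # sqrt(sd2) Z (x) lam] is an arrowhead matrix; its Schur complement and
    # quadratic form reduce to per-individual scalars aggregated per family
    denom = 1.0 + sd2 * q
    fam = fit.ind_fam
    C = fit.C
    s_q = np.bincount(fam, weights=q, minlength=C)
    s_q2 = np.bincount(fam, weights=q * q / denom, minlength=C)
    s_u = np.bincount(fam, weights=u / denom, minlength=C)
    s_u2 = np.bincount(fam, weights=sd2 * u * u / denom, minlength=C)
    s_ld = np.bincount(fam, weights=ld + np.log(denom), minlength=C)
    s_rar = np.bincount(fam, weights=rar, minlength=C)
    s_n = np.bincount(fam, weights=nobs, minlength=C)
    schur = 1.0 + sa2 * s_q - sa2 * sd2 * s_q2
    quad = s_rar - s_u2 - sa2 * s_u**2 / schur
    return -0.5 * (s_n * _LOG_2PI + s_ld + np.log(schur) + quad)


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    if n_nodes not in _GH_CACHE:
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        _GH_CACHE[n_nodes] = (x, w / np.sqrt(2.0 * np.pi))
    return _GH_CACHE[n_nodes]


def loglik_marginal_u_pointwise(theta: ThetaState, latent: LatentState, data,
                                spec: ModelSpec | None = None,
                                n_nodes: int = 25) -> np.ndarray:
    """Per-record log likelihood conditional on (a, d, b) with U integrated out.

    U | X, a, d ~ N(structural mean, 1); the integral over U of the product of
    the record's phenotype densities is computed by Gauss-Hermite quadrature.
    Unlike the conditional-on-U version this focus is sensitive to the
    structural covariate placement, which is what the model grid varies.
    """
    fit = _as_fit(data, spec)
    spec = fit.spec
    nodes, weights = _gh_nodes(n_nodes)  # standard-normal nodes/weights
    m_u = _structural_mean(theta, latent, fit)  # (n,)
    u = m_u[:, None] + nodes[None, :]  # (n, Q)
    base = (
        theta.beta0[None, :]
        + (fit.W @ theta.beta.T if fit.W.shape[1] else np.zeros((fit.n, spec.J)))
        + latent.b[fit.ind_idx, :]
    )  # (n, J)
    logp = np.zeros((fit.n, len(nodes)))
    for j in range(spec.J1):
        mu = base[:, j][:, None] + theta.lam[j] * u  # (n, Q)
        var = theta.sigma2[j]
        terms = -0.5 * (_LOG_2PI + np.log(var) + (fit.y_cont[:, j][:, None] - mu) ** 2 / var)
        logp += np.where(fit.cont_mask[:, j][:, None], terms, 0.0)
    for jb in range(spec.J2):
        j = spec.J1 + jb
        mu = base[:, j][:, None] + theta.lam[j] * u
        y = fit.y_bin[:, jb][:, None]
        terms = np.where(y == 1, log_ndtr(mu), log_ndtr(-mu))
        logp += np.where(fit.bin_mask[:, jb][:, None], terms, 0.0)
    mx = np.max(logp, axis=1, keepdims=True)
    return (mx[:, 0] + np.log(np.clip((np.exp(logp - mx) * weights[None, :]).sum(axis=1),
                                      1e-300, None)))
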