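"""Synthetic longitudinal family data from the generative latent-variable model.

The default configuration emulates the design of the blood-pressure family
study the model was built for: 16 extended families with 11-36 sequenced
members each, one to four visits per individual with visit-count proportions
90/78/131/97 (out of 396), two continuous phenotypes (SBP/DBP-like), sex as a
direct covariate, age (time-varying) and a biallelic SNP dosage as indirect
covariates acting through the latent severity U.

Random number use is stream-separated by purpose (family structure,
covariates, genotypes, random effects, residual noise) so that, at a fixed
seed, changing for example the minor-allele frequency leaves the family
structure untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongFamilyDataset
from .model import LatentState, ModelSpec, ThetaState

__all__ = ["CovariateSpec", "SimConfig", "gaw18_like_theta", "simulate_dataset"]


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate: its name, model role, and generator.

    kinds:
      * ``age``: per-individual baseline ~ Uniform(baseline_range), incremented
        by ``visit_gap`` years per visit (time-varying).
      * ``bernoulli``: per-individual Bernoulli(p) (e.g. sex).
      * ``snp``: per-individual Binomial(2, maf) minor-allele dosage, constant
        across visits (maf defaults to SimConfig.snp_maf).
      * ``normal``: per-individual N(mean, sd).
    """

    name: str
    role: str  # 'direct' | 'indirect'
    kind: str  # 'age' | 'bernoulli' | 'snp' | 'normal'
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("direct", "indirect"):
            raise ValueError(f"CovariateSpec.role must be 'direct' or 'indirect', got {self.role!r}")
        if self.kind not in ("age", "bernoulli", "snp", "normal"):
            raise ValueError(f"CovariateSpec.kind unknown: {self.kind!r}")


DEFAULT_COVARIATES = (
    CovariateSpec("sex", "direct", "bernoulli", {"p": 0.5}),
    CovariateSpec("age", "indirect", "age", {"baseline_range": (25.0, 75.0), "visit_gap": 5.0}),
    CovariateSpec("snp", "indirect", "snp", {}),
)

# visit-count mix of the motivating study: of 396 analyzable individuals,
# 90 / 78 / 131 / 97 had 1 / 2 / 3 / 4 blood-pressure visits.
GAW18_VISIT_MIX = (90 / 396, 78 / 396, 131 / 396, 97 / 396)


def gaw18_like_theta(spec: ModelSpec) -> ThetaState:
    """Generating truth mirroring the fitted blood-pressure application.

    Loadings 13.15 (SBP-like) and 7.60 (DBP-like), direct sex effects
    (-0.66, -1.79) mmHg, indirect age effect 0.043 latent units/year and SNP
    effect -0.045 latent units/allele; variance components chosen to give
    realistic marginal blood-pressure scales (SBP SD ~ 21, DBP SD ~ 13 mmHg).
    Values for covariates the spec does not include default to zero.
    """
    lam_defaults = {"sbp": 13.15, "dbp": 7.60}
    beta0_defaults = {"sbp": 125.0, "dbp": 75.0}
    sex_defaults = {"sbp": -0.66, "dbp": -1.79}
    alpha_defaults = {"age": 0.043, "snp": -0.045}
    tau2_defaults = {"sbp": 36.0, "dbp": 25.0}
    sigma2_defaults = {"sbp": 64.0, "dbp": 36.0}

    lam = np.array([lam_defaults.get(p, 1.0) for p in spec.phenotypes])
    beta0 = np.array([beta0_defaults.get(p, 0.0) for p in spec.phenotypes])
    beta = np.zeros((spec.J, spec.p1))
    for k, w in enumerate(spec.direct_covariates):
        if w == "sex":
            beta[:, k] = [sex_defaults.get(p, 0.0) for p in spec.phenotypes]
        elif w == "age":
            beta[:, k] = [alpha_defaults["age"] * lam_defaults.get(p, 1.0)
                          for p in spec.phenotypes]
    alpha = np.array([alpha_defaults.get(x, 0.0) for x in spec.indirect_covariates])
    tau2 = np.array([tau2_defaults.get(p, 1.0) for p in spec.phenotypes])
    sigma2 = np.array([sigma2_defaults.get(p, 1.0) for p in spec.continuous_phenotypes])
    return ThetaState(beta0=beta0, beta=beta, alpha=alpha, lam=lam,
                      tau2=tau2, sigma2=sigma2, sigma_a2=0.3, sigma_d2=0.7)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated study.

    The defaults reproduce the motivating family design; ``true_theta`` left as
    None resolves to :func:`gaw18_like_theta` for the implied ModelSpec.
    """

    n_families: int = 16
    family_size_range: tuple[int, int] = (11, 36)
    visit_count_distribution: tuple[float, ...] = GAW18_VISIT_MIX
    continuous_names: tuple[str, ...] = ("sbp", "dbp")
    binary_names: tuple[str, ...] = ()
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    true_theta: ThetaState | None = None
    snp_maf: float = 0.16
    missing_binary_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("SimConfig.n_families must be >= 1")
        lo, hi = self.family_size_range
        if lo < 1 or hi < lo:
            raise ValueError("SimConfig.family_size_range must satisfy 1 <= min <= max")
        p = np.asarray(self.visit_count_distribution, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("SimConfig.visit_count_distribution must be probabilities summing to 1")
        if not (0.0 < self.snp_maf <= 0.5):
            raise ValueError("SimConfig.snp_maf must lie in (0, 0.5]")
        if not (0.0 <= self.missing_binary_rate < 1.0):
            raise ValueError("SimConfig.missing_binary_rate must lie in [0, 1)")

    def model_spec(self) -> ModelSpec:
        direct = tuple(c.name for c in self.covariates if c.role == "direct")
        indirect = tuple(c.name for c in self.covariates if c.role == "indirect")
        snp = next((c.name for c in self.covariates if c.kind == "snp"), None)
        return ModelSpec(self.continuous_names, self.binary_names, direct, indirect,
                         snp_name=snp if snp in indirect else None)

    def resolved_theta(self) -> ThetaState:
        spec = self.model_spec()
        theta = self.true_theta if self.true_theta is not None else gaw18_like_theta(spec)
        try:
            theta.validate(spec)
        except ValueError as err:
            raise ValueError(f"SimConfig.true_theta inconsistent with config: {err}") from err
        return theta


def simulate_dataset(config: SimConfig, seed: int | None = None) -> LongFamilyDataset:
    """Draw one dataset from the generative model.

    The hierarchy is sampled exactly as the model states it: per family
    a_c ~ N(0, sigma_a2); per individual d_ci ~ N(0, sigma_d2) and
    b_cij ~ N(0, tau_j^2); per record eps ~ N(0,1) giving
    U = X'alpha + a + d + eps; continuous phenotypes add N(0, sigma_j^2)
    measurement noise; binary phenotypes are thresholded probit latents.
    Identical (config, seed) gives a bit-identical dataset.
    """
    theta = config.resolved_theta()
    spec = config.model_spec()
    use_seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(use_seed).spawn(5)
    rng_struct = np.random.default_rng(streams[0])
    rng_cov = np.random.default_rng(streams[1])
    rng_geno = np.random.default_rng(streams[2])
    rng_eff = np.random.default_rng(streams[3])
    rng_noise = np.random.default_rng(streams[4])

    # --- structure: family sizes and per-individual visit counts
    lo, hi = config.family_size_range
    sizes = rng_struct.integers(lo, hi + 1, size=config.n_families)
    M = int(sizes.sum())
    visit_support = np.arange(1, len(config.visit_count_distribution) + 1)
    visits = rng_struct.choice(visit_support, size=M,
                               p=np.asarray(config.visit_count_distribution, dtype=float))

    ind_fam = np.repeat(np.arange(config.n_families), sizes)
    ind_idx = np.repeat(np.arange(M), visits)
    fam_idx = ind_fam[ind_idx]
    n = len(ind_idx)
    visit_no = np.concatenate([np.arange(1, t + 1) for t in visits])

    # --- covariates
    cov_cols: dict[str, np.ndarray] = {}
    age_record = None
    for c in config.covariates:
        if c.kind == "age":
            a0, a1 = c.params.get("baseline_range", (25.0, 75.0))
            gap = c.params.get("visit_gap", 5.0)
            base = rng_cov.uniform(a0, a1, size=M)
            vals = base[ind_idx] + gap * (visit_no - 1)
            age_record = vals
        elif c.kind == "bernoulli":
            p = c.params.get("p", 0.5)
            vals = rng_cov.binomial(1, p, size=M)[ind_idx].astype(float)
        elif c.kind == "snp":
            maf = c.params.get("maf", config.snp_maf)
            if not (0.0 < maf <= 0.5):
                raise ValueError(f"CovariateSpec {c.name!r}: maf must lie in (0, 0.5]")
            vals = rng_geno.binomial(2, maf, size=M)[ind_idx].astype(float)
        elif c.kind == "normal":
            mu, sd = c.params.get("mean", 0.0), c.params.get("sd", 1.0)
            vals = rng_cov.normal(mu, sd, size=M)[ind_idx]
        cov_cols[c.name] = np.asarray(vals, dtype=float)

    W = (np.column_stack([cov_cols[w] for w in spec.direct_covariates])
         if spec.p1 else np.zeros((n, 0)))
    X = (np.column_stack([cov_cols[x] for x in spec.indirect_covariates])
         if spec.p2 else np.zeros((n, 0)))

    # --- random effects and latent severity
    a = rng_eff.normal(0.0, np.sqrt(theta.sigma_a2), size=config.n_families)
    d = rng_eff.normal(0.0, np.sqrt(theta.sigma_d2), size=M)
    b = rng_eff.normal(0.0, np.sqrt(theta.tau2)[None, :], size=(M, spec.J))
    eps = rng_noise.normal(size=n)
    xa = X @ theta.alpha if spec.p2 else np.zeros(n)
    U = xa + a[fam_idx] + d[ind_idx] + eps

    # --- phenotypes
    mean = (theta.beta0[None, :]
            + (W @ theta.beta.T if spec.p1 else 0.0)
            + theta.lam[None, :] * U[:, None]
            + b[ind_idx, :])
    pheno = {}
    y_cont = np.zeros((n, spec.J1))
    for j, name in enumerate(spec.continuous_phenotypes):
        y_cont[:, j] = mean[:, j] + rng_noise.normal(0.0, np.sqrt(theta.sigma2[j]), size=n)
        pheno[name] = y_cont[:, j]
    eta_bin = np.zeros((n, spec.J2))
    for jb, name in enumerate(spec.binary_phenotypes):
        j = spec.J1 + jb
        eta_bin[:, jb] = mean[:, j] + rng_noise.normal(size=n)
        y = (eta_bin[:, jb] > 0).astype(float)
        if config.missing_binary_rate > 0:
            miss = rng_noise.random(n) < config.missing_binary_rate
            y = np.where(miss, np.nan, y)
        pheno[name] = y

    fam_ids = np.array([f"F{c + 1:02d}" for c in range(config.n_families)])
    ind_ids = np.array([f"I{m + 1:03d}" for m in range(M)])
    meta = pd.DataFrame({
        "family_id": fam_ids[fam_idx],
        "individual_id": ind_ids[ind_idx],
        "visit": visit_no,
    })
    if age_record is not None:
        meta["age"] = age_record

    truth = {
        "theta": theta,
        "latent": LatentState(U=U, a=a, d=d, b=b, eta_bin=eta_bin),
        "spec": spec,
        "config": config,
    }
    return LongFamilyDataset(
        meta=meta,
        phenotypes=pd.DataFrame(pheno),
        covariates=pd.DataFrame(cov_cols, index=pd.RangeIndex(n)),
        truth=truth,
    )
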