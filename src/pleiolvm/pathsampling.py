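"""Path-sampling (thermodynamic integration) Bayes factors.

The evidence ratio between the full model and the null model in which one
coefficient (a loading lam_j, an indirect coefficient alpha_k, or a direct
coefficient beta_jk) is absent is estimated by the path-sampling identity

    log BF = int_0^1 E_t[ d/dt log p_t(Y, latent | Theta) ] dt,

where p_t scales that parameter's likelihood contribution by t (geometric
path; priors held fixed).  At each grid point a short warm-started Gibbs chain
targets the bridging posterior and the expected derivative is averaged; the
grid integral uses the trapezoid rule.  Pleiotropy is declared when the
natural-log Bayes factor for the SNP coefficient exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FitData
from .model import ModelSpec, PriorSpec, _as_fit
from .mcmc import MCMCConfig, PathTemper, run_chain

__all__ = [
    "BFResult",
    "LOG_BF_THRESHOLD",
    "integrate_path",
    "path_sampling_log_bf",
    "decide_pleiotropy",
]

#: decision threshold on the natural-log Bayes factor
LOG_BF_THRESHOLD = 0.5


@dataclass(frozen=True)
class BFResult:
    """A path-sampling log Bayes factor (natural log) for one parameter."""

    parameter: str
    log_bf: float
    grid: tuple[tuple[float, float], ...]  # (t, estimated expected derivative)
    mc_se: float
    threshold: float = LOG_BF_THRESHOLD

    @property
    def verdict(self) -> bool:
        """True iff the evidence clears the (strict) threshold."""
        return self.log_bf > self.threshold


def decide_pleiotropy(bf: BFResult) -> bool:
    """Pleiotropy rule: declared iff log BF > 0.5 (strict, natural log)."""
    return bool(bf.log_bf > bf.threshold)


def integrate_path(ts: np.ndarray, derivative_draws: list[np.ndarray]) -> tuple[float, float, np.ndarray]:
    """Trapezoid integration of per-grid-point expected derivatives.

    Returns (log_bf, mc_se, per-point means).  The Monte-Carlo standard error
    propagates each point's variance (deflated by an autocorrelation-based
    effective sample size) through the trapezoid weights.
    """
    ts = np.asarray(ts, dtype=float)
    if len(ts) < 3:
        raise ValueError("path grid must have at least 3 points")
    if np.any(np.diff(ts) <= 0) or not (ts[0] == 0.0 and ts[-1] == 1.0):
        raise ValueError("path grid must increase strictly from 0 to 1")
    if len(derivative_draws) != len(ts):
        raise ValueError("one derivative sample array is required per grid point")
    means = np.array([float(np.mean(g)) for g in derivative_draws])
    log_bf = float(np.trapezoid(means, ts))
    # trapezoid weights for a (possibly non-uniform) grid
    w = np.zeros_like(ts)
    w[0] = (ts[1] - ts[0]) / 2.0
    w[-1] = (ts[-1] - ts[-2]) / 2.0
    w[1:-1] = (ts[2:] - ts[:-2]) / 2.0
    var = 0.0
    for wi, g in zip(w, derivative_draws):
        v = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
        var += wi**2 * v / max(_ess(g), 1.0)
    return log_bf, float(np.sqrt(var)), means


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size (cheap, no deps)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n // 2, 200)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def _resolve_parameter(spec: ModelSpec, parameter: str) -> PathTemper:
    """Map a parameter name to its PathTemper.

    Accepted forms: ``lam[phen]``, ``alpha[cov]``, ``beta[phen,cov]``, a bare
    indirect covariate name (alpha), or a bare phenotype name (loading).
    """
    phen = list(spec.phenotypes)
    if parameter.startswith("lam[") and parameter.endswith("]"):
        name = parameter[4:-1]
        if name in phen:
            return PathTemper("lam", j=phen.index(name))
    if parameter.startswith("alpha[") and parameter.endswith("]"):
        name = parameter[6:-1]
        if name in spec.indirect_covariates:
            return PathTemper("alpha", k=spec.indirect_covariates.index(name))
    if parameter.startswith("beta[") and parameter.endswith("]"):
        inner = parameter[5:-1]
        if "," in inner:
            p, w = (s.strip() for s in inner.split(",", 1))
            if p in phen and w in spec.direct_covariates:
                return PathTemper("beta", j=phen.index(p),
                                  k=spec.direct_covariates.index(w))
    if parameter in spec.indirect_covariates:
        return PathTemper("alpha", k=spec.indirect_covariates.index(parameter))
    if parameter in phen:
        return PathTemper("lam", j=phen.index(parameter))
    raise KeyError(
        f"parameter {parameter!r} not found; expected lam[phenotype], alpha[covariate] "
        f"or beta[phenotype,covariate] drawn from {phen} / {spec.direct_covariates} / "
        f"{spec.indirect_covariates}"
    )


def path_sampling_log_bf(data, spec: ModelSpec | None = None,
                         priors: PriorSpec | None = None,
                         mcmc_config: MCMCConfig | None = None,
                         parameter: str = "", n_grid: int = 21) -> BFResult:
    """Estimate the log Bayes factor (alternative vs. null) for one parameter.

    Runs a warm-started chain at each of ``n_grid`` equally spaced path points
    from t = 1 (full model) down to t = 0 (parameter's likelihood contribution
    removed); ``mcmc_config`` sets the per-point chain length, so pass a short
    chain (hundreds of sweeps) here rather than the full-fit configuration.
    """
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    fit = _as_fit(data, spec)
    spec = fit.spec
    priors = priors or PriorSpec()
    config = mcmc_config or MCMCConfig(n_iter=400, burn_in=150, thin=1)
    base = _resolve_parameter(spec, parameter)

    ts = np.linspace(0.0, 1.0, n_grid)
    draws_by_point: list[np.ndarray | None] = [None] * n_grid
    warm = None
    for i in range(n_grid - 1, -1, -1):  # t = 1 -> 0, warm-starting downward
        temper = PathTemper(base.kind, j=base.j, k=base.k, t=float(ts[i]))
        cfg = MCMCConfig(
            n_iter=config.n_iter, burn_in=config.burn_in, thin=1,
            seed=config.seed + i, init=config.init if warm is None else "user",
            hierarchical_centering=config.hierarchical_centering,
            parameter_expansion=config.parameter_expansion,
            store_deviance=False, compute_diagnostics=False,
        )
        samples = run_chain(fit, priors=priors, mcmc_config=cfg, temper=temper,
                            init_state=warm)
        warm = samples.final_state
        draws_by_point[i] = samples.path_derivatives
    log_bf, mc_se, means = integrate_path(ts, draws_by_point)
    return BFResult(
        parameter=parameter,
        log_bf=log_bf,
        grid=tuple((float(t), float(m)) for t, m in zip(ts, means)),
        mc_se=mc_se,
    )
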