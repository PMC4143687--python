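"""Gibbs sampler for the latent-variable pleiotropy model.

All full conditionals are conjugate: truncated-normal data augmentation for
the probit cells, Gaussian conditionals for U, the random effects and the
regression blocks, inverse-gamma conditionals for the variance components, and
a normal/inverse-gamma scale-mixture (parameter expansion) for the folded-t
factor loadings.  Two optional mixing accelerators are provided:

* ``parameter_expansion`` — the folded-t loading prior is represented as
  lam_j | phi_j ~ N(0, phi_j), phi_j ~ InvGamma(nu/2, nu s^2 / 2), giving a
  conjugate two-block update whose marginal prior is Student-t_nu(0, s) (folded
  for the sign-anchored first loading).  With the flag off, the loading is
  updated by a slice sampler on its exact conditional (same stationary law,
  slower mixing) as a correctness baseline.
* ``hierarchical_centering`` — translation moves along the exactly
  non-identified directions (a_c vs d_ci within a family; beta0_j vs the
  b_.j block), each a Gibbs draw of the shift under the priors.

The latent sign is fixed by lam_1 > 0: whenever the first loading goes
negative the whole chain state is reflected (lam, U, alpha, a, d negated),
which maps the sign-symmetric posterior onto its lam_1 > 0 fold.

A :class:`PathTemper` lets one parameter's likelihood contribution be scaled
by t in [0, 1]; the sampler then targets the bridging posterior used by
path-sampling Bayes factors and reports the per-sweep derivative of the
complete-data log likelihood with respect to t.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .data import FitData, LongFamilyDataset
from .model import (
    LatentState,
    ModelSpec,
    PriorSpec,
    ThetaState,
    _as_fit,
    folded_t_logpdf,
    loglik_family_pointwise,
    loglik_marginal_u_pointwise,
    loglik_observed_pointwise,
    loglik_subject_pointwise,
)

__all__ = [
    "MCMCConfig",
    "PathTemper",
    "GibbsState",
    "PosteriorSamples",
    "augment_binary",
    "update_latent_U",
    "update_random_effects",
    "update_loadings_px",
    "update_regression_blocks",
    "update_variances",
    "run_chain",
    "draw_theta_from_prior",
    "initial_state",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and sampler options.

    Draws kept = floor((n_iter - burn_in) / thin).  ``init`` is one of
    ``"heuristic"`` (phenotype-mean intercepts, unit loadings and variances, U
    initialized at the standardized first continuous phenotype),
    ``"prior-draw"``, or ``"user"`` (state passed to :func:`run_chain`).
    """

    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    init: str = "heuristic"
    hierarchical_centering: bool = True
    parameter_expansion: bool = True
    store_deviance: bool | tuple[str, ...] = True
    compute_diagnostics: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("MCMCConfig requires 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("MCMCConfig.thin must be >= 1")
        if self.init not in ("heuristic", "prior-draw", "user"):
            raise ValueError(f"unknown init strategy {self.init!r}")
        if not isinstance(self.store_deviance, bool):
            bad = set(self.store_deviance) - _DEVIANCE_FOCUSES
            if bad:
                raise ValueError(f"unknown deviance focus(es) {sorted(bad)}; "
                                 f"choose from {sorted(_DEVIANCE_FOCUSES)}")

    def deviance_focuses(self, n_binary: int) -> frozenset[str]:
        """Focuses whose per-draw deviance this chain will store."""
        if self.store_deviance is True:
            focuses = _DEVIANCE_FOCUSES
        elif self.store_deviance is False:
            return frozenset()
        else:
            focuses = frozenset(self.store_deviance)
        if n_binary:
            focuses = focuses - {"subject", "family"}
        return focuses


_DEVIANCE_FOCUSES = frozenset({"conditional", "marginal", "subject", "family"})


@dataclass(frozen=True)
class PathTemper:
    """Scale one parameter's likelihood contribution by t (path sampling).

    kind 'lam' tempers loading j; 'alpha' tempers indirect coefficient k;
    'beta' tempers direct coefficient (phenotype j, covariate k).
    """

    kind: str
    j: int | None = None
    k: int | None = None
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("lam", "alpha", "beta"):
            raise ValueError(f"PathTemper.kind must be 'lam', 'alpha' or 'beta', got {self.kind!r}")
        if not (0.0 <= self.t <= 1.0):
            raise ValueError("PathTemper.t must lie in [0, 1]")


class _Eff:
    """Temper-adjusted design quantities, computed once per chain."""

    def __init__(self, fit: FitData, temper: PathTemper | None):
        self.temper = temper
        J = fit.spec.J
        self.lam_mult = np.ones(J)
        self.X = fit.X
        self._W_default = fit.W
        self._W_special = None
        self._special_j = None
        self._D_default = None
        self._D_special = None
        if temper is not None:
            if temper.kind == "lam":
                self.lam_mult[temper.j] = temper.t
            elif temper.kind == "alpha":
                X = fit.X.copy()
                X[:, temper.k] *= temper.t
                self.X = X
            elif temper.kind == "beta":
                W = fit.W.copy()
                W[:, temper.k] *= temper.t
                self._W_special = W
                self._special_j = temper.j

    def W(self, j: int) -> np.ndarray:
        if self._special_j is not None and j == self._special_j:
            return self._W_special
        return self._W_default

    def D(self, j: int) -> np.ndarray:
        """Cached intercept-augmented design [1 | W] for phenotype j."""
        if self._special_j is not None and j == self._special_j:
            if self._D_special is None:
                self._D_special = np.column_stack([np.ones(len(self._W_special)),
                                                   self._W_special])
            return self._D_special
        if self._D_default is None:
            self._D_default = np.column_stack([np.ones(len(self._W_default)),
                                               self._W_default])
        return self._D_default

    def lam_eff(self, lam: np.ndarray) -> np.ndarray:
        return lam * self.lam_mult


@dataclass
class GibbsState:
    """Parameters, latent variables and the parameter-expansion scales phi."""

    theta: ThetaState
    latent: LatentState
    phi: np.ndarray  # (J,) loading prior scale-mixture variances

    def copy(self) -> "GibbsState":
        return GibbsState(self.theta.copy(), self.latent.copy(), self.phi.copy())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _resp(fit: FitData, latent: LatentState, j: int):
    """(values, mask) of phenotype j's Gaussian working response (NaN-free)."""
    if j < fit.spec.J1:
        return fit.y_cont_filled[:, j], fit.cont_mask[:, j]
    jb = j - fit.spec.J1
    return latent.eta_bin[:, jb], fit.bin_mask[:, jb]


def _meas_base(state: GibbsState, fit: FitData, eff: _Eff, j: int) -> np.ndarray:
    """Measurement mean of phenotype j without the lam*U term."""
    th = state.theta
    out = th.beta0[j] + state.latent.b[fit.ind_idx, j]
    if fit.spec.p1:
        out = out + eff.W(j) @ th.beta[j]
    return out


def _struct_mean(state: GibbsState, fit: FitData, eff: _Eff) -> np.ndarray:
    th = state.theta
    out = state.latent.a[fit.fam_idx] + state.latent.d[fit.ind_idx]
    if fit.spec.p2:
        out = out + eff.X @ th.alpha
    return out


def _sign_fold(state: GibbsState) -> None:
    """Reflect the chain onto the lam_1 > 0 half-space (exact model symmetry)."""
    if state.theta.lam[0] < 0:
        state.theta.lam *= -1.0
        state.theta.alpha *= -1.0
        state.latent.U *= -1.0
        state.latent.a *= -1.0
        state.latent.d *= -1.0


# ---------------------------------------------------------------------------
# full-conditional updates
# ---------------------------------------------------------------------------


def augment_binary(state: GibbsState, fit: FitData, rng: np.random.Generator,
                   eff: _Eff | None = None) -> None:
    """Redraw the probit latents eta from truncated normals.

    eta_citj | rest ~ N(linear predictor, 1) truncated to (0, inf) when y = 1
    and to (-inf, 0] when y = 0; missing cells are skipped.
    """
    spec = fit.spec
    if spec.J2 == 0:
        return
    eff = eff or _Eff(fit, None)
    lam_eff = eff.lam_eff(state.theta.lam)
    for jb in range(spec.J2):
        j = spec.J1 + jb
        mask = fit.bin_mask[:, jb]
        if not np.any(mask):
            continue
        m = (_meas_base(state, fit, eff, j) + lam_eff[j] * state.latent.U)[mask]
        y = fit.y_bin[mask, jb]
        lo = np.where(y == 1, -m, -np.inf)
        hi = np.where(y == 1, np.inf, -m)
        draws = stats.truncnorm.rvs(lo, hi, loc=0.0, scale=1.0,
                                    size=m.size, random_state=rng)
        state.latent.eta_bin[mask, jb] = m + draws


def update_latent_U(state: GibbsState, fit: FitData, rng: np.random.Generator,
                    eff: _Eff | None = None) -> None:
    """Draw each U_cit from its Gaussian full conditional.

    precision = 1 + sum_cont lam_j^2/sigma_j^2 + sum_bin lam_j^2 (observed
    cells only); the mean precision-weights the structural mean against each
    phenotype's residual net of intercept, direct effects and b.
    """
    spec = fit.spec
    eff = eff or _Eff(fit, None)
    lam_eff = eff.lam_eff(state.theta.lam)
    prec = np.ones(fit.n)
    num = _struct_mean(state, fit, eff).copy()
    for j in range(spec.J):
        vals, mask = _resp(fit, state.latent, j)
        wj = (1.0 / state.theta.sigma2[j]) if j < spec.J1 else 1.0
        r = vals - _meas_base(state, fit, eff, j)
        prec += np.where(mask, lam_eff[j] ** 2 * wj, 0.0)
        num += np.where(mask, lam_eff[j] * wj * r, 0.0)
    state.latent.U = num / prec + rng.standard_normal(fit.n) / np.sqrt(prec)


def update_random_effects(state: GibbsState, fit: FitData, rng: np.random.Generator,
                          eff: _Eff | None = None,
                          hierarchical_centering: bool = True) -> None:
    """Gaussian conditionals for a (family), d (individual) and b (individual x
    phenotype), plus the optional centering translation moves."""
    spec = fit.spec
    th = state.theta
    eff = eff or _Eff(fit, None)
    xa = eff.X @ th.alpha if spec.p2 else np.zeros(fit.n)

    # family effects a_c
    resid = state.latent.U - xa - state.latent.d[fit.ind_idx]
    s = np.bincount(fit.fam_idx, weights=resid, minlength=fit.C)
    prec = 1.0 / th.sigma_a2 + fit.n_records_per_family
    state.latent.a = s / prec + rng.standard_normal(fit.C) / np.sqrt(prec)

    # individual effects d_ci
    resid = state.latent.U - xa - state.latent.a[fit.fam_idx]
    s = np.bincount(fit.ind_idx, weights=resid, minlength=fit.M)
    prec = 1.0 / th.sigma_d2 + fit.n_records_per_individual
    state.latent.d = s / prec + rng.standard_normal(fit.M) / np.sqrt(prec)

    # individual-by-phenotype effects b_cij
    lam_eff = eff.lam_eff(th.lam)
    for j in range(spec.J):
        vals, mask = _resp(fit, state.latent, j)
        wj = (1.0 / th.sigma2[j]) if j < spec.J1 else 1.0
        base = th.beta0[j] + (eff.W(j) @ th.beta[j] if spec.p1 else 0.0)
        r = np.where(mask, vals - base - lam_eff[j] * state.latent.U, 0.0)
        s = np.bincount(fit.ind_idx, weights=r * wj, minlength=fit.M)
        cnt = np.bincount(fit.ind_idx, weights=mask.astype(float), minlength=fit.M)
        prec = 1.0 / th.tau2[j] + cnt * wj
        state.latent.b[:, j] = s / prec + rng.standard_normal(fit.M) / np.sqrt(prec)

    if hierarchical_centering:
        _centering_moves(state, fit, rng)


def _centering_moves(state: GibbsState, fit: FitData, rng: np.random.Generator,
                     beta0_scale2: float | None = None) -> None:
    """Translation Gibbs moves along non-identified directions (mixing aid)."""
    th = state.theta
    # a_c + delta, d_ci - delta within each family
    n_ind = np.bincount(fit.ind_fam, minlength=fit.C)
    d_sum = np.bincount(fit.ind_fam, weights=state.latent.d, minlength=fit.C)
    prec = 1.0 / th.sigma_a2 + n_ind / th.sigma_d2
    mean = (-state.latent.a / th.sigma_a2 + d_sum / th.sigma_d2) / prec
    delta = mean + rng.standard_normal(fit.C) / np.sqrt(prec)
    state.latent.a = state.latent.a + delta
    state.latent.d = state.latent.d - delta[fit.ind_fam]


def _centering_beta0(state: GibbsState, fit: FitData, rng: np.random.Generator,
                     priors: PriorSpec, eff: _Eff | None = None) -> None:
    """Translation moves involving the intercepts.

    (i) beta0_j + delta, b_.j - delta (per phenotype);
    (ii) global latent location: a_c + delta for all c, U + delta,
    beta0_j - lam_j delta — an exact likelihood symmetry pinned only by the
    priors on a and beta0, and the direction along which intercepts, family
    effects and the latent mean would otherwise random-walk together.
    """
    th = state.theta
    eff = eff or _Eff(fit, None)
    for j in range(fit.spec.J):
        prec = 1.0 / priors.beta0_scale**2 + fit.M / th.tau2[j]
        mean = (-th.beta0[j] / priors.beta0_scale**2
                + state.latent.b[:, j].sum() / th.tau2[j]) / prec
        delta = mean + rng.standard_normal() / np.sqrt(prec)
        th.beta0[j] = th.beta0[j] + delta
        state.latent.b[:, j] = state.latent.b[:, j] - delta

    lam_eff = eff.lam_eff(th.lam)
    s0sq = priors.beta0_scale**2
    prec = fit.C / th.sigma_a2 + float(np.sum(lam_eff**2)) / s0sq
    mean = (-state.latent.a.sum() / th.sigma_a2
            + float(np.dot(lam_eff, th.beta0)) / s0sq) / prec
    delta = mean + rng.standard_normal() / np.sqrt(prec)
    state.latent.a += delta
    state.latent.U += delta
    th.beta0 -= lam_eff * delta


def _slice_sample_loading(x0: float, logf, rng: np.random.Generator,
                          w: float = 1.0, max_steps: int = 50) -> float:
    """Scalar slice sampler with stepping out (Neal 2003)."""
    logy = logf(x0) + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logf(left) < logy:
            break
        left -= w
    for _ in range(max_steps):
        if logf(right) < logy:
            break
        right += w
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def update_loadings_px(state: GibbsState, fit: FitData, priors: PriorSpec,
                       rng: np.random.Generator, eff: _Eff | None = None,
                       parameter_expansion: bool = True) -> None:
    """Update the factor loadings (and their scale-mixture variances phi).

    With parameter expansion the update is conjugate: lam_j | phi_j, rest is a
    normal regression of the phenotype-j residuals on (mult_j * U) with prior
    N(0, phi_j), and phi_j | lam_j ~ InvGamma((nu+1)/2, (nu s^2 + lam_j^2)/2).
    Without it, lam_j is slice-sampled under the folded-t prior directly.
    The lam_1 > 0 constraint is enforced by reflecting the whole state.
    """
    spec = fit.spec
    th = state.theta
    eff = eff or _Eff(fit, None)
    nu, s2 = priors.loading_df, priors.loading_scale**2
    for j in range(spec.J):
        vals, mask = _resp(fit, state.latent, j)
        wj = (1.0 / th.sigma2[j]) if j < spec.J1 else 1.0
        x = eff.lam_mult[j] * state.latent.U
        base = _meas_base(state, fit, eff, j)
        r = np.where(mask, vals - base, 0.0)
        xm = np.where(mask, x, 0.0)
        sxx = float(np.sum(xm * xm)) * wj
        sxy = float(np.sum(xm * r)) * wj
        if parameter_expansion:
            prec = 1.0 / state.phi[j] + sxx
            mean = sxy / prec
            th.lam[j] = mean + rng.standard_normal() / np.sqrt(prec)
            state.phi[j] = (nu * s2 + th.lam[j] ** 2) / (2.0 * rng.gamma((nu + 1) / 2.0))
        else:
            def logf(lam, sxx=sxx, sxy=sxy):
                return (-0.5 * sxx * lam * lam + sxy * lam
                        + float(folded_t_logpdf(lam, nu, np.sqrt(s2))))
            th.lam[j] = _slice_sample_loading(float(th.lam[j]), logf, rng,
                                              w=max(1.0, np.sqrt(s2)))
    _sign_fold(state)


def scale_group_move(state: GibbsState, fit: FitData, priors: PriorSpec,
                     rng: np.random.Generator, eff: _Eff | None = None) -> None:
    """Generalized-Gibbs rescaling move along the loading/latent-scale ridge.

    The complete-data likelihood is nearly invariant under c > 0 acting as
    U -> cU, a -> ca, d -> cd, alpha -> c alpha, sigma_a2/sigma_d2 -> c^2 *,
    lam -> lam / c, phi -> phi / c^2 (the measurement terms are exactly
    invariant; only the unit-variance structural residual and the priors pin
    c).  Sampling c from its exact conditional under the Haar measure dc/c
    (Liu & Sabatti 2000) and applying the transformation leaves the posterior
    invariant while jumping along the slowest-mixing direction.  In gamma =
    c^2 the conditional is generalized inverse Gaussian.
    """
    th = state.theta
    spec = fit.spec
    eff = eff or _Eff(fit, None)
    nu, s2 = priors.loading_df, priors.loading_scale**2
    resid = state.latent.U - _struct_mean(state, fit, eff)
    A = (float(np.sum(resid**2)) / 2.0
         + float(np.sum(th.alpha**2)) / (2.0 * priors.alpha_scale**2)
         + float(np.sum(nu * s2 / state.phi)) / 2.0)
    B = priors.ig_scale * (1.0 / th.sigma_a2 + 1.0 / th.sigma_d2)
    K = fit.n + spec.p2 + spec.J * nu - 4.0 * priors.ig_shape - 1.0
    p = (K + 1.0) / 2.0
    gamma = _gig_draw(p, A, B, rng)
    c = np.sqrt(gamma)
    state.latent.U *= c
    state.latent.a *= c
    state.latent.d *= c
    th.alpha *= c
    th.sigma_a2 *= gamma
    th.sigma_d2 *= gamma
    th.lam /= c
    state.phi /= gamma


def _gig_draw(p: float, A: float, B: float, rng: np.random.Generator) -> float:
    """Draw gamma ~ GIG: density prop. to g^(p-1) exp(-A g - B/g), A, B > 0.

    In this sampler's regime B is small (vague inverse-gamma priors), so a
    Gamma(p, A) envelope with acceptance exp(-B/g) <= 1 is exact and nearly
    rejection-free; scipy's generalized-inverse-Gaussian sampler is the
    fallback when B is not small.
    """
    for _ in range(50):
        g = rng.gamma(p) / A
        if np.log(rng.random()) <= -B / g:
            return float(g)
    return float(stats.geninvgauss.rvs(p, 2.0 * np.sqrt(A * B),
                                       scale=np.sqrt(B / A), random_state=rng))


def update_regression_blocks(state: GibbsState, fit: FitData, priors: PriorSpec,
                             rng: np.random.Generator, eff: _Eff | None = None) -> None:
    """Conjugate multivariate-normal updates of (beta0_j, beta_j) and alpha.

    Posterior precision = prior precision + weighted design cross-product; the
    proper priors keep the precision invertible even for rank-deficient
    designs (e.g. a constant covariate or no data).
    """
    spec = fit.spec
    th = state.theta
    eff = eff or _Eff(fit, None)
    lam_eff = eff.lam_eff(th.lam)
    for j in range(spec.J):
        vals, mask = _resp(fit, state.latent, j)
        wj = (1.0 / th.sigma2[j]) if j < spec.J1 else 1.0
        D = eff.D(j) if spec.p1 else np.ones((fit.n, 1))
        r = np.where(mask, vals - lam_eff[j] * state.latent.U
                     - state.latent.b[fit.ind_idx, j], 0.0)
        Dm = D * mask[:, None]
        prior_prec = np.diag(
            [1.0 / priors.beta0_scale**2] + [1.0 / priors.beta_scale**2] * spec.p1
        )
        P = prior_prec + wj * (Dm.T @ Dm)
        rhs = wj * (Dm.T @ r)
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs)
        z = rng.standard_normal(1 + spec.p1)
        draw = mean + np.linalg.solve(L.T, z)
        th.beta0[j] = draw[0]
        if spec.p1:
            th.beta[j] = draw[1:]
    if spec.p2:
        r = state.latent.U - state.latent.a[fit.fam_idx] - state.latent.d[fit.ind_idx]
        P = np.eye(spec.p2) / priors.alpha_scale**2 + eff.X.T @ eff.X
        rhs = eff.X.T @ r
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs)
        th.alpha = mean + np.linalg.solve(L.T, rng.standard_normal(spec.p2))


def update_variances(state: GibbsState, fit: FitData, priors: PriorSpec,
                     rng: np.random.Generator, eff: _Eff | None = None) -> None:
    """Inverse-gamma conjugate updates for sigma_j^2, tau_j^2, sigma_a^2, sigma_d^2."""
    spec = fit.spec
    th = state.theta
    eff = eff or _Eff(fit, None)
    a0, b0 = priors.ig_shape, priors.ig_scale
    lam_eff = eff.lam_eff(th.lam)

    def ig_draw(shape: float, scale: float) -> float:
        return scale / rng.gamma(shape)

    for j in range(spec.J1):
        mask = fit.cont_mask[:, j]
        m = _meas_base(state, fit, eff, j) + lam_eff[j] * state.latent.U
        resid = np.where(mask, fit.y_cont_filled[:, j] - m, 0.0)
        ss = float(np.sum(resid**2))
        nobs = float(mask.sum())
        th.sigma2[j] = ig_draw(a0 + nobs / 2.0, b0 + ss / 2.0)
    for j in range(spec.J):
        ss = float(np.sum(state.latent.b[:, j] ** 2))
        th.tau2[j] = ig_draw(a0 + fit.M / 2.0, b0 + ss / 2.0)
    th.sigma_a2 = ig_draw(a0 + fit.C / 2.0, b0 + float(np.sum(state.latent.a**2)) / 2.0)
    th.sigma_d2 = ig_draw(a0 + fit.M / 2.0, b0 + float(np.sum(state.latent.d**2)) / 2.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def draw_theta_from_prior(spec: ModelSpec, priors: PriorSpec,
                          rng: np.random.Generator) -> tuple[ThetaState, np.ndarray]:
    """Draw (Theta, phi) from the prior; lam uses the scale-mixture and lam_1
    is folded positive."""
    nu, s2 = priors.loading_df, priors.loading_scale**2
    phi = (nu * s2) / (2.0 * rng.gamma(nu / 2.0, size=spec.J))
    lam = rng.standard_normal(spec.J) * np.sqrt(phi)
    beta0 = rng.standard_normal(spec.J) * priors.beta0_scale
    beta = rng.standard_normal((spec.J, spec.p1)) * priors.beta_scale
    alpha = rng.standard_normal(spec.p2) * priors.alpha_scale
    ig = lambda size=None: priors.ig_scale / rng.gamma(priors.ig_shape, size=size)
    theta = ThetaState(beta0=beta0, beta=beta, alpha=alpha, lam=lam,
                       tau2=ig(spec.J), sigma2=ig(spec.J1),
                       sigma_a2=float(ig()), sigma_d2=float(ig()))
    return theta, phi


def initial_state(fit: FitData, priors: PriorSpec, config: MCMCConfig,
                  rng: np.random.Generator) -> GibbsState:
    spec = fit.spec
    if config.init == "prior-draw":
        theta, phi = draw_theta_from_prior(spec, priors, rng)
        n = fit.n
        a = rng.standard_normal(fit.C) * np.sqrt(theta.sigma_a2)
        d = rng.standard_normal(fit.M) * np.sqrt(theta.sigma_d2)
        b = rng.standard_normal((fit.M, spec.J)) * np.sqrt(theta.tau2)[None, :]
        xa = fit.X @ theta.alpha if spec.p2 else np.zeros(n)
        U = xa + a[fit.fam_idx] + d[fit.ind_idx] + rng.standard_normal(n)
        state = GibbsState(theta, LatentState(U, a, d, b, np.zeros((n, spec.J2))), phi)
        _sign_fold(state)
        augment_binary(state, fit, rng)
        return state

    # heuristic: scale-aware, deterministic
    beta0 = np.zeros(spec.J)
    for j in range(spec.J1):
        obs = fit.y_cont[fit.cont_mask[:, j], j]
        beta0[j] = float(obs.mean()) if obs.size else 0.0
    for jb in range(spec.J2):
        obs = fit.y_bin[fit.bin_mask[:, jb], jb]
        freq = float(obs.mean()) if obs.size else 0.5
        beta0[spec.J1 + jb] = float(ndtri(np.clip(freq, 0.01, 0.99)))
    theta = ThetaState(
        beta0=beta0,
        beta=np.zeros((spec.J, spec.p1)),
        alpha=np.zeros(spec.p2),
        lam=np.ones(spec.J),
        tau2=np.ones(spec.J),
        sigma2=np.ones(max(spec.J1, 0)) if spec.J1 else np.zeros(0),
        sigma_a2=1.0,
        sigma_d2=1.0,
    )
    if spec.J1:
        y0 = np.where(fit.cont_mask[:, 0], fit.y_cont[:, 0], np.nan)
        mu, sd = np.nanmean(y0), np.nanstd(y0)
        U = np.nan_to_num((y0 - mu) / (sd if sd > 0 else 1.0))
    else:
        U = np.zeros(fit.n)
    latent = LatentState(U=U, a=np.zeros(fit.C), d=np.zeros(fit.M),
                         b=np.zeros((fit.M, spec.J)),
                         eta_bin=np.zeros((fit.n, spec.J2)))
    state = GibbsState(theta, latent, np.full(spec.J, priors.loading_scale**2))
    augment_binary(state, fit, rng)
    return state


# ---------------------------------------------------------------------------
# path derivative
# ---------------------------------------------------------------------------


def path_derivative(state: GibbsState, fit: FitData, eff: _Eff,
                    temper: PathTemper) -> float:
    """d/dt of the complete-data log likelihood at the current state."""
    th = state.theta
    spec = fit.spec
    if temper.kind == "alpha":
        m = _struct_mean(state, fit, eff)
        return float(np.sum((state.latent.U - m) * th.alpha[temper.k] * fit.X[:, temper.k]))
    j = temper.j
    vals, mask = _resp(fit, state.latent, j)
    wj = (1.0 / th.sigma2[j]) if j < spec.J1 else 1.0
    lam_eff = eff.lam_eff(th.lam)
    m = _meas_base(state, fit, eff, j) + lam_eff[j] * state.latent.U
    r = np.where(mask, np.nan_to_num(vals - m), 0.0)
    if temper.kind == "lam":
        grad = th.lam[j] * state.latent.U
    else:  # beta
        grad = th.beta[j, temper.k] * fit.W[:, temper.k]
    return float(np.sum(r * grad) * wj)


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws with chain metadata.

    ``draws`` maps scalar parameter names (``lam[sbp]``, ``alpha[age]``, ...)
    to arrays of length S; ``latent_means`` holds posterior means of U, a, d, b
    over the stored draws; ``deviance_cond`` / ``deviance_marg`` /
    ``deviance_subject`` are the per-draw deviances under the conditional-on-U,
    marginal-over-U and subject-level (marginal over U, b and noise) focuses;
    the subject focus is stored only for all-continuous phenotype sets.
    """

    spec: ModelSpec
    config: MCMCConfig
    draws: dict[str, np.ndarray]
    latent_means: dict[str, np.ndarray]
    deviance_cond: np.ndarray | None = None
    deviance_marg: np.ndarray | None = None
    deviance_subject: np.ndarray | None = None
    deviance_family: np.ndarray | None = None
    diagnostics: pd.DataFrame | None = None
    final_state: GibbsState | None = None
    path_derivatives: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def theta_state(self, i: int) -> ThetaState:
        return self._theta_from(lambda name: self.draws[name][i])

    def theta_mean(self) -> ThetaState:
        return self._theta_from(lambda name: float(np.mean(self.draws[name])))

    def _theta_from(self, get) -> ThetaState:
        spec = self.spec
        beta0 = np.array([get(f"beta0[{p}]") for p in spec.phenotypes])
        lam = np.array([get(f"lam[{p}]") for p in spec.phenotypes])
        beta = np.array([[get(f"beta[{p},{w}]") for w in spec.direct_covariates]
                         for p in spec.phenotypes]).reshape(spec.J, spec.p1)
        alpha = np.array([get(f"alpha[{x}]") for x in spec.indirect_covariates])
        tau2 = np.array([get(f"tau2[{p}]") for p in spec.phenotypes])
        sigma2 = np.array([get(f"sigma2[{p}]") for p in spec.continuous_phenotypes])
        return ThetaState(beta0=beta0, beta=beta, alpha=alpha, lam=lam, tau2=tau2,
                          sigma2=sigma2, sigma_a2=get("sigma_a2"),
                          sigma_d2=get("sigma_d2"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            __names=np.array(list(self.draws.keys())),
            **{f"draw_{k}": v for k, v in self.draws.items()},
            **{f"latent_{k}": v for k, v in self.latent_means.items()},
        )


def sweep(state: GibbsState, fit: FitData, priors: PriorSpec,
          rng: np.random.Generator, config: MCMCConfig,
          eff: _Eff | None = None) -> None:
    """One full Gibbs scan in the fixed update order."""
    eff = eff or _Eff(fit, None)
    augment_binary(state, fit, rng, eff)
    update_latent_U(state, fit, rng, eff)
    update_random_effects(state, fit, rng, eff,
                          hierarchical_centering=config.hierarchical_centering)
    update_loadings_px(state, fit, priors, rng, eff,
                       parameter_expansion=config.parameter_expansion)
    update_regression_blocks(state, fit, priors, rng, eff)
    if config.parameter_expansion:
        scale_group_move(state, fit, priors, rng, eff)
    if config.hierarchical_centering:
        _centering_beta0(state, fit, rng, priors, eff)
    update_variances(state, fit, priors, rng, eff)


def _check_finite(state: GibbsState, it: int) -> None:
    th = state.theta
    for name, arr in (("beta0", th.beta0), ("beta", th.beta), ("alpha", th.alpha),
                      ("lam", th.lam), ("tau2", th.tau2), ("sigma2", th.sigma2),
                      ("sigma_a2", np.array([th.sigma_a2])),
                      ("sigma_d2", np.array([th.sigma_d2])),
                      ("U", state.latent.U)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite values in component {name!r} at sweep {it}"
            )


def run_chain(data, spec: ModelSpec | None = None, priors: PriorSpec | None = None,
              mcmc_config: MCMCConfig | None = None, temper: PathTemper | None = None,
              init_state: GibbsState | None = None) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned post-burn-in draws.

    Updates run in the fixed order: probit augmentation, latent U, random
    effects, loadings, regression blocks, variances.  The (seed, data, config)
    triple determines the draws exactly.
    """
    fit = _as_fit(data, spec)
    spec = fit.spec
    priors = priors or PriorSpec()
    config = mcmc_config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    eff = _Eff(fit, temper)

    if config.init == "user":
        if init_state is None:
            raise ValueError("init='user' requires init_state")
        state = init_state.copy()
    elif init_state is not None:
        state = init_state.copy()
    else:
        state = initial_state(fit, priors, config, rng)

    names = list(state.theta.flat(spec).keys())
    n_keep = (config.n_iter - config.burn_in) // config.thin
    stored = {name: np.empty(n_keep) for name in names}
    focuses = config.deviance_focuses(spec.J2)
    dev_cond = np.empty(n_keep) if "conditional" in focuses else None
    dev_marg = np.empty(n_keep) if "marginal" in focuses else None
    dev_subj = np.empty(n_keep) if "subject" in focuses else None
    dev_fam = np.empty(n_keep) if "family" in focuses else None
    u_acc = np.zeros(fit.n)
    a_acc = np.zeros(fit.C)
    d_acc = np.zeros(fit.M)
    b_acc = np.zeros((fit.M, spec.J))
    derivs = [] if temper is not None else None

    kept = 0
    for it in range(1, config.n_iter + 1):
        sweep(state, fit, priors, rng, config, eff)
        _check_finite(state, it)
        if temper is not None and it > config.burn_in:
            derivs.append(path_derivative(state, fit, eff, temper))
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_keep:
            flat = state.theta.flat(spec)
            for name in names:
                stored[name][kept] = flat[name]
            u_acc += state.latent.U
            a_acc += state.latent.a
            d_acc += state.latent.d
            b_acc += state.latent.b
            if dev_cond is not None:
                dev_cond[kept] = -2.0 * float(np.sum(
                    loglik_observed_pointwise(state.theta, state.latent, fit)))
            if dev_marg is not None:
                dev_marg[kept] = -2.0 * float(np.sum(
                    loglik_marginal_u_pointwise(state.theta, state.latent, fit)))
            if dev_subj is not None:
                dev_subj[kept] = -2.0 * float(np.sum(
                    loglik_subject_pointwise(state.theta, state.latent, fit)))
            if dev_fam is not None:
                dev_fam[kept] = -2.0 * float(np.sum(
                    loglik_family_pointwise(state.theta, fit)))
            kept += 1

    denom = max(kept, 1)
    latent_means = {"U": u_acc / denom, "a": a_acc / denom,
                    "d": d_acc / denom, "b": b_acc / denom}
    diagnostics = None
    if config.compute_diagnostics and kept >= 4:
        diagnostics = _chain_diagnostics(stored)
    return PosteriorSamples(
        spec=spec, config=config, draws=stored, latent_means=latent_means,
        deviance_cond=dev_cond, deviance_marg=dev_marg, deviance_subject=dev_subj,
        deviance_family=dev_fam, diagnostics=diagnostics,
        final_state=state,
        path_derivatives=np.array(derivs) if derivs is not None else None,
    )


def _chain_diagnostics(stored: dict[str, np.ndarray]) -> pd.DataFrame:
    """Effective sample size and split-Rhat per scalar (single-chain split)."""
    import arviz as az

    rows = []
    for name, arr in stored.items():
        half = len(arr) // 2
        split = np.stack([arr[:half], arr[half:2 * half]])
        if np.allclose(arr.var(), 0.0):
            ess, rhat = float(len(arr)), 1.0
        else:
            ess = float(az.ess(np.asarray(arr)[None, :]))
            rhat = float(az.rhat(split))
        rows.append({"parameter": name, "ess": ess, "rhat": rhat})
    return pd.DataFrame(rows).set_index("parameter")
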