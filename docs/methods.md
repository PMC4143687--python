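# Methods

`pleiolvm` fits a Bayesian latent-variable model for detecting pleiotropy —
one genetic variant influencing several phenotypes — in longitudinal family
data, such as repeated blood-pressure measurements on members of extended
pedigrees.

## Model

Index families by `c`, individuals by `i`, visits by `t` and phenotypes by
`j`. A single latent variable `U_cit` carries the shared signal:

**Measurement equations.** For a continuous phenotype,

    y_citj = beta0_j + w_cit' beta_j + lam_j U_cit + b_cij + e_citj,
    e_citj ~ N(0, sigma_j^2).

For a binary phenotype the same linear predictor (including `b_cij`) drives a
probit link: an augmented variable `eta_citj` with unit residual variance
determines `y = 1{eta > 0}`.

* `w_cit` — covariates with *direct* (phenotype-specific) effects,
* `lam_j` — factor loading of phenotype `j` on the latent variable,
* `b_cij ~ N(0, tau_j^2)` — individual-level phenotype-specific effect that
  absorbs within-person correlation across visits.

**Structural equation.** The latent variable aggregates the *indirect*
covariate effects and the familial structure:

    U_cit = x_cit' alpha + a_c + d_ci + eps_cit,
    a_c ~ N(0, sigma_a^2),  d_ci ~ N(0, sigma_d^2),  eps_cit ~ N(0, 1).

The unit residual variance of `eps` fixes the latent scale; the sign is fixed
by constraining `lam_1 > 0` (enforced by reflecting the whole state
`(lam, alpha, U, a, d) -> -(...)` whenever `lam_1` goes negative, which is a
measure-preserving fold of the exactly symmetric posterior).

A SNP entering `x` with coefficient `alpha_snp != 0` shifts every phenotype
with a nonzero loading at once — that is the operational definition of
pleiotropy here.

## Priors

* loadings `lam_j`: folded Student-t on the magnitude (default 3 degrees of
  freedom, scale 1), implemented by the scale-mixture representation
  `lam_j | phi_j ~ N(0, phi_j)`, `phi_j ~ InvGamma(nu/2, nu s^2/2)`;
* regression blocks: `beta_j ~ N(0, 1)`, `alpha ~ N(0, 1)` componentwise;
* intercepts: `beta0_j ~ N(0, 100^2)`. The wide default matters: with
  mmHg-scale phenotypes a scale-10 intercept prior visibly biases the
  indirect coefficients (the latent mean absorbs the shrunk intercept), which
  showed up as a +20% bias in `alpha_age` and failed interval coverage;
* variances: `InvGamma(0.01, 0.01)`.

All scales are configurable through `PriorSpec`.

## Posterior computation

A Gibbs sampler with conjugate full conditionals updates, in order: the
probit augmentation, `U` (jointly, precision-weighted across phenotypes and
the structural equation), the random effects `(a, d, b)`, the loadings
`(lam, phi)`, the regression blocks `(beta0, beta)` and `alpha`, and the
variance components.

Two optional moves fix the slow mixing that plain Gibbs exhibits on this
posterior (split-Rhat up to ~2.8 at the full study scale without them):

* **parameter expansion** for the loadings (the `phi` scale mixture above),
* a **generalized-Gibbs scale move** along the ridge
  `(U, a, d, alpha, sigma_a, sigma_d) -> c (...)`, `lam -> lam / c`, which the
  likelihood is invariant to except through the structural residual, plus
  **translation moves** on the exactly non-identified shifts (`a_c` vs `d_ci`
  within a family; `beta0_j` vs the mean of `b_.j`).

Both toggles default to on; turning them off leaves a plain Gibbs sampler
with the same stationary distribution (the un-accelerated loading update is a
slice sampler on the exact conditional).

### Sampler validation

* every full conditional was compared in total variation against a
  grid-quadrature oracle of the augmented log joint (100 000 redraws from a
  fixed conditioning state on a 3-family mixed continuous/binary design);
  the worst of 15 checks was TV = 0.006, at the binomial noise floor of the
  estimator itself;
* the whole kernel passes a Geweke two-simulator ("successive-conditional")
  comparison of prior-predictive moments;
* at the motivating scale (16 families, ~400 individuals, 1–4 visits), 95%
  HPD intervals covered the generating loadings and indirect effects in
  18–19 of 20 replicates, with a mean fitted loading ratio of 1.81 against a
  generating ratio of 1.73.

## Bayes factors by path sampling

The evidence for pleiotropy is the Bayes factor for `alpha_snp != 0`. A
geometric path scales the SNP's structural contribution by `t in [0, 1]`; the
log Bayes factor is the integral over `t` of the posterior mean of the path
derivative, estimated by short warm-started chains on an 11-point grid (by default) with
trapezoid integration. `log BF > 0.5` declares pleiotropy.

Calibration on simulated data (20 replicates each): with `alpha_snp = 0` the
rule false-detected 0/20 (log BF between −2.2 and −0.6); with a SNP
explaining half the residual latent variance at MAF 0.3 it detected 20/20
(log BF 11–28). The shared trapezoid integrator also reproduces a closed-form
conjugate-model log Bayes factor to within 0.02.

## DIC and the direct-vs-indirect model grid

Whether each covariate acts directly (on the phenotypes) or indirectly
(through the latent variable) is a model-selection question: with 3
covariates there are 2^3 grid cells. `dic_scan` fits each cell and ranks by
DIC = Dbar + pD.

**Deviance focus.** DIC depends on which likelihood the deviance uses. The
conditional (on `U`, `b`) focus is almost blind to covariate placement — a
free per-record `U` absorbs any structural mean — and latent-conditional
deviances carry Monte-Carlo noise (sd 40–550) that swamps the ~1-unit
parsimony signal. When all phenotypes are continuous the fully marginal
family-block likelihood is available in closed form (the per-family Gaussian
with `a, d, b, U` and noise integrated out, evaluated in O(family size) by a
Woodbury/low-rank identity), depends on `theta` alone, and gives pD close to
the identified parameter count with sd(deviance) ~ 5. It is the default focus
for all-continuous models and the one the selection study uses; with a binary
phenotype the default integrates `U` by Gauss–Hermite quadrature and the
other focuses remain available.

**Selection study and an honest limitation.** Ten replicates were generated
at the study scale with sex direct, age + SNP indirect, and an identifiable
truth (opposite-sign sex effects, which no loading-proportional indirect path
can mimic; SNP effect 0.5 at MAF 0.3). DIC chose the generating cell in
6 of 10 replicates. Every miss picked `direct: sex+age | indirect: snp` — a
cell that *exactly nests* the truth, because moving a covariate from indirect
to direct can always reproduce the likelihood via `beta_j = lam_j alpha`.
Against such a superset the DIC margin behaves like `2 − chi^2_1` overfit
noise (observed margins: wins +1.6 to +3.3, losses −0.3 to −2.2), so no data
size pushes the per-replicate success probability much above ~0.75–0.85.
This is the familiar AIC-like property of DIC — a small but irreducible
chance of preferring a one-parameter-larger nesting model — and should be
kept in mind when reading grid scans: cells within ~2 DIC units of the best
are statistically indistinguishable.

## Scope of the data generator

`simulate_dataset` draws from exactly the hierarchy above: it is a model
simulator, not a population-genetics simulator. Families are independent;
within-family dependence enters only through `a_c` (plus `d_ci` within
individuals); SNP dosages are Hardy–Weinberg draws shared by all members of
an individual's record rows but are *not* transmitted along a pedigree;
covariates are stationary across visits except age, which increments per
visit. Defaults mirror the motivating blood-pressure application (loadings
13.15/7.60, SBP/DBP-scale variances, 1–4 visits with the observed visit-count
mix). Missingness can be injected for binary phenotypes; continuous
missingness is handled at fit time through the observation masks.

## Other limitations

* a single latent variable: genuinely multi-factor pleiotropy is projected
  onto one direction;
* probit-only binary links, and binary phenotypes exclude the fully marginal
  DIC focus;
* the path-sampling grid (11 points) and chain lengths trade accuracy for
  time; `mc_se` is reported and should be checked against the decision
  margin;
* DIC superset selection noise, as described above.
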