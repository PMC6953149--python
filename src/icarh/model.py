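"""Joint density of the integrative CAR-horseshoe (iCARH) model.

The model couples three layers:

* a CAR observation likelihood
  ``x_it^e | mu_it ~ N(mu_it, (I_M - C(phi^e))^{-1} sigma^2)`` with
  group-specific pathway-dependence parameters phi^e,
* a horseshoe-type shrinkage hierarchy linking metabolites to a companion
  omic data type, ``beta_mk | lambda_mk, sigma_beta_m ~ N(0, lambda_mk^2
  sigma_beta_m^2)`` with ``lambda_mk ~ St+(tau, 0, 1)`` (tau = 1 recovers
  the original horseshoe), and
* a mixed-effects design layer
  ``mu_itm = alpha_m + gamma_im + beta_m' y_it + nu_itm`` with individual
  random effects gamma and AR(1) temporal effects nu.

Every component is exposed as an evaluable log-density term so the joint
density decomposes additively; the Hamiltonian Monte Carlo engine in
:mod:`icarh.inference` consumes the same terms with analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml
from scipy import integrate, stats
from scipy.special import betaln, gammaln

from .pathways import PathwayModel, car_covariance

__all__ = [
    "ModelSpec",
    "SamplerSettings",
    "LatentState",
    "log_joint",
    "mean_structure",
    "loglik_observation",
    "horseshoe_logprior",
    "kappa_pdf",
    "expected_kappa",
    "ar1_logprior",
    "beta_posterior_mean_oracle",
]


@dataclass
class SamplerSettings:
    """HMC sampler configuration (defaults mirror the reference analysis)."""

    iterations: int = 2000
    warmup: int = 1000
    chains: int = 2
    seed: int = 0
    max_treedepth: int = 6
    target_accept: float = 0.8

    def __post_init__(self):
        if not (0 < self.warmup < self.iterations):
            raise ValueError("need 0 < warmup < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class ModelSpec:
    """Hyperparameters and structural switches of the iCARH model.

    Parameters
    ----------
    tau : float
        Global sparsity level: degrees of freedom of the half-Student-t
        prior on the local shrinkage scales lambda_mk.  tau = 1 is the
        horseshoe; larger tau shrinks more aggressively.
    psi : float, optional
        Shape of the inverse-gamma(psi, psi - 1) prior on the metabolite
        noise variance sigma^2.  Defaults to N*T/4 at fit time (2*psi
        pseudo-observations against N*T real ones).
    gamma_prior : (shape, rate)
        Inverse-gamma prior on the individual-effect variances
        sigma2_gamma_m; the informative default (1, 0.1) encodes low
        within-group biological variability.
    nu_prior : (shape, rate), optional
        Inverse-gamma prior on the temporal variances sigma2_nu_m.
        Defaults to (T/4, T/4 - 1) at fit time.
    phi_prior : {"beta", "uniform"}
        Boundary-favouring beta-type prior (default) or flat prior on each
        phi_p over its admissible interval.
    treatment_mode : {"indicator", "continuous"}
        "indicator" estimates a per-metabolite treatment effect alpha_m;
        "continuous" replaces it with beta_alpha_m * y_drug_it driven by a
        measured drug level.
    alpha_scale : float
        Scale of the wide normal stand-in for the flat prior on alpha_m
        (data are standardized before fitting, so 100 is effectively flat).
    """

    tau: float = 1.2
    psi: Optional[float] = None
    gamma_prior: tuple = (1.0, 0.1)
    nu_prior: Optional[tuple] = None
    phi_prior: str = "beta"
    treatment_mode: str = "indicator"
    alpha_scale: float = 100.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.psi is not None and self.psi <= 0:
            raise ValueError("psi must be positive")
        if self.phi_prior not in ("beta", "uniform"):
            raise ValueError("phi_prior must be 'beta' or 'uniform'")
        if self.treatment_mode not in ("indicator", "continuous"):
            raise ValueError("treatment_mode must be 'indicator' or 'continuous'")
        if isinstance(self.sampler, dict):
            self.sampler = SamplerSettings(**self.sampler)

    # -- config round-trip ------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        for key in ("gamma_prior", "nu_prior"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class LatentState:
    """A single configuration of all latent variables.

    Shapes: alpha (M,) — or beta_alpha (M,) in continuous treatment mode;
    gamma (N, M); nu (N, T, M); theta (M,); beta (M, K); lam (M, K);
    sigma2 scalar; sigma2_beta, sigma2_gamma, sigma2_nu (M,);
    phi_cases, phi_controls (P,).
    """

    alpha: np.ndarray
    gamma: np.ndarray
    nu: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    sigma2: float
    sigma2_beta: np.ndarray
    sigma2_gamma: np.ndarray
    sigma2_nu: np.ndarray
    phi_cases: np.ndarray
    phi_controls: np.ndarray

    def __post_init__(self):
        for name in ("sigma2_beta", "sigma2_gamma", "sigma2_nu"):
            if (np.asarray(getattr(self, name)) <= 0).any():
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be strictly positive")
        if (np.asarray(self.lam) <= 0).any():
            raise ValueError("lambda scales must be strictly positive")


def mean_structure(state: LatentState, Y: np.ndarray, i: int, t: int,
                   y_drug: Optional[np.ndarray] = None) -> np.ndarray:
    """Mean metabolite level mu_it = alpha + gamma_i + beta Y_it + nu_it.

    In continuous treatment mode (``y_drug`` given) the treatment term is
    ``beta_alpha_m * y_drug[i, t]`` with ``state.alpha`` holding beta_alpha.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(Y).all():
        raise ValueError("Y must be finite")
    beta = np.atleast_2d(state.beta)
    if Y.shape[-1] != beta.shape[1]:
        raise ValueError(
            f"beta has {beta.shape[1]} columns but Y has {Y.shape[-1]} variables"
        )
    treatment = state.alpha if y_drug is None else state.alpha * y_drug[i, t]
    return treatment + state.gamma[i] + beta @ Y[i, t] + state.nu[i, t]


def loglik_observation(x_it, mu_it, pm: PathwayModel, phi_e, sigma2) -> float:
    """Log density of one observation vector under the group's CAR covariance."""
    cov = car_covariance(pm, phi_e, sigma2)
    return stats.multivariate_normal.logpdf(np.asarray(x_it, float),
                                            mean=np.asarray(mu_it, float),
                                            cov=cov)


def horseshoe_logprior(beta, lam, sigma2_beta, tau) -> float:
    """Log prior of the shrinkage layer: sum over (m, k) of
    ``log N(beta_mk; 0, lambda_mk^2 sigma2_beta_m)`` plus
    ``log St+(lambda_mk; tau, 0, 1)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    s2b = np.broadcast_to(np.asarray(sigma2_beta, dtype=float)[..., None],
                          beta.shape)
    if (lam <= 0).any() or (s2b <= 0).any():
        return -np.inf
    var = lam ** 2 * s2b
    normal = -0.5 * np.log(2 * np.pi * var) - beta ** 2 / (2 * var)
    # half-Student-t(tau, 0, 1) on lambda > 0: twice the t density
    half_t = (
        np.log(2.0)
        + gammaln((tau + 1) / 2)
        - gammaln(tau / 2)
        - 0.5 * np.log(tau * np.pi)
        - (tau + 1) / 2 * np.log1p(lam ** 2 / tau)
    )
    return float(normal.sum() + half_t.sum())


def kappa_pdf(kappa, tau, sigma_beta):
    """Density of the shrinkage coefficient kappa = 1/(1 + lambda^2 sigma_beta^2 / tau).

    Obtained by change of variables from lambda ~ St+(tau, 0, 1):

        p(kappa | tau, sigma_beta) = sigma_beta^tau / B(tau/2, 1/2)
            * kappa^{tau/2 - 1} (1 - kappa)^{-1/2}
            * (1 - kappa + kappa sigma_beta^2)^{-(tau+1)/2}

    For sigma_beta = 1 this is the Beta(tau/2, 1/2) density; with tau = 1 in
    addition it is the horseshoe-shaped Beta(1/2, 1/2).  kappa near 1 means
    full shrinkage of beta_mk, kappa near 0 none.  Returns 0 outside (0, 1).
    """
    if tau <= 0 or sigma_beta <= 0:
        raise ValueError("tau and sigma_beta must be positive")
    kappa = np.asarray(kappa, dtype=float)
    out = np.zeros_like(kappa, dtype=float)
    ok = (kappa > 0) & (kappa < 1)
    k = kappa[ok]
    log_pdf = (
        tau * np.log(sigma_beta)
        - betaln(tau / 2, 0.5)
        + (tau / 2 - 1) * np.log(k)
        - 0.5 * np.log1p(-k)
        - (tau + 1) / 2 * np.log1p(k * (sigma_beta ** 2 - 1))
    )
    out[ok] = np.exp(log_pdf)
    if out.ndim == 0:
        return float(out)
    return out


def expected_kappa(tau, sigma_beta=None, improper_truncation=(1e-3, 1e3)) -> float:
    """Prior mean of the shrinkage coefficient, E[kappa | tau].

    With ``sigma_beta`` fixed, integrates ``kappa * p(kappa | tau, sigma_beta)``
    by adaptive quadrature (for sigma_beta = 1 this is the Beta(tau/2, 1/2)
    mean tau/(tau + 1)).  With ``sigma_beta=None`` the global scale is
    marginalized under the improper 1/sigma^2 prior truncated to
    ``improper_truncation`` (a proper surrogate; the improper integral is
    only defined up to such a truncation).  E[kappa | tau] increases with
    tau: larger tau means stronger global shrinkage.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")

    if sigma_beta is not None:
        val, err = integrate.quad(
            lambda k: k * kappa_pdf(k, tau, sigma_beta), 0, 1, limit=200
        )
        if err > 1e-6:
            raise RuntimeError(
                f"quadrature for E[kappa] did not converge (err={err:.2e})"
            )
        return float(val)

    lo, hi = improper_truncation
    if not (0 < lo < hi):
        raise ValueError("truncation bounds must satisfy 0 < lo < hi")
    # p(sigma_beta^2) ∝ 1/sigma_beta^2 on the truncation  <=>  log sigma_beta uniform
    norm = np.log(hi / lo)

    def integrand(log_s, k):
        return k * kappa_pdf(k, tau, np.exp(log_s)) / norm

    val, err = integrate.dblquad(
        integrand, 0, 1, np.log(lo), np.log(hi), epsabs=1e-8
    )
    if err > 1e-5:
        raise RuntimeError(
            f"quadrature for E[kappa] did not converge (err={err:.2e})"
        )
    return float(val)


def ar1_logprior(nu, theta, sigma2_nu) -> float:
    """Log density of the AR(1) temporal effects.

    ``nu_itm | nu_i,t-1,m ~ N(theta_m nu_i,t-1,m, sigma2_nu_m)`` for t >= 2,
    with a stationary initialization ``nu_i1m ~ N(0, sigma2_nu_m/(1 - theta_m^2))``
    so that the marginal variance matches the stationary AR(1) variance used
    by the shrinkage-layer posterior-mean identity.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.ndim != 3:
        raise ValueError("nu must be N x T x M")
    N, T, M = nu.shape
    if T < 2:
        raise ValueError("need T >= 2 time points")
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (M,))
    s2 = np.broadcast_to(np.asarray(sigma2_nu, dtype=float), (M,))
    if (np.abs(theta) >= 1).any():
        return -np.inf
    s2_init = s2 / (1 - theta ** 2)
    lp = stats.norm.logpdf(nu[:, 0, :], 0.0, np.sqrt(s2_init)).sum()
    resid = nu[:, 1:, :] - theta * nu[:, :-1, :]
    lp += stats.norm.logpdf(resid, 0.0, np.sqrt(s2)).sum()
    return float(lp)


def log_joint(state: LatentState, dataset, pm: PathwayModel,
              spec: ModelSpec) -> tuple:
    """Joint log density of data and latents, as (total, parts).

    ``parts`` maps component names to their additive contributions:
    observation likelihood, shrinkage layer, AR(1) temporal effects,
    individual effects, phi priors, treatment-effect prior and the variance
    priors.  The total is what the sampler targets (up to the
    transformation Jacobians of the unconstrained parameterization).
    """
    from scipy.stats import cauchy, invgamma, norm

    from .pathways import phi_prior_logpdf

    X, Y = dataset.X, dataset.Y
    N, T, M = X.shape
    psi = spec.psi if spec.psi is not None else N * T / 4.0
    a_n, b_n = spec.nu_prior if spec.nu_prior is not None \
        else (T / 4.0, T / 4.0 - 1.0)

    parts = {}
    lik = 0.0
    for e, idx in (("controls", dataset.control_indices),
                   ("cases", dataset.case_indices)):
        phi_e = state.phi_controls if e == "controls" else state.phi_cases
        for i in idx:
            for t in range(T):
                mu_it = mean_structure(state, Y, i, t, y_drug=dataset.y_drug
                                       if spec.treatment_mode == "continuous"
                                       else None)
                lik += loglik_observation(X[i, t], mu_it, pm, phi_e,
                                          state.sigma2)
    parts["likelihood"] = lik
    parts["shrinkage"] = horseshoe_logprior(
        state.beta, state.lam, state.sigma2_beta, spec.tau
    )
    parts["temporal"] = ar1_logprior(state.nu, state.theta, state.sigma2_nu)
    parts["individual"] = float(
        norm.logpdf(state.gamma, 0.0,
                    np.sqrt(state.sigma2_gamma)[None, :]).sum()
    )
    phi_lp = 0.0
    for phi_e in (state.phi_controls, state.phi_cases):
        for p in pm.active:
            if spec.phi_prior == "beta":
                phi_lp += phi_prior_logpdf(phi_e[p], pm.phi_lower[p],
                                           pm.phi_upper[p])
            else:
                phi_lp += -np.log(pm.phi_upper[p] - pm.phi_lower[p])
    parts["phi_prior"] = phi_lp
    parts["treatment_prior"] = float(
        norm.logpdf(state.alpha, 0.0, spec.alpha_scale).sum()
    )
    if (np.abs(state.theta) >= 1).any():
        parts["theta_prior"] = -np.inf
    else:
        parts["theta_prior"] = -len(np.atleast_1d(state.theta)) * np.log(2.0)
    parts["variance_priors"] = float(
        invgamma.logpdf(state.sigma2, psi, scale=psi - 1)
        + invgamma.logpdf(state.sigma2_gamma, spec.gamma_prior[0],
                          scale=spec.gamma_prior[1]).sum()
        + invgamma.logpdf(state.sigma2_nu, a_n, scale=b_n).sum()
        + (cauchy.logpdf(np.sqrt(state.sigma2_beta)) + np.log(2.0)).sum()
    )
    total = float(sum(parts.values()))
    return total, parts


def beta_posterior_mean_oracle(Y, kappa_m, tau, mu_tm, theta_m,
                               sigma2_nu, sigma2_gamma) -> np.ndarray:
    """Ridge-like conditional posterior mean of beta_m given the shrinkage
    coefficients kappa_m.

    ``E(beta_m | Y, kappa_m, tau, mu_tm) = (sum_t Y_t' Sigma_m^{-1} Y_t
    + tau Upsilon_m)^{-1} sum_t Y_t' Sigma_m^{-1} mu_tm`` with
    ``Sigma_m = (sigma2_nu/(1 - theta_m^2) + sigma2_gamma) I_N`` and
    ``Upsilon_m = diag(1/kappa_mk - 1)``.  With tau*Upsilon_m = tau*I this is
    exactly ridge regression.  Serves as a conditional-behaviour oracle for
    the sampler, not as a fitting path.  kappa_mk = 1 means an infinite
    penalty: that coefficient is exactly zero.
    """
    Y = np.asarray(Y, dtype=float)  # (T, N, K) or (N, T, K)
    if Y.ndim != 3:
        raise ValueError("Y must be a 3-D array of per-time design matrices")
    mu = np.asarray(mu_tm, dtype=float)
    kappa = np.asarray(kappa_m, dtype=float)
    K = Y.shape[-1]
    if not (0 < kappa).all() or not (kappa <= 1).all():
        raise ValueError("kappa entries must lie in (0, 1]")
    if abs(theta_m) >= 1:
        raise ValueError("theta_m must satisfy |theta| < 1")
    s2 = sigma2_nu / (1 - theta_m ** 2) + sigma2_gamma

    free = kappa < 1.0  # kappa == 1 -> infinite penalty -> exact zero
    beta = np.zeros(K)
    if not free.any():
        return beta
    Yf = Y[..., free]
    ups = 1.0 / kappa[free] - 1.0
    # Sigma_m is a scalar multiple of I_N, so Y_t' Sigma^{-1} Y_t = Y_t'Y_t / s2
    gram = np.einsum("tnk,tnl->kl", Yf, Yf) / s2
    rhs = np.einsum("tnk,tn->k", Yf, mu) / s2
    beta[free] = np.linalg.solve(gram + tau * np.diag(ups), rhs)
    return beta
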