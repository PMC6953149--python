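"""Markov chain Monte Carlo inference for the iCARH model.

The sampler targets the *marginal* posterior in which the Gaussian random
effects — individual perturbations gamma_im and AR(1) temporal effects
nu_itm — are integrated out analytically.  Each individual's T x M
observation block is then marginally Gaussian with covariance

    Sigma_e = kron(sigma^2 (I_M - C(phi^e))^{-1}, I_T)
              + blockdiag_m [ sigma2_gamma_m J_T
                              + sigma2_nu_m / (1 - theta_m^2) * theta_m^{|t-t'|} ],

identical across individuals within an experimental group, so the posterior
over the structural parameters is mathematically identical to the fully
latent hierarchy while its geometry is vastly easier to explore.

One sweep of the sampler combines three exact blocks:

* the covariance block (theta, sigma^2, sigma2_gamma, sigma2_nu, phi^e) is
  updated by dynamic Hamiltonian Monte Carlo (multinomial NUTS-style tree
  doubling, dual-averaging step size, dense metric estimated during
  warmup) with analytic gradients of the marginal log density;
* the mean block (alpha, beta) is drawn exactly from its Gaussian
  conditional (a generalized-least-squares draw under the marginal
  covariance);
* the shrinkage scales (lambda_mk, sigma_beta_m), conditionally
  independent of the data given beta, are updated by univariate slice
  sampling.

Unconstrained transforms: log for scales, tanh for AR coefficients, and a
scaled logit for each phi so every draw respects positive definiteness by
construction.  Posterior draws of gamma and nu are recovered afterwards by
exact conditional Gaussian sampling given each retained draw, so the
returned samples cover every latent block.  All gradients are analytic;
the test suite checks them against finite differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import OmicsDataset
from .model import ModelSpec
from .pathways import PathwayModel
from scipy.linalg.lapack import dpotri as _dpotri

__all__ = ["PosteriorSamples", "fit", "diagnostics"]

logger = logging.getLogger("icarh")

DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergent transition


# ---------------------------------------------------------------------------
# linear-algebra helpers (LAPACK, no finiteness checks)
# ---------------------------------------------------------------------------

def _cholesky(A):
    from scipy.linalg.lapack import dpotrf

    L, info = dpotrf(A, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return L


def _chol_inverse(L):
    """Inverse of Q = L L^T from its lower Cholesky factor (LAPACK dpotri)."""
    from scipy.linalg.lapack import dpotri

    inv, info = dpotri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    # dpotri fills the lower triangle only
    inv = np.tril(inv)
    inv = inv + inv.T
    inv[np.diag_indices_from(inv)] *= 0.5
    return inv


def _tri_inverse(L):
    from scipy.linalg.lapack import dtrtri

    inv, info = dtrtri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("dtrtri failed")
    return np.tril(inv)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _slice_1d(logf, x0, rng, width=1.0, max_steps=20):
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    f0 = logf(x0)
    y = f0 - rng.exponential()
    left = x0 - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if logf(left) <= y:
            break
        left -= width
    for _ in range(max_steps):
        if logf(right) <= y:
            break
        right += width
    for _ in range(50):
        x1 = rng.uniform(left, right)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


# ---------------------------------------------------------------------------
# the marginal model
# ---------------------------------------------------------------------------

class _ZetaPacker:
    """Layout of the unconstrained covariance-block vector."""

    def __init__(self, M, Pa):
        self.M, self.Pa = M, Pa
        sizes = {
            "theta_u": M,
            "log_s2": 1,
            "log_s2g": M,
            "log_s2n": M,
            "w_phi": 2 * Pa,
        }
        self.slices = {}
        start = 0
        for name, size in sizes.items():
            self.slices[name] = slice(start, start + size)
            start += size
        self.dim = start

    def unpack(self, z):
        s = self.slices
        return dict(
            theta_u=z[s["theta_u"]],
            log_s2=z[s["log_s2"]][0],
            log_s2g=z[s["log_s2g"]],
            log_s2n=z[s["log_s2n"]],
            w_phi=z[s["w_phi"]].reshape(2, self.Pa),
        )


class _MarginalModel:
    """Marginal likelihood machinery shared by all sampler blocks."""

    def __init__(self, dataset: OmicsDataset, pm: PathwayModel, spec: ModelSpec):
        self.x = dataset.X
        self.Y = dataset.Y
        N, T, M = self.x.shape
        K = self.Y.shape[2]
        self.N, self.T, self.M, self.K = N, T, M, K
        self.D = T * M
        self.spec = spec
        self.pm = pm

        self.groups = [dataset.control_indices, dataset.case_indices]

        active = pm.active
        self.active = active
        self.Pa = len(active)
        if self.Pa:
            self.Wstack = np.stack([pm.car_terms[p] for p in active])
            self.lo = pm.phi_lower[active]
            self.hi = pm.phi_upper[active]
            self.width = self.hi - self.lo
        else:
            self.Wstack = np.zeros((0, M, M))
            self.lo = self.hi = self.width = np.zeros(0)

        if spec.treatment_mode == "continuous":
            if dataset.y_drug is None:
                raise ValueError("continuous treatment mode needs y_drug")
            self.d = dataset.y_drug
        else:
            self.d = np.ones((N, T))

        self.psi = spec.psi if spec.psi is not None else N * T / 4.0
        if self.psi <= 1:
            raise ValueError("psi must exceed 1 so the sigma^2 prior is proper")
        self.a_g, self.b_g = spec.gamma_prior
        self.a_n, self.b_n = spec.nu_prior if spec.nu_prior is not None \
            else (T / 4.0, T / 4.0 - 1.0)
        if self.a_n <= 0 or self.b_n <= 0:
            raise ValueError("nu_prior shape/rate must be positive (need T > 4 "
                             "for the default; pass nu_prior explicitly)")
        self.packer = _ZetaPacker(M, self.Pa)
        self.eyeM = np.eye(M)
        self.eyeT = np.eye(T)
        self.Delta = np.abs(np.arange(T)[:, None] - np.arange(T)[None, :])
        self.Jt = np.ones((T, T))
        self._sig_buf = np.empty((M, T, M, T))
        self._triu_idx = np.triu_indices(self.D, k=1)
        self._diag_idx = np.diag_indices(self.D)
        self._midx = np.arange(M)
        self._fact_cache = (None, None)

        # per-group treatment/covariate design moments for the GLS block:
        # w^i_{j,t} stacks (d_it, y_it1..K)
        self.Wdes = np.concatenate(
            [self.d[:, None, :], self.Y.transpose(0, 2, 1)], axis=1
        )  # (N, K+1, T)
        self.Mw = [
            np.einsum("ijt,ils->jtls", self.Wdes[idx], self.Wdes[idx])
            for idx in self.groups
        ]
        self.xvec = self.x.transpose(0, 2, 1).reshape(N, self.D)  # m-major
        self._gls_path = np.einsum_path(
            "mtns,jtls->mjnl", np.empty((M, T, M, T)),
            np.empty((K + 1, T, K + 1, T)), optimize="optimal")[0]

    # -- covariance assembly ----------------------------------------------
    def _random_effect_blocks(self, theta, s2g, s2n):
        one_m_t2 = 1.0 - theta ** 2
        c = s2n / one_m_t2
        Rth = theta[:, None, None] ** self.Delta
        B = s2g[:, None, None] * self.Jt + c[:, None, None] * Rth
        return B, Rth, c, one_m_t2

    def _car_inverse(self, phi_active):
        """(I - C(phi))^{-1}, or None when not positive definite."""
        if self.Pa == 0:
            return self.eyeM
        C = np.tensordot(phi_active, self.Wstack, axes=1)
        try:
            L = _cholesky(self.eyeM - C)
        except np.linalg.LinAlgError:
            return None
        return _chol_inverse(L)

    def _assemble_sigma(self, B, V, lower_only=False):
        """Sigma = blockdiag(B_m) + kron(V, I_T) in (m, t) ordering.

        With ``lower_only`` the strict upper triangle is zeroed so that
        LAPACK's lower-triangle routines leave clean zeros there.
        """
        Sig4 = np.multiply(V[:, None, :, None], self.eyeT[None, :, None, :],
                           out=self._sig_buf)
        idx = np.arange(self.M)
        Sig4[idx, :, idx, :] += B
        Sig = Sig4.reshape(self.D, self.D)
        if lower_only:
            Sig[self._triu_idx] = 0.0
        return Sig

    def _zeta_pieces(self, zeta):
        p = self.packer.unpack(zeta)
        theta = np.tanh(p["theta_u"])
        sigma2 = np.exp(p["log_s2"])
        s2g = np.exp(p["log_s2g"])
        s2n = np.exp(p["log_s2n"])
        if self.Pa:
            q = _sigmoid(p["w_phi"])
            phi = self.lo + self.width * q
        else:
            q = phi = np.zeros((2, 0))
        return p, theta, sigma2, s2g, s2n, q, phi

    def resid(self, alpha, beta):
        NT = self.N * self.T
        mean = self.d[:, :, None] * alpha[None, None, :] \
            + (self.Y.reshape(NT, self.K) @ beta.T).reshape(self.N, self.T,
                                                            self.M)
        return self.x - mean

    def group_resid_rows(self, resid, idx):
        return resid[idx].transpose(0, 2, 1).reshape(len(idx), self.D)

    # -- covariance-block log density and gradient ------------------------
    def core_logp_grad(self, zeta, resid):
        """Marginal log density of the covariance block given the mean."""
        M, T, D = self.M, self.T, self.D
        p, theta, sigma2, s2g, s2n, q, phi = self._zeta_pieces(zeta)
        grad = np.zeros_like(zeta)
        sl = self.packer.slices

        B, Rth, c, one_m_t2 = self._random_effect_blocks(theta, s2g, s2n)
        dRdth = np.where(self.Delta > 0,
                         self.Delta * theta[:, None, None]
                         ** np.maximum(self.Delta - 1, 0), 0.0)
        dBdth = (c * 2 * theta / one_m_t2)[:, None, None] * Rth \
            + c[:, None, None] * dRdth

        logp = 0.0
        g_s2 = 0.0
        g_s2g = np.zeros(M)
        g_s2n = np.zeros(M)
        g_theta = np.zeros(M)
        cache_linv = []

        for e, idx in enumerate(self.groups):
            ne = len(idx)
            U = self._car_inverse(phi[e])
            if U is None:
                return -np.inf, grad
            Sig = self._assemble_sigma(B, sigma2 * U, lower_only=True)
            try:
                Lsig = _cholesky(Sig)
            except np.linalg.LinAlgError:
                return -np.inf, grad
            logdet = 2.0 * np.log(np.diag(Lsig)).sum()
            Pinv, info = _dpotri(Lsig, lower=1)
            if info != 0:
                return -np.inf, grad
            P = Pinv + Pinv.T  # upper triangle of Pinv is zero (lower_only)
            P[self._diag_idx] *= 0.5
            cache_linv.append(P)
            Re = self.group_resid_rows(resid, idx)
            Amat = Re @ P
            quad = float(np.dot(Amat.ravel(), Re.ravel()))
            logp += -0.5 * ne * D * np.log(2 * np.pi) - 0.5 * ne * logdet \
                - 0.5 * quad

            P4 = P.reshape(M, T, M, T)
            A4 = Amat.reshape(ne, M, T)
            # per-metabolite diagonal blocks and time-trace of
            # G = Sigma^{-1} S Sigma^{-1} - ne Sigma^{-1}
            Gblocks = A4.transpose(1, 2, 0) @ A4.transpose(1, 0, 2) \
                - ne * P4[self._midx, :, self._midx, :]
            Xa = np.ascontiguousarray(A4.transpose(1, 0, 2)).reshape(M, -1)
            H = Xa @ Xa.T - ne * np.trace(P4, axis1=1, axis2=3)

            g_s2g += 0.5 * Gblocks.sum(axis=(1, 2))
            g_s2n += 0.5 * (Gblocks * Rth).sum(axis=(1, 2)) / one_m_t2
            g_theta += 0.5 * (Gblocks * dBdth).sum(axis=(1, 2))
            g_s2 += 0.5 * float(np.sum(H * U))
            if self.Pa:
                dphi = np.empty(self.Pa)
                for j in range(self.Pa):
                    UWU = U @ self.Wstack[j] @ U
                    dphi[j] = 0.5 * sigma2 * float(np.sum(H * UWU))
                dw = dphi * self.width * q[e] * (1.0 - q[e])
                if self.spec.phi_prior == "beta":
                    logp += (0.5 * np.log(q[e]) + 0.5 * np.log1p(-q[e])).sum()
                    dw += 0.5 - q[e]
                else:
                    logp += (np.log(q[e]) + np.log1p(-q[e])).sum()
                    dw += 1.0 - 2.0 * q[e]
                grad[sl["w_phi"]].reshape(2, self.Pa)[e] = dw

        # covariance-block priors (with log/tanh Jacobians)
        logp += -self.psi * p["log_s2"] - (self.psi - 1.0) * np.exp(-p["log_s2"])
        grad[sl["log_s2"]] = g_s2 * sigma2 - self.psi \
            + (self.psi - 1.0) * np.exp(-p["log_s2"])

        logp += float((-self.a_g * p["log_s2g"] - self.b_g / s2g).sum())
        grad[sl["log_s2g"]] = g_s2g * s2g - self.a_g + self.b_g / s2g

        logp += float((-self.a_n * p["log_s2n"] - self.b_n / s2n).sum())
        grad[sl["log_s2n"]] = g_s2n * s2n - self.a_n + self.b_n / s2n

        logp += float(np.log1p(-theta ** 2).sum())
        grad[sl["theta_u"]] = g_theta * (1.0 - theta ** 2) - 2.0 * theta

        self._fact_cache = (zeta.tobytes(), cache_linv)
        return logp, grad

    def map_init(self, max_iter=500, rounds=4):
        """Approximate joint posterior mode by alternating L-BFGS on the
        covariance block with conditional-mean updates of (alpha, beta).

        Chains are started from a jittered copy of this point, which removes
        the long burn-in transient from the natural phi = 0 start.
        """
        from scipy.optimize import minimize

        M, K = self.M, self.K
        alpha = np.zeros(M)
        beta = np.zeros((M, K))
        lam = np.ones((M, K))
        sb = np.ones(M)
        zeta = self.initial_zeta(np.random.default_rng(0), jitter=0.0)
        for _ in range(rounds):
            resid = self.resid(alpha, beta)

            def negf(z):
                lp, g = self.core_logp_grad(z, resid)
                if not np.isfinite(lp):
                    return 1e12, np.zeros_like(z)
                return -lp, -g

            res = minimize(negf, zeta, jac=True, method="L-BFGS-B",
                           options={"maxiter": max_iter, "maxcor": 25})
            zeta = res.x
            alpha, beta = self.gls_draw(zeta, lam, sb, rng=None)
        return zeta, alpha, beta

    # -- exact conditional draw of (alpha, beta) ---------------------------
    def gls_draw(self, zeta, lam, sb, rng):
        """Gaussian conditional draw of the mean block under the marginal
        covariance (generalized least squares with the shrinkage prior)."""
        M, T, K, D = self.M, self.T, self.K, self.D
        _, theta, sigma2, s2g, s2n, _, phi = self._zeta_pieces(zeta)
        key, cached = self._fact_cache
        if key != zeta.tobytes():
            cached = None
        if cached is None:
            B, _, _, _ = self._random_effect_blocks(theta, s2g, s2n)
        J = K + 1
        Aprec = np.zeros((M, J, M, J))
        rhs = np.zeros((M, J))
        for e, idx in enumerate(self.groups):
            if cached is not None:
                P = cached[e]
            else:
                U = self._car_inverse(phi[e])
                if U is None:
                    raise np.linalg.LinAlgError("phi outside the PD region")
                Sig = self._assemble_sigma(B, sigma2 * U)
                P = _chol_inverse(_cholesky(Sig))
            P4 = P.reshape(M, T, M, T)
            Aprec += np.einsum("mtns,jtls->mjnl", P4, self.Mw[e],
                               optimize=self._gls_path)
            Px = self.xvec[idx] @ P  # (ne, D)
            rhs += np.einsum("ijt,imt->mj", self.Wdes[idx],
                             Px.reshape(len(idx), M, T))
        Aprec = Aprec.reshape(M * J, M * J)
        prior_prec = np.empty((M, J))
        prior_prec[:, 0] = 1.0 / self.spec.alpha_scale ** 2
        if K:
            prior_prec[:, 1:] = 1.0 / (lam ** 2 * sb[:, None] ** 2)
        Aprec[np.diag_indices_from(Aprec)] += prior_prec.ravel()
        La = _cholesky(0.5 * (Aprec + Aprec.T))
        from scipy.linalg import cho_solve, solve_triangular

        mean = cho_solve((La, True), rhs.ravel())
        if rng is None:  # conditional mean (used by map_init)
            draw = mean
        else:
            draw = mean + solve_triangular(La.T, rng.standard_normal(M * J),
                                           lower=False)
        draw = draw.reshape(M, J)
        return draw[:, 0].copy(), draw[:, 1:].copy()

    # -- slice updates of the shrinkage scales -----------------------------
    def shrinkage_update(self, beta, lam, sb, rng):
        tau = self.spec.tau
        M, K = self.M, self.K
        if K == 0:
            return lam, sb
        log_lam = np.log(lam)
        for m in range(M):
            for k in range(K):
                b2 = beta[m, k] ** 2 / (2.0 * sb[m] ** 2)

                def logf(l):
                    return -b2 * np.exp(-2 * l) \
                        - (tau + 1) / 2 * np.log1p(np.exp(2 * l) / tau)

                log_lam[m, k] = _slice_1d(logf, log_lam[m, k], rng)
        lam = np.exp(log_lam)
        log_sb = np.log(sb)
        for m in range(M):
            s = float((beta[m] ** 2 / lam[m] ** 2).sum()) / 2.0

            def logf(v):
                # K normals in beta + half-Cauchy prior + Jacobian
                return -(K - 1) * v - s * np.exp(-2 * v) \
                    - np.log1p(np.exp(2 * v))

            log_sb[m] = _slice_1d(logf, log_sb[m], rng)
        return lam, np.exp(log_sb)

    # -- starting values ---------------------------------------------------
    def initial_zeta(self, rng, jitter=0.01):
        z = np.zeros(self.packer.dim)
        if self.Pa:
            q0 = np.clip((0.0 - self.lo) / self.width, 1e-6, 1 - 1e-6)
            w0 = np.log(q0) - np.log1p(-q0)
            z[self.packer.slices["w_phi"]] = np.tile(w0, 2)
        z += jitter * rng.standard_normal(self.packer.dim)
        return z

    def initial_metric_diag(self):
        """Rough analytic posterior scales for the covariance block."""
        N, T, M = self.N, self.T, self.M
        NT = N * T
        m_inv = np.ones(self.packer.dim)
        sl = self.packer.slices
        m_inv[sl["theta_u"]] = 2.0 / NT
        m_inv[sl["log_s2"]] = 2.0 / (NT * M)
        m_inv[sl["log_s2g"]] = 2.0 / N
        m_inv[sl["log_s2n"]] = 2.0 / NT
        return m_inv

    # -- constrained views of stored draws ---------------------------------
    def constrain_zeta(self, Z):
        Dd = Z.shape[0]
        s = self.packer.slices
        out = {}
        out["theta"] = np.tanh(Z[:, s["theta_u"]])
        out["sigma2"] = np.exp(Z[:, s["log_s2"]][:, 0])
        out["sigma2_gamma"] = np.exp(Z[:, s["log_s2g"]])
        out["sigma2_nu"] = np.exp(Z[:, s["log_s2n"]])
        P = self.pm.n_pathways
        phi_full = np.zeros((2, Dd, P))
        if self.Pa:
            w = Z[:, s["w_phi"]].reshape(Dd, 2, self.Pa)
            phi = self.lo + self.width * _sigmoid(w)
            phi_full[0][:, self.active] = phi[:, 0, :]
            phi_full[1][:, self.active] = phi[:, 1, :]
        out["phi_controls"] = phi_full[0]
        out["phi_cases"] = phi_full[1]
        return out

    def recover_latents(self, draws, rng):
        """Exact conditional Gaussian draws of gamma and nu given each
        retained posterior draw (Rao-Blackwellized recovery)."""
        n_draws = draws["alpha"].shape[0]
        N, T, M, K, D = self.N, self.T, self.M, self.K, self.D
        NT = N * T
        gamma = np.empty((n_draws, N, M))
        nu = np.empty((n_draws, N, T, M))
        midx = np.arange(M)
        for j in range(n_draws):
            theta = draws["theta"][j]
            s2g = draws["sigma2_gamma"][j]
            s2n = draws["sigma2_nu"][j]
            sigma2 = draws["sigma2"][j]
            resid = self.resid(draws["alpha"][j], draws["beta"][j])
            B, Rth, c, _ = self._random_effect_blocks(theta, s2g, s2n)
            Bnu = c[:, None, None] * Rth  # AR(1) covariance alone
            for e, idx in enumerate(self.groups):
                ne = len(idx)
                phi = draws["phi_controls" if e == 0 else "phi_cases"][j]
                U = self._car_inverse(phi[self.active])
                Sig = self._assemble_sigma(B, sigma2 * U)
                P = _chol_inverse(_cholesky(Sig))
                P4 = P.reshape(M, T, M, T)
                # cross-covariance K = Cov(u, x) with u = (gamma, nu):
                # K_gamma[m, (m', t)] = s2g_m delta, K_nu blockdiag(Bnu_m)
                Wg = s2g[:, None] * P4.sum(axis=1).reshape(M, D)
                Pb = P4[midx]  # (M, T, M, T)
                Wn = np.einsum("mst,mtnk->msnk", Bnu, Pb).reshape(D, D)
                W = np.vstack([Wg, Wn])  # (M + D, D) = K Sigma^{-1}
                WKg = W.reshape(M + D, M, T).sum(axis=2) * s2g[None, :]
                WKn = np.einsum("amt,mtk->amk", W.reshape(M + D, M, T),
                                Bnu).reshape(M + D, D)
                Lam = np.zeros((M + D, M + D))
                Lam[:M, :M] = np.diag(s2g)
                Lam_nu = np.zeros((M, T, M, T))
                Lam_nu[midx, :, midx, :] = Bnu
                Lam[M:, M:] = Lam_nu.reshape(D, D)
                cov = Lam
                cov[:, :M] -= WKg
                cov[:, M:] -= WKn
                cov = 0.5 * (cov + cov.T)
                Lc = np.linalg.cholesky(cov + 1e-10 * np.eye(M + D))
                Re = self.group_resid_rows(resid, idx)
                means = Re @ W.T
                u = means + rng.standard_normal((ne, M + D)) @ Lc.T
                gamma[j, idx] = u[:, :M]
                nu[j, idx] = u[:, M:].reshape(ne, M, T).transpose(0, 2, 1)
        return gamma, nu


# ---------------------------------------------------------------------------
# metric (diagonal or dense) for HMC
# ---------------------------------------------------------------------------

class _Metric:
    def __init__(self, diag=None, dense=None):
        if dense is not None:
            self.dense = 0.5 * (dense + dense.T)
            self.diag = None
            Ls = _cholesky(self.dense)  # chol of Minv
            self._Lmom = _tri_inverse(Ls).T  # momentum = _Lmom @ xi
        else:
            self.diag = np.asarray(diag, dtype=float)
            self.dense = None

    def velocity(self, r):
        if self.dense is not None:
            return self.dense @ r
        return self.diag * r

    def kinetic(self, r):
        return 0.5 * float(np.dot(r, self.velocity(r)))

    def sample_momentum(self, rng, dim):
        xi = rng.standard_normal(dim)
        if self.dense is not None:
            return self._Lmom @ xi
        return xi / np.sqrt(self.diag)


# ---------------------------------------------------------------------------
# dynamic HMC (multinomial NUTS-style) on the covariance block
# ---------------------------------------------------------------------------

@dataclass
class _Tree:
    z_minus: np.ndarray
    r_minus: np.ndarray
    g_minus: np.ndarray
    z_plus: np.ndarray
    r_plus: np.ndarray
    g_plus: np.ndarray
    z_prop: np.ndarray
    logp_prop: float
    log_weight: float
    sum_accept: float
    n_leapfrog: int
    diverged: bool
    turning: bool


def _leapfrog(logp_grad, z, r, g, eps, metric):
    r1 = r + 0.5 * eps * g
    z1 = z + eps * metric.velocity(r1)
    logp1, g1 = logp_grad(z1)
    r1 = r1 + 0.5 * eps * g1
    return z1, r1, g1, logp1


def _uturn(z_plus, z_minus, r_plus, r_minus, metric):
    dz = z_plus - z_minus
    return (np.dot(dz, metric.velocity(r_minus)) < 0) or \
        (np.dot(dz, metric.velocity(r_plus)) < 0)


def _logsumexp2(a, b):
    hi = max(a, b)
    if hi == -np.inf:
        return -np.inf
    return hi + np.log(np.exp(a - hi) + np.exp(b - hi))


def _build_tree(logp_grad, z, r, g, depth, direction, eps, metric, h0, rng):
    if depth == 0:
        z1, r1, g1, logp1 = _leapfrog(logp_grad, z, r, g, direction * eps,
                                      metric)
        h1 = -logp1 + metric.kinetic(r1) if np.isfinite(logp1) else np.inf
        diverged = not np.isfinite(h1) or (h1 - h0) > DIVERGENCE_THRESHOLD
        log_w = -np.inf if diverged else h0 - h1
        accept = 0.0 if not np.isfinite(h1) else min(1.0, np.exp(h0 - h1))
        return _Tree(z1, r1, g1, z1, r1, g1, z1, logp1, log_w, accept, 1,
                     diverged, False)

    inner = _build_tree(logp_grad, z, r, g, depth - 1, direction, eps,
                        metric, h0, rng)
    if inner.diverged or inner.turning:
        return inner
    if direction == 1:
        outer = _build_tree(logp_grad, inner.z_plus, inner.r_plus,
                            inner.g_plus, depth - 1, direction, eps, metric,
                            h0, rng)
        z_minus, r_minus, g_minus = inner.z_minus, inner.r_minus, inner.g_minus
        z_plus, r_plus, g_plus = outer.z_plus, outer.r_plus, outer.g_plus
    else:
        outer = _build_tree(logp_grad, inner.z_minus, inner.r_minus,
                            inner.g_minus, depth - 1, direction, eps, metric,
                            h0, rng)
        z_minus, r_minus, g_minus = outer.z_minus, outer.r_minus, outer.g_minus
        z_plus, r_plus, g_plus = inner.z_plus, inner.r_plus, inner.g_plus

    log_w = _logsumexp2(inner.log_weight, outer.log_weight)
    if outer.diverged or log_w == -np.inf:
        z_prop, logp_prop = inner.z_prop, inner.logp_prop
    elif np.log(rng.uniform()) < outer.log_weight - log_w:
        z_prop, logp_prop = outer.z_prop, outer.logp_prop
    else:
        z_prop, logp_prop = inner.z_prop, inner.logp_prop
    turning = outer.turning or _uturn(z_plus, z_minus, r_plus, r_minus, metric)
    return _Tree(z_minus, r_minus, g_minus, z_plus, r_plus, g_plus,
                 z_prop, logp_prop, log_w,
                 inner.sum_accept + outer.sum_accept,
                 inner.n_leapfrog + outer.n_leapfrog,
                 outer.diverged, turning)


def _nuts_step(logp_grad, z, logp, g, eps, metric, max_depth, rng):
    r0 = metric.sample_momentum(rng, z.size)
    h0 = -logp + metric.kinetic(r0)
    z_minus = z_plus = z
    r_minus = r_plus = r0
    g_minus = g_plus = g
    z_sel, logp_sel, g_sel = z, logp, g
    log_w_total = 0.0
    sum_accept = 0.0
    n_leapfrog = 0
    diverged = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, z_plus, r_plus, g_plus, depth,
                              1, eps, metric, h0, rng)
            z_plus, r_plus, g_plus = sub.z_plus, sub.r_plus, sub.g_plus
        else:
            sub = _build_tree(logp_grad, z_minus, r_minus, g_minus, depth,
                              -1, eps, metric, h0, rng)
            z_minus, r_minus, g_minus = sub.z_minus, sub.r_minus, sub.g_minus
        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        if sub.diverged:
            diverged = True
            break
        if sub.turning:
            break
        if sub.log_weight > -np.inf and \
                np.log(rng.uniform()) < sub.log_weight - _logsumexp2(log_w_total, sub.log_weight):
            z_sel, logp_sel = sub.z_prop, sub.logp_prop
            g_sel = None
        log_w_total = _logsumexp2(log_w_total, sub.log_weight)
        depth += 1
        if _uturn(z_plus, z_minus, r_plus, r_minus, metric):
            break
    if g_sel is None:
        logp_sel, g_sel = logp_grad(z_sel)
    accept_stat = sum_accept / max(n_leapfrog, 1)
    return z_sel, logp_sel, g_sel, accept_stat, depth, diverged


def _find_initial_step(logp_grad, z, logp, g, metric, rng):
    eps = 0.1
    r = metric.sample_momentum(rng, z.size)
    h0 = -logp + metric.kinetic(r)
    _, r1, _, logp1 = _leapfrog(logp_grad, z, r, g, eps, metric)
    h1 = -logp1 + metric.kinetic(r1) if np.isfinite(logp1) else np.inf
    direction = 1 if (h0 - h1) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, _, logp1 = _leapfrog(logp_grad, z, r, g, eps, metric)
        h1 = -logp1 + metric.kinetic(r1) if np.isfinite(logp1) else np.inf
        crossed = (h0 - h1) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return eps


def _adaptation_windows(warmup):
    """Stan-style warmup schedule: init buffer, doubling windows, term buffer."""
    init = max(1, int(0.15 * warmup))
    term = max(1, int(0.10 * warmup))
    middle = warmup - init - term
    ends = []
    if middle > 0:
        w = max(5, int(middle * 25 / 175))
        pos = init
        while True:
            if pos + w >= init + middle or pos + 3 * w >= init + middle:
                ends.append(init + middle)
                break
            ends.append(pos + w)
            pos += w
            w *= 2
    return init, ends


def _run_chain(model: _MarginalModel, settings, chain_seed, init=None):
    rng = np.random.default_rng(chain_seed)
    M, K = model.M, model.K

    # sweep state: jittered copy of the approximate posterior mode when
    # available, else the natural phi = 0 start; the mode can sit close to
    # the positive-definiteness boundary, so shrink the jitter on failure
    starts = []
    if init is not None:
        zeta0, alpha0, beta0 = init
        for scale in (1.0, 0.25, 0.0):
            starts.append((
                zeta0 + scale * 0.05 * rng.standard_normal(zeta0.size),
                alpha0 + scale * 0.02 * rng.standard_normal(M),
                beta0 + scale * 0.02 * rng.standard_normal((M, K)),
            ))
    starts.append((model.initial_zeta(rng), np.zeros(M), np.zeros((M, K))))

    lam = np.ones((M, K))
    sb = np.ones(M)
    resid = None

    def core(z):
        return model.core_logp_grad(z, resid)

    logp = -np.inf
    for zeta, alpha, beta in starts:
        resid = model.resid(alpha, beta)
        logp, g = core(zeta)
        if np.isfinite(logp):
            break
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log density at initialization")

    dim = zeta.size
    metric = _Metric(diag=model.initial_metric_diag())
    eps = _find_initial_step(core, zeta, logp, g, metric, rng)

    mu_da = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0, kappa_da = 0.05, 10.0, 0.75
    da_iter = 0

    warmup, iters = settings.warmup, settings.iterations
    init_buf, window_ends = _adaptation_windows(warmup)
    window_buf = []

    n_keep = iters - warmup
    zeta_draws = np.empty((n_keep, dim))
    mean_draws = {"alpha": np.empty((n_keep, M)),
                  "beta": np.empty((n_keep, M, K)),
                  "lam": np.empty((n_keep, M, K)),
                  "sigma2_beta": np.empty((n_keep, M))}
    stats = {"divergent": np.zeros(n_keep, bool),
             "treedepth": np.zeros(n_keep, int),
             "accept_stat": np.zeros(n_keep),
             "logp": np.zeros(n_keep)}
    n_div_warm = 0

    for it in range(iters):
        zeta, logp, g, accept, depth, diverged = _nuts_step(
            core, zeta, logp, g, eps, metric, settings.max_treedepth, rng
        )

        # exact conditional updates of the mean and shrinkage blocks
        alpha, beta = model.gls_draw(zeta, lam, sb, rng)
        lam, sb = model.shrinkage_update(beta, lam, sb, rng)
        resid = model.resid(alpha, beta)
        logp, g = core(zeta)  # refresh cache for the next NUTS step

        if it < warmup:
            if diverged:
                n_div_warm += 1
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + \
                (settings.target_accept - accept) / (da_iter + t0)
            log_eps = mu_da - np.sqrt(da_iter) / gamma_da * h_bar
            wexp = da_iter ** (-kappa_da)
            log_eps_bar = wexp * log_eps + (1 - wexp) * log_eps_bar
            eps = np.exp(log_eps)

            if it >= init_buf and window_ends and it < window_ends[-1]:
                window_buf.append(zeta.copy())
                if (it + 1) in window_ends:
                    n_win = len(window_buf)
                    if n_win > 4:
                        S = np.cov(np.asarray(window_buf), rowvar=False)
                        shrink = n_win / (n_win + 5.0)
                        if n_win >= max(40, dim // 3):
                            dense = shrink * S + (1 - shrink) * np.diag(
                                np.maximum(np.diag(S), 1e-10))
                            dense[np.diag_indices_from(dense)] += 1e-8
                            metric = _Metric(dense=dense)
                        else:
                            var = shrink * np.diag(S) + (1 - shrink) * 1e-3
                            metric = _Metric(diag=np.clip(var, 1e-10, 1e8))
                    window_buf = []
                    eps = _find_initial_step(core, zeta, logp, g, metric, rng)
                    mu_da = np.log(10 * eps)
                    log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            j = it - warmup
            zeta_draws[j] = zeta
            mean_draws["alpha"][j] = alpha
            mean_draws["beta"][j] = beta
            mean_draws["lam"][j] = lam
            mean_draws["sigma2_beta"][j] = sb ** 2
            stats["divergent"][j] = diverged
            stats["treedepth"][j] = depth
            stats["accept_stat"][j] = accept
            stats["logp"][j] = logp

    stats["step_size"] = eps
    stats["warmup_divergences"] = n_div_warm
    return zeta_draws, mean_draws, stats


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Posterior draws of every latent block, indexed (chain, draw, ...).

    ``draws`` maps parameter names (alpha, gamma, nu, theta, beta, lam,
    sigma2, sigma2_beta, sigma2_gamma, sigma2_nu, phi_controls, phi_cases)
    to arrays whose first two axes are chain and iteration.  ``dataset``
    holds the dataset the model was actually fitted to (standardized when
    ``fit(..., standardize=True)``), so draws and data live on one scale.
    """

    draws: dict
    spec: ModelSpec
    pm: PathwayModel
    dataset: OmicsDataset
    sample_stats: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def divergences(self) -> int:
        return int(np.sum(self.sample_stats.get("divergent", 0)))

    def stacked(self, name) -> np.ndarray:
        """Draws with chain and iteration axes merged."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={k: v for k, v in self.draws.items()},
            sample_stats={
                "diverging": self.sample_stats.get("divergent"),
                "lp": self.sample_stats.get("logp"),
            },
        )

    def to_csv(self, directory):
        """Write scalar/vector draws as one CSV per chain (flat columns)."""
        from pathlib import Path
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        skip = {"gamma", "nu"}  # too wide to be useful in flat CSV form
        paths = []
        for c in range(self.n_chains):
            cols = {}
            for name, arr in self.draws.items():
                if name in skip:
                    continue
                flat = arr[c].reshape(self.n_draws, -1)
                if flat.shape[1] == 1:
                    cols[name] = flat[:, 0]
                else:
                    for j in range(flat.shape[1]):
                        cols[f"{name}.{j}"] = flat[:, j]
            path = directory / f"chain_{c}.csv"
            pd.DataFrame(cols).to_csv(path, index=False)
            paths.append(path)
        return paths


def fit(dataset: OmicsDataset, pm: PathwayModel, spec: Optional[ModelSpec] = None,
        standardize: bool = True, recover_latents: bool = True) -> PosteriorSamples:
    """Sample the iCARH posterior.

    By default data are centered and scaled per variable before fitting (so
    effect estimates are on the standardized scale); a constant column is
    rejected.  Pass ``standardize=False`` when the data are already on the
    model's scale (e.g. simulated from the model itself).
    ``recover_latents=False`` skips the conditional recovery of gamma and
    nu draws when only structural parameters are needed (e.g. pathway
    scoring).  Emits a warning — not an error — if any split R-hat exceeds
    1.05 or if more than 1% of post-warmup transitions diverged.
    """
    spec = spec if spec is not None else ModelSpec()
    if pm.n_metabolites != dataset.X.shape[2]:
        raise ValueError("pathway model and dataset disagree on M")
    ds = dataset.standardized() if standardize else dataset
    model = _MarginalModel(ds, pm, spec)

    settings = spec.sampler
    seed_seq = np.random.SeedSequence(settings.seed)
    chain_seeds = seed_seq.spawn(settings.chains + 1)

    try:
        init = model.map_init()
    except Exception:  # fall back to the phi = 0 start
        logger.warning("mode-finding initialization failed; using phi = 0")
        init = None

    all_zeta, all_mean, all_stats = [], [], []
    for c in range(settings.chains):
        logger.info("chain %d/%d starting", c + 1, settings.chains)
        zeta_draws, mean_draws, stats = _run_chain(model, settings,
                                                   chain_seeds[c], init=init)
        all_zeta.append(zeta_draws)
        all_mean.append(mean_draws)
        all_stats.append(stats)

    n_ch = settings.chains
    n_keep = all_zeta[0].shape[0]
    Z = np.concatenate(all_zeta)  # (chains * n_keep, dim)
    flat = model.constrain_zeta(Z)
    for key in ("alpha", "beta", "lam", "sigma2_beta"):
        flat[key] = np.concatenate([m[key] for m in all_mean])
    if recover_latents:
        latent_rng = np.random.default_rng(chain_seeds[-1])
        gamma, nu = model.recover_latents(flat, latent_rng)
        flat["gamma"] = gamma
        flat["nu"] = nu
    draws = {k: v.reshape((n_ch, n_keep) + v.shape[1:]) for k, v in flat.items()}

    sample_stats = {
        key: np.stack([s[key] for s in all_stats])
        for key in ("divergent", "treedepth", "accept_stat", "logp")
    }
    sample_stats["step_size"] = np.array([s["step_size"] for s in all_stats])

    samples = PosteriorSamples(
        draws=draws, spec=spec, pm=pm, dataset=ds, sample_stats=sample_stats
    )

    n_div = samples.divergences
    total = n_ch * n_keep
    if n_div > 0.01 * total:
        warnings.warn(
            f"{n_div}/{total} post-warmup transitions diverged (> 1%); "
            "posterior geometry may be poorly explored",
            RuntimeWarning,
        )
    if n_ch >= 2:
        table = diagnostics(samples)
        worst = table["r_hat"].max()
        if worst > 1.05:
            warnings.warn(
                f"max split R-hat {worst:.3f} > 1.05; chains have not mixed",
                RuntimeWarning,
            )
    return samples


def diagnostics(samples: PosteriorSamples):
    """Convergence summary per parameter block: split R-hat, bulk ESS and
    divergence counts.  R-hat needs at least two chains and is reported as
    NaN otherwise."""
    import pandas as pd

    if samples.n_draws == 0:
        raise ValueError("no draws to diagnose")
    import arviz as az

    rows = []
    single = samples.n_chains < 2
    for name, arr in samples.draws.items():
        if name in ("gamma", "nu"):
            continue  # per-unit nuisance blocks; summarized at block level
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = np.nan if single else float(
                np.max(az.rhat(az.convert_to_dataset(flat)).x.values)
            )
            ess = float(np.min(az.ess(az.convert_to_dataset(flat)).x.values))
        rows.append({"parameter": name, "r_hat": rhat, "ess_bulk": ess})
    table = pd.DataFrame(rows)
    table.attrs["divergences"] = samples.divergences
    return table
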