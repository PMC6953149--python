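"""Synthetic longitudinal multi-omic data with pathway-perturbation truth.

The generator follows the model's own generative process: a random binary
metabolite-to-pathway matrix Z with a KEGG-like distribution of per-
metabolite pathway counts, co-membership adjacency ``A_p = z_p z_p^T``
(diagonal zeroed), group-specific pathway-dependence parameters phi^e drawn
inside their admissible intervals, horseshoe-distributed association
coefficients, and the mixed-effects mean structure with AR(1) temporal
effects.  A binary indicator omega marks which pathways are truly perturbed
(phi differs between cases and controls).  ``corrupt_membership`` emulates
annotation inaccuracies by falsely reassigning metabolites between pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .io import OmicsDataset
from .pathways import PathwayModel, build_design_matrices

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "KEGG_PATHWAY_COUNT_PROBS",
    "simulate_membership",
    "simulate_phi",
    "simulate_dataset",
    "corrupt_membership",
]

#: Default distribution of the number of pathways a single metabolite maps
#: to.  KEGG compound-to-pathway annotations are dominated by metabolites in
#: a single pathway, with a quickly decaying tail of multi-pathway hubs;
#: this fixed table emulates those frequencies so simulations need no
#: database access.  Keys are pathway counts, values probabilities.
KEGG_PATHWAY_COUNT_PROBS = {1: 0.55, 2: 0.25, 3: 0.13, 4: 0.07}


def _as_rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimulationSpec:
    """Conditions of a simulated study.

    Defaults reproduce the reference simulation setting: N=22 individuals,
    T=7 time points, M=40 metabolites, K=1 companion variable, P=11
    pathways, global sparsity tau=1.2 (medium sparsity).

    CAR models only reproduce appreciable within-pathway interaction when
    phi sits close to a boundary of its admissible interval, so pathway
    dependence is generated as an on/off contrast between the boundaries:
    an "on" pathway draws phi around ``phi_on * upper`` (strong positive
    dependence) and an "off" pathway around ``phi_off * lower`` (dependence
    of the opposite sign).  Unperturbed pathways are "on" in both groups
    and share a single draw; perturbed pathways are "on" in controls and
    "off" in cases.  Draws scatter with sd ``phi_sd`` times the anchored
    boundary's magnitude and are truncated to the open admissible interval
    by rejection.  ``omega`` may fix the perturbation indicators; by
    default each pathway is perturbed independently with probability
    ``perturb_prob`` (resampled so both classes occur).
    """

    N: int = 22
    T: int = 7
    M: int = 40
    K: int = 1
    P: int = 11
    tau: float = 1.2
    membership_probs: dict = field(
        default_factory=lambda: dict(KEGG_PATHWAY_COUNT_PROBS)
    )
    omega: Optional[np.ndarray] = None
    perturb_prob: float = 0.5
    phi_on: float = 0.9
    phi_off: float = 0.3
    phi_sd: float = 0.03
    sigma2: float = 1.0
    sigma2_gamma: float = 0.1
    sigma2_nu: float = 0.25
    sigma_beta: float = 1.0
    alpha_sd: float = 1.0
    theta_range: tuple = (-0.7, 0.7)
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.N, self.T, self.M, self.K + 1, self.P) < 1:
            raise ValueError("dimensions must be positive (K may be 0)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        total = sum(self.membership_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("membership_probs must sum to 1")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=int)
            if self.omega.shape != (self.P,):
                raise ValueError("omega must have one indicator per pathway")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    Z: np.ndarray
    omega: np.ndarray
    phi_controls: np.ndarray
    phi_cases: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    nu: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    sigma2: float
    corruption: list = field(default_factory=list)

    def to_manifest(self) -> dict:
        """JSON-serializable summary of the generating configuration."""
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
            else:
                out[key] = val
        return out


def simulate_membership(spec: SimulationSpec, rng) -> np.ndarray:
    """Random binary metabolite-to-pathway matrix Z (M x P).

    Each metabolite's number of pathways is drawn from
    ``spec.membership_probs`` and the pathway identities uniformly without
    replacement; the matrix is resampled until no pathway is empty.
    """
    rng = _as_rng(rng)
    counts = np.array(sorted(spec.membership_probs))
    probs = np.array([spec.membership_probs[c] for c in counts], dtype=float)
    feasible = counts[probs > 0]
    if feasible.max() > spec.P:
        raise ValueError(
            f"metabolites may map to up to {feasible.max()} pathways "
            f"but only P={spec.P} exist"
        )
    for _ in range(1000):
        Z = np.zeros((spec.M, spec.P), dtype=int)
        n_paths = rng.choice(counts, size=spec.M, p=probs)
        for m in range(spec.M):
            Z[m, rng.choice(spec.P, size=n_paths[m], replace=False)] = 1
        if (Z.sum(axis=0) > 0).all():
            return Z
    raise RuntimeError("could not draw a membership matrix with no empty pathway")


def simulate_phi(pm: PathwayModel, omega, rng, phi_on=0.9, phi_off=0.3,
                 phi_sd=0.03):
    """Group-specific pathway-dependence parameters.

    Generating means are anchored near the admissibility boundaries, where
    the CAR component produces its strong within-pathway interaction: "on"
    pathways draw around ``phi_on * upper``, "off" pathways around
    ``phi_off * lower``.  Unperturbed pathways (omega=0) share a single
    "on" draw; perturbed pathways (omega=1) are "on" in controls and "off"
    in cases — two normal draws with well-separated means.  Draws are
    rejected and redrawn until strictly inside the admissible interval (any
    in-bounds vector keeps I - C(phi) positive definite).  Inert pathways
    get phi=0 in both groups and omega forced to 0, with a warning.
    """
    rng = _as_rng(rng)
    omega = np.asarray(omega, dtype=int).copy()
    P = pm.n_pathways
    if omega.shape != (P,):
        raise ValueError("omega must have one indicator per pathway")
    phi_c = np.zeros(P)
    phi_t = np.zeros(P)

    def truncated_normal(mean, sd, lo, hi):
        for _ in range(10000):
            draw = rng.normal(mean, sd)
            if lo < draw < hi:
                return draw
        raise RuntimeError("rejection sampling for phi failed to terminate")

    for p in range(P):
        if pm.inert[p]:
            if omega[p] == 1:
                warnings.warn(
                    f"pathway {p} is inert; forcing omega[{p}] = 0",
                    RuntimeWarning,
                )
                omega[p] = 0
            continue
        lo, hi = pm.phi_lower[p], pm.phi_upper[p]
        mean_on = phi_on * hi
        mean_off = phi_off * lo
        if omega[p] == 1:
            phi_c[p] = truncated_normal(mean_on, phi_sd * hi, lo, hi)
            phi_t[p] = truncated_normal(mean_off, phi_sd * abs(lo), lo, hi)
        else:
            shared = truncated_normal(mean_on, phi_sd * hi, lo, hi)
            phi_c[p] = phi_t[p] = shared
    return phi_c, phi_t, omega


def _sample_omega(spec: SimulationSpec, rng) -> np.ndarray:
    if spec.omega is not None:
        return spec.omega.copy()
    for _ in range(1000):
        omega = (rng.uniform(size=spec.P) < spec.perturb_prob).astype(int)
        if 0 < omega.sum() < spec.P:
            return omega
    raise RuntimeError("could not draw omega with both classes present")


def simulate_dataset(spec: SimulationSpec, rng=None):
    """Draw one full dataset from the generative process.

    Returns ``(OmicsDataset, SimulationTruth)``.  Individuals are split
    into first-half controls and second-half cases (ceil/floor halves with
    a warning when N is odd).
    """
    rng = _as_rng(rng if rng is not None else spec.seed)
    N, T, M, K, P = spec.N, spec.T, spec.M, spec.K, spec.P

    Z = simulate_membership(spec, rng)
    pm = build_design_matrices(Z)
    omega = _sample_omega(spec, rng)
    phi_c, phi_t, omega = simulate_phi(pm, omega, rng, phi_on=spec.phi_on,
                                       phi_off=spec.phi_off,
                                       phi_sd=spec.phi_sd)

    Y = rng.standard_normal((N, T, K))
    lam = np.abs(rng.standard_t(spec.tau, size=(M, K)))
    beta = rng.normal(0.0, lam * spec.sigma_beta)
    alpha = rng.normal(0.0, spec.alpha_sd, size=M)
    theta = rng.uniform(*spec.theta_range, size=M)
    gamma = rng.normal(0.0, np.sqrt(spec.sigma2_gamma), size=(N, M))

    sn = np.sqrt(spec.sigma2_nu)
    nu = np.empty((N, T, M))
    nu[:, 0, :] = rng.normal(0.0, sn / np.sqrt(1 - theta ** 2), size=(N, M))
    for t in range(1, T):
        nu[:, t, :] = theta * nu[:, t - 1, :] + rng.normal(0.0, sn, size=(N, M))

    mu = alpha[None, None, :] + gamma[:, None, :] \
        + np.einsum("ntk,mk->ntm", Y, beta) + nu

    if N % 2:
        warnings.warn(
            f"odd N={N}: using {N - N // 2} controls and {N // 2} cases",
            RuntimeWarning,
        )
    n_controls = N - N // 2
    group = np.array(["controls"] * n_controls + ["cases"] * (N // 2))

    X = np.empty((N, T, M))
    sig = np.sqrt(spec.sigma2)
    for phi_e, rows in ((phi_c, np.arange(n_controls)),
                        (phi_t, np.arange(n_controls, N))):
        Q = np.eye(M) - pm.car_matrix(phi_e)
        L = np.linalg.cholesky(Q)
        eta = rng.standard_normal((len(rows) * T, M))
        # cov = sigma2 * Q^{-1} = sigma2 * L^{-T} L^{-1}, so x = sigma * L^{-T} eta
        eps = sig * np.linalg.solve(L.T, eta.T).T
        X[rows] = mu[rows] + eps.reshape(len(rows), T, M)

    dataset = OmicsDataset(X=X, Y=Y, group=group)
    truth = SimulationTruth(
        Z=Z, omega=omega, phi_controls=phi_c, phi_cases=phi_t,
        alpha=alpha, gamma=gamma, nu=nu, theta=theta, beta=beta, lam=lam,
        sigma2=spec.sigma2,
    )
    return dataset, truth


def corrupt_membership(Z, fraction, mode="reassign", rng=None):
    """Falsely reassign a fraction of each pathway's metabolites.

    For every pathway, ``floor(fraction * members)`` metabolites are
    selected and either removed from it (``mode="drop"``) or moved to a
    uniformly chosen other pathway (``mode="reassign"``).  If the selection
    would empty a pathway, one member is left in place and the event noted.
    Unselected rows are bit-identical to the input.

    Returns ``(Z_corrupted, record)`` where record is a list of dicts
    ``{"metabolite": m, "from": p, "to": p' or None}``.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("drop", "reassign"):
        raise ValueError("mode must be 'drop' or 'reassign'")
    rng = _as_rng(rng)
    Z = np.asarray(Z, dtype=int)
    Zc = Z.copy()
    M, P = Z.shape
    record = []
    for p in range(P):
        members = np.flatnonzero(Z[:, p] == 1)
        n_move = int(np.floor(fraction * len(members)))
        if n_move == 0:
            continue
        if n_move >= len(members):
            n_move = len(members) - 1
            record.append({"metabolite": None, "from": p, "to": None,
                           "note": "kept one member to avoid empty pathway"})
            if n_move == 0:
                continue
        chosen = rng.choice(members, size=n_move, replace=False)
        for m in chosen:
            Zc[m, p] = 0
            dest = None
            if mode == "reassign":
                others = [q for q in range(P) if q != p]
                dest = int(rng.choice(others))
                Zc[m, dest] = 1
            record.append({"metabolite": int(m), "from": p, "to": dest})
    return Zc, record
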