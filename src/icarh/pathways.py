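"""Pathway-structured CAR design matrices and the dependence-parameter prior.

Metabolites that share a metabolic pathway tend to be correlated because
pathways are regulated in a coordinated fashion.  We encode this with a
conditional autoregressive (CAR) component: each metabolite's conditional
mean is a weighted sum of the deviations of its pathway neighbours, and the
joint covariance of an observation vector is ``(I - C(phi))^{-1} sigma^2``
with ``C(phi) = sum_p phi_p W_p``.  Here ``W_p`` combines a zero-diagonal
adjacency matrix ``A_p`` (entries are reciprocals of within-pathway
shortest-path lengths, or 1 for plain co-membership) with a diagonal
neighbour-count weight ``G_p``; ``phi_p`` scales the contribution of pathway
``p`` and is the quantity whose case/control difference signals pathway
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

__all__ = [
    "PathwayModel",
    "build_design_matrices",
    "car_covariance",
    "phi_prior_logpdf",
]

# |extreme eigenvalue| below this flags a pathway as carrying no identifiable
# dependence signal; its phi is pinned to 0.
INERT_EIGENVALUE_TOL = 1e-10


@dataclass
class PathwayModel:
    """CAR design matrices for P pathways over M metabolites.

    Attributes
    ----------
    membership : (M, P) int array
        Binary metabolite-to-pathway assignment matrix Z.
    adjacency : list of (M, M) arrays
        Per-pathway symmetric, zero-diagonal adjacency matrices A_p with
        entries in [0, 1].
    weights : list of (M, M) arrays
        Diagonal neighbour-weight matrices G_p; ``G_p[m, m]`` is the
        reciprocal of metabolite m's neighbour count in pathway p (0 for
        non-members / isolated members).
    car_terms : list of (M, M) arrays
        Symmetrized per-pathway CAR contributions
        ``W_p = (G_p A_p + A_p G_p) / 2``; ``C(phi) = sum_p phi_p W_p``.
        When all members of a pathway have equal neighbour counts (always
        true for co-membership adjacency) ``W_p == G_p A_p`` exactly.
    phi_lower, phi_upper : (P,) arrays
        Admissible open interval for each phi_p, ``(1/(kappa xi_p^1),
        1/(kappa xi_p^2))`` with xi the extreme eigenvalues of W_p and
        kappa the largest number of (connected) pathways any single
        metabolite belongs to.  Because ``W_p <= xi_p^2 Pi_p`` with Pi_p
        the projector onto pathway p's connected members, any phi inside
        these boxes gives ``sum_p phi_p W_p <= (1/kappa) diag(c_m) <= I``,
        so ``I - C(phi)`` is positive definite for every admissible phi;
        kappa is the sharp worst-case constant (the number of pathways P
        itself is the cruder bound obtained when every metabolite could sit
        in every pathway).  Inert pathways carry ``(-inf, inf)`` sentinels.
    inert : (P,) bool array
        True for pathways with no identifiable dependence signal (fewer than
        two connected members, or vanishing extreme eigenvalues); their
        phi_p is fixed at 0.
    unmapped_mask : (M,) bool array
        True for metabolites assigned to no pathway; their row/column of
        every A_p is zero so they are conditionally independent.
    """

    membership: np.ndarray
    adjacency: list = field(repr=False)
    weights: list = field(repr=False)
    car_terms: list = field(repr=False)
    phi_lower: np.ndarray
    phi_upper: np.ndarray
    inert: np.ndarray
    unmapped_mask: np.ndarray

    @property
    def n_metabolites(self) -> int:
        return self.membership.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.membership.shape[1]

    @property
    def active(self) -> np.ndarray:
        """Indices of pathways with estimable phi."""
        return np.flatnonzero(~self.inert)

    def car_matrix(self, phi: np.ndarray) -> np.ndarray:
        """C(phi) = sum_p phi_p W_p (inert pathways contribute nothing)."""
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (self.n_pathways,):
            raise ValueError(
                f"phi must have length {self.n_pathways}, got {phi.shape}"
            )
        C = np.zeros((self.n_metabolites, self.n_metabolites))
        for p in self.active:
            C += phi[p] * self.car_terms[p]
        return C

    def validate_phi(self, phi: np.ndarray) -> None:
        phi = np.asarray(phi, dtype=float)
        for p in range(self.n_pathways):
            if self.inert[p]:
                if phi[p] != 0.0:
                    raise ValueError(
                        f"pathway {p} is inert; phi[{p}] must be 0, got {phi[p]}"
                    )
            elif not (self.phi_lower[p] < phi[p] < self.phi_upper[p]):
                raise ValueError(
                    f"phi[{p}]={phi[p]} outside admissible interval "
                    f"({self.phi_lower[p]}, {self.phi_upper[p]})"
                )


def build_design_matrices(membership, distances=None) -> PathwayModel:
    """Construct the CAR design matrices from pathway assignments.

    Parameters
    ----------
    membership : (M, P) array-like of {0, 1}
        Metabolite-to-pathway assignment matrix.  No pathway column may be
        all-zero.
    distances : sequence of (M, M) arrays, optional
        Per-pathway within-pathway shortest-path lengths (positive, symmetric
        for co-pathway pairs).  When given, adjacency entries are the
        reciprocals ``1/d``; when omitted, every co-member pair gets weight 1
        (the ``z_p z_p^T`` convention with a zeroed diagonal).

    Returns
    -------
    PathwayModel
    """
    Z = np.asarray(membership)
    if Z.ndim != 2:
        raise ValueError("membership must be a 2-D M x P matrix")
    if not np.isin(Z, (0, 1)).all():
        raise ValueError("membership entries must be binary")
    Z = Z.astype(int)
    M, P = Z.shape
    if (Z.sum(axis=0) == 0).any():
        empty = np.flatnonzero(Z.sum(axis=0) == 0)
        raise ValueError(f"pathway column(s) {empty.tolist()} have no members")
    if distances is not None and len(distances) != P:
        raise ValueError("need one distance matrix per pathway")

    adjacency, weights, car_terms = [], [], []
    phi_lower = np.empty(P)
    phi_upper = np.empty(P)
    inert = np.zeros(P, dtype=bool)
    extremes = np.zeros((P, 2))
    connected = np.zeros((M, P), dtype=bool)

    for p in range(P):
        members = Z[:, p].astype(bool)
        A = np.zeros((M, M))
        if distances is None:
            A[np.ix_(members, members)] = 1.0
            np.fill_diagonal(A, 0.0)
        else:
            D = np.asarray(distances[p], dtype=float)
            if D.shape != (M, M):
                raise ValueError(f"distance matrix {p} must be {M}x{M}")
            if not np.allclose(D, D.T):
                raise ValueError(f"distance matrix {p} is not symmetric")
            pair = np.outer(members, members)
            np.fill_diagonal(pair, False)
            finite = pair & np.isfinite(D) & (D > 0)
            A[finite] = 1.0 / D[finite]
            if ((D[finite] < 1) | (D[finite] != np.round(D[finite]))).any():
                raise ValueError(
                    f"distance matrix {p} must hold positive integer path lengths"
                )
        neighbours = (A > 0).sum(axis=1)
        g = np.zeros(M)
        np.divide(1.0, neighbours, out=g, where=neighbours > 0)
        G = np.diag(g)
        GA = G @ A
        W = 0.5 * (GA + GA.T)

        adjacency.append(A)
        weights.append(G)
        car_terms.append(W)

        if neighbours.max(initial=0) == 0:
            # single-member (or fully disconnected) pathway: inert
            inert[p] = True
            continue
        connected[:, p] = neighbours > 0
        eigvals = np.linalg.eigvalsh(W)
        xi1, xi2 = eigvals[0], eigvals[-1]
        if min(abs(xi1), abs(xi2)) < INERT_EIGENVALUE_TOL:
            inert[p] = True
        else:
            extremes[p] = (xi1, xi2)

    # sharp joint-PD constant: the largest number of non-inert pathways a
    # single metabolite is connected in
    kappa = max(int(connected[:, ~inert].sum(axis=1).max(initial=0)), 1)
    for p in range(P):
        if inert[p]:
            phi_lower[p], phi_upper[p] = -np.inf, np.inf
        else:
            phi_lower[p] = 1.0 / (kappa * extremes[p, 0])
            phi_upper[p] = 1.0 / (kappa * extremes[p, 1])

    unmapped = Z.sum(axis=1) == 0
    return PathwayModel(
        membership=Z,
        adjacency=adjacency,
        weights=weights,
        car_terms=car_terms,
        phi_lower=phi_lower,
        phi_upper=phi_upper,
        inert=inert,
        unmapped_mask=unmapped,
    )


def car_covariance(pm: PathwayModel, phi, sigma2: float) -> np.ndarray:
    """Joint CAR covariance ``(I_M - C(phi))^{-1} sigma^2``.

    Raises
    ------
    ValueError
        If phi lies outside its admissible bounds or ``I - C`` is not
        positive definite.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    phi = np.asarray(phi, dtype=float)
    pm.validate_phi(phi)
    Q = np.eye(pm.n_metabolites) - pm.car_matrix(phi)
    try:
        L = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError as err:
        raise ValueError("I - C(phi) is not positive definite") from err
    inv = np.linalg.inv(L)
    cov = sigma2 * (inv.T @ inv)
    return 0.5 * (cov + cov.T)


def phi_prior_logpdf(phi_p: float, lower: float, upper: float) -> float:
    """Log density of the boundary-favouring beta-type prior on phi_p.

    The density is proportional to ``(phi - lower)^{-1/2} (upper - phi)^{-1/2}``
    on the open admissible interval — a Beta(1/2, 1/2) rescaled to
    ``(lower, upper)``, normalized by the interval length so it integrates
    to one.  It places substantial mass near the boundaries, where CAR
    models reproduce strong within-pathway interaction.

    Returns ``-inf`` at or outside the boundaries.
    """
    if not np.isfinite(lower) or not np.isfinite(upper) or upper <= lower:
        raise ValueError("need finite bounds with lower < upper")
    if not (lower < phi_p < upper):
        return -np.inf
    width = upper - lower
    u = (phi_p - lower) / width
    # Beta(1/2,1/2) on u, with the change-of-variables 1/width factor
    return -betaln(0.5, 0.5) - 0.5 * np.log(u) - 0.5 * np.log1p(-u) - np.log(width)
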