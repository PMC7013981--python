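"""Shared fixtures: small lattices, random graphs, hand-built draw objects."""

from __future__ import annotations

import numpy as np
import pytest

from stcar import AdjacencyMatrix, PosteriorSamples, make_lattice


@pytest.fixture
def strip3() -> AdjacencyMatrix:
    """1 x 3 strip of squares: degrees [1, 2, 1]."""
    return make_lattice(1, 3)[1]


@pytest.fixture
def grid22() -> AdjacencyMatrix:
    return make_lattice(2, 2)[1]


def random_adjacency(K: int, rng: np.random.Generator, p: float = 0.4) -> AdjacencyMatrix:
    """Random symmetric 0/1 graph with at least a spanning path (no islands)."""
    W = np.zeros((K, K))
    for i in range(K - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0  # path keeps the graph connected
    extra = rng.random((K, K)) < p
    extra = np.triu(extra, 1)
    W = np.clip(W + extra + extra.T, 0, 1)
    return AdjacencyMatrix(W, [f"u{i}" for i in range(K)])


def joint_conditional(Q: np.ndarray, tau2: float, psi: np.ndarray, k: int):
    """Conditional mean/variance of component k from the joint precision.

    For N(0, tau2 Q^{-1}): mean_k = -sum_{j != k} Q_kj psi_j / Q_kk,
    var_k = tau2 / Q_kk.
    """
    others = np.arange(len(psi)) != k
    mean = -float(Q[k, others] @ psi[others]) / Q[k, k]
    var = tau2 / Q[k, k]
    return mean, var


def st_precision(Q: np.ndarray, lam: float, T: int) -> np.ndarray:
    """KT x KT unscaled precision of the LCAR-AR(1) field, time-major blocks."""
    K = Q.shape[0]
    P = np.zeros((K * T, K * T))
    for t in range(T):
        c_t = 1.0 + (lam**2 if t < T - 1 else 0.0)
        P[t * K : (t + 1) * K, t * K : (t + 1) * K] = c_t * Q
        if t < T - 1:
            P[t * K : (t + 1) * K, (t + 1) * K : (t + 2) * K] = -lam * Q
            P[(t + 1) * K : (t + 2) * K, t * K : (t + 1) * K] = -lam * Q
    return P


def exact_joint_posterior(
    y: np.ndarray,
    Z: np.ndarray,
    Q: np.ndarray,
    lam: float,
    tau2: float,
    sigma2: float,
    m0: np.ndarray,
    P0: np.ndarray,
):
    """Exact Gaussian posterior of (theta, psi) with dependence/variances fixed.

    The model is jointly Gaussian once (rho, lambda, tau2, sigma2) are
    pinned, so the posterior mean and covariance follow from one dense
    solve on the stacked (theta, psi) vector.  Brute-force oracle for the
    Gibbs sampler's conjugate limit.
    """
    K, T, p = Z.shape
    n = K * T
    Zf = np.transpose(Z, (1, 0, 2)).reshape(n, p)  # time-major stacking
    yf = y.T.reshape(n)
    Om = st_precision(Q, lam, T)
    P = np.zeros((p + n, p + n))
    P[:p, :p] = Zf.T @ Zf / sigma2 + P0
    P[:p, p:] = Zf.T / sigma2
    P[p:, :p] = Zf / sigma2
    P[p:, p:] = np.eye(n) / sigma2 + Om / tau2
    rhs = np.concatenate([Zf.T @ yf / sigma2 + P0 @ m0, yf / sigma2])
    cov = np.linalg.inv(P)
    mean = cov @ rhs
    return mean, cov  # first p entries correspond to theta


def manual_samples(
    coef: np.ndarray,
    psi: np.ndarray,
    sigma2: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    names: list[str],
    n_chains: int = 1,
    tau2=None,
    rho=None,
    lam=None,
) -> PosteriorSamples:
    """Build a PosteriorSamples from explicit draws (split evenly by chain)."""
    nd = coef.shape[0]
    K, T = y.shape
    loglik = np.array(
        [
            -0.5 * K * T * np.log(2 * np.pi * s)
            - 0.5 * np.sum((y - Z @ c - p) ** 2) / s
            for c, p, s in zip(coef, psi, sigma2)
        ]
    )
    tau2 = np.ones(nd) if tau2 is None else tau2
    rho = np.full(nd, 0.5) if rho is None else rho
    lam = np.full(nd, 0.5) if lam is None else lam
    per = nd // n_chains
    chains = []
    for c in range(n_chains):
        sl = slice(c * per, (c + 1) * per)
        chains.append(
            {
                "coef": coef[sl],
                "psi": psi[sl],
                "sigma2": sigma2[sl],
                "tau2": tau2[sl],
                "rho": rho[sl],
                "lam": lam[sl],
                "loglik": loglik[sl],
            }
        )
    return PosteriorSamples(
        chains=chains,
        coef_names=list(names),
        unit_ids=[f"u{i}" for i in range(K)],
        years=list(range(T)),
        y=y,
        Z=Z,
    )
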