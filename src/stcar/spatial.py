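"""Contiguity weights and Leroux-CAR (LCAR) linear algebra.

The spatial prior used throughout the package is the Leroux conditional
autoregressive model: a Gaussian Markov random field on K areal units whose
unscaled precision matrix is

    Q(rho, W) = diag(1 - rho + rho * w+) - rho * W,

where ``W`` is a binary, symmetric contiguity matrix, ``w+`` its row sums
(neighbour counts) and ``rho`` in [0, 1] the spatial-dependence parameter.
The full precision of the field is ``Q / tau2``.  ``rho = 0`` gives i.i.d.
N(0, tau2) effects; ``rho = 1`` the (improper) intrinsic CAR.

Because ``Q(rho) = (1 - rho) I + rho (diag(w+) - W)`` shares its
eigenvectors with the graph Laplacian ``L = diag(w+) - W``, a single
eigendecomposition of ``L`` yields the log-determinant of ``Q`` for every
``rho`` in O(K), which is what the Metropolis update of ``rho`` needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AdjacencyMatrix",
    "LCARStructure",
    "build_adjacency",
    "build_adjacency_from_edges",
    "lcar_precision",
    "lcar_conditional",
    "lcar_logdensity",
]


@dataclass
class AdjacencyMatrix:
    """Binary symmetric contiguity structure among K areal units."""

    W: np.ndarray
    unit_ids: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be a square matrix")
        if len(self.unit_ids) != self.W.shape[0]:
            raise ValueError("unit_ids length must match W")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        if not np.isin(self.W, (0.0, 1.0)).all():
            raise ValueError("W entries must be 0 or 1")

    @property
    def K(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Neighbour count w+ per unit (row sums of W)."""
        return self.W.sum(axis=1)

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian diag(w+) - W."""
        return np.diag(self.degrees) - self.W

    def edges(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.W))
        return [(self.unit_ids[a], self.unit_ids[b]) for a, b in zip(i, j)]


@dataclass
class LCARStructure:
    """Q(rho, W) together with cached Laplacian eigenvalues.

    ``logdet_eigs`` are the eigenvalues of diag(w+) - W, so that
    log det Q(rho) = sum_k log(1 - rho + rho * logdet_eigs[k]).
    """

    rho: float
    Q: np.ndarray
    logdet_eigs: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)

    @property
    def intrinsic(self) -> bool:
        return self.rho == 1.0

    def logdet(self) -> float:
        if self.intrinsic:
            raise ValueError("Q is singular at rho = 1 (intrinsic CAR)")
        return float(np.sum(np.log1p(self.rho * (self.logdet_eigs - 1.0))))


def _shares_border(a: BaseGeometry, b: BaseGeometry) -> bool:
    # rook rule: neighbours iff boundaries overlap with positive length;
    # a corner touch intersects in a point set of zero length.
    inter = a.boundary.intersection(b.boundary)
    return bool(inter.length > 0.0)


def build_adjacency(
    polygons: list[BaseGeometry],
    unit_ids: list[str] | None = None,
) -> AdjacencyMatrix:
    """Rook-contiguity adjacency from a set of non-overlapping polygons.

    Two units are neighbours iff their boundaries share a segment of
    positive length; polygons touching only at a corner are not neighbours.
    """
    if len(polygons) == 0:
        raise ValueError("empty polygon set")
    if unit_ids is None:
        unit_ids = [str(i) for i in range(len(polygons))]
    K = len(polygons)
    W = np.zeros((K, K))
    tree = STRtree(polygons)
    for i, poly in enumerate(polygons):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            if _shares_border(poly, polygons[j]):
                W[i, j] = W[j, i] = 1.0
    adj = AdjacencyMatrix(W, list(unit_ids))
    _warn_islands(adj)
    return adj


def _warn_islands(adj: AdjacencyMatrix) -> None:
    isolated = [u for u, d in zip(adj.unit_ids, adj.degrees) if d == 0]
    if isolated:
        warnings.warn(
            f"units with no neighbours: {isolated}; the Leroux model stays "
            "proper for rho < 1 (conditional N(0, tau2/(1-rho))) but is "
            "improper at rho = 1",
            stacklevel=3,
        )


def build_adjacency_from_edges(
    edge_list: list[tuple[str, str]],
    unit_ids: list[str],
) -> AdjacencyMatrix:
    """Adjacency from an explicit neighbour-pair list (idempotent, mirrored)."""
    index = {u: i for i, u in enumerate(unit_ids)}
    K = len(unit_ids)
    W = np.zeros((K, K))
    for a, b in edge_list:
        if a not in index or b not in index:
            raise ValueError(f"edge ({a}, {b}) references unknown unit id")
        if a == b:
            raise ValueError(f"self-edge on unit {a!r}")
        W[index[a], index[b]] = W[index[b], index[a]] = 1.0
    adj = AdjacencyMatrix(W, list(unit_ids))
    _warn_islands(adj)
    return adj


def lcar_precision(W: AdjacencyMatrix, rho: float) -> LCARStructure:
    """Unscaled LCAR precision Q = diag(1 - rho + rho*w+) - rho*W.

    Positive definite for rho in [0, 1); at rho = 1 the rows of Q sum to
    zero (intrinsic CAR) and the density is improper — downstream density
    evaluation refuses it.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    L = W.laplacian()
    eigs, vecs = np.linalg.eigh(L)
    Q = (1.0 - rho) * np.eye(W.K) + rho * L
    return LCARStructure(rho=rho, Q=Q, logdet_eigs=eigs, eigenvectors=vecs)


def lcar_conditional(
    k: int,
    psi: np.ndarray,
    W: AdjacencyMatrix,
    rho: float,
    tau2: float,
) -> tuple[float, float]:
    """Full conditional of psi_k given the rest of the field.

    mean = rho * sum_{l ~ k} psi_l / (1 - rho + rho*w_k+)
    var  = tau2 / (1 - rho + rho*w_k+)
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1) for a proper conditional")
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    psi = np.asarray(psi, dtype=float)
    denom = 1.0 - rho + rho * W.degrees[k]
    mean = rho * float(W.W[k] @ psi) / denom
    var = tau2 / denom
    return mean, var


def lcar_logdensity(
    psi_vec: np.ndarray,
    W: AdjacencyMatrix,
    rho: float,
    tau2: float,
    structure: LCARStructure | None = None,
) -> float:
    """Log density of N(psi | 0, tau2 * Q(rho, W)^{-1}).

    Uses the cached eigenvalue log-determinant; equals the dense
    multivariate-normal evaluation.
    """
    if rho == 1.0:
        raise ValueError("improper density at rho = 1")
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if structure is None or structure.rho != rho:
        structure = lcar_precision(W, rho)
    psi = np.asarray(psi_vec, dtype=float)
    K = W.K
    quad = float(psi @ structure.Q @ psi) / tau2
    return -0.5 * K * np.log(2.0 * np.pi * tau2) + 0.5 * structure.logdet() - 0.5 * quad
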