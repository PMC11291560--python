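"""Initial node representations: random walk with restart and polynomial expansion.

A walker starts at a node, at each step either restarts at its origin (with
probability 1 - gamma) or moves along the similarity graph according to the
row-normalized transition matrix P. The stationary visiting probabilities

    M = (1 - gamma) * (I - gamma * P)^(-1)

give every node a probability-vector feature row that encodes the global
topology of its similarity network. The disease network is small (tens of
nodes), so disease feature rows are additionally expanded with polynomial
(monomial) features up to a target width, giving the downstream model a
richer input space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import SimilarityMatrix

__all__ = ["FeatureMatrix", "rwr_features", "polynomial_expand"]


@dataclass
class FeatureMatrix:
    """Per-node real-valued feature rows."""

    entity_ids: list[str]
    values: np.ndarray
    provenance: str = "rwr"  # "rwr" | "poly" | "embedding"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.entity_ids):
            raise ValueError("feature rows do not match entity labels")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.provenance == "rwr":
            if self.values.min() < -1e-12:
                raise ValueError("RWR features must be non-negative")
            if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("RWR feature rows must sum to 1 (tol 1e-8)")


def _transition_matrix(S: SimilarityMatrix) -> np.ndarray:
    row_sums = S.values.sum(axis=1)
    dead = row_sums == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} node(s) with all-zero similarity rows get a "
            "pure-restart (identity) distribution"
        )
    P = np.zeros_like(S.values)
    alive = ~dead
    P[alive] = S.values[alive] / row_sums[alive, None]
    P[dead, np.nonzero(dead)[0]] = 1.0  # self-loop: walker never leaves
    return P


def rwr_features(
    S: SimilarityMatrix,
    gamma: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
    method: str = "auto",
) -> FeatureMatrix:
    """Stationary random-walk-with-restart probabilities for every node.

    Solves the fixed point M = (1-gamma)*I + gamma*M*P with P the
    row-normalized transition matrix of ``S``. Row i is the feature vector
    of entity i. Solved in closed form for networks below 2000 nodes,
    otherwise by fixed-point iteration until the maximum row-wise L1 change
    drops below ``tol``.
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    n = S.n
    if gamma == 0:
        return FeatureMatrix(list(S.entity_ids), np.eye(n), provenance="rwr")
    P = _transition_matrix(S)
    if method == "closed" or (method == "auto" and n < 2000):
        M = (1 - gamma) * np.linalg.inv(np.eye(n) - gamma * P)
    elif method in ("auto", "iterative"):
        M = np.eye(n)
        restart = (1 - gamma) * np.eye(n)
        for _ in range(max_iter):
            M_next = restart + gamma * (M @ P)
            if np.abs(M_next - M).sum(axis=1).max() < tol:
                M = M_next
                break
            M = M_next
        else:
            warnings.warn(f"RWR did not converge within {max_iter} iterations")
    else:
        raise ValueError("method must be 'auto', 'closed' or 'iterative'")
    np.clip(M, 0.0, None, out=M)
    M /= M.sum(axis=1, keepdims=True)
    return FeatureMatrix(list(S.entity_ids), M, provenance="rwr")


def _monomials(n_vars: int, degree: int):
    """Exponent index tuples of exactly ``degree`` in graded-lex order."""
    return itertools.combinations_with_replacement(range(n_vars), degree)


def _n_monomials(n_vars: int, degree: int) -> int:
    from math import comb

    return comb(n_vars + degree - 1, degree)


def polynomial_expand(F: FeatureMatrix, degree: int, target_dim: int) -> FeatureMatrix:
    """Expand feature rows with monomial features of bounded total degree.

    Emits the constant term and all monomials of total degree <= ``degree``
    in graded-lexicographic order. If that exceeds ``target_dim`` the
    ``target_dim`` highest-variance features are kept (ties by generation
    order); if it falls short, monomials of the next degree are appended in
    order until the target width is reached.
    """
    if degree < 1:
        raise ValueError("degree must be at least 1")
    X = F.values
    n_vars = X.shape[1]
    if target_dim < n_vars:
        raise ValueError(f"target_dim ({target_dim}) below input dimension ({n_vars})")

    columns: list[np.ndarray] = [np.ones(X.shape[0])]
    d = 1
    while True:
        base_done = d > degree
        if base_done and len(columns) >= target_dim:
            break
        gen = _monomials(n_vars, d)
        if base_done:
            gen = itertools.islice(gen, target_dim - len(columns))
        for idx in gen:
            col = np.ones(X.shape[0])
            for v in idx:
                col = col * X[:, v]
            columns.append(col)
        d += 1

    mat = np.column_stack(columns)
    if mat.shape[1] > target_dim:
        variances = mat.var(axis=0)
        # stable sort keeps generation order among equal-variance features
        keep = np.sort(np.argsort(-variances, kind="stable")[:target_dim])
        mat = mat[:, keep]
    return FeatureMatrix(list(F.entity_ids), mat, provenance="poly")
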