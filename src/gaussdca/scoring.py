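"""Pair scoring: Frobenius norm, Gaussian direct information, APC, ranking.

Each column pair (i, j) carries a (q-1) x (q-1) coupling block of the
precision matrix; scoring maps that block to one scalar.  Two scores are
provided:

* FN — the Frobenius norm of the coupling block after (i) shifting to the
  zero-sum gauge (every row and column of the q x q block, gap state
  included as a zero row/column, sums to zero) and (ii) dropping the gap
  row and column again.  Gauge fixing removes the non-interacting
  row-constant + column-constant degrees of freedom that the one-hot
  parametrization leaves undetermined.
* DI — the mutual information between columns i and j under the two-site
  "direct" model: the Gaussian whose precision keeps only the direct
  coupling W = J_ij while its single-column marginals are constrained to
  the estimated Sigma_ii and Sigma_jj.  DI is gauge invariant and
  non-negative.

Scores are assembled into a symmetric zero-diagonal N x N matrix, adjusted
by the average-product correction, and ranked with a minimum chain
separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian_model import GaussianModel

#: Fixed-point tolerance (max-abs update) for the DI self-consistency.
DI_TOL = 1e-12
DI_MAX_ITER = 1000


class DIConvergenceError(RuntimeError):
    pass


def frobenius_score(J: np.ndarray, gauge_states: str = "residues") -> float:
    """Zero-sum-gauge Frobenius norm of a coupling block.

    The gauge shift K_ab = J_ab - rowmean_a - colmean_b + grandmean
    (double centering) projects out the row-constant + column-constant
    degrees of freedom the one-hot parametrization leaves undetermined,
    and the norm of the gauged residue block is returned.

    With the default ``gauge_states='residues'`` the means run over the
    q-1 residue states of the block itself — the only convention under
    which a pure-gauge coupling (u_a + v_b) scores exactly zero.
    ``gauge_states='embed-gap'`` instead embeds the block in a q x q
    matrix with an all-zero gap row/column, centers with means over all q
    states, and drops the gap row/column again before taking the norm;
    this leaves a small residual on pure-gauge couplings.
    """
    J = np.asarray(J, dtype=np.float64)
    s = J.shape[0]
    if gauge_states == "embed-gap":
        K = np.zeros((s + 1, s + 1))
        K[1:, 1:] = J
    elif gauge_states == "residues":
        K = J
    else:
        raise ValueError(f"unknown gauge_states {gauge_states!r}")
    K = K - K.mean(axis=1, keepdims=True) - K.mean(axis=0, keepdims=True) + K.mean()
    if gauge_states == "embed-gap":
        K = K[1:, 1:]
    return float(np.linalg.norm(K, "fro"))


def gaussian_di(
    Sigma_ii: np.ndarray,
    Sigma_jj: np.ndarray,
    W: np.ndarray,
    tol: float = DI_TOL,
    max_iter: int = DI_MAX_ITER,
) -> float:
    """Direct information of the two-site direct Gaussian model.

    Solves the self-consistency A = Sigma_ii^{-1} + W B^{-1} W^T,
    B = Sigma_jj^{-1} + W^T A^{-1} W by fixed-point iteration from the
    uncoupled point, so that the joint precision [[A, W], [W^T, B]] has
    marginal covariances exactly Sigma_ii and Sigma_jj; then
    DI = 1/2 * ln det(I + Sigma_ii W B^{-1} W^T), the Gaussian mutual
    information of the two blocks.
    """
    Sigma_ii = np.asarray(Sigma_ii, dtype=np.float64)
    Sigma_jj = np.asarray(Sigma_jj, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    for S in (Sigma_ii, Sigma_jj):
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("marginal covariance blocks must be positive definite")
    inv_ii = np.linalg.inv(Sigma_ii)
    inv_jj = np.linalg.inv(Sigma_jj)
    A, B = inv_ii.copy(), inv_jj.copy()
    for _ in range(max_iter):
        A_new = inv_ii + W @ np.linalg.solve(B, W.T)
        B_new = inv_jj + W.T @ np.linalg.solve(A_new, W)
        delta = max(
            float(np.abs(A_new - A).max()), float(np.abs(B_new - B).max())
        )
        A, B = A_new, B_new
        if delta < tol:
            break
    else:
        raise DIConvergenceError(
            f"DI fixed point did not converge (residual {delta:.3e})"
        )
    s = Sigma_ii.shape[0]
    sign, logdet = np.linalg.slogdet(
        np.eye(s) + Sigma_ii @ W @ np.linalg.solve(B, W.T)
    )
    if sign <= 0:
        raise DIConvergenceError("non-positive determinant in DI evaluation")
    return 0.5 * float(logdet)


@dataclass
class ScoreMatrix:
    """Symmetric, zero-diagonal N x N matrix of pair scores."""

    S: np.ndarray
    kind: str  # "fn" | "di"
    apc_applied: bool = False

    @property
    def n_cols(self) -> int:
        return self.S.shape[0]


def score_model(
    model: GaussianModel, kind: str = "fn", gauge_states: str = "residues"
) -> ScoreMatrix:
    """Score every column pair of a fitted model."""
    N = model.n_cols
    S = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            W = model.coupling_block(i, j)
            if kind == "fn":
                val = frobenius_score(W, gauge_states=gauge_states)
            elif kind == "di":
                val = gaussian_di(
                    model.sigma_block(i, i), model.sigma_block(j, j), W
                )
            else:
                raise ValueError(f"unknown score kind {kind!r}")
            S[i, j] = S[j, i] = val
    return ScoreMatrix(S=S, kind=kind)


def apc_correct(sm: ScoreMatrix) -> ScoreMatrix:
    """Average-product correction.

    S'_ij = S_ij - R_i * R_j / Rbar with R_i the mean of row i excluding
    the diagonal and Rbar the overall off-diagonal mean; background signal
    shared by whole columns (conservation, gaps) cancels.
    """
    S = sm.S
    N = S.shape[0]
    if N < 3:
        raise ValueError("APC requires at least 3 columns")
    row_mean = (S.sum(axis=1) - np.diag(S)) / (N - 1)
    grand = (S.sum() - np.trace(S)) / (N * (N - 1))
    if grand == 0:
        raise ValueError("APC undefined: all off-diagonal scores are zero")
    corrected = S - np.outer(row_mean, row_mean) / grand
    np.fill_diagonal(corrected, 0.0)
    return ScoreMatrix(S=corrected, kind=sm.kind, apc_applied=True)


@dataclass
class RankedPairs:
    """Pairs (i, j, score), 1-based, i < j, scores non-increasing."""

    pairs: list[tuple[int, int]]
    scores: list[float]

    def __iter__(self):
        return iter(zip(self.pairs, self.scores))

    def __len__(self) -> int:
        return len(self.pairs)


def rank_pairs(sm: ScoreMatrix, min_separation: int = 5) -> RankedPairs:
    """Rank eligible pairs by descending score.

    Pairs closer than ``min_separation`` along the chain are excluded
    (trivial neighbors are always in contact); ties keep lexicographic
    (i, j) order.  Reported indices are 1-based.
    """
    N = sm.S.shape[0]
    entries = [
        (i + 1, j + 1, float(sm.S[i, j]))
        for i in range(N)
        for j in range(i + 1, N)
        if j - i >= min_separation
    ]
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return RankedPairs(
        pairs=[(i, j) for i, j, _ in entries],
        scores=[s for _, _, s in entries],
    )
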