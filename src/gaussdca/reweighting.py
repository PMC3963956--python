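"""Sequence reweighting and reweighted frequency counts.

Phylogeny and biased species sampling make MSA rows strongly non-i.i.d.;
the standard correction down-weights each sequence by the size of its
similarity neighborhood.  A sequence with many near-duplicates (pairwise
difference fraction below the threshold ``theta``) counts as a fraction of
one observation, and the effective sample size ``meff`` replaces M
everywhere downstream.  With every pairwise identity below ``1 - theta``
all weights are 1 and meff = M; in the opposite limit the scheme reduces
to plain de-duplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .msa_io import Alignment, encode_onehot

#: Auto-theta heuristic constant (0.38 * 0.32): theta is set to
#: min(0.5, 0.1216 / mean_pairwise_identity), following the widely used
#: similarity-threshold pre-pass of contact-prediction codes.
AUTO_THETA_NUMERATOR = 0.1216

#: All unordered pairs are enumerated for the identity pre-pass up to this
#: count; beyond it a seeded uniform subsample of the same size is used.
MAX_IDENTITY_PAIRS = 2_000_000


@dataclass
class Weights:
    """Per-sequence weights ``w``, their sum ``meff`` and the ``theta`` used."""

    w: np.ndarray
    meff: float
    theta: float


def mean_pairwise_identity(
    aln: Alignment,
    max_pairs: int = MAX_IDENTITY_PAIRS,
    seed: int = 0,
) -> float:
    """Mean fraction of identical symbols over unordered sequence pairs.

    Gap-gap agreements count as matches (identity is computed over all
    matched columns).  All M(M-1)/2 pairs are used when that is at most
    ``max_pairs``; otherwise ``max_pairs`` pairs are drawn uniformly with
    the given seed.
    """
    M, N = aln.symbols.shape
    if M < 2:
        raise ValueError("mean pairwise identity undefined for M < 2")
    n_pairs = M * (M - 1) // 2
    sym = aln.symbols
    if n_pairs <= max_pairs:
        idx_i, idx_j = np.triu_indices(M, k=1)
    else:
        rng = np.random.default_rng(seed)
        idx_i = rng.integers(0, M, size=max_pairs)
        idx_j = rng.integers(0, M - 1, size=max_pairs)
        idx_j[idx_j >= idx_i] += 1  # uniform over ordered distinct pairs
    total = 0.0
    chunk = max(1, 8_000_000 // max(N, 1))
    for lo in range(0, len(idx_i), chunk):
        hi = lo + chunk
        total += float(
            (sym[idx_i[lo:hi]] == sym[idx_j[lo:hi]]).mean(axis=1).sum()
        )
    return total / len(idx_i)


@njit(cache=True)
def _neighbor_counts(sym: np.ndarray, max_diff: float) -> np.ndarray:
    """Count, for each row, rows (incl. itself) differing at < max_diff
    positions.  Early exit once a pair is known to be dissimilar."""
    M, N = sym.shape
    counts = np.ones(M, dtype=np.int64)
    cutoff = int(np.ceil(max_diff))  # diff >= cutoff ⟹ not a neighbor
    for m in range(M):
        row_m = sym[m]
        for mp in range(m + 1, M):
            row_p = sym[mp]
            diff = 0
            for k in range(N):
                if row_m[k] != row_p[k]:
                    diff += 1
                    if diff >= cutoff:
                        break
            if diff < max_diff:
                counts[m] += 1
                counts[mp] += 1
    return counts


def compute_weights(
    aln: Alignment,
    theta: float | str = "auto",
    max_pairs: int = MAX_IDENTITY_PAIRS,
    seed: int = 0,
) -> Weights:
    """Similarity-based sequence weights.

    ``w_m = 1 / |{m' : fraction of differing positions(m, m') < theta}|``,
    the neighborhood including m itself; ``meff = sum(w)``.  ``theta='auto'``
    derives the threshold from :func:`mean_pairwise_identity` via the
    0.1216/identity rule, capped at 0.5.
    """
    M, N = aln.symbols.shape
    if theta == "auto":
        if M < 2:
            theta_val = 0.5
        else:
            mpi = mean_pairwise_identity(aln, max_pairs=max_pairs, seed=seed)
            theta_val = min(0.5, AUTO_THETA_NUMERATOR / max(mpi, 1e-12))
    else:
        theta_val = float(theta)
        if not 0.0 < theta_val < 1.0:
            raise ValueError("theta must lie in (0, 1)")
    counts = _neighbor_counts(
        np.ascontiguousarray(aln.symbols, dtype=np.int8), theta_val * N
    )
    w = 1.0 / counts
    return Weights(w=w, meff=float(w.sum()), theta=theta_val)


@dataclass
class FrequencyCounts:
    """Reweighted one-hot moments.

    ``mean`` is the length (q-1)*N vector of reweighted single-site
    frequencies (the empirical mean of the binary encoding), ``second`` the
    matching second-moment matrix, and ``cov = second - mean mean^T``.
    Within one column the indicators are mutually exclusive, so two
    different residues at the same site are anti-correlated:
    cov((i,a),(i,b)) = -mean(i,a)*mean(i,b) for a != b.
    """

    mean: np.ndarray
    second: np.ndarray
    cov: np.ndarray
    meff: float
    n_cols: int
    q: int


def weighted_frequencies(aln: Alignment, weights: Weights) -> FrequencyCounts:
    """Reweighted empirical mean and covariance of the one-hot rows."""
    if len(weights.w) != aln.M:
        raise ValueError("weights do not match alignment size")
    X = encode_onehot(aln)
    p = weights.w / weights.meff
    mean = X.T @ p
    second = X.T @ (X * p[:, None])
    second = 0.5 * (second + second.T)
    cov = second - np.outer(mean, mean)
    return FrequencyCounts(
        mean=mean,
        second=second,
        cov=cov,
        meff=weights.meff,
        n_cols=aln.N,
        q=aln.q,
    )
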