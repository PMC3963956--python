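"""Interaction-partner scoring from paired alignments.

Given an alignment of concatenated cognate pairs (each row the sequence of
protein A joined to its known partner from family B), three Gaussian
models are fitted: the joint model over all N_A + N_B columns, which
captures inter-protein co-evolution, and the two marginal models over the
restricted alignments.  A candidate pair (x_A, x_B) is then scored by the
log-odds ratio between its probability under the joint model and under the
product of the marginals,

    l(x_A, x_B) = ln N(x | mu_J, Sigma_J) - ln N(x_A | mu_A, Sigma_A)
                  - ln N(x_B | mu_B, Sigma_B),

with x the concatenation.  The 2*pi volume factors cancel because the
dimensions add, leaving the quadratic forms plus the constant
c = 1/2 (ln det Sigma_A + ln det Sigma_B - ln det Sigma_J).  Positive l
means the pair is more coherent with the interacting model than with two
independent family members; it also equals the log-odds between the
conditional probability of one sequence given the other and its
unconditioned probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian_model import GaussianModel, pseudocount_covariance
from .msa_io import Alignment, encode_onehot
from .reweighting import Weights, compute_weights, weighted_frequencies

#: Likelihood-based scores use the DI pseudo-count default.
DEFAULT_PARTNER_PC = 0.8


@dataclass
class PairedAlignment:
    """Row-aligned cognate pairs: joint row m = left row m + right row m."""

    left: Alignment
    right: Alignment

    def __post_init__(self) -> None:
        if self.left.M != self.right.M:
            raise ValueError("left/right alignments must have equal depth")
        if self.left.q != self.right.q:
            raise ValueError("left/right alignments must share the alphabet")

    @property
    def M(self) -> int:
        return self.left.M

    @property
    def joint(self) -> Alignment:
        return Alignment(
            np.hstack([self.left.symbols, self.right.symbols]),
            ids=list(self.left.ids),
            q=self.left.q,
        )

    @classmethod
    def from_joint(cls, joint: Alignment, n_left: int) -> "PairedAlignment":
        """Split a concatenated alignment at column ``n_left``."""
        if not 0 < n_left < joint.N:
            raise ValueError("split point outside the alignment")
        return cls(
            left=Alignment(joint.symbols[:, :n_left], ids=list(joint.ids), q=joint.q),
            right=Alignment(joint.symbols[:, n_left:], ids=list(joint.ids), q=joint.q),
        )


@dataclass
class InteractionModel:
    model_joint: GaussianModel
    model_left: GaussianModel
    model_right: GaussianModel
    c: float

    @property
    def dim_left(self) -> int:
        return self.model_left.mu.shape[0]

    @property
    def dim_right(self) -> int:
        return self.model_right.mu.shape[0]


def fit_interaction_model(
    paired: PairedAlignment,
    pc: float = DEFAULT_PARTNER_PC,
    theta: float | str = "auto",
    separate_weights: bool = False,
    seed: int = 0,
) -> InteractionModel:
    """Fit joint and marginal Gaussian models from the cognate set.

    Sequence weights are computed once on the joint alignment and reused
    for the two restricted alignments, keeping the three models consistent
    (``separate_weights=True`` reweights each alignment independently).
    """
    if paired.M < 2:
        raise ValueError("need at least 2 cognate pairs to fit a model")
    joint = paired.joint
    w_joint = compute_weights(joint, theta=theta, seed=seed)
    parts = []
    for aln in (joint, paired.left, paired.right):
        w = (
            compute_weights(aln, theta=theta, seed=seed)
            if separate_weights and aln is not joint
            else w_joint
        )
        counts = weighted_frequencies(aln, w)
        parts.append(pseudocount_covariance(counts, pc))
    mj, ml, mr = parts
    c = 0.5 * (ml.logdet_sigma + mr.logdet_sigma - mj.logdet_sigma)
    return InteractionModel(model_joint=mj, model_left=ml, model_right=mr, c=c)


def interaction_score(
    x_left: np.ndarray, x_right: np.ndarray, m: InteractionModel
) -> float | np.ndarray:
    """Log-odds score l for one pair or a batch (rows of 2-d inputs)."""
    x_left = np.atleast_2d(np.asarray(x_left, dtype=np.float64))
    x_right = np.atleast_2d(np.asarray(x_right, dtype=np.float64))
    if x_left.shape[1] != m.dim_left or x_right.shape[1] != m.dim_right:
        raise ValueError(
            f"one-hot dimensions {x_left.shape[1]}, {x_right.shape[1]} do "
            f"not match the model ({m.dim_left}, {m.dim_right})"
        )
    x = np.hstack([x_left, x_right])

    def quad(model: GaussianModel, v: np.ndarray) -> np.ndarray:
        d = v - model.mu
        return np.einsum("mi,ij,mj->m", d, model.precision, d)

    ell = (
        -0.5 * quad(m.model_joint, x)
        + 0.5 * quad(m.model_left, x_left)
        + 0.5 * quad(m.model_right, x_right)
        + m.c
    )
    return float(ell[0]) if ell.shape[0] == 1 else ell


def score_alignment_pairs(
    paired: PairedAlignment, m: InteractionModel
) -> np.ndarray:
    """Score each row of a paired alignment (true pairings)."""
    return np.atleast_1d(
        interaction_score(
            encode_onehot(paired.left), encode_onehot(paired.right), m
        )
    )


def rank_partners(
    queries: Alignment, candidates: Alignment, m: InteractionModel
) -> tuple[np.ndarray, list[list[int]]]:
    """Full query x candidate score matrix plus per-query rankings.

    Inputs must be pre-aligned to the family column spaces (gap-padded,
    inserts removed); this tool does not run the alignment step.  Returns
    (scores, rankings) where rankings[qi] lists candidate indices in
    descending score order.
    """
    s = queries.q - 1
    if queries.N * s != m.dim_left:
        raise ValueError(
            f"query alignment has {queries.N} columns but the model expects "
            f"{m.dim_left // s}; align the queries against the family model "
            "first"
        )
    if candidates.N * s != m.dim_right:
        raise ValueError(
            f"candidate alignment has {candidates.N} columns but the model "
            f"expects {m.dim_right // s}; align the candidates against the "
            "family model first"
        )
    Xq = encode_onehot(queries)
    Xc = encode_onehot(candidates)
    scores = np.empty((queries.M, candidates.M))
    for qi in range(queries.M):
        if candidates.M == 0:
            continue
        rep = np.repeat(Xq[qi:qi + 1], candidates.M, axis=0)
        scores[qi] = np.atleast_1d(interaction_score(rep, Xc, m))
    rankings = [
        sorted(range(candidates.M), key=lambda ci: (-scores[qi, ci], ci))
        for qi in range(queries.M)
    ]
    return scores, rankings
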