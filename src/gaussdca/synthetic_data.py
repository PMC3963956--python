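"""Synthetic alignments with known ground truth.

The Gaussian coupling estimator is meant to be run on discrete sequence
data, so ground truth is generated from Potts models (categorical Markov
random fields): columns are q-state variables, designated column pairs
carry explicit coupling matrices, and everything else is independent given
the fields.  Sampling is exact (full enumeration of the q^N state space)
whenever that space is small enough, which makes the target distribution
known to machine precision; a Gibbs sampler covers larger specs.  Helpers
add near-duplicate redundancy (emulating phylogenetic clustering) and
paired alignments with planted inter-protein couplings for the
partner-scoring pipeline.

Symbol 0 of a synthetic alignment is the reference state mapped to the
all-zero one-hot block — the role the gap plays for protein data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import Alignment

#: Exact mode enumerates at most this many configurations.
EXACT_STATE_LIMIT = 10_000_000

GIBBS_BURNIN = 1000  # sweeps
GIBBS_THIN = 10  # sweeps between retained samples


@dataclass
class PottsSpec:
    """A Potts model: P(s) ∝ exp(beta * [sum_i h_i(s_i) + sum_{i<j} e_ij(s_i, s_j)]).

    ``fields`` is N x q; ``couplings`` maps ordered column pairs (i, j),
    i < j, to q x q matrices.  Pairs absent from the dict are uncoupled.
    """

    N: int
    q: int
    fields: np.ndarray | None = None
    couplings: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not 2 <= self.q <= 21:
            raise ValueError("q must lie in 2..21")
        if self.fields is None:
            self.fields = np.zeros((self.N, self.q))
        self.fields = np.asarray(self.fields, dtype=np.float64)
        if self.fields.shape != (self.N, self.q):
            raise ValueError("fields must be N x q")
        for (i, j), e in self.couplings.items():
            if not 0 <= i < j < self.N:
                raise ValueError(f"coupling pair {(i, j)} must satisfy 0 <= i < j < N")
            if np.asarray(e).shape != (self.q, self.q):
                raise ValueError(f"coupling block {(i, j)} must be q x q")

    @property
    def coupled_pairs(self) -> list[tuple[int, int]]:
        return sorted(
            (i, j) for (i, j), e in self.couplings.items() if np.any(e)
        )


def make_coupled_spec(
    N: int,
    q: int,
    pairs: list[tuple[int, int]],
    strength: float = 1.0,
    kind: str = "potts",
    seed: int | None = None,
) -> PottsSpec:
    """Convenience constructor planting couplings on designated pairs.

    ``kind='potts'`` uses the ferromagnetic matrix strength * delta_ab;
    ``kind='random'`` draws a seeded Gaussian q x q block scaled by
    ``strength`` (symmetrized under the pair swap by construction of use).
    """
    rng = np.random.default_rng(seed)
    couplings = {}
    for i, j in pairs:
        if kind == "potts":
            e = strength * np.eye(q)
        elif kind == "random":
            e = strength * rng.standard_normal((q, q))
        else:
            raise ValueError(f"unknown coupling kind {kind!r}")
        couplings[(i, j)] = e
    return PottsSpec(N=N, q=q, couplings=couplings)


def _enumerate_states(N: int, q: int) -> np.ndarray:
    """All q^N configurations as a (q^N, N) int8 matrix (mixed radix)."""
    K = q**N
    codes = np.arange(K)
    out = np.empty((K, N), dtype=np.int8)
    for i in range(N - 1, -1, -1):
        out[:, i] = codes % q
        codes //= q
    return out


def _log_weights(spec: PottsSpec, states: np.ndarray) -> np.ndarray:
    lw = np.zeros(states.shape[0])
    for i in range(spec.N):
        lw += spec.fields[i, states[:, i]]
    for (i, j), e in spec.couplings.items():
        lw += np.asarray(e)[states[:, i], states[:, j]]
    return spec.beta * lw


def boltzmann_probabilities(spec: PottsSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact (states, probabilities) by full enumeration."""
    if spec.q**spec.N > EXACT_STATE_LIMIT:
        raise ValueError(
            f"state space q^N = {spec.q}**{spec.N} exceeds the exact-mode "
            f"limit of {EXACT_STATE_LIMIT}"
        )
    states = _enumerate_states(spec.N, spec.q)
    lw = _log_weights(spec, states)
    lw -= lw.max()
    p = np.exp(lw)
    p /= p.sum()
    return states, p


def _gibbs_sample(spec: PottsSpec, M: int, rng: np.random.Generator) -> np.ndarray:
    neighbors: dict[int, list[tuple[int, np.ndarray, bool]]] = {
        i: [] for i in range(spec.N)
    }
    for (i, j), e in spec.couplings.items():
        e = np.asarray(e)
        neighbors[i].append((j, e, False))
        neighbors[j].append((i, e, True))
    s = rng.integers(0, spec.q, size=spec.N)
    out = np.empty((M, spec.N), dtype=np.int8)
    kept = 0
    sweep = 0
    while kept < M:
        for i in range(spec.N):
            logits = spec.fields[i].copy()
            for j, e, transposed in neighbors[i]:
                logits += e[:, s[j]] if not transposed else e[s[j], :]
            logits *= spec.beta
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            s[i] = rng.choice(spec.q, p=p)
        sweep += 1
        if sweep > GIBBS_BURNIN and (sweep - GIBBS_BURNIN) % GIBBS_THIN == 0:
            out[kept] = s
            kept += 1
    return out


def sample_potts(
    spec: PottsSpec, M: int, seed: int, mode: str = "auto"
) -> Alignment:
    """Draw M sequences from a Potts model.

    Exact mode enumerates all q^N configurations, computes the Boltzmann
    probabilities and draws i.i.d. rows; it is used automatically whenever
    q^N <= 10^7.  Gibbs mode runs a single chain with 1000 burn-in sweeps
    and 10 sweeps of thinning between retained samples.
    """
    rng = np.random.default_rng(seed)
    if mode == "auto":
        mode = "exact" if spec.q**spec.N <= EXACT_STATE_LIMIT else "gibbs"
    if mode == "exact":
        states, p = boltzmann_probabilities(spec)
        rows = states[rng.choice(states.shape[0], size=M, p=p)]
    elif mode == "gibbs":
        rows = _gibbs_sample(spec, M, rng)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return Alignment(rows, ids=[f"sample{m+1}" for m in range(M)], q=spec.q)


def make_redundant(
    aln: Alignment, copies: int = 2, mutation_rate: float = 0.0, seed: int = 0
) -> Alignment:
    """Expand each sequence into ``copies`` rows (the original plus mutated
    near-duplicates), emulating phylogenetic clustering.

    Each symbol of a duplicate is independently resampled uniformly over
    the q states with probability ``mutation_rate``; rate 0 yields exact
    repeats, rate near 1 yields nearly independent rows.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for m in range(aln.M):
        rows.append(aln.symbols[m])
        ids.append(aln.ids[m])
        for k in range(1, copies):
            dup = aln.symbols[m].copy()
            mask = rng.random(aln.N) < mutation_rate
            dup[mask] = rng.integers(0, aln.q, size=int(mask.sum()))
            rows.append(dup)
            ids.append(f"{aln.ids[m]}_dup{k}")
    return Alignment(np.vstack(rows), ids=ids, q=aln.q)


def sample_paired(
    spec_left: PottsSpec,
    spec_right: PottsSpec,
    inter_couplings: dict[tuple[int, int], np.ndarray],
    M: int,
    shuffle_fraction: float = 0.0,
    seed: int = 0,
):
    """Paired alignment with planted inter-protein couplings.

    ``inter_couplings`` maps (left column, right column) pairs to q x q
    blocks.  A joint Potts model over N_A + N_B columns is sampled; then a
    ``shuffle_fraction`` of rows have their right halves cyclically
    re-paired among themselves, breaking those pairings.  Returns
    ``(PairedAlignment, truth)`` with ``truth[m]`` True iff row m kept its
    original partner.
    """
    from .partner import PairedAlignment

    if spec_left.q != spec_right.q:
        raise ValueError("left and right specs must share q")
    na, nb, q = spec_left.N, spec_right.N, spec_left.q
    couplings = dict(spec_left.couplings)
    for (i, j), e in spec_right.couplings.items():
        couplings[(na + i, na + j)] = e
    for (i, j), e in inter_couplings.items():
        if not (0 <= i < na and 0 <= j < nb):
            raise ValueError(f"inter coupling {(i, j)} out of range")
        couplings[(i, na + j)] = np.asarray(e)
    joint_spec = PottsSpec(
        N=na + nb,
        q=q,
        fields=np.vstack([spec_left.fields, spec_right.fields]),
        couplings=couplings,
        beta=spec_left.beta,
    )
    joint = sample_potts(joint_spec, M, seed=seed)
    truth = np.ones(M, dtype=bool)
    n_shuffle = int(round(shuffle_fraction * M))
    right = joint.symbols[:, na:].copy()
    if n_shuffle >= 2:
        rng = np.random.default_rng(seed + 1)
        sel = rng.choice(M, size=n_shuffle, replace=False)
        right[sel] = right[np.roll(sel, 1)]  # cyclic shift: every row re-paired
        truth[sel] = False
    paired = PairedAlignment(
        left=Alignment(joint.symbols[:, :na], ids=list(joint.ids), q=q),
        right=Alignment(right, ids=list(joint.ids), q=q),
    )
    return paired, truth


def toy_contact_truth(spec: PottsSpec) -> np.ndarray:
    """Boolean N x N map of the designated coupled pairs (symmetric)."""
    truth = np.zeros((spec.N, spec.N), dtype=bool)
    for i, j in spec.coupled_pairs:
        truth[i, j] = truth[j, i] = True
    return truth
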