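"""Contact maps from distance matrices and true-positive-rate curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scoring import RankedPairs

#: Minimal heavy-atom distance defining a residue contact, in angstroms.
DEFAULT_CONTACT_CUTOFF = 8.0


@dataclass
class ContactMap:
    contacts: np.ndarray  # boolean N x N, symmetric; diagonal ignored
    cutoff: float

    @property
    def n_cols(self) -> int:
        return self.contacts.shape[0]


def contact_map(
    distances: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    inclusive: bool = True,
    atol: float = 1e-6,
) -> ContactMap:
    """Threshold a residue-residue distance matrix (angstroms) into contacts.

    A pair is a contact when its minimal heavy-atom distance is <= cutoff
    (``inclusive=False`` switches to strict <).
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(d - d.T).max() > atol:
        raise ValueError("distance matrix is not symmetric")
    if d.size and d.min() < 0:
        raise ValueError("distances must be non-negative")
    contacts = d <= cutoff if inclusive else d < cutoff
    return ContactMap(contacts=contacts, cutoff=cutoff)


def read_distance_matrix(path) -> np.ndarray:
    """Whitespace-separated numeric N x N table."""
    return np.loadtxt(path)


def tpr_curve(
    ranked: RankedPairs, truth: ContactMap, max_k: int | None = None
) -> list[tuple[int, float]]:
    """TPR(k) = (true contacts among the top k pairs) / k, k = 1..max_k.

    ``max_k`` beyond the number of eligible pairs is truncated with a
    warning.
    """
    n_pairs = len(ranked)
    if max_k is None:
        max_k = n_pairs
    elif max_k > n_pairs:
        warnings.warn(
            f"max_k={max_k} exceeds the {n_pairs} eligible pairs; truncating"
        )
        max_k = n_pairs
    hits = 0
    out = []
    for k, ((i, j), _) in enumerate(ranked, start=1):
        if k > max_k:
            break
        if truth.contacts[i - 1, j - 1]:
            hits += 1
        out.append((k, hits / k))
    return out


def write_tpr_curve(curve, path) -> None:
    with open(path, "w") as fh:
        for k, tpr in curve:
            fh.write(f"{k}\t{tpr!r}\n")
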