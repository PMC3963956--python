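import numpy as np
import pytest
from hypothesis import settings

import gaussdca as g

settings.register_profile(
    "ci", max_examples=25, derandomize=True, deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def tiny_fasta(tmp_path):
    """Aligned FASTA with inserts, ambiguity codes and a gap-heavy row."""
    text = (
        ">seq1\nACDE-\n"
        ">seq2\nAxCDEF\n"  # lowercase insert -> removed
        ">seq3\nAC-EX\n"
        ">seq4\n-----\n"  # all gaps: dropped by the 90% filter
    )
    # seq2 has 6 chars but 5 matched columns after removing the insert
    path = tmp_path / "tiny.fasta"
    path.write_text(text)
    return path


def random_alignment(seed, M=None, N=None, q=21):
    """Seeded random alignment used by the property tests."""
    rng = np.random.default_rng(seed)
    M = M or int(rng.integers(2, 20))
    N = N or int(rng.integers(2, 10))
    return g.Alignment(rng.integers(0, q, size=(M, N)), q=q)


@pytest.fixture(scope="session")
def coupled_counts():
    """Reweighted counts from a small coupled Potts sample (shared)."""
    spec = g.make_coupled_spec(5, 4, [(0, 3)], strength=1.0)
    aln = g.sample_potts(spec, 2000, seed=42)
    w = g.compute_weights(aln, theta=0.2)
    return g.weighted_frequencies(aln, w)
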