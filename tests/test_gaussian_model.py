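import numpy as np
import pytest

import gaussdca as g
from gaussdca.reweighting import FrequencyCounts

from conftest import random_alignment


def counts_from(aln, theta=0.3):
    return g.weighted_frequencies(aln, g.compute_weights(aln, theta=theta))


def empty_counts(N, q):
    """meff = 0 counts (no data)."""
    D = (q - 1) * N
    return FrequencyCounts(
        mean=np.zeros(D), second=np.zeros((D, D)), cov=np.zeros((D, D)),
        meff=0.0, n_cols=N, q=q,
    )


class TestUninformativePrior:
    def test_uniform_mean(self):
        prior = g.uninformative_prior(3, q=21)
        assert np.allclose(prior.mu0, 1 / 21)

    def test_uniform_covariance_entries(self):
        # at the reference point nu = D + 2 the scale factor is 1
        prior = g.uninformative_prior(2, q=21)
        assert prior.Lambda[0, 0] == pytest.approx(1 / 21 - 1 / 441)
        assert prior.Lambda[0, 1] == pytest.approx(-1 / 441)

    def test_cross_column_blocks_zero(self):
        prior = g.uninformative_prior(2, q=21)
        assert np.all(prior.Lambda[:20, 20:] == 0)

    def test_integrability_bound(self):
        with pytest.raises(ValueError):
            g.uninformative_prior(2, q=21, nu=41.0)  # D + 1 = 41


class TestNIWPosterior:
    def test_no_data_returns_prior(self):
        prior = g.uninformative_prior(2, q=3, kappa=2.0)
        post = g.niw_posterior(empty_counts(2, 3), prior)
        assert np.allclose(post.mu_n, prior.mu0)
        assert np.allclose(post.Lambda_n, prior.Lambda)
        assert post.kappa_n == prior.kappa and post.nu_n == prior.nu

    def test_data_dominated_limit(self):
        aln = random_alignment(2, M=10, N=2, q=3)
        counts = counts_from(aln)
        prior = g.uninformative_prior(2, q=3, kappa=1e-12)
        post = g.niw_posterior(counts, prior)
        assert np.allclose(post.mu_n, counts.mean, atol=1e-10)

    def test_hand_computed_single_column(self):
        """N=1, q=3, sequences [1], [2], [0]: all moments are simple
        fractions worked out by hand."""
        aln = g.Alignment(np.array([[1], [2], [0]]), q=3)
        counts = g.weighted_frequencies(aln, g.Weights(np.ones(3), 3.0, 0.2))
        assert np.allclose(counts.mean, [1 / 3, 1 / 3])
        assert np.allclose(
            counts.cov, [[2 / 9, -1 / 9], [-1 / 9, 2 / 9]]
        )
        prior = g.uninformative_prior(1, q=3, kappa=2.0, nu=4.0)
        post = g.niw_posterior(counts, prior)
        assert post.kappa_n == 5.0 and post.nu_n == 7.0
        assert np.allclose(post.mu_n, [1 / 3, 1 / 3])  # dev = 0
        assert np.allclose(
            post.Lambda_n, [[8 / 9, -4 / 9], [-4 / 9, 8 / 9]]
        )
        model = g.posterior_mean_estimates(post)
        assert np.allclose(
            model.Sigma, [[2 / 9, -1 / 9], [-1 / 9, 2 / 9]]
        )


class TestPosteriorMeanEstimates:
    def test_prior_mean_with_no_data(self):
        prior = g.uninformative_prior(1, q=3, kappa=1.0, nu=6.0)
        model = g.posterior_mean_estimates(
            g.niw_posterior(empty_counts(1, 3), prior)
        )
        # Lambda/(nu - D - 1) is the uniform-categorical covariance
        assert np.allclose(
            model.Sigma, [[1 / 3 - 1 / 9, -1 / 9], [-1 / 9, 1 / 3 - 1 / 9]]
        )

    def test_dof_violation(self):
        prior = g.uninformative_prior(1, q=3, nu=4.0)
        post = g.niw_posterior(empty_counts(1, 3), prior)
        post.nu_n = 2.0
        with pytest.raises(ValueError):
            g.posterior_mean_estimates(post)

    def test_output_symmetric_pd(self, coupled_counts):
        prior = g.equivalent_niw_prior(
            coupled_counts.n_cols, coupled_counts.q, 0.3, coupled_counts.meff
        )
        model = g.posterior_mean_estimates(
            g.niw_posterior(coupled_counts, prior)
        )
        assert np.allclose(model.Sigma, model.Sigma.T)
        assert np.linalg.eigvalsh(model.Sigma).min() > 0


def literal_tilde_sigma(counts, pc):
    """Entry-wise evaluation of the tilde-frequency formulas."""
    q, N, s = counts.q, counts.n_cols, counts.q - 1
    D = s * N
    f1 = (1 - pc) * counts.mean + pc / q
    f2 = np.empty((D, D))
    for ia in range(D):
        for jb in range(D):
            i, a = divmod(ia, s)
            j, b = divmod(jb, s)
            if i == j:
                f2[ia, jb] = (1 - pc) * counts.second[ia, jb] + (
                    pc / q if a == b else 0.0
                )
            else:
                f2[ia, jb] = (1 - pc) * counts.second[ia, jb] + pc / q**2
    return f2 - np.outer(f1, f1)


class TestPseudocountCovariance:
    def test_pc_zero_is_empirical_cov(self):
        aln = random_alignment(9, M=500, N=2, q=3)
        counts = counts_from(aln)
        model = g.pseudocount_covariance(counts, 0.0)
        assert np.allclose(model.Sigma, counts.cov, atol=1e-14)

    def test_pc_zero_rank_deficient_raises(self):
        aln = g.Alignment(np.array([[1, 2]]), q=21)
        counts = g.weighted_frequencies(aln, g.Weights(np.ones(1), 1.0, 0.2))
        with pytest.raises(np.linalg.LinAlgError, match="pseudo-count"):
            g.pseudocount_covariance(counts, 0.0)

    def test_pc_one_uniform_block_diagonal(self, coupled_counts):
        model = g.pseudocount_covariance(coupled_counts, 1.0)
        q, s = coupled_counts.q, coupled_counts.q - 1
        expect = np.eye(s) / q - np.full((s, s), 1 / q**2)
        for i in range(coupled_counts.n_cols):
            for j in range(coupled_counts.n_cols):
                block = model.sigma_block(i, j)
                assert np.allclose(block, expect if i == j else 0.0)

    def test_toy_alignment_matches_literal_formulas(self):
        aln = g.Alignment(np.array([[1, 2], [2, 2]]), q=3)
        counts = g.weighted_frequencies(aln, g.Weights(np.ones(2), 2.0, 0.2))
        model = g.pseudocount_covariance(counts, 0.5)
        assert np.allclose(
            model.Sigma, literal_tilde_sigma(counts, 0.5), atol=1e-14
        )

    def test_invalid_pc(self, coupled_counts):
        with pytest.raises(ValueError):
            g.pseudocount_covariance(coupled_counts, 1.5)

    @pytest.mark.parametrize("pc", [0.1, 0.5, 0.9])
    def test_equivalent_to_niw_posterior_mean(self, coupled_counts, pc):
        """Central cross-check: the pseudo-count covariance IS the NIW
        posterior mean under the uniform prior with kappa = nu - D - 1 =
        meff*pc/(1-pc)."""
        counts = coupled_counts
        direct = g.pseudocount_covariance(counts, pc)
        prior = g.equivalent_niw_prior(counts.n_cols, counts.q, pc, counts.meff)
        via_niw = g.posterior_mean_estimates(g.niw_posterior(counts, prior))
        scale = np.abs(direct.Sigma).max()
        assert np.abs(direct.Sigma - via_niw.Sigma).max() / scale < 1e-8
        assert np.allclose(direct.mu, via_niw.mu, atol=1e-12)

    @pytest.mark.parametrize("pc", [0.1, 0.5, 0.9])
    def test_precision_inverts_sigma(self, coupled_counts, pc):
        model = g.pseudocount_covariance(coupled_counts, pc)
        D = model.Sigma.shape[0]
        resid = model.precision @ model.Sigma - np.eye(D)
        assert np.abs(resid).max() < 1e-8
        sign, logdet = np.linalg.slogdet(model.Sigma)
        assert sign > 0
        assert model.logdet_sigma == pytest.approx(logdet, rel=1e-10)

    def test_off_diagonal_shrinks_with_pc(self, coupled_counts):
        def off_norm(model):
            total = 0.0
            s = model.block
            for i in range(model.n_cols):
                for j in range(i + 1, model.n_cols):
                    total += np.linalg.norm(model.sigma_block(i, j)) ** 2
            return np.sqrt(total)

        norms = [
            off_norm(g.pseudocount_covariance(coupled_counts, pc))
            for pc in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestExtractCouplings:
    def test_pc_one_couplings_vanish(self, coupled_counts):
        cmap = g.extract_couplings(
            g.pseudocount_covariance(coupled_counts, 1.0)
        )
        for block in cmap.couplings.values():
            assert np.abs(block).max() < 1e-10

    def test_symmetry(self, coupled_counts):
        model = g.pseudocount_covariance(coupled_counts, 0.4)
        s = model.block
        for i in range(model.n_cols):
            for j in range(i + 1, model.n_cols):
                Jij = model.coupling_block(i, j)
                Jji = model.precision[
                    j * s:(j + 1) * s, i * s:(i + 1) * s
                ]
                assert np.allclose(Jij, Jji.T)

    def test_matches_direct_inversion(self, coupled_counts):
        model = g.pseudocount_covariance(coupled_counts, 0.5)
        brute = np.linalg.inv(model.Sigma)
        cmap = g.extract_couplings(model)
        s = model.block
        for (i, j), block in cmap.couplings.items():
            assert np.allclose(
                block, brute[i * s:(i + 1) * s, j * s:(j + 1) * s], atol=1e-9
            )
        for i, blk in enumerate(cmap.sigma_diag):
            assert np.allclose(blk, model.sigma_block(i, i))


class TestFitModel:
    def test_pseudocount_route_default(self, coupled_counts):
        m = g.fit_model(coupled_counts, pc=0.2)
        assert m.pc == 0.2

    def test_niw_route(self, coupled_counts):
        m = g.fit_model(coupled_counts, prior="niw", kappa=2.0)
        assert np.isfinite(m.logdet_sigma)

    def test_unknown_prior(self, coupled_counts):
        with pytest.raises(ValueError):
            g.fit_model(coupled_counts, prior="bogus")
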