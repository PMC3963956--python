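"""Gaussian model estimation under a normal-inverse-Wishart prior.

The one-hot encoded MSA is modeled as i.i.d. draws from a multivariate
Gaussian with mean mu and covariance Sigma of dimension D = (q-1)*N.  The
empirical covariance is typically rank deficient, so (mu, Sigma) are
estimated as posterior means under the conjugate NIW prior.  With the
uninformative prior (mean and covariance of uniformly distributed
categorical samples) the posterior-mean covariance coincides exactly with
the classic pseudo-count-corrected covariance: writing pc for the prior
weight, mixing the empirical frequencies with the uniform ones at ratio
(1-pc):pc reproduces the NIW posterior mean for

    kappa = nu - D - 1 = meff * pc / (1 - pc),      Lambda = kappa * Lambda_u,

where Lambda_u is block-diagonal with within-column entries
delta_ab/q - 1/q^2.  (Derivation: the posterior mean of mu is
(kappa*mu0 + meff*xbar)/(kappa+meff), which equals the tilde frequency
(1-pc)*xbar + pc*mu0 iff kappa/(kappa+meff) = pc; substituting into the
posterior scale matrix and dividing by nu_n - D - 1 matches the tilde
covariance term by term iff nu - D - 1 = kappa and Lambda = kappa*Lambda_u.)

The (q-1) x (q-1) blocks of the precision matrix Sigma^{-1} linking two
columns play the role of the direct couplings of DCA and feed the scoring
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .reweighting import FrequencyCounts

logger = logging.getLogger("gaussdca")

#: Diagonal jitter added once if the Cholesky factorization of Sigma fails;
#: pc > 0 makes Sigma positive definite analytically, so this only guards
#: floating-point edge cases.
CHOLESKY_JITTER = 1e-8


class SingularModelError(np.linalg.LinAlgError):
    """Sigma is numerically singular (typically pc = 0 on undersampled data)."""


@dataclass
class NIWPrior:
    """Normal-inverse-Wishart prior: N(mu | mu0, Sigma/kappa) x IW(Sigma | Lambda, nu)."""

    mu0: np.ndarray
    kappa: float
    nu: float
    Lambda: np.ndarray
    q: int = 21

    @property
    def dim(self) -> int:
        return self.mu0.shape[0]


@dataclass
class NIWPosterior:
    mu_n: np.ndarray
    kappa_n: float
    nu_n: float
    Lambda_n: np.ndarray
    q: int = 21

    @property
    def dim(self) -> int:
        return self.mu_n.shape[0]


@dataclass
class GaussianModel:
    """Estimated Gaussian parameters with precomputed inverse and log-det."""

    mu: np.ndarray
    Sigma: np.ndarray
    precision: np.ndarray
    logdet_sigma: float
    pc: float
    n_cols: int
    q: int = 21

    @property
    def block(self) -> int:
        """One-hot block size per column, q - 1."""
        return self.q - 1

    def sigma_block(self, i: int, j: int) -> np.ndarray:
        s = self.block
        return self.Sigma[i * s:(i + 1) * s, j * s:(j + 1) * s]

    def coupling_block(self, i: int, j: int) -> np.ndarray:
        s = self.block
        return self.precision[i * s:(i + 1) * s, j * s:(j + 1) * s]


@dataclass
class CouplingMap:
    """Direct couplings J_ij (precision blocks, i < j) plus the diagonal
    Sigma blocks that the direct-information score needs."""

    couplings: dict[tuple[int, int], np.ndarray]
    sigma_diag: list[np.ndarray]
    n_cols: int
    q: int = 21


def _uniform_column_cov(q: int) -> np.ndarray:
    """Covariance of the (q-1) one-hot indicators of a uniform categorical
    over q states: delta_ab/q - 1/q^2."""
    s = q - 1
    return np.eye(s) / q - np.full((s, s), 1.0 / q**2)


def uninformative_prior(
    N: int, q: int = 21, kappa: float = 1.0, nu: float | None = None
) -> NIWPrior:
    """Prior matching uniformly distributed samples.

    mu0 is the constant vector 1/q and Lambda is block-diagonal with the
    uniform-categorical covariance in each column block (off-diagonal
    blocks zero), scaled by (nu - D - 1) so that the prior mean of Sigma,
    Lambda/(nu - D - 1), is exactly the uniform covariance.  ``nu`` defaults
    to D + 2, the smallest integer choice with a finite prior mean.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    D = (q - 1) * N
    if nu is None:
        nu = D + 2
    if nu <= D + 1:
        raise ValueError(
            f"nu must exceed D + 1 = {D + 1} for the prior mean of Sigma "
            "to exist"
        )
    mu0 = np.full(D, 1.0 / q)
    Lambda = (nu - D - 1) * sla.block_diag(*[_uniform_column_cov(q)] * N)
    return NIWPrior(mu0=mu0, kappa=float(kappa), nu=float(nu), Lambda=Lambda, q=q)


def equivalent_niw_prior(
    N: int, q: int, pc: float, meff: float
) -> NIWPrior:
    """The NIW prior whose posterior mean reproduces the pseudo-count
    covariance with parameter ``pc`` on data of effective size ``meff``."""
    if not 0.0 < pc < 1.0:
        raise ValueError("the NIW identification requires 0 < pc < 1")
    D = (q - 1) * N
    kappa = meff * pc / (1.0 - pc)
    nu = kappa + D + 1
    return uninformative_prior(N, q=q, kappa=kappa, nu=nu)


def niw_posterior(counts: FrequencyCounts, prior: NIWPrior) -> NIWPosterior:
    """Conjugate update of the NIW prior with reweighted counts.

    meff replaces the i.i.d. sample size M, consistent with the reweighted
    likelihood.
    """
    if counts.mean.shape[0] != prior.dim:
        raise ValueError("prior/counts dimension mismatch")
    meff = counts.meff
    kappa_n = prior.kappa + meff
    nu_n = prior.nu + meff
    mu_n = (prior.kappa * prior.mu0 + meff * counts.mean) / kappa_n
    dev = counts.mean - prior.mu0
    Lambda_n = (
        prior.Lambda
        + meff * counts.cov
        + (prior.kappa * meff / kappa_n) * np.outer(dev, dev)
    )
    return NIWPosterior(
        mu_n=mu_n, kappa_n=kappa_n, nu_n=nu_n, Lambda_n=Lambda_n, q=prior.q
    )


def _invert_spd(
    Sigma: np.ndarray, allow_jitter: bool = True
) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via Cholesky, with one jitter retry."""
    try:
        c, low = sla.cho_factor(Sigma, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        if not allow_jitter:
            raise SingularModelError(
                "covariance matrix is not positive definite; use a "
                "pseudo-count pc > 0 (or a proper NIW prior) on "
                "undersampled alignments"
            )
        logger.warning(
            "Cholesky factorization failed; retrying with %g diagonal jitter",
            CHOLESKY_JITTER,
        )
        try:
            c, low = sla.cho_factor(
                Sigma + CHOLESKY_JITTER * np.eye(Sigma.shape[0]),
                lower=True,
                check_finite=False,
            )
        except np.linalg.LinAlgError:
            raise SingularModelError(
                "covariance matrix is not positive definite; use a "
                "pseudo-count pc > 0 (or a proper NIW prior) on "
                "undersampled alignments"
            )
    precision = sla.cho_solve((c, low), np.eye(Sigma.shape[0]), check_finite=False)
    precision = 0.5 * (precision + precision.T)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return precision, logdet


def posterior_mean_estimates(post: NIWPosterior, pc: float = np.nan) -> GaussianModel:
    """Posterior means of (mu, Sigma): mu_n and Lambda_n / (nu_n - D - 1)."""
    D = post.dim
    if post.nu_n <= D + 1:
        raise ValueError(
            f"nu_n = {post.nu_n} must exceed D + 1 = {D + 1} for the "
            "posterior mean of Sigma to exist"
        )
    Sigma = post.Lambda_n / (post.nu_n - D - 1)
    precision, logdet = _invert_spd(Sigma)
    return GaussianModel(
        mu=post.mu_n.copy(),
        Sigma=Sigma,
        precision=precision,
        logdet_sigma=logdet,
        pc=pc,
        n_cols=D // (post.q - 1),
        q=post.q,
    )


def pseudocount_covariance(counts: FrequencyCounts, pc: float) -> GaussianModel:
    """Pseudo-count route to the same estimate.

    Tilde frequencies mix empirical and uniform statistics:
    f~_i(a) = (1-pc)*xbar(i,a) + pc/q; cross-column pair moments get
    pc/q^2, same-column ones pc*delta_ab/q (the uniform second moment of
    mutually exclusive indicators).  Sigma is the covariance of the tilde
    statistics; for pc -> 0 it tends to the empirical covariance, for
    pc = 1 to the block-diagonal uniform covariance.
    """
    if not 0.0 <= pc <= 1.0:
        raise ValueError("pc must lie in [0, 1]")
    q = counts.q
    N = counts.n_cols
    s = q - 1
    mean = (1.0 - pc) * counts.mean + pc / q
    second = (1.0 - pc) * counts.second + pc / q**2
    for i in range(N):
        sl = slice(i * s, (i + 1) * s)
        blk = (1.0 - pc) * counts.second[sl, sl] + (pc / q) * np.eye(s)
        second[sl, sl] = blk
    Sigma = second - np.outer(mean, mean)
    Sigma = 0.5 * (Sigma + Sigma.T)
    precision, logdet = _invert_spd(Sigma, allow_jitter=pc > 0.0)
    return GaussianModel(
        mu=mean,
        Sigma=Sigma,
        precision=precision,
        logdet_sigma=logdet,
        pc=pc,
        n_cols=N,
        q=q,
    )


def fit_model(
    counts: FrequencyCounts,
    pc: float = 0.2,
    prior: str = "pseudocount",
    kappa: float | None = None,
    nu: float | None = None,
) -> GaussianModel:
    """Front door: pseudo-count route by default, explicit NIW on request."""
    if prior == "pseudocount":
        return pseudocount_covariance(counts, pc)
    if prior == "niw":
        p = uninformative_prior(
            counts.n_cols,
            q=counts.q,
            kappa=1.0 if kappa is None else kappa,
            nu=nu,
        )
        return posterior_mean_estimates(niw_posterior(counts, p), pc=np.nan)
    raise ValueError(f"unknown prior mode {prior!r}")


def extract_couplings(model: GaussianModel) -> CouplingMap:
    """Per-pair precision blocks J_ij (i < j) and diagonal Sigma blocks."""
    N = model.n_cols
    couplings = {
        (i, j): model.coupling_block(i, j)
        for i in range(N)
        for j in range(i + 1, N)
    }
    sigma_diag = [model.sigma_block(i, i) for i in range(N)]
    return CouplingMap(
        couplings=couplings, sigma_diag=sigma_diag, n_cols=N, q=model.q
    )
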