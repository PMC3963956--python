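# Methods

## The model

A multiple sequence alignment (MSA) of M homologous protein sequences over
N columns is encoded one column at a time into 20 binary indicator
variables (one per amino acid, alphabet ACDEFGHIKLMNPQRSTVWY); the gap is
the all-zero block. Each sequence thus becomes a vector x in {0,1}^D,
D = 20N (block size q−1 in general, with q the alphabet size; the package
is generic in q because synthetic benchmarks use smaller alphabets). The
rows of the encoded MSA are modelled as i.i.d. draws from a multivariate
Gaussian N(mu, Sigma).

The inferential target is the inverse covariance: the 20×20 block of
Sigma⁻¹ linking columns i and j is the *direct coupling* J_ij between the
two positions, the analogue of the pairwise interaction term of a Potts
model after mean-field treatment. Correlations propagated through chains
of intermediate positions inflate the covariance but not the precision
blocks, which is what makes the inverse the right object for contact
prediction.

## Reweighting

Biological sampling is phylogenetically clustered, not i.i.d. Each
sequence m receives weight w_m = 1/n_m, where n_m counts the sequences
(including m itself) whose fraction of differing positions is below a
threshold theta; meff = Σ w_m is the effective sample size and replaces M
everywhere. In the limit of small theta this reduces to de-duplication.
Identity is computed over all matched columns, gap–gap agreements
included (simplest convention; configurable through the preprocessing).

theta defaults to `auto`: a pre-pass estimates the mean pairwise identity
(all pairs up to 2×10⁶, then a seeded uniform subsample) and sets
theta = min(0.5, 0.1216 / identity) — the 0.38·0.32 heuristic familiar
from contact-prediction reweighting code. The auto rule is a documented
stand-in for a tuning pass that is not fully specified in the literature
this package follows; `--theta` overrides it.

The empirical moments are reweighted sums over the one-hot rows:
x̄ = Σ (w_m/meff) x_m and C = Σ (w_m/meff) x_m x_mᵀ − x̄ x̄ᵀ. Within one
column the indicators are mutually exclusive, so
C((i,a),(i,b)) = −x̄(i,a)x̄(i,b) for a ≠ b holds exactly — an identity the
tests use as a machine-precision invariant.

## Estimation under the normal-inverse-Wishart prior

C is rank deficient whenever meff < D (always, in practice), so maximum
likelihood is unusable. The package estimates (mu, Sigma) as posterior
means under the conjugate normal-inverse-Wishart (NIW) prior with
hyperparameters (mu0, kappa, nu, Lambda):

- posterior mean of mu: (kappa·mu0 + meff·x̄)/(kappa + meff)
- posterior mean of Sigma: Lambda_n/(nu_n − D − 1), with
  nu_n = nu + meff and
  Lambda_n = Lambda + meff·C + (kappa·meff/(kappa+meff))(x̄−mu0)(x̄−mu0)ᵀ.

The uninformative prior takes mu0 and Lambda from uniformly distributed
categorical samples: mu0 = 1/q everywhere and Lambda block-diagonal with
within-column entries δ_ab/q − 1/q² (scaled by nu − D − 1 so the prior
mean of Sigma is exactly that uniform covariance for any admissible nu).

**Pseudo-count identity.** Mixing the empirical frequencies with the
uniform ones at ratio (1−pc):pc — single-site f̃_i(a) = (1−pc)x̄(i,a)+pc/q,
cross-column pair moments get pc/q², same-column ones pc·δ_ab/q — and
taking Sigma = f̃₂ − f̃f̃ᵀ reproduces the NIW posterior mean exactly when

    kappa = nu − D − 1 = meff·pc/(1−pc),   Lambda = kappa·Lambda_u.

Derivation: the posterior mean of mu equals f̃ iff kappa/(kappa+meff) = pc;
expanding Sigma_pc = (1−pc)C + pc·Lambda_u + pc(1−pc)(x̄−mu0)(x̄−mu0)ᵀ and
matching it to Lambda_n/(nu_n−D−1) term by term forces the remaining two
identifications. The pseudo-count route is the production path (one mixing
parameter, no matrix hyperparameters); the explicit NIW route is exposed
for research use and the equivalence is enforced by a cross-check test at
relative 1e−8.

pc defaults: 0.2 for Frobenius-norm scoring, 0.8 for direct information
and the partner score. The optimum genuinely depends on the scoring
function; these are the conventional choices for each and are plain flags.

Sigma is inverted by Cholesky factorization; pc > 0 guarantees positive
definiteness analytically, and a single 1e−8 diagonal jitter retry
(logged) guards floating-point corner cases. pc = 0 on rank-deficient
data raises a singular-model error instead of jittering, since a silently
regularized maximum-likelihood estimate would be misleading.

## Scoring column pairs

**Frobenius norm (FN).** The one-hot parametrization leaves a
row-constant + column-constant gauge freedom in each coupling block; the
score must not depend on it. The block is double-centred
(K_ab = J_ab − rowmean_a − colmean_b + grandmean) and its Frobenius norm
returned. The means run over the 20 residue states of the block: this is
the only convention under which a pure-gauge coupling scores exactly
zero, which the test suite enforces at 1e−10. The alternative
convention — embed the block in a 21×21 matrix with a zero gap
row/column, centre over all 21 states, drop the gap again — is available
as `gauge_states="embed-gap"`; it differs by a small residual
(1/441 of the shift per entry) on pure-gauge inputs.

**Direct information (DI).** The mutual information between columns i
and j under the *two-site direct model*: the Gaussian whose precision is
[[A, W],[Wᵀ, B]] with W = J_ij fixed and (A, B) chosen so that the
marginal covariances equal the estimated Sigma_ii and Sigma_jj. The
self-consistency A = Sigma_ii⁻¹ + W B⁻¹ Wᵀ, B = Sigma_jj⁻¹ + Wᵀ A⁻¹ W is
solved by fixed-point iteration from the uncoupled point (tolerance
1e−12 on the max-abs update, cap 1000 iterations; convergence failure
raises with the residual), after which
DI = ½·ln det(I + Sigma_ii W B⁻¹ Wᵀ). DI is gauge invariant and
non-negative; both properties are tested, and the fixed-point result is
checked against a brute-force construction of the joint covariance at
1e−8. The iterative solution was chosen over a closed form because the
defining equations are unambiguous and the independent oracle pins the
result.

**APC and ranking.** Both scores improve under the average-product
correction S′_ij = S_ij − R_i R_j / R̄ (row means and grand mean over
off-diagonal entries), which removes background signal shared by whole
columns (conservation, gap density). APC is applied by default
(`--no-apc` disables it). Pairs closer than 5 positions along the chain
are excluded from the ranking (trivial neighbours are always in
contact); ties break lexicographically for cross-platform determinism.

## Interaction-partner score

From an alignment of concatenated cognate pairs, three Gaussian models
are fitted — joint (N_A + N_B columns), left, right — with one weight
vector computed on the joint alignment and reused for the marginals
(`--separate-weights` opts out), and a shared pc (default 0.8). A
candidate pair is scored by the log-odds

    l(x_A, x_B) = ln N(x | mu_J, Sigma_J) − ln N(x_A | mu_A, Sigma_A)
                  − ln N(x_B | mu_B, Sigma_B),

whose volume terms cancel exactly because dimensions add, leaving the
three quadratic forms plus c = ½(ln det Sigma_A + ln det Sigma_B −
ln det Sigma_J). When the joint model factorizes, l ≡ 0 identically; the
constant c cancels in any per-query ranking. Orphan queries must be
pre-aligned to the family columns; gaps in them follow the all-zero-block
convention, contributing through the mean terms only.

## Evaluation

A residue pair is a contact when its minimal heavy-atom distance is
≤ 8 Å (inclusive boundary; flag to flip). Structure files are not
parsed — the user supplies a plain numeric distance matrix, since mapping
alignment columns to structure residues is outside this package's scope.
Ranked predictions are summarized by TPR(k) = (true contacts among the
top k)/k.

## Synthetic ground truth

Benchmarks sample discrete Potts models, not Gaussians, so the tests
exercise the method exactly as it is used in production: discrete data,
Gaussian approximation. A `PottsSpec` holds fields h_i(a) and coupling
matrices e_ij(a,b) on a designated pair set;
P(s) ∝ exp(β[Σ h + Σ e]). Sampling is exact — full enumeration of the
q^N state space (limit 10⁷) with i.i.d. draws from the Boltzmann
distribution — whenever possible, making the target distribution known
to machine precision; a Gibbs sampler (1000 burn-in sweeps, thinning 10)
covers larger specs. Helpers add near-duplicate rows (per-symbol uniform
resampling at a given mutation rate) to exercise reweighting, and paired
alignments with planted inter-protein couplings, where a chosen fraction
of rows has its right halves cyclically re-paired to create labelled
false pairings.

Default study conditions used by the recovery benchmarks: contact
recovery uses N = 8, q = 4, three coupled pairs at chain separation 5
with ferromagnetic coupling strength 1.2, M = 5×10⁴ exact samples per
run, five runs; partner experiments use N_A = N_B = 4, q = 3, four
diagonal inter couplings of strength 2.5, M = 6000 cognates with half
the rows re-paired. These sizes keep every benchmark exactly sampled
(state spaces 65536 and 6561) while giving the estimator a comfortable
signal-to-noise margin.

What the generator does *not* emulate: phylogenetic tree structure
(redundancy is star-shaped around each ancestor), indels and alignment
errors, composition bias, and the 21-letter alphabet at realistic column
counts. Passing tests therefore demonstrate correctness of the
estimator and scores and recoverability under clean conditions, not
field performance on real Pfam families.

## Numerical choices and edge cases

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  alignments and byte-identical CLI output.
- The O(M²) neighbour count is a compiled (numba) kernel with early exit
  once a pair is provably dissimilar; a literal Python implementation
  serves as its oracle in the tests and the two agree exactly.
- Second moments are computed as Xᵀ diag(w) X on the explicit one-hot
  matrix and symmetrized; this is the definitional computation, executed
  densely.
- Sequences with ≥ 90% gaps are dropped (boundary inclusive). Ambiguous
  residues (B, J, O, U, X, Z) map to the gap class — they have no slot
  in the 20-letter scheme; the policy is deliberately simple and
  documented rather than configurable per-code.
- Columns are never filtered; reported pair indices are 1-based.
- APC requires N ≥ 3 and a nonzero grand mean; degenerate all-zero score
  matrices raise instead of returning NaN.

## Known limitations

- The Gaussian likelihood is a model mismatch for categorical data; it
  is used because the posterior is closed-form and empirically accurate
  for ranking, not because it is generative truth.
- The partner score requires pre-aligned queries; no HMM alignment is
  performed.
- Gibbs-mode sampling is validated on marginals only, at small size; the
  exact mode is the reference path.
- No sparse (L1) precision estimation, no sampling from the full NIW
  posterior, no mean-field Potts DI.
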