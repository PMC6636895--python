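# Methods

## Model

The package estimates the structure of a Gaussian graphical model over p
*output* variables `X` conditional on m *input* variables `Z`, when an
unknown number of variables `H` is unobserved.  The generative assumption is
a Gaussian conditional random field over (X, H) given Z with joint
conditional precision blocks `M_X, M_XH, M_H` and input loadings
`M_ZX, M_ZH`; nothing is assumed about the distribution of Z itself.
Marginalizing H gives

    Y_X | Y_Z = z ~ N( -(S_X - L_X)^{-1} (S_ZX - L_ZX)^T z, (S_X - L_X)^{-1} ),

with `S_X = M_X`, `S_ZX = M_ZX`, `L_X = M_XH M_H^{-1} M_XH^T` and
`L_ZX = M_ZH M_H^{-1} M_XH^T`.  The data identify only the differences
`S - L` (stacked (p+m) x p matrices, X block on top); the estimator
separates them by exploiting that direct effects are *sparse* while
marginalized latent effects are *low-rank*:

    min  -l(S - L; Sigma_n) + lambda [ gamma ||S||_1 + (1-gamma) ||L||_* ]
    s.t. S_X - L_X > 0 (strict),  L_X >= 0,

a jointly convex problem.  The log-likelihood is used in its
sufficient-statistic form (second-moment matrices `Sigma_Z, Sigma_X,
Sigma_ZX`); it equals twice the average per-sample conditional log-density
plus a constant, which is also the convention the tests' density oracle
asserts.  The (0,1) penalty parameterization `lambda(gamma ||S||_1 +
(1-gamma) ||L||_*)` is canonical throughout; `penalty_to_paper` /
`penalty_from_paper` convert to and from the `lambda_n(gamma_n ||S||_1 +
||L||_*)` form.  The l1 norm includes the diagonal of `S_X` by default
(`penalize_diagonal=False` excludes it).

Four estimators share this machinery (`LSCGGM(..., method=...)`):

* `lscggm` - the full conditional sparse + low-rank estimator;
* `scggm`  - the low-rank component frozen at zero (sparse conditional GGM);
* `lrps`   - the same sparse + low-rank program applied to the *joint*
  (m+p) x (m+p) second-moment matrix, with `S_X`, `S_ZX`, `L_X` read off the
  corresponding sub-blocks of the joint estimates;
* `glasso` - `lrps` with the low-rank component frozen (graphical lasso).

Zero-mean convention: the sufficient statistics are raw 1/n cross-products;
no centering is applied by the statistics layer.  The model front-end and
CLI expose `center` / `standardize` flags (CLI default: center on, since
real data are rarely mean-zero; the simulator generates zero-mean data so
the library default is off).

## ADMM solver

The objective is split with a consensus variable `R = S - L`:

1. **R-block** - `argmin -l(R) + rho/2 ||R - (S - L - U)||^2`.  With no
   inputs (m = 0) this is the classic log-det prox with a closed form via
   one eigendecomposition.  With inputs, the matrix-fractional likelihood
   term couples the blocks of R and no closed form exists; the subproblem is
   solved inexactly by a Barzilai-Borwein gradient method with Armijo
   backtracking that rejects steps leaving the positive-definite cone.  The
   inner tolerance tightens proportionally to the outer residuals
   (inexact ADMM with diminishing errors), so early iterations are cheap and
   the final accuracy is not limited by the inner solve.
2. **S-block** - elementwise soft-thresholding at `lambda gamma / rho`.
3. **L-block** - the proximal operator of the stacked nuclear norm subject
   to a symmetric PSD top block.  It has no closed form; it is computed by a
   Dykstra-style proximal iteration alternating singular-value
   soft-thresholding with PSD projection of the top block, carrying the two
   correction sequences that make the alternation converge to the prox of
   the sum.  Typically well under ten inner iterations suffice at the
   tolerances used.
4. Scaled dual update, relative primal/dual residuals, and
   residual-balancing adaptation of rho (factor 2 when the residuals differ
   by more than 10x; adaptation stops after iteration 200 so the final
   iterations run at fixed rho).

Defaults: `rho = 1`, `tol_primal = tol_dual = 1e-5` (relative),
`max_iter = 1000`, initialization `S_X = I`, all else zero (or a warm
start).  Feasibility of the returned parameters is enforced by clipping
`L_X` at the PSD cone (prox output is PSD up to rounding) and shifting
`S_X` by at most `pd_floor = 1e-8` on the diagonal.

The consensus objective trace is *not* monotone: ADMM oscillates at the
level of the squared residuals.  The property test asserts the honest
version (non-increase within 1e-7 once residuals are below 1e-6).

## SDP reformulation and the built-in interior-point oracle

The problem admits an exact SDP form with auxiliary blocks `W` (Schur
complement certificate for the quartic input term), `F` (elementwise
epigraph of `||S||_1`) and `(H1, H2)` (epigraph of the nuclear norm,
`min (Tr H1 + Tr H2)/2` over `[[H1, L], [L^T, H2]] >= 0`).  Two readings of
the printed objective were fixed by identities rather than taste: the
nuclear scaling must be `(Tr H1 + Tr H2)/2` (otherwise the epigraph value at
`L = diag(3, 1)` fails to equal 4), and the log-det term must act on
`S_X - L_X` (otherwise the SDP optimum does not coincide with the penalized
likelihood optimum whenever `L_X != 0`).

No external conic solver is bundled; `solve_sdp` ships a log-barrier
path-following Newton method.  `W` and `F` are eliminated analytically at
each barrier parameter mu (the W elimination is exact; the F elimination is
the smoothed absolute value with explicit value/gradient/curvature), while
the `(H1, H2)` epigraph and the `L_X >= 0` cone remain as explicit log-det
barriers with analytic Hessians (`mu Tr(G^{-1} E_i G^{-1} E_j)` assembled
blockwise).  The central path is followed from mu = 1 down to 1e-9 with
damped Newton (Armijo backtracking, ridge-regularized solves for the
symmetric-parameterization null space).  Suboptimality is O(mu x cone
dimension); measured agreement with converged ADMM runs is ~1e-8 in
objective on desk-scale instances.  `SDPProblem.to_json` exports shapes,
cones and coefficients so an external conic solver can be attached instead.
The same machinery provides `prox_psd_nuclear_reference`, the independent
check of the Dykstra prox operator.  Intended scale: p + m up to a few tens
(dense Newton).

## Simulator

The structured designs are indexed by `(d_Z, d_H)` with `p = 2^k` outputs
and `m = p` inputs:

* `S*_X` is a chain with every fifth link removed: off-diagonal support
  exactly `{(i, j) : i = j + 1, i mod 5 != 0}` (1-based), 25 undirected
  edges at p = 32.
* `2^{d_H}` latent confounders; each confounds exactly `p / 2^{d_H}`
  outputs and each output loads on exactly one confounder, so
  `rank(L*_X) = 2^{d_H}`.  At `d_H = k` the pairing is one-to-one - no
  confounding.
* `M*_ZX` has rank exactly `2^{d_Z}` with exactly `p / 2^{d_Z}` nonzeros per
  row and per column: inputs are partitioned into `2^{d_Z}` groups acting on
  disjoint output blocks with rank-one within-block structure (sign-random
  factor entries whose products have magnitude in [0.2, 0.4]).
* `M*_ZH = 0`, hence `L*_ZX = 0` in every design.
* Inputs are iid t(4) (heavy-tailed, variance 2); outputs are drawn from the
  implied Gaussian conditional law via a Cholesky solve.

Unstated magnitudes are package choices: nonzero effects uniform on
+/-[0.2, 0.4]; `M_H` is a dominance diagonal plus a symmetric perturbation
uniform on +/-0.05; all diagonals of the joint (X, H) conditional precision
are set to the off-diagonal absolute row sum plus 0.5, which guarantees
strict diagonal dominance and hence positive definiteness of every design
(all configurable through `EffectConfig`).  Seeding is counter-based: a base
seed plus the design/replicate indices spawn independent `SeedSequence`
children, so any single dataset is regenerable in isolation.

What the simulator does *not* emulate: discrete (0/1/2-coded) inputs,
missing data, non-Gaussian outputs, or mean structure.  Passing tests
demonstrate support/rank recovery under the stated Gaussian-conditional,
heavy-tailed-input conditions, not performance on arbitrary real data.

## Evaluation protocol

Support recovery is scored over the p(p-1)/2 undirected off-diagonal pairs
of `S_X` only.  Supports use the threshold 1e-6 on `max(|.|, |.|^T)`;
latent ranks count singular values above `1e-6 x sigma_max` (both
solver-tolerance-scaled and configurable).  An empty estimate has precision
1, so curves start at recall 0.  AUC integrates the monotonized upper
precision envelope over recall (zero beyond the largest achieved recall);
fixed-recall precision tables read the same envelope at recalls 0.1, ...,
1.0.  The VUS is the trapezoidal integral of AUC(gamma) over the gamma
grid, normalized by the gamma range.

Regularization paths warm-start along decreasing lambda within each gamma.
`lambda_max` is found by doubling plus log-bisection for the smallest
lambda with an empty `S_X` support.  For gamma sweeps each gamma gets its
own grid, rescaled as `lambda_max(gamma) ~ lambda_max(0.5) x 0.5 / gamma`:
the support empties when the l1 weight `lambda x gamma` crosses the
data-dependent threshold, so a grid anchored at a single gamma would leave
small-gamma paths entirely in the dense regime and bias every gamma-
sensitivity comparison.

Identifiability diagnostics are documented proxies, not the exact
incoherence quantities (whose full definitions involve the Fisher
information): `mu_bound` is the maximum row/column support cardinality of
the stacked `S*`; `xi_bound` is `2 max_i ||P_U e_i||` over the row and
column spaces of `L*` (2/sqrt(p) for one uniform confounder, 2 for a
diagonal `L*`).

## Stability selection

Complementary-pairs selection: B pairs of disjoint floor(n/2) subsamples
(default B = 50); an edge is counted once per subsample if selected
anywhere along the lambda path (max-over-path, the "pointwise" usage; a
per-lambda mode is available).  Inclusion probability = fraction of the 2B
subsamples selecting the edge.  The threshold is calibrated through the
bound `E(V) <= q^2 / ((2 tau - 1) p_cand)` with q the average per-subsample
selected-set size: tau is the smallest value meeting the requested budget
(default `E(V) <= 1`), and when no tau <= 1 can meet it the selection is
empty with a warning - on dense paths this is the bound doing its job.
`stability_lambda_grid` calibrates the lambda region to a target full-data
support size `sqrt(0.8 x budget x p_cand)` (the largest q for which
tau = 0.9 still meets the budget), since the q^2 dependence makes deep,
dense paths useless for selection.  The sharper r-concave bound is left as
a documented alternative; the implemented form is the one matching the
E(V) <= 1 usage.  Similarity between selected graphs across gamma is the
Jaccard index of edge sets (1 when both are empty); the "stable region" is
the largest contiguous gamma block with all pairwise similarities above a
threshold (default 0.9).

## Problem sizes in the shipped experiments

The test-suite experiments run at desk scale, chosen once as the package's
study conditions: solver/oracle agreement on 20 instances with p, m <= 4;
sign recovery at p = m = 16, two diffuse confounders, n = 20000, a 5 x 3
(lambda, gamma) grid, 5 seeds; the method comparison on the (d_Z = 2,
d_H = 2) design at p = 32, n = 1500 with 10 replicates, 9 gamma values over
(0.02, 0.98) and 6 lambdas per gamma; stability error control at p = 8,
n = 400, B = 25, 20 runs.  Benchmark fits use relaxed tolerances
(1e-4 residuals) because support patterns, not final digits, are scored.

## Known limitations

* The ADMM R-update for m > 0 is first-order; very high accuracy
  (residuals below ~1e-9) is better obtained from the SDP path.
* The interior-point oracle builds dense Hessians: O((p^2 + pm)^2) memory;
  it is an oracle, not a large-scale fitting path.
* `lambda_max` is found by bisection on fits (no closed form exists for the
  mixed penalty), so path construction costs a handful of extra fits.
* No missing-data handling, no non-Gaussian conditional likelihoods, no
  mean-parameter estimation, no randomized SVD for very large p.
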