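# Methods

## Model class and gauge freedoms

The package works with linear one-hot models `f(s; θ) = x(s)·θ` on
sequences of length `L` over an alphabet of `α` characters.  Features are
indexed by augmented sequences — patterns over the alphabet plus the
wildcard `*` — and a *model specification* is the set of active features.
The all-order model activates all `(α+1)^L`; additive and pairwise models
activate the subsets of order ≤ 1 and ≤ 2.  A specification is
*hierarchical* when its active set is downward closed: replacing any
character of an active pattern with `*` yields another active pattern.
Additive, pairwise and nearest-neighbor models are all hierarchical.

Because an order-`K` feature summed over all characters at one of its
positions reproduces an order-`K−1` feature, the design matrix `X` (rows =
sequences, columns = features) is column-rank-deficient and the model has
gauge freedoms `G = null(X)`.  Predictions determine `θ` only up to `G`;
fixing the gauge means choosing a subspace Θ with `ℝ^M = Θ ⊕ G` and
projecting onto Θ along `G`.

### Orderings

The bookkeeping is fixed once: per position the augmented
symbols are ordered wildcard-first (`*`, then the declared alphabet
order), and feature labels are enumerated in the mixed-radix order with
position 1 most significant.  This is exactly the index order of a
Kronecker product of per-position blocks, which is what makes the
parametric projector factorize (below).  Sequences are enumerated
lexicographically in declared alphabet order.  User-facing positions are
1-based.

## The parametric gauge family

A family member is a pair `(λ, p)`: `λ ∈ [0, ∞]` sets how strongly
higher-order features are penalized relative to lower-order ones, and `p`
is a factorized position-specific distribution `p(s) = Π_l p_{l,s_l}`
setting how strongly individual characters are penalized.  All formulas go
through `η = λ/(1+λ) ∈ [0,1]`; `λ = ∞` is represented symbolically and
never enters arithmetic, since the projector is finite at `η = 1`.

The projector onto the gauge space is the Kronecker product over positions
of the `(α+1)×(α+1)` block with wildcard row `(η, p_1η, …, p_αη)` and
character rows `(1−η, δ_{cc'} − p_{c'}η)`.  Each entry of the full
projector is therefore a polynomial of degree ≤ L in η, and so is every
gauge-fixed parameter — the basis of the η-sweep diagnostic, which checks
that trajectories on a grid are interpolated exactly by degree-L
polynomials.  Two independent implementations are kept deliberately: the
Kronecker/tensor-contraction route (used for computation; lazy contraction
above 10^4 features so the M×M matrix is never materialized) and a direct
elementwise evaluation of the product formula (used as a cross-check).

For `0 < λ < ∞` and strictly positive `p` the same gauge arises by
minimizing `θᵀΛθ` over the gauge orbit with the diagonal penalizer
`Λ_{s's'} = p(s')·λ^{o(s')}` (wildcard positions contribute factor 1 to
`p(s')`).  The penalizer route refuses the limit points (`λ ∈ {0, ∞}` or
zero probabilities), where the quadratic form is degenerate; limit gauges
always go through the projection formula.  Gauges with zero-probability
characters (generalized wild-type) are validated empirically as limits of
the smoothing family `p_ε = (1−ε)p + ε/α`, whose projections are checked
to converge to the direct `η = 1` projection as ε decreases.

Named members: trivial (`λ=0`; parameters become a catalog of activities
on full-order features), Euclidean (`λ=α`, uniform p; the orthogonal
projector onto the row space of X, equivalently what plain L2-regularized
regression converges to), equitable (`λ=1`; penalizes each parameter in
proportion to the fraction of sequences it touches), hierarchical
(`λ→∞`), zero-sum (hierarchical, uniform p), wild-type (hierarchical,
indicator p), generalized wild-type (hierarchical, p with zeros).

## Arbitrary linear gauges

Beyond the parametric family, a gauge space can be given by a basis or by
any positive-definite penalizer Λ, with projector
`P = Λ^{-1/2}(XΛ^{-1/2})⁺X`.  Numerical guards: `Λ^{-1/2}` is computed by
symmetric eigendecomposition and refused when the condition number exceeds
1e12; pseudoinverses use a 1e-10 relative singular-value cutoff; for the
basis route, transversality of Θ and G is required.  The smallest
principal angle between Θ and G must exceed 1e-8 radians; it is measured
through the smallest singular value of the stacked orthonormal bases
(σ_min ≈ angle/√2 for small angles), because arccos-based angle routines
bottom out at √eps ≈ 1.5e-8 and cannot certify this threshold.

## Hierarchical gauges without enumeration

The hierarchical gauge has an ANOVA reading: the constant is the p-mean of
the landscape, each additive coefficient the change in conditional mean
from fixing one position to one character, each pairwise coefficient the
excess from fixing two, and so on.  The implementation takes this reading
as the algorithm: each gauge-fixed coefficient is built by
inclusion–exclusion over conditional means,

    θ'_F = Σ_{F' ⊆ F} (−1)^{|F|−|F'|} E_p[f | F'],

where `F` is the feature's set of (position, character) fixings and the
conditional expectation fixes those positions while drawing the rest from
`p`.  Conditional means have a closed form under a factorized `p` (a
weighted sum over active features, no sequence enumeration), so the same
code handles additive, pairwise and other hierarchical models at
protein-alphabet scale; conditional means are memoized across features.
Fixing a position overrides `p` there, which keeps everything well-defined
when `p` assigns the fixed character probability zero — the generalized
wild-type case.  On all-order models the construction is verified against
the η = 1 Kronecker projector; on lower-order models against
orbit-preservation and the marginalization property (every p-weighted
character sum of a coefficient group vanishes).

Projecting within a hierarchical specification preserves its zero pattern
*structurally* — inactive features simply do not exist in the output.  The
equivalent route of embedding the model in the all-order space and
projecting there reproduces the same values with inactive features at zero
up to floating-point residue (~1e-15); tests check both.

Consequences used as tools:

* **Variance decomposition.** In the hierarchical gauge the landscape
  splits into p-orthogonal components, one per star/non-star pattern, so
  `var_p[f] = Σ_k var_p[f_k]` with `var_p[f_k] = Σ_{o(s')=k} p(s')θ_{s'}²`.
  The constant component carries no variance by convention.  Input not in
  the hierarchical gauge is refused (marginalization residual above
  1e-10 × parameter scale) unless auto-projection is requested, in which
  case a notice is logged — silent reinterpretation is avoided.  With
  zeros in `p` the variance refers to the supported region only.
* **Truncation.** Dropping all terms above order `k` from a
  hierarchical-gauge model yields the p-weighted least-squares
  approximation among order-`k` models (orthogonal projection in the
  p-inner product).  With `p` uniform on a region and zero outside, this
  produces local additive approximations tailored to that region, and the
  region's own gauge provably dominates truncations derived from other
  regions' gauges in that region's mean squared error.
* **Maximum gauge** (additive models only).  Per position the largest
  additive value is moved into the constant, leaving all additive
  parameters ≤ 0 with at least one zero per position; the constant becomes
  the activity of the best sequence.  The constraint set is nonlinear, so
  non-additive specifications are refused.

## Numerical choices

* Null spaces: SVD of the dense design matrix with a 1e-10 relative
  singular-value cutoff when sequence space is small (≤ 8192 sequences);
  otherwise the closed-form feature Gram matrix (`X^T X` entries are
  `α^(L−u)` for compatible pattern pairs with `u` the union of their fixed
  positions) with the equivalent relative eigenvalue cutoff.  The nonzero
  spectrum of these binary designs sits many orders above the numerical
  noise floor, so the cutoffs are not delicate.
* Dense enumeration caps: 10^6 sequences / 10^5 features; operations with
  closed forms (hierarchical projection, conditional means, variance) never
  enumerate.
* Ridge regression uses the augmented least-squares form
  `[X; √ridge·I]`, which stays well-conditioned for arbitrarily small
  ridge weights; the unpenalized fitter returns the minimum-norm solution,
  which lies in the Euclidean gauge.
* Degenerate inputs fail loudly with the offending position or condition
  named: characters outside the alphabet, non-hierarchical zero patterns,
  penalizers at limit points, empty region character sets.

## The synthetic-landscape generator

The generator stands in for empirical datasets in all tests and in the
acceptance script.

* `random_all_order` draws i.i.d. standard-normal activities for every
  sequence (default scale 1) and returns them as a trivial-gauge parameter
  vector — a maximally epistatic random landscape, the design used for the
  η-sweep study on binary length-3 sequences.
* `region_structured_pairwise` builds a pairwise model over a 4-letter
  alphabet at length 4 by default: a random additive/pairwise background
  (scales 0.5/0.5), plus, for each of three disjoint regions (defined by
  allowed characters at positions 3 and 4), a +6 bonus planted on the
  conjunction of the region's defining characters — on additive features
  for one-position regions, split across the pairwise features of the
  defining combination otherwise — so that exactly the region's members
  are lifted; plus region-specific random pairwise couplings (scale 1)
  between defining characters and free positions so each region has its
  own local additive structure.  Planting the bonus on conjunctions rather
  than on individual characters is what keeps the high-activity regions
  disjoint: a bonus on "A-or-C at position 3" alone would leak into half
  of sequence space.
* `additive` draws a random additive landscape.

Optional noise is additive i.i.d. Gaussian.  One seed in the configuration
drives every draw.  What the generator does **not** emulate: enrichment
noise of count-based assays, missing genotypes, measurement
nonlinearities, or the biochemical structure of any particular protein.
Passing tests therefore demonstrate the correctness of the gauge-fixing
machinery and the qualitative region logic, not predictive performance on
real assay data.

## Problem sizes

Routine tests run on binary/3- and 4-letter alphabets with L ∈ {2, 3, 4}
(design matrices up to 256 × 625).  Hierarchical-gauge identities are also
exercised on a pairwise model over the 20-letter amino-acid alphabet at
L = 4 (2481 parameters) through the closed-form route.  The region
truncation study uses 100 seeded replicates of the 4-letter length-4
generator with exact p-weighted evaluation over all 256 sequences.

## Known limitations

* Only factorized distributions `p` are supported; the parametric family
  is not defined for correlated position distributions.
* The maximum gauge is implemented for additive models only.
* The projector for the parametric family is defined on the all-order
  feature space; lower-order models are handled exclusively through the
  hierarchical (η = 1) route, which is the only family member that
  preserves their form.
* Variable-length sequences, alignments and raw-read ingestion are out of
  scope; sequences arrive as fixed-length strings in TSV tables.
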