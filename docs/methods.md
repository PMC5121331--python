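# Methods

## The correlated family-DD model

A founder cell (generation 0) founds a binary-division family tree.  The
model is generation-synchronous: of the `c_k` cells alive in generation
`k`, a beta-binomially distributed number progresses past `k` with
per-generation progression probability `p_k` and within-family pairwise
correlation ρ ∈ [0, 1].  The beta-binomial is parameterized through its
Beta(α, β) mixing density with

    α = p (1 − ρ) / ρ,    β = (1 − p)(1 − ρ) / ρ,

so the intraclass correlation of any two same-generation cell fates is
exactly ρ; ρ = 0 and ρ = 1 are handled as the analytic binomial and
all-or-none limits.  A family tree's DD information is the count vector
`t = (t_0, …, t_D)` of cells stopping per generation; the likelihood is a
product of per-generation beta-binomial terms and depends only on these
counts, never on the tree's shape (shape multiplicity cancels from the
branching law), which is why trees are represented by count vectors
throughout.

The progression profile is identified from pooled data alone: whatever ρ,
the expected pooled cohort-corrected DD mass per generation is fixed by
`p`, so `p_k` is estimated as the cohort-corrected conditional
progression frequency `Σ_{j>k} n_j 2^−j / Σ_{j≥k} n_j 2^−j` and only ρ is
fitted by likelihood.  Binomial cell recovery with probability `r` leaves
these pooled proportions unbiased, so the same estimator applies to
thinned data.

## Range distribution and the ρ likelihood

Observed clones are per-cell binomial thinnings (probability `r`) of full
trees.  The probability of observing clonal range `f` is defined as a sum
over all full trees `T` and sub-trees `S ≤ T` of
`L(T) · L(S | T, r) · χ(Range(S) = f)`.  Rather than enumerating the
`Π (t_i + 1)` sub-trees of each tree, the implementation marginalizes the
sum in closed form: sampling is independent per cell, so conditional on
`T` the events "generation `i` contributes at least one sampled cell"
are independent with probability `1 − (1 − r)^{t_i}`, and the joint law
of the minimum and maximum occupied generation factorizes into prefix
products.  The result is identical to the double sum and costs `O(D²)`
per tree.  Mass is conditioned on a non-empty sampled clone, since clones
with no recovered progeny never enter a dataset.

Full trees are enumerated by brute force per depth `D` and cached;
enumeration is refused above `D = 8` (the space grows combinatorially:
36 trees at `D = 4`, 202 at `D = 5`, 27,338 at `D = 7`).

`fit_rho` maximizes the sum over clones of the log marginal likelihood
`log Σ_T L(T | p, ρ) L(S | T, r) − log P(non-empty)`.  The per-clone
sampling likelihoods form a clones × trees matrix independent of ρ, so a
ρ-scan costs one matrix–vector product per grid point; a grid of step
0.01 is followed by bounded refinement, and estimates within 10⁻⁴ of a
boundary are reported as exactly 0 or 1.  A coarser variant fitting only
each clone's range value (`statistic="range"`) is exposed for
comparison; the count-vector likelihood is the default because it is
strictly more informative.  Model confidence envelopes for the range
distribution are finite-sample binomial quantile intervals at the number
of recovered families.

## Tree addition and linearity

A family tree corresponds to a rooted binary tree whose leaves are the
quiescent cells, with leaf generation equal to depth.  The DD vector is
the coefficient vector of the leaf generating function `X(s) = Σ x_i s^i`.
Concatenating a second tree into a first — inserting a copy of the second
at each vertex of a final-cell partition and re-appending the remainder
of the first at the copies' leaves — multiplies generating functions.
The DD vector of any concatenation is therefore the convolution `x * y`,
regardless of the interlacing plan; more general interlacings are
compositions of such steps and inherit the property.  `maxdd` and the
cohort-normalized `mdd` are additive under convolution; using cohort
weights `2^−i` makes full-tree DD vectors behave as probability
distributions under convolution, so `mdd` additivity is exact.  DD-vector
arithmetic is integer; cohort mass is checked in exact rational
arithmetic.

## The convolution equality test

Additivity of maxDD/mDD converts the hypothesis of independent signal
integration into equality of convolved distributions:
`law(X) * law(Y) = law(A) * law(B)` for the condition quadruple
(base, base+S1+S2, base+S1, base+S2).  The statistic is the quadratic
form `S = V' Σ⁺ V` in
`V = √n_X [(X/n_X)*(Y/n_Y) − (A/n_A)*(B/n_B)]`, with Σ assembled by the
delta method: each sample contributes `(n_X/n_sample) · T Σ_p T'`, where
`Σ_p = diag(p̂) − p̂ p̂'` is its multinomial covariance and `T` the
convolution Jacobian `(T)_{ij} = other_{i−j}`, all at per-sample plug-in
estimates.  `S` is referred to a χ² law with dof equal to the number of
retained eigendirections of Σ, and the covariance assembly is audited by
simulation (the empirical covariance of simulated `V` matches Σ
entrywise).

Two regularizations are applied before inversion:

* **Sparse-category projection.**  Adjacent convolved categories are
  merged left-to-right until each merged bin's expected count (the
  pointwise minimum of the two estimated convolutions, scaled by the
  smallest sample size) reaches `min_expected = 5`; the same 0/1
  projection is applied to `V` and Σ.
* **Noise-floor spectral cutoff.**  Eigendirections with eigenvalue below
  `max(10⁻¹⁰ λ_max, 4 · tr(Σ)/n_min)` are treated as null.  The
  convolution difference always possesses near-degenerate variance
  directions, and there both the neglected second-order delta terms and
  the sampling noise of Σ̂ itself are of order `tr(Σ)/n`; such directions
  cannot be studentized reliably at realistic sample sizes, and keeping
  them distorts the null law of `S` in either direction (over-rejection
  with the exact Σ, severe under-rejection with the estimated one).
  Discarding small eigenvalues is the standard remedy for reduced-rank
  Wald statistics; the factor 4 was fixed once by a null-calibration
  simulation across equal-law and convolution-equal scenarios of varying
  conditioning and is not data-dependent.  Degenerate inputs (no retained
  direction) return p = 1 with a warning.

mDD values are binned into the fixed eleven-category scheme
{2}, (2,3), {3}, …, {6}, (6,7), [7,+∞) — integers to singleton bins,
non-integers to open intervals — before testing; values below 2, which
can occur in synthetic data, go to a flagged underflow bin.  Because
integer increments shift bin indices exactly, the bin-level null holds
exactly for additive constructions as long as single-condition mDD stays
below 7; the lumped tail bin otherwise breaks index additivity, a
limitation inherited from the fixed binning.  For maxDD, integer supports
are aligned to one common categorization and no merging is normally
needed.

The MLE of the CDF of a sum of independent variables is the convolution
of the empirical CDFs, computed exactly as the weighted eCDF of all
pairwise sums.  Confidence bands are pointwise percentile-bootstrap
intervals (default K = 1,000 resamples, seeded): each condition is
resampled, the bootstrap eCDFs convolved, and the 2.5/97.5 percentiles
taken at each point of the full-data convolution support.

## Synthetic assay generator

The generator emulates the statistical structure of a multiplex
division-tracking clone assay, not its optics: per condition, founders
grow beta-binomial family trees; wells are harvested at fixed times;
every cell is recovered independently with probability `r`; and the
quiescence call is flipped with a symmetric misclassification
probability.  Defaults (chosen once): four conditions N4, N4+aCD28,
N4+IL-2, N4+aCD28+IL-2 with founder inputs 96/224/96/224; DD mass placed
in generations 2–6 with condition means ≈ 3.3, 4.3, 3.9 and 5.1
divisions; within-family correlation ρ = 0.9; recovery r = 0.9;
misclassification 4%; harvests at 54, 62 and 72 h.

Harvest times map to division frontiers through a nominal cadence (first
division completed at 30 h, 8 h per subsequent division, giving frontiers
4/5/6): at frontier G, cells with DD ≤ G appear quiescent in their DD
generation and still-progressing lineages appear as dividing cells in
generation G.  This is a deliberate simplification — real division times
are per-cell random variables — adopted because only the DD structure
matters downstream.  Consequences: simulated "mixed" clones always have
their dividing cells at the frontier generation, and the generator
reproduces the qualitative harvest-time progression (mostly dividing at
54 h, mostly quiescent at 72 h) but not realistic division-time
dispersion.  Other unmodelled features of real data: cell death, dye
transfer/gating errors beyond the flat misclassification rate, and
founder heterogeneity in `r`.  Passing tests therefore certify the
statistical machinery under the model's own assumptions, not the
biology of any particular dataset.

Additive-condition constructions convolve each family's DD vector with
independent draws from an increment sampler — the generative model under
independent signal integration; a dependent alternative reuses one
increment draw across the two combined signals.

## In-vivo extrapolation

Given a probability function `f_i` for family DD over divisions `i`
(default: a synthetic discretized normal over divisions 4–19, standing in
for a fitted in-vivo distribution) and a mean initial cell number
`mN₀ = 1,808`, expansion is reintroduced as `N_i = f_i · mN₀ · 2^i` and
the cumulative percentage contribution to response magnitude is plotted
against the cumulative percentage of clones, cumulating from the largest
DD downward so the curve reads "the top x% of clones contribute y%".
Percentages are invariant to `mN₀`.  Conversely, clone sizes `N` map to
DD estimates `⌈log₂ N⌉` (concordant families, minimal death) binned every
second division starting at the smallest observed DD.

## Numerical choices and limitations

* Probabilities and likelihoods in double precision; tree and DD-vector
  counts in integer arithmetic; cohort-mass checks in exact rationals.
* Likelihood normalization holds to 1e-9 over enumerations up to depth 5;
  mDD additivity to 1e-12.
* The ρ grid step (0.01) bounds the scan cost; refinement tolerance 1e-5.
* Degenerate inputs: empty clones are rejected everywhere; all-zero count
  vectors raise; range-distribution mass is renormalized over non-empty
  subtrees.
* The test suite and acceptance checks use scaled-down problem sizes
  (10⁵ Monte-Carlo trees, 200-family fits, 2,000-replicate calibrations)
  chosen to make the checks statistically decisive at desk scale.
* The model has no cell death and no per-cell division-time variation;
  ρ is a single per-condition scalar, and `r` a per-condition scalar
  rather than per-well.
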