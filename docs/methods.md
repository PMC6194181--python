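# Methods

## Honest model

The honest joint distribution of the two ordinal variables is the
discretized standardized bivariate normal (underlying variable
approach).  Thresholds are obtained by inverting the standard normal
CDF at the cumulative marginal masses, so the discretization reproduces
any requested marginal distribution exactly.  Cell probabilities are
computed by inclusion–exclusion on four bivariate-normal CDF
evaluations (scipy's `multivariate_normal.cdf`); the grid is clipped at
zero and renormalized to absorb CDF rounding at the 1e-9 level, so every
`JointPMF` carries unit mass exactly.

Default marginals, symmetric around zero by construction: v = 5 uses
masses (0.06, 0.25, 0.38, 0.25, 0.06); v = 2 splits evenly (threshold
at 0); v = 7 discretizes at the equispaced thresholds ±0.5, ±1.5, ±2.5
(masses ≈ 0.006, 0.061, 0.242, 0.383, mirrored).  Other supports fall
back to equal-mass categories.  All of these are configurable per
variable; the two variables share one threshold set unless two are
given.

## Replacement kernels

Faking good from true value i admits fake values h ∈ {i+1, …, v}.  The
kernel column is a discretized generalized beta density
∝ (x − i)^(γ−1) (v − x)^(δ−1) on [i, v].  Two discretizations are
implemented:

* `midpoint` (default): mass of category h proportional to the density
  at the bin midpoint h − ½, normalized over the admissible categories.
* `bin`: exact integral of the density over the unit bin [h−1, h]
  (regularized incomplete-beta differences); self-normalizing.

The two variants produce similar kernels for mid-scale origins but
differ materially near the support boundary, where the density is
steep.  The default was fixed by calibration: with `midpoint`, the
exact population pipeline reproduces all of the published reference
effect sizes for the v = 5 grid (slight/average/extreme, same and
opposite directions, several faker shares and original correlations)
within |Δ| ≤ 0.024, while `bin` misses the high-correlation
high-prevalence case by ≈ 0.19.  `midpoint` also yields the documented
qualitative kernel shape (slight faking from the bottom of a 7-point
scale peaks at the adjacent category and decays monotonically; under
`bin` the peak sits one category higher).  The variant remains a
parameter (`variant=`) on every kernel-consuming entry point.

A respondent already at the boundary category keeps it
(z_{v|v} = 1 for faking good, z_{1|1} = 1 for faking bad): no
admissible strict shift exists, and the kernel must stay column-
stochastic.  Faking bad is the exact mirror
z_{h|i}(bad) = z_{v+1−h|v+1−i}(good); at v = 2 every kernel is forced
(1 → 2 with probability 1), which makes the dichotomous design cells
independent of (γ, δ).

## Mixture algebra

The fully-faked distribution is Z = K₁ P K₂ᵀ (conditional independence
of the two variables' faking given the honest pair), the observed
population S = (1 − α) P + α Z, and with c faker classes
S = (1 − Σαₗ) P + Σ αₗ Z⁽ˡ⁾, Σαₗ ≤ 1.  Kernels are stored with the
origin category indexing columns and the fake category indexing rows;
the test suite checks the matrix form and the Kronecker-vectorized form
against the brute-force double sum to 1e-14, which pins the orientation.

## Correlations

Population Pearson is the product-moment correlation of the
integer-coded support under the pmf.  Population Spearman uses the
ties-corrected discrete form

ρ_S = 3 Σᵢⱼ pᵢⱼ [(Fᵢ + Fᵢ₋₁)(Gⱼ + Gⱼ₋₁) − 1] /
√((1 − Σ pᵢ.³)(1 − Σ p.ⱼ³)),

whose sample plug-in coincides with the mid-rank sample Spearman; the
suite enforces the reduction to 1e-12 on random tied samples.  Sample
estimators use mid-ranks (the convention under which the reduction
holds).  A constant column raises a typed degenerate-sample signal —
distinct from an invalid input — which the Monte Carlo engine catches,
counts and excludes.

## Effect size

Cohen's Q = arctanh(ρₘ) − arctanh(ρ_d).  ρ_d is always the
index-specific correlation of the *discrete* honest pmf, not the latent
normal correlation, so Q(α = 0) = 0 identically; the latent value is
reported alongside for transparency.  |r| = 1 (possible at small n,
especially v = 2) maps to ±∞, which is propagated rather than raised:
the design-cell summaries are medians, robust to infinities, and the
count of infinite replicates is recorded per cell.

The population analysis states original correlations on the discrete
scale.  `latent_from_discrete` inverts the attenuation map (strictly
increasing in the latent correlation) by Brent root-finding, so "an
original Spearman correlation of −0.60" is realized exactly by the
honest pmf; discretizing a latent −0.60 instead gives a discrete
Spearman of ≈ −0.54.  The Monte Carlo design, by contrast, draws
latent normal pairs at the stated correlation levels directly, matching
the generative procedure it emulates.

## Monte Carlo engine

Per replicate: draw n honest pairs, select fakers by i.i.d. Bernoulli(α)
per row, replace both entries of each faker's row by inverse-CDF draws
from the kernel columns of the original values, then compute r_d on the
honest matrix and r_m on the perturbed matrix for both indices and
q = arctanh(r_m) − arctanh(r_d).  Cells are summarized by the median q
(and its variance over finite replicates).  Table-style summaries take
the median within each sample-size level and then the arithmetic mean
across the four levels; the pooled-median alternative is available via
`across="median"` (the two differ by < 0.01 in the checked cells).

Seeding: each cell's stream is `SeedSequence(master, spawn_key=k)` with
k derived from the factor levels through CRC32 (stable across
processes), so any subset of cells — or a restricted factor grid —
reproduces the full run's values exactly.

The full factorial crossing (3,360 cells × 2,000 replications) is
supported but the shipped checks run scaled-down problem sizes chosen
for precision per unit cost: the reference table cells use 200–300
replications per (sample size, cell), which puts the Monte Carlo
standard error of the summarized median q near 0.005 — an order of
magnitude below the comparison tolerances.  The significance cross-tab
uses the standard t approximation t = r√((n−2)/(1−r²)) on n−2 degrees
of freedom, two-sided.

## Synthetic data and external validity

All data in the tests and the acceptance run are generated by the
package itself: threshold-discretized bivariate normal honest samples,
perturbed by the parametric kernels.  This matches the framework's own
generative assumptions — symmetric thresholds shared by both variables,
normal latent copula, faking that only depends on the true value of the
same variable, and a single faker class.  Passing tests therefore
demonstrate internal correctness of the distribution algebra and the
simulation pipeline, not that real questionnaire data satisfy those
assumptions: skewed marginals, variable-specific thresholds,
covariate-dependent faking propensity, or item-specific faking styles
are outside what the generator emulates (the multi-class mixture
relaxes only the single-class assumption).  The applied
`sensitivity_report` deliberately makes no distributional assumption on
the honest model — it plugs the empirical contingency table in as P —
so its projections inherit sampling noise of order n^(−1/2) in each
cell.

## Numerical choices and limitations

* Bivariate normal CDF tolerance is scipy's default (~1e-8 per call);
  grid renormalization removes the accumulated error's effect on total
  mass.  |ρ_latent| must be < 1.
* `latent_from_discrete` brackets on (−1+1e-6, 1−1e-6) and fails
  loudly for targets outside the attainable (attenuated) range.
* Degenerate replicates are excluded from medians and counted; a cell
  whose replicates are all degenerate (e.g. v = 2, α = 1, faking good)
  is flagged rather than summarized.
* Population curves are smooth in α but not monotone (hump-shaped for
  polytomous supports under extreme faking); tests assert ordering
  relations, not monotonicity.
* The CLI's plots are advisory; every checked number flows through
  CSV/JSON.
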