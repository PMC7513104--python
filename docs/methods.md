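# Methods

## Model and criteria

The observation model is `y_i ~ N(θ, σ²)`, i.i.d., with scalar mean
parameter `θ` on a parameter space `Θ` (an interval, default the real
line). The residual scale σ is not estimated jointly: by default it is
plugged in as the sample SD (`sigma_mode = "plugin_sample_sd"`), which
keeps every posterior, divergence and evidence integral one-dimensional
and yields the normal-form posteriors this methodology reports. A
`fixed(σ)` mode exists mainly so conjugate closed forms can serve as
test oracles. Joint unknown-variance posteriors are out of scope.

Given experts' priors `π_d` and a benchmark `π_J`, the package computes

- `KL_d = KL[π_J(·|y) ‖ π_d]` and `DAC_d = KL_d / KL[π_J(·|y) ‖ π_J]`,
  disagreement iff `DAC_d > 1` (strict: a score of exactly 1 is
  classified as agreement);
- `log m_d(y)` and `BF_Jd = m_J(y)/m_d(y)`, disagreement iff `> 1`;
- `DAC2_dJ = BF_Jd · exp{KL[π_J(·|y) ‖ π_d(·|y)]}`.

Experts are ranked ascending on DAC (equivalently on `KL_d`; the
denominator is shared) and descending on evidence. Ties are broken by
input order with a logged warning. In benchmark-free mode (benchmark
explicitly `null`) only raw `KL_d` values, their ranking and the
pairwise tables are produced — without a yardstick there is no
(dis)agreement verdict, and arbitrary benchmarks shift that verdict
anyway (see the sweep below).

## Densities

Four families: normal, uniform, two-piece skew normal, and gridded
numeric (used for fitted posteriors). The two-piece skew normal follows
the scale-both-halves construction: with `ε = (x−μ₀)/σ₀`,
`pdf = (1/σ₀)·2/(γ₀+1/γ₀)·φ(ε/γ₀ if ε ≥ 0 else γ₀ε)`. The normalizing
constant is exact, the density is continuous at the mode, `γ₀ > 1`
skews right. Two conventions are deliberate and documented because
elicitation reports are ambiguous about them:

- **σ₀ is a standard deviation**, not a variance. Elicited panels in
  this literature print scale columns that the text sometimes calls
  variances; scales of 0.07–0.11 around a location of ~2.2 are only
  plausible as SDs, and the choice is isolated in one conversion point.
- **μ₀ is the mode of the symmetric base density** (the transform's
  centre), not the mean of the skewed result; the closed-form mean
  `μ₀ + σ₀·√(2/π)(γ₀−1/γ₀)` is available via `moments_of`.

Sampling uses the two-piece construction directly (right half with
probability `γ₀²/(1+γ₀²)`), grid densities by inverse-CDF interpolation.

## KL divergence

Normal–normal pairs use the closed form
`ln(σ_q/σ_p) + (σ_p² + (μ_p−μ_q)²)/(2σ_q²) − ½`. Everything else is
integrated over the support of the reference density p: adaptive
quadrature (`scipy.integrate.quad`, breakpoints at two-piece modes and
uniform edges) for analytic p, an exact trapezoid sum on the grid when
p is a fitted posterior. Unbounded supports are truncated at the
reference mean ± 12 reference SDs (tail mass < 1e-30, invisible at the
1e-6 tolerances the tests enforce). Natural log throughout.

Infinity is a verdict, not an error: when q is zero on a set carrying
more than 1e-12 of p's mass, the result is a `math.inf` sentinel — an
infinitely overconfident expert is simply the worst possible expert.
Conversely, grid nodes whose escaping p-mass is below that tolerance
(posterior tails of ~1e-300 falling off another grid's extent) are
treated as zero contribution rather than spurious infinities. A Dirac
(point-mass) prior is intentionally not a constructible family; the
limiting behavior — KL growing without bound as an expert's scale
shrinks, while the Bayes factor stays bounded — is covered by an
explicit test instead.

## Posterior and evidence quadrature

Posteriors under normal priors (unbounded Θ) are conjugate closed
forms. Otherwise the log-posterior `log f(y|θ) + log π(θ)` is evaluated
on an adaptive grid and renormalized by trapezoid integration. The grid
is built in two passes: a 2049-point coarse scan of the hull (the
likelihood region `ȳ ± 10·σ/√n` united with the prior's high-density
region, intersected with Θ and the prior support), then 8193 dense
nodes over the central `1 − 2×10⁻⁹` posterior-mass interval found on
the coarse pass, always including the likelihood region. A single
uniform grid over the hull was measured to leave ~4×10⁻⁵ pointwise pdf
error when the prior is very diffuse (e.g. `U(−50,50)` against a
posterior SD of 0.03); the focused grid brings the conjugate-oracle
agreement below 10⁻⁶. The posterior is a product of log-concave
factors, hence log-concave and unimodal, so the mass region is a single
interval and the refinement cannot miss modes.

Evidence is computed entirely in log space. Through the sufficient
statistics the θ-integral reduces to averaging a `N(ȳ, σ²/n)` kernel
over the prior: closed forms for normal and uniform priors, otherwise
log-sum-exp with trapezoid weights over the same grid. Magnitudes like
1e-68 (realistic at n ≈ 100) and e⁻¹⁶⁰ are handled without underflow
because no linear-scale evidence value is ever formed; Bayes factors
are `exp(Δ log m)`. Deterministic quadrature replaces the bridge
sampling used in MCMC workflows — for this one-dimensional model that
is an exact equivalence, not an approximation.

## Sensitivity analyses

`benchmark_sweep` reruns the full pipeline per candidate benchmark
(each induces its own reference posterior) and tabulates expert KLs,
the benchmark KL and `log m_J` per column; a degenerate column (prior
excluding all likelihood mass) is flagged and the others proceed. For
uninformative benchmarks the reference posterior is stable, so expert
KLs and the ranking barely move and only the disagreement threshold
(`kl_J`) shifts; this stability is asserted for the uniform(−50,50) vs
normal(0, sd 100) pair only — informative benchmarks may legitimately
reorder experts.

`dac_grid_simulation` maps DAC over a lattice of normal expert priors
`N(μ₀, σ₀²)` against one seeded dataset (default: n = 100 standard
normal draws; `μ₀ ∈ ȳ ± 4` step 0.1, `σ₀ ∈ [0.1, 3]` step 0.1 — the
step is an assumption, axes are configurable). Because each cell's
prior is normal, `KL(posterior ‖ cell)` reduces to the posterior's
entropy and first two moments, so the surface is one posterior fit plus
a closed-form array computation; `dac_at` probes off-grid cells the
same way. Expected patterns: uninformative benchmarks give an agreement
valley centred on ȳ; an accurate informative benchmark (`N(0,1)`)
flags nearly every cell; an inaccurate informative one (`N(5, 0.5)`,
scale read as an SD, consistent with the package convention) flags only
wrong-location, small-σ₀ cells.

## Synthetic data and fixtures

`generate_dataset` draws seeded i.i.d. normals (the study's outcome —
average turnover per professional, n = 104 — is approximately normal
and positive; the generator does not truncate at zero, which matters
only for scales far larger than the study's). `synthetic_expert_panel`
assigns the first three members fixed archetypes — near-truth
(offset 0, scale 0.3), biased (offset 1.2, scale 0.45), overconfident
(offset 0.6, scale 0.05) — so their KL ordering against a
data-dominated posterior is known in closed form; further members get
seeded offsets. A green ranking test therefore establishes that the
pipeline recovers an *analytically known* ordering, not that it would
rank real experts correctly; real elicited priors carry correlations
and shape irregularities the generator does not emulate.

The packaged CSV fixtures store a published study's printed tables for
regression arithmetic. Printed inputs limit what recomputation can hit:
cells fully determined at two decimals are asserted exactly; cells the
authors evidently computed from unrounded values (KL ratios against the
0.19 divergence, e.g. printed 7.63 vs 1.43/0.19 = 7.53, and 30.75 vs
5.76/0.19 = 30.32) are asserted to lie within the interval implied by
half-ulp rounding of both inputs and the printed cell. The absolute KL
and evidence values of those tables require the original (restricted)
data and are replaced by the closed-form/property checks above.

## Known limitations

- One scalar mean parameter, normal likelihood, plug-in σ; no
  multivariate or unknown-variance extension.
- Improper benchmark priors are rejected by construction (only proper
  families exist); reference priors must be approximated by wide proper
  ones.
- KL is tail-sensitive: slightly fatter-tailed priors can halve their
  divergence without a comparable evidence gain — visible when two
  experts share a location but not a scale. That behavior is inherent
  to the criterion, not a numerical artifact.
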