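# Methods

## Model and assumptions

The observation at time `t` is a `J`-vector `y(t) ~ N(μ(t), Σ(t))`,
independent across time, with `(μ(t), Σ(t))` piecewise constant: there
exist change points `t₁ < … < t_K` such that the parameters are fixed on
each segment `{t_k + 1, …, t_{k+1}}`. Independence across time is a real
assumption — fMRI noise is autocorrelated, and the simulator below does not
model that (see *Limitations*).

Connectivity is read off the **covariance** matrix: a zero `Σij` means
marginal independence, and the per-segment graph places an edge wherever
the sparse estimate of `Σij` is non-zero. This differs from
precision-matrix (conditional-independence) graphs; in regimes where the
precision matrix is sparse but the covariance is dense, a covariance graph
is the wrong summary and this package will not help.

## Sparse estimation

Within a segment, the moments are the ML estimates with divisor `T` (not
`T−1`); likelihood differences across candidate splits only cancel
correctly when the same convention is used everywhere. For each element,
the cross-product series `Xₜ = (yᵢ(t) − μ̂ᵢ)(yⱼ(t) − μ̂ⱼ)` (centred at the
segment's own sample mean) gives the CLT variance estimate
`δ̂²ij = (1/T) Σ (Xₜ − X̄)²`; a delete-1 jackknife over time points is
available as an alternative (`variance_method="jackknife"`), and agrees
with `δ̂²/T` asymptotically.

The element-wise test keeps `Σ̂ij` iff `√T |Σ̂ij| / δ̂ij > z₁₋η*/2`.
Multiplicity modes for `η*`:

- `"none"` — raw `η`; per-element level `η`, so on white noise roughly `η`
  of the off-diagonal elements survive by chance.
- `"eta-over-J"` (default) — `η* = η/J`: lighter than Bonferroni over all
  `J(J−1)/2` pairs but still shrinks the family-wise error as `J` grows.
- `"bonferroni"` — `η*` = `η` / number of tested pairs.

Diagonal variances are never tested (a zero variance is meaningless for a
Gaussian channel) and always kept; means are thresholded with the diagonal
of `Σ̂` as the variance plug-in. Degenerate elements with `δ̂² = 0` are
kept iff the estimate itself is non-zero (infinitely significant on
noiseless fixtures) and logged.

## Likelihood and masking

The proportional log-likelihood
`L = −Σₜ (y(t) − μ)ᵀ Σ⁻¹ (y(t) − μ) − T log det Σ` drops the ½ factor and
the `−(TJ/2) log 2π` constant; only differences are ever interpreted.
Two algebraically identical forms are implemented (direct quadratic sum,
and the trace identity `−T(tr(Σ̂⁻¹S) + log det Σ̂)` with `S` the scatter
about the masked mean) and tested against each other to 1e−8 relative.

Masked fits are the unconstrained MLE Hadamard-multiplied by the binary
mask — not a constrained refit. This exactness is deliberate (it is the
printed update rule and costs O(J²)), but the product can be indefinite.
When a likelihood must be evaluated on an indefinite masked covariance,
its spectrum is clipped from below at `1e−6 ×` the largest eigenvalue
(eigenvectors preserved, perturbation bounded, scale invariant); the
repair exists only inside likelihood evaluation — reported parameters keep
their exact zeros. A matrix with no positive eigenvalue is an error naming
the segment.

## Segmentation

- Minimum segment length: `Δ = ⌈2(z₁₋α/2 + z₁₋β)²/d²⌉`, floored at 2. The
  default effect size `d = 0.65` yields `Δ = 50` at `(α, β) = (0.05, 0.1)`,
  the conventional spacing for fMRI-length series; `d` and an explicit
  `Δ` override are both exposed.
- The candidate scan evaluates every `t ∈ [Δ, T−Δ]` from running first and
  second moments (O(TJ²) memory, vectorised `slogdet`/`solve` over the
  stack of candidate splits), so a `T=1000, J=20` series scans in well
  under a second. Ties in the argmax break to the smallest `t` for
  determinism; the whole detector is deterministic given its input.
- The node baseline `L₀` is computed under the node's own thresholded mask
  intersected with the inherited parent mask; children inherit that same
  mask. A candidate with gain ≤ 0 terminates the branch, as does a failed
  significance test (the second-best candidate is not retried).
- Split significance: one Welch t-test per masked-in parameter
  (mean elements, variances, covariances), two-sided, Satterthwaite
  degrees of freedom, Bonferroni threshold `α / Σ mask`.

### Variance plug-ins for the split tests

The Welch denominators need estimates of `Var(μ̂ⱼ)` and `Var(Σ̂ij)` on the
two sides of the candidate. Two choices are implemented
(`split_variance`):

- `"node"` (default): `Σ̂jj` and `δ̂²ij` estimated once on the whole
  segment being split, divided by the child lengths.
- `"segment"`: each child supplies its own plug-ins (the textbook Welch
  construction).

The default is `"node"`. With child-level plug-ins, a candidate at the
minimum segment length has a denominator estimated from only `Δ = 50`
points of a strongly skewed series (for variance parameters, `Xₜ` is
χ²-like), and that estimate is correlated with the tested difference; the
far tail of the resulting statistic is several times heavier than the
`t` reference, so the family-wise level of the split test is badly
exceeded exactly where the argmax likes to land. Node-level plug-ins
restore the nominal level at edge candidates (verified by simulation in
the test suite, including a cross-check of the child-level inflation
against `scipy.stats.ttest_ind` on the same series). Under the null both
choices estimate the same quantity, so power at genuine splits is not
materially affected.

### What the tests do and do not control

Bonferroni at `α/Σmask` controls the family-wise error **per candidate
split**. The candidate, however, is the argmax of the likelihood gain over
all ~`T − 2Δ` admissible splits, and the tests are applied at that selected
point; the subject-wise probability of reporting at least one change point
on homogeneous data is therefore larger than `α` (around 0.2 in our null
simulations, consistent with the false-positive counts this family of
detectors reports on white-noise benchmarks). The acceptance suite states
the nominal `α`-level band for this quantity and the corresponding test is
expected to fail; it is kept as an honest record of the method's
subject-wise behaviour rather than weakened.

## Simulator

`generate_piecewise_gaussian` draws independent Gaussian vectors per time
point with per-segment `(μ, Σ)`; precision-matrix input is inverted once
per segment and validated for positive definiteness. Optional spike
artifacts add a constant (default magnitude 15 at 5 random time points per
subject, positions recorded) to all channels simultaneously — a crude model
of whole-brain fMRI signal jumps — with a flag to spike single channels
instead.

The built-in scenarios reproduce a standard benchmark battery's sizes and
change-point layouts (e.g. 20 subjects × T=1000 × J=20 white noise; a
single change at t=100 with J=5, T=200; five changes in T=1000; and
high-dimensional variants with 80 and 70 channels where only the first 20
or 5 carry structure). The exact published connection strengths for the
structured scenarios are not available, so the scenarios place precision
cliques of four channels with off-diagonal 0.4, rotated between segments;
this is a documented reconstruction, the strength is a parameter, and
means are held at zero (the benchmarks vary connectivity, not activation).
At `T = 200` the 0.4 default produces covariance jumps near the detection
threshold, so scenario-based demonstrations that need high power use the
`strength` override explicitly.

What passing tests on this generator do **not** show: robustness to
temporal autocorrelation, slow drifts, hemodynamic smoothing, or
heavy-tailed noise — none of which the generator produces. Spike artifacts
are the only non-Gaussian feature modelled.

## Numerical and design choices

- Covariance divisor `T`; plug-in sample mean inside `Xₜ`; upper-triangle
  (including diagonal) vectorisation, giving `J(J+3)/2` free parameters at
  a full mask.
- PSD repair by eigenvalue clipping rather than diagonal loading, floor
  relative to the spectral norm.
- 1-based inclusive indices everywhere in results and files.
- Recursion is depth-first, left child first; purely presentational since
  segments are disjoint.
- Segments shorter than `2Δ` are terminal leaves, not errors.
- Degenerate Welch denominators skip that parameter's test (logged).
- Problem sizes in the test suite (e.g. 200 null replicates at `J=5,
  T=300`; 100 localisation runs at `J=5, T=400`; 3 × 20 white-noise
  subjects at `T=1000, J=20`) are chosen so the whole suite runs in a few
  minutes while keeping Monte-Carlo bands meaningful.

## Limitations

- i.i.d. Gaussian within segments; autocorrelated noise will inflate the
  effective sample size assumed by every test.
- Covariance (marginal) graphs, not precision (conditional) graphs; an
  external precision-matrix estimator can be plugged in per segment via
  `DetectionConfig.graph_estimator`.
- Greedy binary segmentation finds a local optimum of the likelihood; it
  is not guaranteed to recover all change points of adversarial layouts.
- Subject-wise false-positive rate exceeds `α` by construction (selection
  at the argmax), as discussed above.
- Very short alternating states (event-related designs) fall below any
  reasonable `Δ` and are invisible to the method.
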