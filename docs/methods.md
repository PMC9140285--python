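# Methods

This note records the scientific and numerical choices behind `synchfim`:
what is modeled, what the defaults mean, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## The statistical model

Neural activity is represented as T independent samples of N ternary states
s_m ∈ {−1, 0, +1} (down / flat / up, the sign of the activity derivative).
The pairwise maximum-entropy model is the Boltzmann distribution

    p(s) = exp(−E(s)) / Z,
    E(s) = − Σ_{m<t} J_mt δ(s_m, s_t) − Σ_k Σ_m h_mk δ(k, s_m).

Its sufficient statistics — per-neuron state frequencies r_k(s_m) and
pairwise agreement probabilities ⟨δ(s_m, s_t)⟩ — are the quantities the model
reproduces exactly at the maximum-likelihood solution.  Two conventions are
fixed throughout:

- **Gauge.**  The three state indicators of a neuron sum to one, so one field
  per neuron is redundant.  The reference gauge sets h_{m,0} = 0, making the
  free-parameter count 2N + N(N−1)/2 equal the number of independent
  constraints.  All parameter vectors ("theta") use the ordering
  (h_{m,−1}, h_{m,+1}) per neuron, then couplings J_{mt} for m < t.
- **Agreement, not product moments.**  The pairwise statistic is the
  probability that two neurons share a state (a Kronecker-delta average), not
  the product moment ⟨s_m s_t⟩; the single coupling per pair is conjugate to
  that agreement indicator.  General 3×3 per-pair coupling matrices are out
  of scope.

Exact computations enumerate all 3^N configurations and are allowed up to
N = 12 (≈ 5.3·10⁵ states, seconds on one CPU); larger systems use the Monte
Carlo paths.

## Fitting

- **Independent model** (fields only): closed form,
  h_{m,k} = log(r_k / r_0).
- **Exact pairwise fit**: the negative log-likelihood is convex with gradient
  ⟨O⟩_θ − ō and Hessian cov(O, O); a damped Newton iteration with
  backtracking line search reaches the default constraint-error tolerance
  1e−6 (often 1e−10) in a handful of steps.  Convergence is declared on the
  max absolute difference between model and target sufficient statistics —
  an observable-space criterion, so any optimizer meeting it is
  interchangeable.
- **Boltzmann learning** (any N): gradient steps with Metropolis-sampled
  expectations, learning rate 1/(1 + it/100).  The sampling noise floor of an
  estimated probability is at most √(0.25/T_mc); iteration stops when the
  constraint error falls below max(tolerance, 3× that floor), and convergence
  is certified only if the requested tolerance is itself resolvable
  (tolerance ≥ floor).  Unreachable tolerances return the best model with
  `converged=False`.
- **Zero frequencies** (finite-T data can miss a state entirely): an additive
  pseudocount of 1/(2T) is applied to the state frequencies before logs/fits
  when the sample count is supplied.  No regularization is applied by
  default; an optional L2 ridge is exposed on the exact fit.

## Perturbations and the localized Jacobian

The experimental primitive is a stochastic clamp of matcher m to target t
with probability ε, giving the observable-space replacement rule
r̃ = (1−ε) r_m + ε r_t, and the same mixture for the matcher's agreement
probabilities.  The matcher–target agreement mixes toward 1 because clamped
states agree by construction; treating the target like any other neighbor j
(mixing agree_{mt} with agree_{tt} = 1) gives the identical formula, so the
two readings coincide.

For small ε the clamp is assumed to stay *localized*: only the matcher's
parameters (two fields, N−1 couplings) move.  In an exponential family
d⟨O_a⟩/dθ_b = cov(O_a, O_b), so the parameter image solves the square
(N+1)-dimensional system χ·dθ = dO/dε, with χ the covariance (susceptibility)
of the matcher's own sufficient statistics.  The solve is direct, with the
condition number monitored (failure above 1e12); no pseudo-inverse fallback.

Two points established empirically and enforced by tests:

- The linear-response solution agrees with an independent nonlinear oracle —
  Newton-solving for the matcher's parameters that reproduce the perturbed
  matcher-block observables at ε = 1e−3, divided by ε — to well under 1%.
- "Refit" must respect localization: refitting *all* parameters to the
  perturbed observables differs from the localized delta at first order
  (the untouched observables couple back through the Hessian's off-block
  terms), whereas the localized refit differs from the linear-response
  prediction only at O(ε²) in parameters, hence ~O(ε⁴) in KL divergence.

Canonical perturbations (a unit change of one coupling) are provided as the
parameter-space baseline.

## Synchrony and its Fisher information

A configuration coarse-grains to sorted occupancy counts (n₁, n₂, n₃); the
support is the set of partitions of N into ≤ 3 parts, of size
round((N+3)²/12) — 234 for N = 50 — ordered descending-lexicographically so
ranks are deterministic.  Coarse synchrony keeps only n₁.

Because synchrony is a deterministic coarse-graining of p(s), its Fisher
matrix over θ has the exact Gram form

    G_ij = Σ_n φ(n) c_i(n) c_j(n),  c_i(n) = ⟨O_i | n⟩ − ⟨O_i⟩,

and the matcher–target FIM is the congruence F = Jᵀ G J over the N(N−1)
localized Jacobian columns (matcher-major direction ordering).  This
analytic form realizes the ε → 0 limit exactly; symmetric finite-difference
KL estimates (with the polarization identity for off-diagonal entries) are
kept only as the independent test oracle, and agree to ~1e−7 relative at
ε = 1e−4.  Coarse states with φ(n) = 0 contribute nothing; on empirical
paths, KL comparisons use additive 1/(2T) smoothing.

A consequence worth noting: even for an independent model with identically
distributed neurons the diagonal FIM entries are *not* zero — the matcher–
target agreement derivative 1 − agree_{mt} survives any statistical
redundancy of the pair, and the induced coupling change moves synchrony.
The oracle confirms the nonzero value.

### Eigenmode analysis

Eigenvectors (descending eigenvalue, rank 1-based) are reshaped to
zero-diagonal N×N eigenmatrices with rows indexing targets and columns
matchers, sign-fixed so the largest-magnitude entry is positive.  Row and
column uniformities are the squared row/column sums; the column sums run
over the N−1 structural entries of the zero-diagonal convention (one
consistent reading of the square-sum definition, which does not by itself
resolve the indexing).  Pivotal-neuron flags pool column uniformities over
all neurons, modes and Monte Carlo runs, cut at the 99th (or 99.9th)
percentile; a neuron is flagged in a run if any of its column uniformities
exceeds the pooled cutoff.  Matcher-diagonal (N−1)×(N−1) blocks give a
per-neuron principal eigenvalue; this block ranking is what the subsample
curve uses to grow "pivotal" subsets, since it directly scores the
restricted sensitivity (the max-column-uniformity ranking can pick small
subsets that underperform random ones).  Degenerate eigenvalues are left in
the deterministic order of the symmetric eigensolver, uniformities reported
per mode without symmetrization.

### Spectra and nulls

Rank spectra are fit by ordinary least squares on log λ_z with equal rank
weights to log A − α log z − z/z̄; the exponential special case (α = 0) is
fit alongside, and nesting guarantees residual(full) ≤ residual(exponential).
A nonpositive fitted decay coefficient is reported as z̄ = ∞.  The truncation
rank keeps eigenvalues above 1e−12 × the principal one (the double-precision
eigensolver floor), capped at the synchrony dimensionality when N is known.
Null models: independent fit, couplings shuffled uniformly over pairs
(preserving the coupling distribution, destroying topology), and the
canonical-perturbation FIM (the coupling block of G).  The design bound
T ~ (ε²F)⁻¹ converts a mode's Fisher information into the minimum number of
independent samples needed to resolve a perturbation of strength ε.

## Synthetic data: what it emulates, what it does not

The generator draws reference-gauge fields h_{m,k} ~ N(0, field_scale²) and
couplings with magnitudes |N(0, coupling_scale²)| and a negative sign with
probability `coupling_sign_fraction` — a signed, heterogeneous coupling
distribution of the kind inferred from real recordings, without claiming its
exact law.  Defaults: N = 50, field_scale = 0.5, coupling_scale = 0.3, sign
fraction 0.5; these produce broad agreement statistics away from saturation,
the weakly-coupled heterogeneous regime the analysis targets at desk scale.
Sampling is single-site Metropolis with burn-in 100·N sweeps and thinning
10·N single-site updates — conservative for these regimes (validated against
exact enumeration at N ≤ 8).  Ternarization of continuous derivative traces
offers a per-neuron symmetric threshold at a quantile of |derivative|
(default keeps the flat fraction at 1/3), a fixed threshold, and a signed
tercile rule; the discretization threshold is an analysis choice, not a
measured quantity.

What a green test on synthetic data does *not* establish: anything about
imaging noise, derivative extraction from fluorescence, temporal correlation
between samples (the generator's thinned samples are effectively
independent; real recordings are not), or the behavioral meaning of
synchrony.  Conclusions about real recordings require the real ternarized
data as input.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds; every operation is a
  pure function of (inputs, seed), and artifacts rewritten from the same
  config are byte-identical (floats serialized with 17 significant digits).
- Exact-path tolerances: distribution normalization 1e−12; FIM symmetry
  1e−8; fit constraint error 1e−6 (default).
- Ill-conditioned susceptibility blocks (condition number > 1e12) raise with
  diagnostics rather than silently pseudo-inverting; near-deterministic
  neurons (frequencies at 0 or 1) are the typical cause.
- Single-neuron systems have a constant coarse statistic and a zero Fisher
  matrix; empty coarse states are skipped in all sums.

## Known limitations

- Exact paths scale as 3^N; N > 12 requires the Monte Carlo estimators,
  whose error is reported but makes strict tolerances uncertifiable.
- The localized-perturbation assumption is an approximation for finite ε:
  observables outside the matcher's block shift at O(ε²)·(cross-covariance),
  which is invisible to the (N+1)-block solve by construction.
- The spectrum fit is a least-squares summary of the eigenvalue decay, not a
  likelihood-based test of power-law behavior.
- No estimation from incomplete Fisher matrices, no temporal/kinetic
  modeling, and no decoding of behavior from synchrony.
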