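# Methods

## The measurement and the model

Kinetic sequencing measures reaction kinetics for every sequence in a mixed
pool at once.  Aliquots of an input RNA pool are reacted with an activated
substrate at a series of initial concentrations, reacted molecules are
pulled down and sequenced alongside the unreacted pool, and read counts are
converted into per-sequence *reacted fractions*.  For the aminoacylation
ribozymes this package targets, the kinetics are pseudo-first order in the
substrate: with reaction time `t` fixed and initial substrate concentration
`c_j` varied,

    f_ij = A_i * (1 - exp(-alpha * t * k_i * c_j)),

where `k_i` (min⁻¹M⁻¹) is the rate constant, `A_i ∈ [0, 1]` the maximum
amplitude (the fraction of molecules competent to react), and `alpha` a
dimensionless coefficient absorbing first-order substrate degradation over
the fixed reaction window.  Defaults are `alpha = 0.479` and `t = 90` min,
matching the aminoacylation assay the package is built around; both are
plain numbers in `KineticModelConfig` and can be changed freely.  The
product `kA` — the initial slope of the curve — is the robust activity
measure: it stays well determined even when the data never approach
saturation and `k` and `A` cannot be separated.

Time-course designs (fixed `c`, varying `t`) fit the same machinery by
passing the composed exposure `alpha·t_j·c` as the condition variable;
only the product enters the exponent.

## From counts to fractions

The pipeline starts at de-replicated count tables (sequence → reads, one
file per sample).  Standard pre-fit filters remove sequences of unexpected
length or with ambiguous bases, and attribute to the spike-in all reads
within an (inclusive) edit distance of 2 of the spike-in sequence —
computed as true Levenshtein distance via `edlib`, since sequencing indels
land spike-in reads at lengths L±1, L±2.  Spike-in attribution runs before
the length filter for exactly that reason.  Reads are conserved through
filtering: retained + tallied-per-reason = original column sums, per
sample.

Total RNA recovered in sample `j` is either measured directly
(fluorometry/qPCR; the default when both are available) or inferred from
the spike-in read share, `Q_j = (N_j - n_sj)/n_sj · q_sj`.  Per-sequence
amounts are `q_ij = n_ij/(N_j - n_sj) · Q_j`, and reacted fractions are
`f_ij = q_ij / q_i,unreacted`.  A sequence is *analyzable* when it has a
non-zero unreacted count and at least one non-zero reacted count.
Fractions above 1 — possible under measurement noise — are kept and
flagged, never clamped: clamping would bias the fit, and the bound
`A ≤ 1` already constrains the model.

## Fitting

The model is linear in `A`, so for any fixed `k` the optimal amplitude has
the closed form `A*(k) = clip(Σ g·y / Σ g², 0, 1)` with
`g = 1 - exp(-alpha·t·k·c)`.  The default engine exploits this: the
least-squares problem collapses to a one-dimensional profile minimization
over `k`, which is bracketed on a 120-point logarithmic grid spanning
`k ∈ [1e-6, 1e6]` min⁻¹M⁻¹ and refined by 60 golden-section iterations
(~1e-9 relative in `k`).  Each row is normalized by its maximum before
fitting, making the search scale-free, and the whole procedure is
vectorized across sequences — a pool of 10⁴ sequences fits in well under a
second, which is what makes bootstrap uncertainty affordable at full
scale.  The profile optimum is deterministic and global over the search
interval; the test suite verifies it never exceeds the objective reached
by `scipy.optimize.least_squares` (trust-region reflective, analytic
Jacobian, tolerances 1e-8) from any tested random start, and beats it on a
fraction of noisy cases.  The formal bounds are `k ∈ [0, ∞)`, `A ∈ [0, 1]`;
the finite grid interval acts as an effective search range three decades
beyond any simulated `k` on either side.  Rows where the zero model
(`k = 0`) matches or beats the interior optimum return `k = A = kA = 0`.

The scipy engine remains available (`engine="trf"`, initial values drawn
Uniform(0,1)) for two purposes: as an independent cross-check, and as the
required engine for the multi-start convergence diagnostic
`ΔA = A_max - A_min` over 20 restarts with `k ~ Uniform(0,10)`,
`A ~ Uniform(0,1)` — that diagnostic is *defined* by the spread of a local
optimizer across random starts, which a deterministic global solver cannot
produce by construction.

All-zero fraction vectors short-circuit to `kA = 0`.  Per-sequence RNG
streams are derived from `(seed, row position)`, so batch order and worker
count never change results.

## Uncertainty and identifiability

Bootstrap: relative residuals `r_ij = (f_ij - f̂_ij)/f̂_ij` are resampled
with replacement to the original sample size and re-applied as
`(1 + r*)·f̂_ij`; each of the `n_boot = 100` resampled datasets is
refitted.  Observations with `f̂_ij = 0` have no defined relative residual
and are kept as fixed zeros.  Two CI-95s are computed — normal-theory
`mean ± 1.96 s.d.` and the 2.5–97.5 percentile interval — with percentile
the reporting default.  If every residual is exactly zero the bootstrap is
a fixed point: all resampled estimates equal the point estimate, s.d. = 0,
both intervals collapse, fold-range = 1.

Identifiability of `k` and `A` separately is scored by
`gamma = log10(sigma_k · mu_A / sigma_kA)` over the bootstrap samples:
near 0 when the rate constant is as well determined as the product, and
increasingly positive as `k` decouples.  `gamma` is invariant under
rescaling of the `k` axis; the degenerate case `sigma_kA = 0` scores 0
when `sigma_k = 0` (perfectly determined) and +inf otherwise.  Per-sequence
precision is the fold-range, `kA` 97.5-percentile / 2.5-percentile.

The replicate-series alternative assigns each replicate at every
concentration to one series, fits each series separately, and builds
`mean ± 1.96 s.d.` across the (typically three) series.  On simulated
pools its coverage of the true `kA` runs ~5–10 points below the bootstrap
interval's — replicate s.d. from n = 3 underestimates the tail — which is
the practical argument for bootstrapping in sequencing experiments where
replicates are expensive.

## Doped-pool mathematics and sequencing error

A doped pool synthesized around family centers with per-position mutation
rate `eta` gives every specific mutant at Hamming distance `d` the
abundance `(1-eta)^(L-d)·(eta/3)^d`, with `n_families·C(L,d)·3^d` possible
sequences per class; the order-to-order abundance ratio is
`(eta/3)/(1-eta)` (≈0.033 at `eta = 0.09`), and the rate maximizing a
target order `d` is `eta = d/L` (≈0.095 for double mutants of a 21-mer —
the rationale for the 9% design).

Sequencing error is modelled to first order in the per-base rate `xi`:
only single-substitution read errors, `xi/3` to each alternative base, no
indels (higher-order terms are O(xi²) at the rates of interest).  A
specific `d`-mutant retains reads with probability `(1-xi)^L` and gains
misreads from its `3L` Hamming-1 neighbors — `d` reversions at order
`d-1`, `2d` lateral at order `d`, `3(L-d)` forward at order `d+1` — each
with probability `(xi/3)(1-xi)^(L-1)`, neighbor abundances taken as the
ensemble-average class probabilities.  The survival factor `(1-xi)^(L-1)`
multiplies the gain as well as the loss term; at `L = 21`, `xi = 0.01` it
is ≈0.82 and materially lowers the spurious-read fraction (10.4% rather
than the 12.4% obtained if gains are not attenuated).  Both model routes
are verified against brute-force enumeration over all 4^L sequences at
small `L` and against explicit neighbor-string enumeration at `L = 21`.

## Simulators

*Grid*: sequences on a (log10 k, log10 A) grid — defaults 101×101 over
`log10 k ∈ [-1, 3]`, `log10 A ∈ [-2, 0]` — with noise
`f = max(f⁰ + Normal(0, eps·f⁰), 0)`.  `eps` is the *relative error* of
the reacted fraction, i.e. the noise scale parameter is the standard
deviation `eps·f⁰`; a literal-variance reading (scale `sqrt(eps·f⁰)`) is
available behind `noise_as_variance=True` for comparison.  Condition sets:
standard (2/10/50/250 µM ×3), added-replicate (×4), extended
(+1250 µM ×3).

*Pool*: `M` sequences with log-normal unreacted abundances (σ = 2.0 in log
space by default — an uneven but not extreme pool; raise it to emulate
heavily skewed doped or selected pools), log-uniform `k` over
`[0.1, 1000]` min⁻¹M⁻¹ and uniform `A` on `[0, 1]`, normalized
`p0`.  Sequencing is one exact multinomial draw per sample of
`N_j = 40·M` reads (40 reads/sequence mean, a realistic per-sequence
depth), with reacted-sample probabilities `p_ij ∝ p_i0·f_ij`.  Recovered
RNA totals get Gaussian relative noise (default 15%, matching typical
spike-in vs direct quantitation scatter), clamped at zero, applied to
*reacted* samples only: the unreacted input amount is known by
construction and serves as the mass unit.  Ground truth `(p0, k, A, kA)`
is retained for every sequence.

What the pool simulator does *not* emulate: read-level sequencing error
(treated analytically above, not injected into counts), PCR amplification
bias, non-specific retention, or correlations between abundance and
activity that a real selected pool would carry.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under
counting + quantitation noise, not robustness to those systematic effects.

## Numerical choices and edge cases

- Profile search interval `k ∈ [1e-6, 1e6]`; golden-section for 60
  iterations; residual sums computed from explicit residuals (not the
  expanded quadratic form) to avoid catastrophic cancellation for
  small-signal rows.
- trf engine tolerances (ftol/xtol/gtol) 1e-8; analytic Jacobian.
- Family classification ties (equidistant centers) go to the lowest family
  index and are flagged.
- Bootstrap sd of an exactly-constant sample column is forced to exact 0
  (pandas' mean-subtraction otherwise leaves ~1e-15 dust).
- Fold-range with a zero lower percentile is +inf; with a degenerate
  (point) interval it is 1 for positive estimates and NaN at zero.
- Sequences are uppercased and `U` mapped to `T` on load (RNA sequenced as
  cDNA).  Count files reject negative counts, malformed lines and
  duplicate sequences, naming file and line.

## Known limitations

- The residual bootstrap assumes relative residuals are exchangeable
  across conditions.  For saturating, moderately counted sequences the
  informative low-concentration observations are systematically noisier
  than the saturated ones, and the shared unreacted-denominator count
  error is invisible to residual resampling; both effects make the
  bootstrap CI anti-conservative in the high-`kA`, mid-count corner of
  parameter space.  Pool-level CI-95 coverage measured here is ~89–92%
  rather than the nominal 95% when a third of the pool sits in that
  corner; coverage is on target (_≈96–98%_) where the exchangeability
  assumption holds.  Replicate-series CIs are worse (~84%).
- Accuracy metrics conditioned on high counts are dominated by the
  *shared* per-sample total-RNA noise, so a single simulated pool yields a
  stratum median error that is itself random across seeds (observed
  ~5–17% at 15% noise); conclusions about the high-count error floor
  should average over pools.
- Only the pseudo-first-order model ships; other closed-form kinetics can
  be fitted through the scipy engine by swapping the model function, but
  the fast profile engine is specific to models linear in the amplitude.
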