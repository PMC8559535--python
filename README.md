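# kseqtools

Per-sequence reaction kinetics from high-throughput sequencing count data.

Kinetic sequencing assays measure the activity of every sequence in a mixed
pool at once: aliquots of an input pool (e.g. ribozyme variants) are
reacted at a series of substrate concentrations, reacted molecules are
isolated and sequenced together with the unreacted pool, and each
sequence's read counts are converted into *reacted fractions* and fitted
to a kinetic model.  `kseqtools` implements the full desk side of such an
experiment for pseudo-first-order kinetics,

&nbsp;&nbsp;&nbsp;&nbsp;*f<sub>ij</sub> = A<sub>i</sub> (1 − e^(−α t k<sub>i</sub> c<sub>j</sub>))*,

estimating the rate constant *k* (min⁻¹M⁻¹), amplitude *A* ∈ [0, 1] and
the product *kA* (the initial-rate activity measure) for every sequence,
with bootstrap confidence intervals and identifiability scores
(γ = log₁₀(σ<sub>k</sub>·μ<sub>A</sub>/σ<sub>kA</sub>), σ<sub>A</sub>, ΔA).

The package covers, as importable modules:

- `pool` — doped variant-pool design math: mutant-class sizes
  (4·C(L,d)·3ᵈ), per-class abundances, expected counts, coverage, the
  doping rate maximizing a target mutant order (η = d/L), and a
  first-order model of read misassignment between Hamming-1 neighbors
  under per-base sequencing error;
- `counts` — per-sample count-file loading, length/ambiguity filters,
  spike-in attribution by edit distance (`edlib`), analyzable-sequence
  criteria, family classification by Hamming distance;
- `quantify` — absolute quantitation via a spike-in internal standard
  (Q = (N−nₛ)/nₛ·qₛ) or direct RNA measurement, and reacted fractions
  f = q/q₀;
- `kinetics` — a fast deterministic global least-squares fitter
  (profile over k with closed-form amplitude, vectorized across
  sequences) plus scipy's bounded trust-region engine for cross-checks
  and multi-start convergence diagnostics;
- `uncertainty` — relative-residual bootstrap (CI-95 as mean ± 1.96 s.d.
  and as 2.5–97.5 percentiles), γ scoring, fold-range precision,
  replicate-series CIs, coverage and accuracy reports;
- `simulate` — generators with retained ground truth: a (log k, log A)
  grid with relative Gaussian noise, and a multinomial pool sequencing
  simulator with noisy total-RNA recovery.

A thin CLI (`kseq`) wraps the same functions for shell use.

## Worked example

`examples/03_fit_single_sequence.py` simulates one ribozyme with known
kinetics (k = 40 min⁻¹M⁻¹, A = 0.65) over the extended substrate series
(2, 10, 50, 250, 1250 µM in triplicate, α = 0.479, t = 90 min), adds 20%
relative noise, fits, and bootstraps:

```
truth:     k = 40.0 /min/M   A = 0.65   kA = 26.0
estimate:  k = 46.0        A = 0.59   kA = 27.2
kA CI-95 (percentile bootstrap): [21.9, 31.1]
gamma = 0.19  (near 0: k and A separable)
fold-range = 1.42  (CI spans 1.4x)
```

The point estimate lands within a few percent of the truth, the bootstrap
interval covers it, and γ near zero says the saturation visible at the
two highest concentrations lets *k* and *A* be reported separately rather
than only their product.  The other examples walk the remaining
capabilities: doped-pool design tables (`01`), sequencing-error
misassignment — at 1% per-base error over 10% of a single mutant's reads
are really its neighbors' (`02`) — pool-scale simulation and
accuracy-vs-counts strata (`04`), and identifiability maps showing that
adding a higher substrate concentration extends the separable region
~10× further down in kA where an extra replicate does not (`05`).

```sh
python examples/03_fit_single_sequence.py
kseq pool-design --length 21 --eta 0.09 --families 4 --total-reads 32931917
```

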