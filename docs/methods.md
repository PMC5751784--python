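# Methods

## Observation model

A sequencing run is modelled as drawing `S` cDNA fragments uniformly
without replacement from a pool of `N`; a gene contributing `k` of those
fragments (its *true count*) therefore shows an observed count
`X ~ Hypergeometric(N, k, S)`. Two consequences drive everything else:

* `E[X] = b·k` with `b = S/N` the *coverage*;
* the mean-to-variance ratio is `(N/(N−k))·((N−1)/(N−S)) ≈ 1/(1−b)` for
  `k ≪ N`, i.e. counts are **underdispersed** and increasingly so at high
  coverage.

Because `N` is large and unknown in practice, the bounded hypergeometric is
replaced by a Generalized Poisson (GP) with `λ₁ = bk√m`, `λ₂ = 1−√m`,
`m = 1/(1−b)`, which has exactly the mean `bk` and variance `bk/m` and no
upper support bound. The GP is valid for `0 < m < 4` (`|λ₂| < 1`), i.e.
coverage below 0.75; beyond that the package warns but still runs the gamma
production path, and any use at coverage ≥ 1 is refused outright. For
`λ₂ < 0` the pmf is truncated to zero where `λ₁ + xλ₂ ≤ 0` (Consul's
convention), without renormalisation — the posterior normalises anyway.
All pmf evaluation is in log space with `log Γ` for factorials, since
counts reach 10⁵.

## Posterior of the true count

With a uniform (improper) prior on `k = 1, 2, …`, the posterior
`P(T=k | X=x, b)` is a proper distribution proportional to
`k·(bk√m + x(1−√m))^{x−1}·e^{−bk√m}` over `k ≥ max(x, 1)`. The support
choice deserves a note: the normalising sum formally starts at `k = x`,
which is empty advice at `x = 0`; since the prior covers `k ≥ 1`, the exact
posterior at `x = 0` is taken over `k ≥ 1`, while the continuous gamma
approximation (below) is used as printed with support `k ≥ 0`. This matches
the approximation's positive mean at `x = 0`.

Two implementations are provided:

* **Brute force** (`posterior_pmf_bruteforce`) — reference path. The sum is
  truncated initially at `⌈μ + 12σ⌉` (taken from the gamma approximation)
  and extended geometrically until a tail bound — last term times
  `r/(1−r)`, `r` the terminal term ratio — falls below `tol` (default
  1e−10) relative to the retained mass; the result is renormalised and the
  achieved bound reported. Failure to converge within the term cap raises,
  reporting the achieved bound.
* **Gamma approximation** (`posterior_gamma`) — production path, with
  `μ = (x+1)/b − (1+1/2b)⁻¹` and `σ² = (x+1)/[b(b+1)]²`, shape `μ²/σ²`,
  scale `σ²/μ`. These closed forms are fitted approximations taken as
  given; the package does not refit them.

**Approximation quality.** Validated against the brute-force posterior, the
gamma approximation is excellent for `x ≳ 50` (posterior means within 0.5%,
total variation distance < 0.05) and degrades at small observed counts,
most at high coverage: at `x = 1` the mean is off by ~4% (b = 0.1), ~10%
(b = 0.25) and ~19% (b = 0.5), with TV distances up to ~0.17. The unit
suite pins this behaviour with per-cell empirically frozen bounds. Users
calling genes whose observed counts are in the single digits at high
coverage should expect the quoted credibility to be approximate.

## Coverage arithmetic

`b = S/N`, with `S` the number of sequenced fragments (read *pairs* for
paired-end data) and `N` the pre-sequencing fragment population. Defaults
follow standard Illumina library arithmetic: a post-PCR yield of 4.818×10¹²
fragments over 14 cycles gives `N ≈ 3×10⁸`, the default population when
nothing else is supplied. Alternatively `N` comes from loading
concentration × volume (default 120 μL) × Avogadro's number. Multiple runs
of one sample are averaged before computing `b`.

Imperfect PCR: with per-cycle efficiency `e`, the population grows by
`(1+e)` per cycle instead of doubling, so `((1+e)/2)^cycles` of the nominal
population is effectively present — 70%, 49%, 34%, 23% at 14 cycles for
e = 95%, 90%, 85%, 80% — and the effective coverage is `S/(N·retention)`.
Any derived coverage ≥ 1 is a hard error.

## Decision rule

For control/treatment observed counts `(x₀, x₁)` at coverages `(b₀, b₁)`,
the side with the larger posterior mean is the candidate direction; the
gene is called when the candidate's `(1−α)/2` quantile is at least `φ`
times the other side's `(1+α)/2` quantile. Defaults `α = 0.99`, `φ = 1.5`.
Exactly tied posterior means are never called (the rule requires a strictly
larger mean). Genes with `x = 0` are processed normally; no minimum-count
filter is applied. Each record keeps both means, both percentile bounds and
the `fold_bound` ratio so users can re-threshold without recomputation.
The rule is a per-gene credibility statement; no multiple-testing
adjustment across genes is performed or appropriate.

## Simulator and studies

`sample_observed_count` draws hypergeometric counts directly; the literal
construction (Fisher–Yates shuffle of the `N` indices, count gene indices
in the first `S`) is distributionally identical and kept only as a small-`N`
test oracle, since shuffling 3×10⁸ indices buys nothing but memory traffic.

The power study (`run_test1`) mirrors the three-scenario design: no effect
(fold 1, true counts up to 10,000), weak (1.5-fold, up to 6,666) and strong
(2-fold, up to 5,000) — 21,666 genes at full scale. For each true count `k`
the control carries `k`, the treatment `round(fold·k)` (banker's rounding;
the 6,666 cap for 1.5-fold shows integer rounding was intended), draws are
independent between samples (no coupling is stated for the two runs), and
the per-`k` call frequency over iterations is the FPR (no effect) or TPR
(effect scenarios, direction-aware). Defaults scale the population to
`N = 3×10⁶` with proportional `S` and a log-spaced grid of ~30 `k` points
per decade; since coverage is the governing parameter for `k ≪ N`, this
preserves call-rate curves within Monte-Carlo error (property-tested), and
100 iterations per point keeps the default study in seconds. The package's
own studies and the acceptance script use these desk-scale sizes.

The PCR-efficiency study (`run_pcr_efficiency_study`) generates data once
per expected coverage at the true coverage, then re-analyses it with the
coverage inflated by `1/retention(e)` for each assumed efficiency, skipping
(with a warning) cells where that reaches 1 — which happens already at
expected coverage 0.25 for 80% efficiency. ROC curves come from the
standard cut-off sweep (α = 0.99, φ: 1.5 → 0.75; then φ = 0.75,
α: 0.99 → 0.01); AUC is a raw trapezoid over the swept points plus (0,0)
and (1,1), with no convex-hull smoothing. A TPR that decreases along the
sorted curve triggers a warning rather than an error, since noisy sweeps
can be locally non-monotone.

## Evaluation conventions

Confusion matrices are direction-aware: an up-call on a truly
down-regulated gene is a false positive *and* that gene's truth is counted
missed. Undefined ratios (0/0, e.g. PPV with no calls) are reported as NaN
with an explicit flag, never imputed as zero.

## Synthetic data: what it does and does not emulate

The fixture generator (`make_fixture`) and simulator implement the chance
mechanism of the model itself: uniform random fragment sampling at known
coverage, log-uniform true counts, planted fold changes in alternating
directions. They deliberately do **not** emulate library-preparation
biases (fragment GC/length effects, priming bias), read-mapping ambiguity,
or biological variance between replicates — there are none to model in an
unreplicated design. Tests passing on these data therefore demonstrate
correctness of the inference given the sampling model, not robustness to
violations of it; the PCR-efficiency study probes one specific violation
(mis-specified coverage) and finds AUC shifts of only a few percent.

## Known limitations

* The gamma moment formulas lose accuracy for observed counts below ~10,
  notably at coverage ≥ 0.25 (quantified above).
* Sensitivity at coverage 0.1 reaches 0.95 for 2-fold changes only at true
  counts of roughly 4,000 and above; at coverages ≥ 0.25 it does so from
  ~2,000 (and earlier as counts grow).
* Coverage ≥ 1 (deep sequencing relative to the fragment pool) is outside
  the method's domain and refused.
* Single control vs single treatment only; replicate pooling and
  multi-replicate posteriors are out of scope.
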