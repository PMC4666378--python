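# Methods

## Model and rationale

Bisulfite sequencing counts at a CpG site are doubly stochastic: reads
are a binomial sample of molecules, and the underlying methylation
proportion itself varies between biological replicates.  The
beta-binomial captures both, parameterized here by mean μ and dispersion
φ with Var(p) = μ(1−μ)φ, so the marginal count variance is
N μ(1−μ)(1+(N−1)φ).  Three structural assumptions make the
single-replicate problem tractable:

1. **Spatial smoothness of the mean.**  μ_ij = f_j(l_i) with f_j smooth,
   reflecting the strong local correlation of methylation levels.  f_j
   is estimated by a moving average of collapsed counts over a ±w window
   (strict inequality |l_m − l_i| < w; windows never cross chromosome
   boundaries).  Collapsing weights window sites by read depth.
2. **A genome-wide dispersion distribution.**  φ_ij ~ log-normal(m_j0,
   r_j0²).  The hyperparameters are shared across the genome (fitted
   per group), which is what lets a one-observation-per-site problem
   borrow strength.
3. **Conditional independence.**  Given the smooth mean and per-site
   dispersions, counts at different sites are independent; all spatial
   correlation lives in f_j.

## Smoothing

`smooth_moving_average` resolves windows per chromosome with
searchsorted bounds and prefix sums (O(n log n)); the estimate is
μ̂ = ΣX/ΣN over the window.  Sites whose window holds no covered CpG
(or fewer than `min_sites`, default 1) are flagged unsmoothable and
excluded downstream — on sparse RRBS-like data this confines analysis to
CpG-dense regions.  The default half-width w = 500 bp is deliberately
conservative: over-smoothing is much more harmful than under-smoothing
(see the span benchmark below), so a small span is the safe default.

## Dispersion estimation

Per-site method-of-moments ("naive") estimates
φ̃ = ((x−nμ̂)²/(nμ̂(1−μ̂)) − 1)/(n−1) are defined for n ≥ 2 and interior
μ̂, clamped to [1e−4, 0.99].  They are kept as a diagnostic and
fallback, but a single observation's φ̃ carries χ²₁-scale multiplicative
noise (variance of log φ̃ ≈ π²/2 plus a point mass at the clamp floor),
so log-moment fitting of (m0, r0²) from them is badly biased.  The
default fit instead maximizes the **marginal likelihood**
Σ_i log ∫ BB(x_i | n_i, μ̂_i, φ) dLogN(φ; m0, r0²), evaluated by
trapezoid quadrature on an 80-point geometric φ grid and optimized by
Nelder-Mead over (m0, log r0²).  On the standard simulation this
recovers the generating hyperparameters (−2.5, 1.0) to within ~0.15 in
m0 and ~0.3 in r0².

Point estimates for the genome-wide field are **posterior means**
E[φ | data] on the same grid — the MSE-optimal choice, and the reason
the single-replicate estimator beats a genome-wide constant dispersion
in MSE.  (A φ-space MAP is biased toward the prior mode
exp(m0 − r0²) ≈ 0.03, well below the dispersion median ≈ 0.08, and loses
to the constant on MSE even under the true prior.)  `shrink_phi`
additionally exposes the penalized-likelihood MAP for single-site work,
computed by coarse-grid bracketing plus golden-section refinement to
<1e−6 and validated against a 10⁴-point grid search.

Three estimation modes share one likelihood machine: `single` (each
site's own observation, the default — neighbors already inform μ̂),
`window` (window sites pooled into the likelihood as pseudo-replicates),
and the multi-replicate path (replicates' log-likelihoods summed at the
common smoothed mean, used for the replicated-data comparison arm).

## Testing and region calling

The Wald statistic is (μ̂_i1 − μ̂_i2)/√(V1+V2) with the ratio-estimator
variance V = Σ_l n_l μ̂(1−μ̂)(1+(n_l−1)φ̂_l) / (Σ_l n_l)² over the
smoothing window, per-site dispersions plugged in.  When μ̂ ∈ {0, 1} a
continuity-corrected mean (ΣX+0.5)/(ΣN+1) enters the variance only.
Two-sided p-values come from the standard normal; with one replicate
there are no residual degrees of freedom for a t correction.  Sites with
no reads in either group's window are emitted with NaN statistics so
output rows align with input sites.

Regions: flag sites with p < 1e−5 and |μ̂1−μ̂2| > δ (δ = 0 by default);
group consecutive flagged sites, tolerating unflagged interruptions
while the running flagged fraction stays ≥ 0.5, but breaking at
site-free gaps longer than the 100 bp merge distance (an empty gap is
absence of evidence, not an interruption); merge groups within 100 bp;
drop regions under 50 bp or with fewer than 3 significant CpGs; rank by
|area statistic| (summed Wald statistics of significant sites), ties to
the longer region.  All thresholds are arguments (and CLI flags).

## Synthetic data

The generator emulates an embryonic-stem-cell-like WGBS comparison; all
randomness flows from one integer seed through numpy seed sequences with
per-stage stream tags, so outputs are byte-reproducible.

* **Positions.**  Log-normal gaps with a state-dependent median — 40 bp
  inside hypomethylated island segments, 120 bp in the methylated bulk
  (CpG islands are by definition CpG-dense) — heavy upper tail, minimum
  2 bp.
* **Mean curve.**  A two-state process alternates geometric runs of
  hypermethylated sea (level 0.93, mean 60 sites ≈ 7 kb) and
  hypomethylated islands (level 0.03, mean 25 sites ≈ 1 kb), matching
  the sharp bimodality of an ESC methylome (bulk genome > 0.9
  methylated, island troughs < 0.05, ~25–30 % of CpGs in or near
  islands).  Beta noise (concentration 60) is added per site and the
  profile is moving-average smoothed at the configured truth span
  (500 bp default), clamped to [0.01, 0.99].
* **Spiked DMRs.**  Disjoint target regions (lengths uniform 5–50 CpGs)
  are overwritten with equally sized source stretches *in the raw
  profile*, and the second group's curve is re-smoothed — so spiked
  curves stay smooth and effect edges taper naturally over ~one span.
  Truth intervals record the target CpG ranges;
  `SimTruth.effective_intervals` derives the bp where the curves
  actually differ (> 0.01), which is the reference the benchmarks use,
  since tapering also means a target whose source resembled it
  contributes little or no true effect.
* **Counts.**  Per group, φ ~ log-normal(−2.5, 1) clamped to
  [1e−4, 0.99] (median exp(−2.5) ≈ 0.08), shared by that group's
  replicates; per replicate N ~ Poisson(depth) (10x default; Poisson is
  a modeling choice — overdispersed depths were tested and change the
  benchmarks marginally) and X ~ beta-binomial.  N = 0 sites are kept
  with X = 0 and handled by the union join policy.

What the simulation does **not** model: read-level artifacts (bisulfite
conversion errors, mapping bias), CpG-density variation beyond the
two-state island/sea structure, partially methylated domains, sample
heterogeneity, and any correlation of dispersion with mean or position
(true φ are i.i.d.).  Passing benchmarks therefore demonstrate correct
inference under the stated model, not robustness to those real-data
features.

## Benchmarks and problem sizes

Three frozen profiles (median over 10 seeds; 20,000 sites each, a desk
scale chosen so the whole suite runs in minutes on one core):

* `table1` — mean recovery vs smoothing span, truth spans {500, 2000} ×
  estimation spans {none, 500, 1000, 2000}, 10x.  Expected pattern:
  matched span ≈ 0.99 correlation, no smoothing lower, 4×-over-smoothed
  markedly lower (over-specification is the harmful direction).
* `table2_fig1` — dispersion recovery at depths {10, 20, 30} for one and
  three replicates plus the constant-dispersion reference (the median of
  the true dispersions, ≈ 0.08).  The single-replicate arm reuses
  replicate 1 of the three-replicate simulation (identical marginal
  law, half the runtime).  Expected orderings, which hold in every seed:
  correlation rises with depth and replicates; MSE(3-rep) <
  MSE(1-rep) < MSE(constant).
* `fig3` — spike-in detection, 20 DMRs per 20,000 sites (the same
  site:region ratio as a 100,000-site / 100-region design; the realized
  truly-differential site fraction, ~2–3 %, is reported rather than
  assumed).  Site-level TDR uses |Wald| ranking versus Fisher-exact
  (p ascending) and |smoothed mean difference| rankings.  Region-level
  comparison: each method calls regions at its natural operating point
  (shared p < 1e−5 for the two p-value methods; |diff| > 0.1 for the
  scoreless baseline, with the shared region machinery and |summed
  score| ranking), and TDR curves are compared at the largest common
  total-bp prefix (capped at 20 kb, scaled from 100 kb at the full
  design) so no method is evaluated beyond territory it actually
  ranked.

Numerical conventions worth knowing: the dispersion domain is clamped to
[1e−4, 0.99] everywhere (φ = 0 is handled as an exact binomial);
internal coordinates are 1-based inclusive with BED export 0-based
half-open; the union join fills absent sites with N = 0 and excludes
them from testing but not from regions; ranking NaNs always sort last;
region assembly is deterministic for identical input.

## Known limitations

* The mean-recovery and dispersion-recovery correlations depend on the
  synthetic template's marginal and spectral properties; a template
  built from real WGBS counts (supported by constructing `SiteCounts`
  from any count table) will shift them by a few hundredths.  On this
  template the dispersion-recovery correlations sit within ~0.04 of the
  information-theoretic ceiling (posterior mean under the true means and
  true prior), i.e. the estimator, not the data model, is near-optimal.
* The Wald test is asymptotic; at very low window depths the normal
  approximation thins out (the null false-positive rate stays within
  [0.03, 0.08] at 10x in the benchmark).
* No region-level FDR is provided; regions are ranked, not assigned
  significance.
* Smoothing assumes dense CpG coverage; sparse data are skipped rather
  than analyzed, and data types with weak spatial correlation (e.g.
  hydroxymethylation) violate the smoothness assumption outright.
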