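# Methods

## Model and estimator

The quantity of interest, λ_s, is the fractional depletion of rare
single-nucleotide variants (population frequency 0 < AF < 0.001) in a
target set of sites relative to the neutral expectation. The observation
model is allele-specific Bernoulli sampling: at retained site *i*, each of
the three alternative alleles *j* carries an independent indicator
Y_i^(j) ~ Bernoulli((1 − λ_s) P_i^(j)), where P_i^(j) is the neutral
probability that the allele appears as a rare variant in the panel. Sites
are excluded wholesale when any alternative allele is common (AF ≥ 0.001),
when the reference forms a CpG dinucleotide on either strand, when mean
sequencing coverage is below 20 reads, or when the heptamer context
contains a non-ACGT base.

The estimator is the bias-corrected closed form λ̂_s = 1 − R′/(M P̄) with
variance (1−λ̂)/(M P̄) − (1−λ̂)² T/(M P̄)² (T = Σ P²). It is exactly
unbiased given unbiased P values and — because the point estimate depends
on the P values only through their sum — exactly invariant to
mean-preserving noise in them; the reported standard error moves only
through T, which enters at second order. λ̂_s is reported unclamped:
negative values are informative (a systematic excess of rare variants, in
real data typically a sign of local mutation-model misspecification, e.g.
near transcription start sites). The likelihood-ratio test maximizes the
exact likelihood numerically (1-D bounded search seeded at the closed
form, so the statistic is never negative) and refers 2Δℓ to χ²(1).

A numerical note on the closed form: with uniform P the closed form *is*
the exact maximizer identically. With heterogeneous P it matches the exact
argmax to roughly (1−λ̂)²·P̄ per allele, which is far below the standard
error whenever the expected variant count is more than a handful; at very
small expected counts (a 50-site instance with ΣP ≈ 1) the estimate itself
moves in increments of 1/ΣP and no point estimator is meaningfully more
precise than that granularity.

## Mutation model

Three stages, all fitted on putatively neutral sites only:

1. **Heptamer context rates.** Relative frequencies of each substitution
   a→b and of "no substitution" conditional on the focal base and three
   flanking bases each side (4⁸ cells, strands kept distinct). A
   pseudocount of 0.5 per outcome keeps every probability strictly
   positive. Contexts unseen in training fall back to the 3-mer (one flank
   each side) rate for the same substitution, then to the reference-base
   marginal.
2. **Covariate adjustment.** A binomial-logistic model of per-(site,
   allele) rare-variant presence on four covariates: the logit of the raw
   context rate, log(coverage + 1) (the +1 tolerates zero-coverage sites),
   fractional G+C in a 200 bp window, and a CpG-island indicator (an input
   BED track, not recomputed). Fitted with statsmodels GLM on a seeded
   simple random sample of sites (default 1%), all three allele rows of a
   sampled site kept together.
3. **Regional rescaling.** One free intercept per sliding window (150 kb
   long, every 50 kb) on the logit scale, fitted with the stage-2 logit as
   an offset with fixed coefficient one — a local mutation-rate scaling
   factor. Windows with fewer than 100 neutral sites inherit the
   chromosome-wide intercept. A site covered by several windows takes the
   arithmetic mean of their intercepts (smooth and symmetric; the overlap
   resolution is otherwise arbitrary).

**Leave-one-out covariates during fitting.** At production data scales a
heptamer cell aggregates thousands of sites, so the contribution of any
one site to its own context rate is negligible. At the scales used for
testing (tens of sites per context) that contribution is not negligible:
regressing an indicator on a covariate that contains the indicator itself
inflated the raw-rate coefficient several-fold and biased λ̂_s detectably.
Stages 2 and 3 therefore compute each training row's raw-rate covariate
from its context's counts with that row's own outcome removed. Prediction
on held-out or target sites uses the full-count rates, which contain no
such leak.

Predicted per-allele rates are capped just below 1/3, so the per-site
total stays below one even for sparsely observed contexts; realistic rates
are two orders of magnitude below the cap.

## Selection-coefficient conversion

Under strong selection against heterozygotes and mutation–selection
balance, the equilibrium allele frequency is μ/s_het and the count of the
allele in 2N sampled chromosomes is Poisson(2Nμ/s_het). Equating expected
polymorphic sites under that model and under the depletion model gives
s_het ≈ (2N/c)/(1 − λ_s) with c = P̄/μ. Defaults follow a gnomAD-v3-sized
panel: N = 71,702 diploids, μ = 1.2×10⁻⁸ per site per generation,
P̄ = 0.162, hence c = 1.35×10⁷. When s_het varies across sites the same
expression estimates the harmonic mean H[s] — a lower bound on the
arithmetic mean — and when a fraction π₀ of sites is neutral, the adjusted
form (2N/c)·ρ/(ρ − λ_s) with ρ ≈ 1 − π₀ removes part of the bias. The
conversion is exposed only as the simple form above; the common-variant
correction to the balance equation is omitted (about 3% of variants are
common in the intended regime, and the relation is approximate anyway).
A warning is emitted for λ_s < 0.45, below which the conversion is
unreliable for a panel of this size.

## Simulators

`bernoulli_simulate` draws indicators directly from the observation model
— the exact generative counterpart of the likelihood — and is the oracle
for estimator calibration tests.

`msb_simulate` draws per-site s_het from a DFE (point mass at zero of
weight π₀ plus a Gamma over s_het; the preset `DFE.kim2017()` carries the
published human coding-region parameters π₀ = 0.031, α = 0.1930, with the
Gamma scale offered in both the s and s_het conventions, θ = 0.0331 and
0.0168, since the published account uses both and does not resolve the
factor of two) and samples allele counts at equilibrium,
Poisson(2Nμ/s_het). Below a strong-selection threshold (default s_het =
10⁻³) the equilibrium mean would exceed the neutral expectation, so such
sites instead draw rare-variant presence at the empirical neutral rate
(default 0.162). A count at or above ⌊0.001·2N⌋ = 143 copies flags the
site common, mirroring the estimator's filter. This equilibrium sampler is
demography-free by construction: it emulates the strong-selection regime,
where allele frequencies are insensitive to demography, and is not valid
for weak selection — recovery tests therefore target s_het ≥ 0.03, with
bias growing to a few percent by s_het = 0.02 (relative bias ≈ Nμ/s_het,
the second-order term of 1 − e^(−2Nμ/s)). For variable-selection runs the
recovered value is compared against the harmonic mean over the
strong-regime sites; the harmonic mean over all sites is degenerate for
DFEs with mass near zero.

`decompose_missing_dfe` recovers the DFE of the rare variants removed by
selection as h(x) = [f(x) − (1−λ_s)·g(x)]/λ_s on a shared histogram, where
f is the DFE of new mutations and g the empirical DFE among surviving rare
variants. Negative bin masses (model inconsistency or sampling noise) are
clamped to zero and their total reported before renormalization.

`synthetic_genome` writes an i.i.d. random genome (default G+C 0.41) with
alternating neutral/target blocks, scattered 500 bp CpG-island intervals
and a clipped-normal per-site coverage track (mean 32, SD 5, so a small
tail falls below the coverage filter). `simulate_rare_variants` draws
variants from the depletion model with ground-truth per-allele rates
assigned at 3-mer resolution (log-normally dispersed around 0.04 with
log-SD 0.5, capped at 0.15 — dispersion comparable to real
context-to-context rate variation), giving the fitted model genuine
sequence-context signal to recover. What this synthetic data does *not*
emulate: overdispersion of mutation rates beyond the context model,
regional rate variation (the true rates are position-independent, so
regional intercepts are tested by injecting explicit logit shifts),
linkage, indels, strand-asymmetric mutational processes, and the
methylation-driven hypermutation that motivates the CpG filter. Passing
end-to-end tests therefore demonstrate correct inference under the model's
own assumptions, not robustness to every real-data pathology.

## Genome-wide accounting

Given per-category (λ_s, stderr, site count) rows for a mutually exclusive
partition, the budget subtracts a background λ_s (default: nonconserved
introns; choosing nonconserved intergenic instead is the less conservative
variant), floors negative adjusted values at zero, multiplies by site
counts to get expected ultraselected sites, and multiplies by 2μ for
expected de novo strongly deleterious mutations per potential zygote.
Fold enrichment is the category's share of expected ultraselected sites
over its share of all sites. Standard errors propagate in quadrature
assuming independent category and background estimates; totals likewise.
Totals are computed from unrounded values; rounding happens only at
presentation.

## Problem sizes and numerical choices

Monte-Carlo suites use 10,000 sites × 500 replicates (estimator
calibration), 1,000 replicates (LRT size), 10⁶ sites (equilibrium
round-trips) and a 400 kb genome (end-to-end recovery) — sizes at which
the targeted tolerances (2 standard errors; 10% on variances) are
comfortably resolvable. The exact-likelihood maximization uses bounded
Brent with tolerance 10⁻¹⁰ on the interval (1 − 1/max P, 1]. The regional
intercept Newton iteration is clipped to ±20 logits. Degenerate inputs
(no retained sites, zero expected variants, negative variance from
floating-point cancellation) raise typed errors or clamp with a warning,
as documented per function.

## Limitations

- The depletion estimate is only as good as the mutation model;
  systematically under-predicted neutral rates inflate λ̂_s and
  vice versa. Real-data pathologies (promoter-region excesses,
  transcription-factor-binding mutagenesis) are out of scope here.
- The s_het conversion assumes strong selection, near-additive dominance
  and mutation–selection balance; below λ_s ≈ 0.45 it is not meaningful
  for a ~70k-genome panel.
- The equilibrium sampler cannot generate realistic data for weakly
  selected sites; no demographic forward simulation is included.
- ρ (the fraction of sites under any selection, used in the adjusted
  conversion) is an external input, never computed here.
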