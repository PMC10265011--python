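# Methods

## Model

Each decision a participant faces is a menu of labelled allocations
(x, y) — own payoff x and the co-player's payoff y, in JPY. Preferences
follow the two-parameter inequity-aversion utility

    U(x, y) = x − α · max((x + y)/2 − x, 0) − β · max(x − (x + y)/2, 0)

α (disadvantageous inequity aversion, DIA) weights the gap when the other
is ahead of the midpoint; β (advantageous inequity aversion, AIA) weights
the gap when the chooser is ahead. At the equal split both penalties
vanish and U = x. Choices are stochastic through a softmax with inverse
temperature λ:

    P(option i) = exp(λ U_i) / Σ_j exp(λ U_j)

λ = 0 is uniform random choice; large λ approaches strict utility
maximisation. Payoffs are rescaled to kJPY (divided by 1000) before the
softmax so a single λ of order 1–10 is comparable across games whose
stakes range from JPY 300 to JPY 3000; α and β are scale-free. The
likelihood treats a participant's decisions as conditionally independent
given (α, β, λ), and every decision is weighted equally.

## Decision contexts

One session comprises 37 decisions:

| game | contexts | options each | what varies |
|---|---|---|---|
| Dictator (DG) | 7 | E/100 + 1 | endowments 1000, 300, 400, 600, 700, 1200, 1300 |
| Prisoner's dilemma (PDG) | 1 | 11 | own contribution 0–1000 |
| Public goods (PGG) | 1 | 11 | own contribution 0–1000 |
| Trust, truster (TG) | 1 | 11 | transfer 0–1000 |
| Trust, trustee (TG) | 10 | 11 | returned fraction 0–100% per transfer 100–1000 |
| Ultimatum, proposer (UG) | 1 | 16 | offer 0–1500 |
| Ultimatum, responder (UG) | 16 | 2 | accept/reject each offer 0–1500 |

All monetary grids are closed ranges in JPY 100 steps (10% steps for the
trustee), matching the experimental elicitation. The trustee holds no own
endowment; rejection in the ultimatum game pays (0, 0) to both.

In the simultaneous-move games the chooser's payoff depends on the
co-player's unobserved action. Contexts are therefore built against an
explicit belief configuration: assumed PDG opponent contribution (default
500, the grid midpoint), assumed PGG contribution of each of the nine
others (default 500), and expected trustee return fraction (default 1/3,
the break-even point at which transferring neither gains nor loses). In
the public-goods game inequity is evaluated against a single
representative other, since the utility is inherently two-player. The
ultimatum proposer is by default modelled as a pure distribution choice
(offers are never rejected); an optional mode instead weights each
offer's utility by the acceptance probability of a softmax responder with
configurable parameters. The same belief configuration must be used when
simulating choices and when fitting — the pipeline shares one config
object across stages to enforce this.

## Bayesian estimation

Parameters are estimated per participant. Priors (on the kJPY scale):
α, β ~ Normal(0, 2), λ ~ half-Normal(0, 5) — weakly informative, covering
published inequity-aversion ranges several times over. The posterior is
sampled by adaptive random-walk Metropolis on (α, β, log λ); the log
transform (with its Jacobian in the target) symmetrises λ's skewed,
boundary-constrained posterior. During warmup each chain adapts (i) a
scalar step multiplier toward ~0.3 acceptance (Robbins–Monro) and (ii) a
full 3×3 proposal covariance estimated from its own history — necessary
because the likelihood depends on λ through the products λα and λβ, which
puts strong correlation into the posterior. Adaptation freezes when the
kept draws begin. Defaults: 4 chains × 2000 warmup + 2000 kept draws,
dispersed starts from the prior. The point estimate is the posterior
mean. Convergence is flagged (never dropped) at split-chain R-hat > 1.05
or bulk ESS < 200, computed with arviz.

Because utilities are linear in (α, β), the session likelihood is
precompiled into flat coefficient arrays and evaluated for all chains of
all participants in one vectorised batch; a 420-participant cohort fits
in well under a minute at default settings.

A dense-grid quadrature posterior over the same unnormalised density
(trapezoid weights, lattice covering ≥ 99% of the prior mass) serves as
an independent numerical oracle: sampler and quadrature posterior means
agree to ~0.03 per parameter at the settings used in the checks.

## Genotype coding and association statistics

AVPR1A RS3 alleles arrive as fragment lengths in bp and are dichotomised
at the cohort-median threshold: < 330 bp is short (S), ≥ 330 bp long (L),
yielding SS/SL/LL; carriers of the specific 334 bp allele are tracked
separately. OXTR rs53576 and OPRM1 rs1799971 are AA/AG/GG. Genotype
distributions are checked by the Pearson goodness-of-fit test against
Hardy–Weinberg proportions (allele frequency estimated from the counts,
1 df, no continuity correction — this convention reproduces the published
χ² values exactly) and pairwise genotype independence by the ordinary
Pearson χ² without Yates correction.

The association model is an ANCOVA with the preference estimate (DIA or
AIA posterior mean) as dependent variable, the three genotype factors
entered simultaneously with sum-to-zero coding, and age as covariate
(centred), giving denominator df = n − 8 for the three-gene model.
Factor tests are Type-III marginal Wald F tests; partial η² =
SS_factor / (SS_factor + SS_error). Pairwise genotype contrasts compare
covariate-adjusted means (covariates at the grand mean, other factors
averaged equally over levels) using the model error term, with the
Bonferroni per-comparison threshold 0.05/3 reported as 0.017 and
Cohen's d = adjusted-mean difference / √MSE. Optional sex × gene
interaction terms can be added. An exactly-fit model (zero residual
variance) reports all tests as zero effect rather than 0/0 noise. The
model is fitted by OLS on an explicitly constructed design matrix
(statsmodels), and agrees with an independent normal-equations solver to
10⁻⁸ in the checks.

## Synthetic-data generator

The generator emulates the cohort's statistical skeleton so every stage
can be exercised without data access:

- **Genotypes** are drawn allele-wise — Hardy–Weinberg by construction —
  at the cohort's frequencies: OXTR G 0.36, RS3 S 0.52, OPRM1 G 0.49,
  with 334 bp making up 0.43 of long alleles. RS3 alleles get concrete
  lengths (short 310–328 bp, long 330–350 bp) so the classifier recovers
  the intended class exactly. Ages ~ Normal(41, 10.5) years, clipped to
  20–75; ~50.5% female.
- **True preferences**: α ~ Normal(0.6, 0.4) truncated to [−0.5, 3],
  β ~ Normal(0.4, 0.3) truncated to [−0.5, 2], λ ~ LogNormal(ln 5, 0.4) —
  plausible ranges on the kJPY scale, simulation conventions rather than
  estimates of any real cohort. α and β are built on a linear predictor
  that accepts additive per-allele genotype effects and an age slope; the
  default slopes give age–preference correlations of ≈ 0.13 (DIA) and
  ≈ 0.32 (AIA), the cohort's reported values. Genotype effects default to
  zero.
- **Choices** are drawn from the softmax forward model via the Gumbel-max
  construction, using the same belief configuration as the fitting stage.

`mirror_study_config` switches on a negative per-L-allele effect on AIA
(short/short homozygotes end up highest) calibrated so the genotype
factor explains a target partial η² (default 0.023) of the variance of
the *fitted* AIA — the scale on which the association stage operates.
The calibration therefore includes the estimation-noise term: the
posterior-mean error sd of AIA at the default schedule and truth
distributions, measured by simulation at ≈ 0.49 and stored as a package
constant. One master seed expands into independent child streams for
genotypes, preferences and choices, so stages re-run independently yet
reproducibly.

What the generator does **not** emulate: measurement-date/carryover
structure, income and other socioeconomic covariates, linkage between
genes, real RS3 allele-length distributions beyond the S/L/334 split,
and any behavioural heterogeneity outside the inequity-aversion model
(reciprocity, reputation concern). Passing recovery and detection checks
therefore demonstrates internal consistency of the pipeline, not
validity of the behavioural model for real cohorts.

## What the standing checks show, and problem sizes

- *Sampler vs quadrature*: posterior means within 0.05 per parameter on
  3 seeded participants (long chains: 8 × 20 000 kept draws; lattice
  spacing 0.15).
- *Parameter recovery*: Pearson r between truth and posterior means over
  100 agents at fixed λ = 5 kJPY⁻¹. At these conditions the measured r
  is ≈ 0.70–0.75 for both parameters. This is an information ceiling of
  the design, not a sampler artefact: with the prior set equal to the
  generative truth distribution (the Bayes-optimal estimator) r is
  0.74/0.75, and the quadrature posterior shows β posterior sds of
  0.2–0.7 — at λ = 5, agents with β anywhere below 1 behave
  near-selfishly, so the likelihood is flat over much of the truth
  range. Near-deterministic agents (λ = 20) recover at r ≈ 0.83–0.91.
- *Type-I error*: three-gene ANCOVA on true AIA under the null, 500
  replicates at n = 200; factor-level false-positive rate 5% ± 2%.
- *Detection power*: full simulate → fit → associate replicates at
  n = 420 with the RS3 effect calibrated to partial η² ≈ 0.023 on fitted
  AIA. At that effect size the three-gene ANCOVA has ≈ 80% power per
  replicate, so the observed detection rate over 20 replicates is itself
  a binomial draw around 0.8. Replicate fits use 3 chains × 1500 kept
  draws; the extra Monte-Carlo noise on posterior means (< 0.05) is
  negligible against the ≈ 0.49 posterior width, though about half the
  fits sit just under the strict ESS flag threshold at this chain length
  (R-hat stays fine; flagged fits are kept, as always).

## Numerical choices

- Softmax stabilised by per-context max subtraction; no overflow for
  λU up to ±700 and beyond.
- Ties in the deterministic (λ → ∞) choice break to the lowest option
  label, for reproducibility.
- Grid quadrature uses trapezoid weights so boundary densities (the
  half-Normal mode at λ = 0) are not overcounted.
- HWE test on a monomorphic sample returns χ² = 0 with a warning.
- Truncated-Normal truth draws are clipped at the bounds; a zero scale
  is allowed and yields a point mass (used in degenerate-input tests).
- CSV dialect: UTF-8, comma-separated, header row, '.' decimal; JPY
  amounts stored as integers; the kJPY rescaling is internal.

## Known limitations

- Beliefs about co-players in simultaneous-move games are fixed
  configuration, not estimated; fitted α, β are conditional on them.
- The per-participant fit has no pooling across participants; weakly
  informative priors stand in for a hierarchy.
- Pairwise contrasts evaluate covariate-adjusted means at the grand mean
  with equal level weights; other adjusted-means conventions (e.g.
  frequency-weighted margins) would differ slightly in unbalanced data.
- At realistic choice noise (λ ≈ 5) individual-level preference
  estimates carry posterior sds comparable to the population spread;
  cohort-level associations remain unbiased but are attenuated, which is
  why effect calibration works on the fitted-estimate scale.
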