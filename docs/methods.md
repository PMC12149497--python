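# Methods

This note documents the models, algorithms and design choices behind
`feedpattern`. It is written for a reader who wants to know exactly what the
package computes and what its validation does — and does not — demonstrate.

## The feeding-pattern phenotype

Automated feeders record, per bunk visit, the entry/exit timestamps and the
feed weight at entry and exit. The within-day feeding pattern of a cow is
summarised by one number per cow-day:

1. Visits of all cows in a pen are ordered in time; **Time 0** is the first
   visit by any cow at or after the morning fresh-feed delivery (the lockout
   that precedes delivery guarantees a pen-wide silence, so the first
   post-delivery visit is well defined).
2. Each visit's intake (kg) is divided by the cow's total intake that day,
   giving intake proportions.
3. The cumulative proportion curve is anchored at (0, 0) and (86 400 s, 1)
   and integrated by the trapezoid rule.

The resulting **AUC** is measured in seconds: a perfectly uniform eater
scores exactly 43 200 (half a day); intake concentrated just after delivery
pushes the AUC toward its upper bound, deferred feeding pulls it down. Two
per-cow phenotypes summarise the daily values: the mean daily AUC (**AUC**,
the feeding pattern) and the natural log of the sample variance of daily AUC
(**log-Var-dAUC**, day-to-day consistency; logged for approximate normality
in the genetic model).

Cleaning follows the standard funnel: visits with as-fed intake ≤ 0 or
> 20 kg, or duration < 5 s or > 3000 s, are removed (retained sets are
(0, 20] kg and [5, 3000] s — the removal conditions are read literally as
strict inequalities, so boundary values stay); cow-days with fewer than 5
visits or total intake ≤ 12 or > 115 kg are removed; within cow, days whose
AUC sits more than 3.5 sample SDs from the cow's mean AUC over the whole
period are removed in a single pass (the mean and SD are not re-estimated
after removals). Cows need at least `min_days` retained days (default 20,
configurable) before their phenotypes are computed; the sample (n−1)
variance is used for log-Var-dAUC, and a cow whose retained days are all
identical (variance exactly zero) is flagged and excluded from the
log-variance analysis rather than given a −∞ phenotype.

Two points the procedure leaves open were fixed as follows. The curve
abscissa of a visit is its **exit** time offset from Time 0 — the intake of
a visit is only realised (weighed) at exit. And the integration horizon is
fixed at 86 400 s regardless of the actual spacing of consecutive Time 0
anchors, which keeps AUC values commensurable across days and makes the
uniform construction integrate to exactly 43 200.

## Feed-efficiency traits

Weekly secreted milk energy (Mcal) is
`(0.0929·fat% + 0.0563·protein% + 0.0395·lactose%) · milk yield (kg)`,
averaged over weeks per cow (**MilkE**). Body weights are completed by a
per-cow ordinary least-squares line of BW on trial day; **metabolic BW** is
the mean of daily BW^0.75 (read literally as the average of the powered
values; the difference from powering the average is < 0.1 % at realistic
within-cow variation), and **ΔBW** is the difference of the fitted line's
endpoints over the trial (robust to single-day scale noise, which raw
first/last weighings are not). **RFI** is the residual of the OLS regression

    DMI = DIM class + lactation + cohort + b1·MilkE + b2·mBW + b3·ΔBW + e

with reference-level factor coding and an explicit intercept (residuals are
invariant to the coding). The DIM classes are the printed 16-day bins
50–66 … 169–185 plus an open top class; day 186, which the printed bins skip,
is assigned to the top class. A rank-deficient design (e.g. a cohort
confounded with another factor) raises an error naming the aliased columns.

## The animal model and its Gibbs sampler

For one trait, `y = Xb + Zu + e`, with flat priors on `b`,
`u ~ N(0, A σ²a)` where A is the numerator relationship matrix of the traced
pedigree (five generations back from the phenotyped cows by default), and
`e ~ N(0, I σ²e)`. A⁻¹ is assembled directly by Henderson's rules with
inbreeding coefficients from the recursive L·D·L′ traversal; the dense
tabular A is kept for small-pedigree cross-checks (A·A⁻¹ = I is a standing
property test).

Sampling alternates (i) a Gauss–Seidel sweep drawing every location effect
from its scalar normal full conditional over the sparse mixed-model
equations, and (ii) conjugate variance draws — scaled inverse chi-square for
σ²a (shape from the number of pedigree animals, scale from u′A⁻¹u) and for
σ²e (from the residual sum of squares). The prior on both variances is flat
(ν = −2, zero scale). The coefficient matrix keeps one sparsity pattern
across iterations; only the variance ratio rescales the A⁻¹ entries, so a
sweep costs O(nnz) with no factorisation. The sweep kernel is compiled
(numba), which makes a 40 000-iteration chain on ~1 400 pedigree animals a
matter of seconds on one core.

The bivariate model stacks two traits with
`[u1; u2] ~ N(0, G0 ⊗ A)` and `[e1; e2] ~ N(0, R0 ⊗ I)` on complete cases
(both traits observed on the same cows; the traits may carry different
fixed-effect designs — RFI enters with an intercept only, because its
phenotype is already adjusted for lactation, DIM and cohort). G0 and R0 are
drawn from inverse Wisharts on the genetic and residual cross-products.
Two implementation details matter here:

* **Per-animal 2×2 block updates.** The two genetic effects of one animal
  are drawn jointly from their bivariate normal full conditional. With
  scalar updates they are so strongly coupled through G0 that the sampled
  genetic correlation moves extremely slowly.
* **Flat priors on G0 and R0** (ν = −3 for two traits, zero scale),
  mirroring the univariate default. This is a deliberate deviation from the
  common "minimally informative" inverse Wishart IW(p+1, εI): that prior's
  density diverges at singular matrices, and inside a Gibbs chain the
  divergence acts as an absorbing boundary — in testing, chains for a
  low-heritability trait collapsed (g₁₁ → 0 with the sampled correlation
  pinned at ±0.99) under IW(3, 10⁻³I), and an independent dense block-Gibbs
  reference implementation collapsed identically, confirming the prior
  rather than the sweep as the cause. With flat priors recovery is unbiased
  across all truth settings tested. Both priors remain configurable.

Heritability and the genetic correlation are computed per retained sample
and then summarised (posterior mean, SD, and the shortest 90 % highest
posterior density interval). Chain defaults are 100 000 iterations with
20 000 burn-in; thinning (default 10) is applied to bivariate chains, and is
available but off for univariate ones. Convergence diagnostics cover the
Geweke first-10 %-vs-last-50 % z score with Bartlett-window spectral
variances, the Heidelberger–Welch stationarity test (Cramér–von Mises
statistic on the standardised cumulative-sum bridge, discarding the front of
the chain in 10 % steps and rejecting if less than half the chain would
remain), and the Gelman–Rubin potential scale reduction factor across ≥ 2
chains (clipped at 1 from below).

## The synthetic-data generator

No public dataset accompanies this analysis, so the generator is a
first-class part of the package, emulating each input at the level of
structure the methods consume.

**Pedigree and genetics.** Discrete non-overlapping generations: founders,
then a fixed number of offspring per generation with parents drawn from the
previous one (random, or hierarchical with paternal half-sib blocks).
Breeding values descend the pedigree: founders ~ N(0, G0); non-founders get
the parent average plus a Mendelian-sampling deviation with variance
`0.5·(1 − 0.5(F_s + F_d))` per unit genetic variance, with exact inbreeding
coefficients — so simulated pair covariances reproduce A·σ²a entry for
entry, a property tested against the tabular A. Phenotypes add drawn
factor-level effects (lactation, DIM class, cohort) and independent
residuals.

**Visit streams.** Within-day visit times follow an exponential eating
intensity anchored at the two deliveries (11:00 and 17:00 with an hour's
lockout): intensity `exp(−θ·(t − last delivery))`, zero during lockout.
θ > 0 concentrates intake after delivery, θ < 0 defers it, θ = 0 is uniform.
Visits sit at the intensity's quantiles; intakes are a Dirichlet split of
the daily total with one dominant post-delivery meal, rejected until every
visit respects the 20 kg cap. Because the pipeline-computed AUC is monotone
in θ, each cow-day is calibrated by bisection to a target AUC. The map has
small jumps where a visit quantile crosses the lockout gap, so calibration
accepts the nearest attainable placement and fails beyond 600 s. Default
day structure follows the herd averages the methods were built around: ~31
visits and ~43.8 kg per cow-day, cow-mean AUC near 56 000 s. Emitted logs
pass the visit filters by construction; fault injection (zero intakes,
oversized meals, out-of-range durations) is opt-in for negative tests.

**Efficiency records.** Weekly milk components at Holstein mid-lactation
means (fat 4.0 %, protein 3.2 %, lactose 4.8 %, yield 40 kg — giving MilkE
near 29.6 Mcal), a BW series as line + noise measured on a configurable
weighing schedule, and DMI generated from the RFI model's own right-hand
side (b1 = 0.35 kg/Mcal, b2 = 0.09 kg/kg^0.75, b3 = 0.02, true-RFI SD
1.63 kg, herd-mean DMI 24.8 kg with the intercept derived from the covariate
means rather than hard-coded).

What the generator does **not** emulate: pen social dominance and feeder
competition, diet and season effects, station-to-station measurement
systems, selection or assortative mating in the pedigree, and heterogeneous
residual variances. Passing recovery tests therefore show that the
estimation machinery is correct under the stated model, not that the model
captures every feature of real feeder data.

## Validation studies and problem sizes

The recovery studies simulate herds at the published genetic parameters
(heritabilities 0.35 and 0.16 for the two feeding-pattern phenotypes;
genetic correlations 0.47 with DMI and −0.30 with MilkE) and re-estimate
them: ~1 200 phenotyped cows over five generations with 40 000/8 000
univariate chains, and ~800 cows with 30 000/6 000 thinned bivariate chains.
At these sizes a single herd's data-realisation noise is of the same order
as the published posterior SDs, so each study averages the posterior means
of five independent replicate herds — chain settings per replicate unchanged
— which isolates what the estimator recovers from what one finite herd
happens to show. Across seeds, replicated recoveries land within ~0.02 of
the univariate truths and ~0.05 of the bivariate ones. Bias checks over
eight independent herds put the mean posterior-mean h² within 0.003 of the
truth at both variance-component settings.

Numerical details worth knowing: variance chains start from an equal split
of the phenotypic variance; location effects start at zero; the inverse
Wishart draw uses the conjugate update IW(ν₀ + q, V₀ + cross-products);
duplicate curve abscissae (two visits in the same second) contribute
zero-width trapezoids and are harmless; a visit beyond the 86 400 s horizon
(possible when a delivery slips late) is clamped onto the horizon with its
intake retained.
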