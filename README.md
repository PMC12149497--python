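# feedpattern

Within-day **feeding-pattern phenotyping** from automated-feeder visit logs,
**feed-efficiency trait derivation**, and **Bayesian pedigree animal-model
genetics** for lactating dairy cattle — with a synthetic-data generator so
the whole chain is testable without proprietary feeder data.

Dairy research stations record every bunk visit of every cow: entry and exit
times, and the feed weight before and after. Classical behaviour traits
(visits per day, intake per visit) ignore *when* during the day a cow eats.
This package implements a phenotype that captures the whole daily
trajectory: each visit's intake is expressed as a proportion of the cow's
daily total, the cumulative proportion curve is anchored at Time 0 (the
first pen visit after morning feed delivery) and at 24 h, and its area under
the curve (AUC, in seconds) is computed by the trapezoid rule,

> AUC = Σₖ (tₖ₊₁ − tₖ)(cₖ + cₖ₊₁)/2,  0 ≤ AUC ≤ 86 400,

so a uniform eater scores exactly 43 200 s, an early aggressive eater more,
a deferrer less. Per cow, the phenotypes are the mean daily AUC and the log
variance of daily AUC (day-to-day consistency). Genetic analysis uses the
animal model y = Xb + Zu + e with u ~ N(0, A σ²ₐ) on a pedigree traced five
generations back, estimated by Gibbs sampling (scaled inverse chi-square /
inverse Wishart variance draws; heritabilities and genetic correlations
summarised per sample with 90 % HPD intervals). Feed-efficiency traits
(secreted milk energy, metabolic body weight, ΔBW, residual feed intake)
are derived exactly as a feed-efficiency consortium computes them, so the
genetic correlations between feeding patterns and efficiency are estimable
end to end.

Intended users: quantitative geneticists and feeding-behaviour researchers
working with automated-feeder (e.g. roughage intake control) data.

## Worked example

Compute the phenotype for one cow-day (first visits 0.4, 0.2 and 5.3 kg of
a 43.8 kg day, shortly after delivery):

```python
import numpy as np
from feedpattern.pattern import cumulative_curve
from feedpattern.sim import uniform_day

offsets = [600, 1200, 1800, 14_000, 30_000, 55_000]   # s after Time 0
intakes = [0.4, 0.2, 5.3, 20.0, 12.0, 5.9]            # kg per visit
curve = cumulative_curve("cow42", 0, offsets, intakes)
print(f"first proportions: {np.round(np.diff(curve.cumprops)[:3], 3)}")
print(f"AUC = {curve.auc:,.0f} s")
u_off, u_int = uniform_day(24, curve.total_intake_kg)
print(f"uniform eater:   AUC = {cumulative_curve('u', 0, u_off, u_int).auc:,.0f} s")
```

```
first proportions: [0.009 0.005 0.121]
AUC = 70,852 s
uniform eater:   AUC = 43,200 s
```

The first proportions are 0.009, 0.005 and 0.121 of the daily total, and
this cow concentrates intake early (AUC well above the uniform 43 200 s).

Estimate heritability on a synthetic herd simulated at a known truth
(additive and residual variances 1 315 780 and 2 421 331, i.e. h² = 0.352):

```python
from feedpattern.studies import univariate_recovery
from feedpattern.posterior import summarize

r = univariate_recovery(1_315_780.0, 2_421_331.0, n_cows=1200,
                        n_iter=40_000, burn_in=8_000, seed=7)
print(f"true h2 {r['h2_true']:.3f}  posterior-mean h2 {r['h2_mean']:.3f}")
print(summarize(r["chain"]).round(3).to_string())
```

```
true h2 0.352  posterior-mean h2 0.378
                  mean          sd      hpd_low     hpd_high
parameter
sigma2_a   1394554.027  215525.621  1039085.281  1739544.441
sigma2_e   2282442.628  165702.322  2011887.343  2553633.990
h2               0.378       0.049        0.300        0.460
```

The posterior mean lands within one posterior SD of the truth; averaging
over replicate herds (`replicates=5`) tightens the recovery further.

A command-line interface mirrors the stages:

```sh
feedpattern simulate --out-dir study/inputs --scale small --seed 1
feedpattern clean-visits --visits study/inputs/visits.csv --out clean.csv \
    --trials study/inputs/trials.csv --report cleaning.txt
feedpattern feeding-pattern --visits clean.csv --out phenotypes.csv
feedpattern h2 --phenotypes phenotypes.csv --pedigree study/inputs/pedigree.csv \
    --trait auc_mean --cows study/inputs/cows.csv --n-iter 40000 --burn-in 8000
feedpattern run-all --config config.yaml
```

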