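# gtpd

Exponential–gamma mixture lifetime distributions for positive data:
the **general two-parameter distribution** (GTPD) and its special case,
the **Gemeay distribution** (GD), with the estimation and benchmarking
machinery a survival/reliability analyst needs around them.

The GTPD has density

```
f(x; θ, k) = h(θ, k) (b(θ) + x^k) e^(−θx),      x > 0,
h(θ, k)    = θ^(k+1) / (θ^k b(θ) + Γ(k+1)),
```

which is a two-component mixture: with probability
z = θ^k b(θ)/(θ^k b(θ) + Γ(k+1)) an Exponential(θ), otherwise a
Gamma(k+1, θ).  Choosing b(θ) = θ⁻² gives the GD, a flexible two-parameter
model for right-skewed lifetime-type series whose hazard can be increasing
(k ≤ 1) or bathtub-shaped (k > 1).  The package targets practitioners
fitting short positive series (epidemiological rates, failure times) and
methodologists comparing estimation strategies for such families.

What's inside:

* `gtpd.distribution` — densities, CDF/survival/hazard, moments and
  derived measures (variance, non-central skewness/kurtosis ratios, CV,
  MGF, incomplete moments, mean residual life, Lorenz/Bonferroni curves),
  Rényi/Shannon entropy, quantiles, seeded sampling, density/hazard shape
  classification, likelihood-ratio-order checking.
* `gtpd.estimators` — ten classical estimators (MLE, ADE, RTADE, LTADE,
  CVME, LSE, WLSE, MPSE, MSADE, MSALDE) as objective functions plus a
  multi-start Nelder–Mead front-end on the log-parameter scale.
* `gtpd.simulation` — a seeded Monte-Carlo harness: BIAS/MSE/MRE per
  method and sample size, tie-averaged partial ranks, rank sums, and the
  overall cross-scenario ranking table.
* `gtpd.selection` — model comparison against classical baselines
  (exponential, Fréchet, Lindley, Lomax, half-logistic, Maxwell) by
  AIC/AICc/BIC/HQIC and Anderson–Darling / Cramér–von Mises /
  Kolmogorov–Smirnov statistics, plus TTT and P-P plot coordinates.
* `gtpd.io` / `gtpd.cli` — single-column series reader, seeded synthetic
  fixture generator, and the `gtpd` command line
  (`sample`, `fit`, `simulate`, `rank`, `gof`, `fixture`).

## Worked example

Generate a synthetic 30-value series from GD(θ=0.636297, k=3.12766) —
a law with mean 6.10, variance 11.34, a unimodal density and a bathtub
hazard (minimum near x = 0.76) — then fit it and compare candidate
models:

```
$ gtpd fixture --seed 42 --out demo.csv
$ gtpd fit demo.csv --method MLE
{
  "method": "MLE",
  "theta": 0.8424,
  "k": 3.5992,
  "standard_errors": [0.1586, 0.6774],
  ...
}
$ gtpd gof demo.csv
```

The goodness-of-fit report ranks the candidates by each criterion; for
this seed the table (sorted by AIC = Cr1) reads

```
     neg_loglik       Cr1       Cr3      G3    G3_p
GD      69.3354  142.6709  145.4733  0.1168  0.8076
MD      70.8451  143.6902  145.0914  0.1181  0.7965
LD      74.6717  151.3433  152.7445  0.1982  0.1895
HLD     75.6821  153.3643  154.7655  0.2383  0.0662
ED      79.3612  160.7224  162.1236  0.2797  0.0183
LoD     79.3612  162.7224  165.5248  0.2797  0.0183
FD      85.0660  174.1321  176.9345  0.2603  0.0343
```

GD attains the lowest negative log-likelihood, AIC and KS distance with a
KS p-value of 0.81: the generating family is recovered.  The maximum
likelihood estimates θ̂ = 0.84 (SE 0.16) and k̂ = 3.60 (SE 0.68) bracket
the generating parameters within sampling error at n = 30.

Benchmarking estimators on a scenario reproduces the Monte-Carlo
protocol (here at desk scale):

```
$ gtpd simulate --theta 0.5 --k 1.5 --sizes 30,150 --reps 500 \
      --methods mle,mpse,wlse --seed 1 --out sim/
$ gtpd rank sim/metrics.csv
```

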