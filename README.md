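# gebayes

Likelihood and approximate-Bayes estimation for the **generalised
exponential (GE) distribution** fitted to **randomly right-censored
survival data**, with a Monte-Carlo harness for comparing the estimators.

The package is aimed at biostatisticians and reliability analysts who
model time-to-event data parametrically: clinical follow-up studies where
patients are lost to follow-up or still alive at study end, and lifetime
tests where some units never fail during observation.

## Model

The GE (exponentiated exponential) law with scale θ > 0 and shape p > 0 has

    F(t) = (1 − e^{−θt})^p,   f(t) = pθ (1 − e^{−θt})^{p−1} e^{−θt},
    S(t) = 1 − F(t),          t ≥ 0.

For p = 1 it reduces to the exponential distribution; p < 1 gives a
decreasing hazard, p > 1 an increasing-then-plateauing hazard, which makes
the family a practical alternative to the Weibull and gamma for lifetime
data.

Under random (noninformative) censoring each subject has independent
failure time T and censoring time C; one observes tᵢ = min(Tᵢ, Cᵢ) and
δᵢ = 1{Tᵢ ≤ Cᵢ}. The likelihood is

    L(θ, p) = ∏ᵢ f(tᵢ)^{δᵢ} S(tᵢ)^{1−δᵢ}.

Five estimators of (θ, p) are provided:

* **ML** — maximisation of the censored log-likelihood (quasi-Newton on
  the log-parameter scale, analytic gradient), observed-information
  standard errors, Wald intervals.
* **Lindley-SEL / Lindley-LINEX** — Bayes point estimates under
  independent gamma priors π(θ) ∝ θ^{b−1}e^{−aθ}, π(p) ∝ p^{d−1}e^{−cp},
  via Lindley's two-parameter expansion of the posterior expectation
  about the MLE, using analytic first/second/third log-likelihood
  derivatives. Squared-error loss gives the expanded posterior mean;
  LINEX loss with parameter k gives −(1/k)·log of the expanded
  E[e^{−kα}] (k > 0 penalises overestimation more).
* **TK-SEL / TK-LINEX** — the same posterior functionals via the
  Tierney–Kadane Laplace-ratio approximation: two maximisations (of the
  scaled log-posterior ℓ and of the estimand-tilted surface ℓ*) and a
  Hessian-determinant ratio, with relative error O(1/n²).

A brute-force 2-D quadrature **oracle** computes the same posterior
expectations by adaptive Gauss–Legendre integration and serves as the
correctness authority for both approximations in the test suite. The
all-zero hyperparameter setting (an improper prior ∝ 1/(θp)) is supported
and flagged; posterior integrability is then checked empirically by the
oracle rather than assumed.

The **simulation** module draws GE lifetimes by inverse-CDF sampling,
censors them with Uniform(0, b) times — b calibrated by root-solving so
the expected censoring fraction hits a target — and tabulates Monte-Carlo
mean squared errors and mean absolute deviations for all five estimators.

## Worked example

Two clinical datasets ship with the package: `data1` (16 cervical-cancer
patients under radiotherapy alone, days, 5 censored) and `data2`
(121 breast-cancer patients, months, 56 censored).

```
$ gebayes fit --fixture data2
       method  loss_k parameter  estimate       sd  ci_lower  ci_upper  level  converged
           ML     NaN     theta  0.011768 0.002349  0.007165  0.016372   0.95       True
           ML     NaN         p  1.014238 0.152387  0.715564  1.312912   0.95       True
  Lindley-SEL     NaN     theta  0.011617 0.002344  0.007023  0.016210   0.95       True
  Lindley-SEL     NaN         p  1.006424 0.152187  0.708143  1.304705   0.95       True
Lindley-LINEX     0.7     theta  0.011615 0.002344  0.007021  0.016208   0.95       True
Lindley-LINEX     0.7         p  0.998385 0.152187  0.700104  1.296666   0.95       True
...
       TK-SEL     NaN         p  1.006633 0.152224  0.708279  1.304988   0.95       True
```

Reading: the ML shape estimate p̂ = 1.014 (SE 0.152) says the hazard of
these breast-cancer survival times is nearly exponential; the scale
θ̂ = 0.0118 month⁻¹ corresponds to a mean survival of roughly
1/0.0118 ≈ 85 months at p ≈ 1. With the noninformative prior the Bayes
posterior means sit slightly below the MLE (shrinkage from the 1/(θp)
prior), the two approximation routes agree to ~2×10⁻⁴, and the LINEX
estimates with k = +0.7 sit below the posterior means, as the asymmetry
of the loss dictates. The shape estimate is invariant to the time unit;
θ̂ scales inversely with it (`--time-scale`).

The Monte-Carlo comparison (defaults: n ∈ {25, 50, 100}, θ = 1,
p ∈ {0.8, 1.2, 2.0}, 25% expected censoring, 1000 replicates, k = ±0.7,
zero hyperparameters):

```
$ gebayes simulate --n 25 --p 2.0 --replicates 1000 --seed 1 --output study.csv
```

writes one tidy row per (n, true shape, estimator, loss, parameter) with
`mse`, `abs_bias`, the Monte-Carlo standard error of the MSE, the failure
count and the realised censoring fraction.

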