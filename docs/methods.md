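# Methods

## Model and likelihood

Lifetimes follow the generalised exponential law GE(θ, p) with
cdf F(t) = (1 − e^{−θt})^p. Censoring is random and noninformative:
C ⊥ T, the observed datum is (t, δ) = (min(T, C), 1{T ≤ C}), and the
censoring law drops out of the likelihood
∏ f(tᵢ)^{δᵢ} S(tᵢ)^{1−δᵢ}. δ is taken as given; ties between event and
censoring times need no special handling because δ = 1 encodes T ≤ C.
A time of 0 is accepted only for censored records (S(0) = 1); an event at
0 is rejected because the density is degenerate there for p ≠ 1.

Everything involving A = 1 − e^{−θt} is computed through
log(−expm1(−θt)), and censored terms log(1 − A^p) through the analogous
log/expm1 form, so the likelihood and its derivatives survive θt spanning
several orders of magnitude (the packaged day-scale data reach θt ≈ 17).

First, second and third partial derivatives of the log-likelihood in
(θ, p) are implemented in closed form. Writing L = log A, the event terms
reduce to polynomials in 1/θ, 1/p and the L-derivatives
L₁ = t e^{−θt}/A, L₂ = −t²e^{−θt}/A², L₃ = t³e^{−θt}(2−A)/A³; the
censored terms are chain-rule compositions of F(L, p) = log(1 − e^{pL}),
whose partials are rational in B/S, B/S², B(S+2B)/S³ with B = A^p,
S = 1 − B. The closed forms were derived once with symbolic assistance
and are locked by finite-difference tests (relative 10⁻⁴ on the third
order, 10⁻⁵/10⁻⁶ below).

## Maximum likelihood

Optimisation runs on (log θ, log p) — positivity for free, no constraint
handling — with the analytic gradient mapped by the chain rule; a
censored-exponential start θ₀ = Σδ/Σt, p₀ = 1 is augmented by a
three-point multistart p₀ ∈ {0.5, 1, 2} keeping the best log-likelihood.
Convergence is declared at gradient max-norm < 10⁻⁸ on the natural scale
(one Newton polish is applied if BFGS stops short). Standard errors use
the observed information — the expected information under random
censoring would require the unknown censoring law — and intervals are
Wald at a default 95%.

## Priors and losses

Independent gamma priors π(θ) ∝ θ^{b−1}e^{−aθ}, π(p) ∝ p^{d−1}e^{−cp}.
Note the convention: a and c are rate-like, b and d shape-like; the
prior gradient entering the Lindley expansion is
ρ = ((b−1)/θ − a, (d−1)/p − c). The all-zero setting is implemented
literally — prior ∝ 1/(θp), ρ = (−1/θ, −1/p) — and flagged improper;
propriety of the resulting posterior is an empirical matter that the
quadrature oracle verifies per sample (its boundary-mass check fails
loudly on a non-integrable posterior).

Squared-error loss yields the posterior mean. LINEX loss
exp(kΔ) − kΔ − 1 yields −(1/k) log E[e^{−kα}]; k > 0 penalises
overestimation. A non-positive approximated moment is raised as an
error, never clipped.

## Lindley expansion

E[u | data] ≈ u + ½ Σᵢⱼ (uᵢⱼ + 2uᵢρⱼ)σᵢⱼ + ½ Σᵢⱼₖₗ lᵢⱼₖ σᵢⱼ σₖₗ uₗ,
every index over both parameters (all 2⁴ third-order combinations kept),
σ the negative inverse log-likelihood Hessian, everything evaluated at
the MLE. The MLE — not the posterior mode — is the expansion point; that
is the variant in which σ comes from the likelihood Hessian alone, with
the prior entering only through ρ. Relative error is O(1/n²) for smooth
estimands.

Posterior standard deviations come from the same expansion applied to
θ² and p²: sd = √(E[α²] − E[α]²). This second-moment convention is a
package choice (there is no canonical "standard error" for an expansion
estimate); it is isolated in one function and mirrored exactly by the
Tierney–Kadane module so the two columns of any comparison are
commensurable. The variance difference cancels leading terms, so this
quantity needs moderate n — at n = 50 it can sit 15% from the oracle
value, at n = 400 within a few percent — and the reported Bayes SDs
should be read accordingly.

## Tierney–Kadane ratio

For a positive estimand v, ℓ = (1/n)(log prior + log lik) and
ℓ* = ℓ + (1/n) log v are maximised separately and

E[v] ≈ √(det Σ*/det Σ) · exp{n[ℓ*(α̂*) − ℓ(α̂)]},

Σ, Σ* the negative inverse Hessians at the two maximisers. Leading
Laplace errors cancel in the ratio, giving O(1/n²) relative error with
only second derivatives.

Design choices:

* **Per-parameter starred surfaces.** Each tabulated quantity gets its
  own tilt: log θ for E[θ], log p for E[p], −kα for the LINEX moments,
  2 log α for second moments. A joint tilt log θ + log p is exposed
  separately (`tk_joint_product_expectation`) but approximates E[θp],
  not the individual means, and is not used by the estimators.
* **Warm starts and Newton polish.** ℓ* is maximised from the maximiser
  of ℓ (the surfaces differ by O(1/n)). Because the ratio exponentiates
  a height *difference* and the determinants are not stationary at the
  optimum, both maximisers are polished by Newton steps with the
  analytic Hessian; near the optimum small steps are accepted without a
  value guard, since height changes there fall below float resolution
  while the determinant ratio still needs the position. Without this,
  residual position error of ~10⁻⁸ is amplified by 1/k in the k → 0
  LINEX limit.
* **Determinant ratio in log space** via eigenvalues of the negated
  Hessians, each checked positive definite.

Two facts about the method worth knowing when reading outputs: the
k → ±0 LINEX estimates collapse onto a common limit, but that limit
differs from the log-tilted SEL value by a genuine O(α/n²) term
(≈ 5×10⁻⁴ for the shape on the n = 121 dataset, ≈ 10⁻² at n = 25), since
the two functionals use differently tilted surfaces; and the Jensen
ordering LINEX(k>0) ≤ SEL ≤ LINEX(k<0), exact for the true posterior,
holds for the approximations only down to that same resolution — on the
day-scale dataset, where kθ ≈ 7×10⁻⁴, the ordering for θ is decided by
approximation noise. Tests assert these properties at the method's
resolution, 10⁻⁵(1 + |α|) for orderings and 30·max(1, α)/n² for the
k → 0 limit.

In the shape-known exponential sub-model (p = 1, Gamma prior on θ) the
same ratio construction is available in closed form
(`tk_expectation_exponential`) and is tested against the conjugate
posterior mean (b + Σδ)/(a + Σt) and LINEX moment
((a + Σt)/(a + Σt + k))^{b+Σδ}; the LINEX case is exact because the tilt
only shifts the gamma rate.

## Quadrature oracle

Posterior expectations are also computed by brute force:
tensor-product Gauss–Legendre quadrature in (log θ, log p) over a box
centred at the MLE with half-widths 10 standard errors on the log scale.
The log parameterisation makes positivity automatic and absorbs the
1/(θp) of the improper prior into the Jacobian. Nodes per axis double
(64 → 512) until successive values agree within tolerance (default
10⁻⁸ relative), and the box grows by factors of 1.5 if more than a
negligible fraction of posterior mass sits in its outer shell; failure
of either loop raises instead of returning a silently wrong value. The
oracle is the authority the approximation modules are tested against,
including a one-dimensional variant for conjugate sub-model checks.

## Synthetic data and the comparison study

Lifetimes are inverse-CDF draws T = −log(1 − U^{1/p})/θ. Censoring times
are Uniform(0, b) with b solving P(C < T) = (1/b)∫₀ᵇ S(c) dc = target
fraction by Brent root-search — the one definition under which b depends
only on the GE parameters and the fraction. The study defaults are the
reference conditions: n ∈ {25, 50, 100}, θ = 1, p ∈ {0.8, 1.2, 2.0},
25% expected censoring, 1000 replicates, k = ±0.7, all hyperparameters
zero. Per replicate all five estimators are fitted; replicates where an
optimiser or approximation fails are dropped and counted (a cell with
> 20% failures carries a warning), and the realised censoring fraction
is logged per cell. Reproducibility comes from one SeedSequence stream
per (n, shape, replicate), spawned from the master seed with a
documented key, so results are bit-identical regardless of evaluation
order.

What the generator emulates: independent uniform censoring with a known
expected fraction acting on homogeneous GE lifetimes. What it does not:
covariate structure, informative or administrative censoring, ties from
coarse measurement, or model misspecification — so passing tests say the
estimators work when the model is true, not that the GE family fits any
particular dataset.

Uniform censoring at a 25% expected fraction costs real information:
ML mean squared errors under it run some 30–50% above their uncensored
counterparts at the same n (e.g. ≈ 0.033 vs ≈ 0.022 for the scale at
n = 100, p = 0.8). Comparisons of censored results against uncensored
baselines will show exactly this gap.

Problem sizes in the test suite are chosen for determinism and runtime:
the two Monte-Carlo reference cells run at the full 1000 replicates with
the ML estimator; the all-estimator structural check (MSE decreasing
in n) runs at 300 replicates over n ∈ {25, 100} and p ∈ {0.8, 2.0}.

## Real-data notes

The packaged datasets are stored exactly as printed in their clinical
listings (days for `data1`, months for `data2`), censoring marked as in
the listings. Shape estimates are invariant to the time unit; scale
estimates transform inversely (`--time-scale` on the CLI makes the
choice explicit). The `data2` fit (p̂ ≈ 1.01) says these survival times
are close to exponential; the `data1` fit (p̂ ≈ 1.31, SE 0.50) is
essentially uninformative about the hazard shape at n = 16. Fixture
checksums are pinned in the tests so the packaged records cannot drift
silently.

## Known limitations

* Both approximations assume a well-separated interior posterior mode
  with negative-definite Hessians; heavily censored tiny samples can
  violate this, which surfaces as a counted failure, not a wrong number.
* Lindley/TK posterior SDs are second-moment constructions with the
  accuracy caveats above; they are comparison devices, not calibrated
  uncertainty intervals.
* The oracle's box-plus-refinement design is specific to two dimensions;
  it is an arbiter for this model, not a general integrator.
* No covariates, no alternative lifetime families, no bootstrap or
  profile intervals.
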