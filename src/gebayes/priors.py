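"""Gamma priors and loss-function machinery shared by the Bayes estimators.

The scale and shape parameters carry independent gamma priors

    pi(theta) ∝ theta**(b-1) * exp(-a*theta)
    pi(p)     ∝ p**(d-1)     * exp(-c*p)

Note the convention: ``a`` and ``c`` multiply the parameter inside the
exponential (rate-like), ``b`` and ``d`` appear as exponent + 1
(shape-like).  Setting a = b = c = d = 0 yields the improper prior
∝ 1/(theta*p), which is flagged as such rather than rejected; whether the
resulting posterior is proper for a given sample is an empirical question
answered by the quadrature oracle.

Two losses are supported: squared error (SEL), whose Bayes estimator is
the posterior mean, and LINEX with asymmetry parameter k != 0, whose
Bayes estimator is ``-(1/k) * log E[exp(-k*alpha)]``.  ``k > 0`` penalises
overestimation more heavily than underestimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .distribution import GEParams

__all__ = [
    "GammaPriors",
    "LossSpec",
    "EstimandTransform",
    "log_prior",
    "log_prior_gradient",
    "log_prior_hessian_diag",
    "linex_point_estimate",
    "sel_transform",
    "linex_transform",
    "second_moment_transform",
]


@dataclass(frozen=True)
class GammaPriors:
    """Hyperparameters (a, b) for the scale prior and (c, d) for the shape prior."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"hyperparameter {name} must be >= 0, got {v}")

    @property
    def improper(self) -> bool:
        """True when the prior does not integrate (e.g. the all-zero setting)."""
        return (self.b <= 0 or self.a <= 0) or (self.d <= 0 or self.c <= 0)


@dataclass(frozen=True)
class LossSpec:
    """Loss under which a Bayes point estimate is taken: SEL or LINEX(k)."""

    kind: str = "SEL"
    k: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("SEL", "LINEX"):
            raise ValueError(f"loss kind must be 'SEL' or 'LINEX', got {self.kind!r}")
        if self.kind == "LINEX":
            if self.k is None or self.k == 0 or not np.isfinite(self.k):
                raise ValueError("LINEX loss requires a finite nonzero k")
        elif self.k is not None:
            raise ValueError("k is only meaningful for LINEX loss")


@dataclass(frozen=True)
class EstimandTransform:
    """A scalar estimand u(theta, p) with the partials the Lindley expansion needs.

    Cross partials are zero for every estimand used here (each u depends on
    a single parameter), so only u1 = du/dtheta, u2 = du/dp and the pure
    second partials are carried.
    """

    u: Callable[[float, float], float]
    u1: Callable[[float, float], float]
    u2: Callable[[float, float], float]
    u11: Callable[[float, float], float]
    u22: Callable[[float, float], float]


def sel_transform(which: str) -> EstimandTransform:
    """Identity estimand for the posterior mean of theta or p."""
    if which == "theta":
        return EstimandTransform(
            u=lambda th, p: th,
            u1=lambda th, p: 1.0, u2=lambda th, p: 0.0,
            u11=lambda th, p: 0.0, u22=lambda th, p: 0.0,
        )
    if which == "p":
        return EstimandTransform(
            u=lambda th, p: p,
            u1=lambda th, p: 0.0, u2=lambda th, p: 1.0,
            u11=lambda th, p: 0.0, u22=lambda th, p: 0.0,
        )
    raise ValueError(f"unknown parameter {which!r}")


def linex_transform(which: str, k: float) -> EstimandTransform:
    """Exponential estimand exp(-k*alpha) whose expectation drives LINEX."""
    if k == 0:
        raise ValueError("LINEX k must be nonzero")
    if which == "theta":
        return EstimandTransform(
            u=lambda th, p: math.exp(-k * th),
            u1=lambda th, p: -k * math.exp(-k * th),
            u2=lambda th, p: 0.0,
            u11=lambda th, p: k * k * math.exp(-k * th),
            u22=lambda th, p: 0.0,
        )
    if which == "p":
        return EstimandTransform(
            u=lambda th, p: math.exp(-k * p),
            u1=lambda th, p: 0.0,
            u2=lambda th, p: -k * math.exp(-k * p),
            u11=lambda th, p: 0.0,
            u22=lambda th, p: k * k * math.exp(-k * p),
        )
    raise ValueError(f"unknown parameter {which!r}")


def second_moment_transform(which: str) -> EstimandTransform:
    """Estimand alpha**2, used for posterior standard deviations."""
    if which == "theta":
        return EstimandTransform(
            u=lambda th, p: th * th,
            u1=lambda th, p: 2.0 * th, u2=lambda th, p: 0.0,
            u11=lambda th, p: 2.0, u22=lambda th, p: 0.0,
        )
    if which == "p":
        return EstimandTransform(
            u=lambda th, p: p * p,
            u1=lambda th, p: 0.0, u2=lambda th, p: 2.0 * p,
            u11=lambda th, p: 0.0, u22=lambda th, p: 2.0,
        )
    raise ValueError(f"unknown parameter {which!r}")


def log_prior(priors: GammaPriors, params: GEParams) -> float:
    """Joint log prior density up to an additive constant."""
    th, p = params.theta, params.p
    return float(
        (priors.b - 1.0) * math.log(th) - priors.a * th
        + (priors.d - 1.0) * math.log(p) - priors.c * p
    )


def log_prior_gradient(priors: GammaPriors, params: GEParams) -> np.ndarray:
    """The prior-gradient pair (rho_1, rho_2) entering the Lindley expansion."""
    th, p = params.theta, params.p
    return np.array(
        [(priors.b - 1.0) / th - priors.a, (priors.d - 1.0) / p - priors.c]
    )


def log_prior_hessian_diag(priors: GammaPriors, params: GEParams) -> np.ndarray:
    """Diagonal of the log-prior Hessian (off-diagonals are zero)."""
    th, p = params.theta, params.p
    return np.array([-(priors.b - 1.0) / th**2, -(priors.d - 1.0) / p**2])


def linex_point_estimate(expectation: float, k: float) -> float:
    """Map an approximated E[exp(-k*alpha)] to the LINEX point estimate."""
    if k == 0:
        raise ValueError("LINEX k must be nonzero")
    if not (np.isfinite(expectation) and expectation > 0):
        raise ValueError(
            f"E[exp(-k*alpha)] must be positive and finite, got {expectation}"
        )
    return -math.log(expectation) / k
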