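"""Generalised exponential (exponentiated exponential) distribution.

The GE(theta, p) law has cdf ``F(t) = (1 - exp(-theta*t))**p`` for t >= 0,
with scale ``theta > 0`` (inverse time units) and shape ``p > 0``.  For
``p = 1`` it reduces to the exponential distribution with rate theta.

This module also provides the log-likelihood for randomly right-censored
samples — each subject contributes ``f(t)`` if the event was observed and
``S(t)`` if censored — together with its analytic gradient, Hessian and
third-order partial derivatives in (theta, p).  The higher-order
derivatives feed the Lindley posterior expansion and the Laplace-ratio
Hessians downstream.

All quantities involving ``(1 - exp(-theta*t))**p`` are evaluated through
``log(-expm1(-x))`` so that nothing underflows when ``theta*t`` is large
or loses digits when it is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GEParams",
    "SurvivalSample",
    "DerivativeBundle",
    "ge_cdf",
    "ge_pdf",
    "ge_survival",
    "ge_quantile",
    "censored_loglik",
    "loglik_derivatives",
]


@dataclass(frozen=True)
class GEParams:
    """Parameter pair of the GE law: scale ``theta`` and shape ``p``."""

    theta: float
    p: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"scale parameter theta must be positive, got {self.theta}")
        if not (np.isfinite(self.p) and self.p > 0):
            raise ValueError(f"shape parameter p must be positive, got {self.p}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.p], dtype=float)


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data: times t_i and event indicators delta_i.

    ``events[i] == 1`` means the failure was observed at ``times[i]``;
    ``0`` means the subject was censored there (the failure time exceeds
    ``times[i]``).  A time of exactly zero is only admissible for a
    censored record: the GE density at 0 is degenerate for p < 1.
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if times.size == 0:
            raise ValueError("sample must contain at least one record")
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        if np.any((times == 0) & (events == 1)):
            raise ValueError("an observed event at time 0 is not supported")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int8))

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events


@dataclass(frozen=True)
class DerivativeBundle:
    """Censored log-likelihood value with partial derivatives in (theta, p).

    ``gradient`` is (l_theta, l_p); ``hessian`` is the symmetric 2x2 matrix
    of second partials; ``third`` is the symmetric 2x2x2 tensor of third
    partials (invariant under any permutation of indices).
    """

    loglik: float
    gradient: np.ndarray
    hessian: np.ndarray
    third: np.ndarray | None = field(default=None)


def _validate_t(t, allow_zero: bool = True) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if np.any(t < 0) or (not allow_zero and np.any(t <= 0)):
        raise ValueError("time values out of domain")
    return t


def _log_A(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(-x)) for x > 0, stable at both ends."""
    with np.errstate(divide="ignore"):
        return np.log(-np.expm1(-x))


def ge_cdf(params: GEParams, t) -> np.ndarray | float:
    """GE distribution function ``(1 - exp(-theta t))**p``."""
    t = _validate_t(t)
    x = params.theta * t
    with np.errstate(divide="ignore"):
        out = np.exp(params.p * _log_A(x))
    out = np.where(x == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def ge_pdf(params: GEParams, t) -> np.ndarray | float:
    """GE density ``p theta (1 - exp(-theta t))**(p-1) exp(-theta t)``."""
    t = _validate_t(t, allow_zero=False)
    x = params.theta * t
    log_pdf = (
        np.log(params.p)
        + np.log(params.theta)
        + (params.p - 1.0) * _log_A(x)
        - x
    )
    out = np.exp(log_pdf)
    return out if out.ndim else float(out)


def ge_survival(params: GEParams, t) -> np.ndarray | float:
    """GE survival function ``1 - (1 - exp(-theta t))**p``."""
    t = _validate_t(t)
    x = params.theta * t
    out = -np.expm1(params.p * _log_A(x))
    out = np.where(x == 0.0, 1.0, out)
    return out if out.ndim else float(out)


def ge_quantile(params: GEParams, u) -> np.ndarray | float:
    """Inverse cdf: ``-log(1 - u**(1/p)) / theta`` for u in [0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1) or not np.all(np.isfinite(u)):
        raise ValueError("probability u must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        out = -np.log1p(-np.exp(np.log(u) / params.p)) / params.theta
    out = np.where(u == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def censored_loglik(params: GEParams, sample: SurvivalSample) -> float:
    """Random-censoring log-likelihood sum(d_i log f + (1-d_i) log S)."""
    theta, p = params.theta, params.p
    t = sample.times
    d = sample.events.astype(bool)
    x = theta * t

    ll = 0.0
    if d.any():
        xe = x[d]
        if np.any(xe == 0.0):
            raise ValueError("event at time 0 has no finite density contribution")
        ll += np.sum(np.log(p) + np.log(theta) + (p - 1.0) * _log_A(xe) - xe)
    if (~d).any():
        xc = x[~d]
        log_surv = np.where(xc == 0.0, 0.0, np.log(-np.expm1(p * _log_A(xc))))
        ll += np.sum(log_surv)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite censored log-likelihood")
    return float(ll)


def loglik_derivatives(
    params: GEParams, sample: SurvivalSample, order: int = 3
) -> DerivativeBundle:
    """Analytic partial derivatives of the censored log-likelihood.

    Returns the value, gradient, Hessian and (for ``order == 3``) the full
    symmetric tensor of third partials.  Writing ``A = 1 - exp(-theta t)``,
    ``L = log A`` and per censored record ``B = A**p``, ``S = 1 - B``, every
    term reduces to powers of ``exp(-x - k log A)`` and ``B / S**k``, which
    are the forms evaluated here.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    theta, p = params.theta, params.p
    t = sample.times
    d = sample.events.astype(bool)
    x = theta * t
    if np.any((x == 0.0) & ~d):
        # censored at t=0 contributes log S(0) = 0 identically
        keep = ~((x == 0.0) & ~d)
        t, d, x = t[keep], d[keep], x[keep]

    logA = _log_A(x)
    A = -np.expm1(-x)
    # derivatives of L = log A with respect to theta
    L1 = t * np.exp(-x - logA)
    L2 = -(t**2) * np.exp(-x - 2.0 * logA)
    L3 = (t**3) * np.exp(-x - 3.0 * logA) * (2.0 - A)

    te, tc = t[d], t[~d]
    L1e, L2e, L3e = L1[d], L2[d], L3[d]
    L1c, L2c, L3c = L1[~d], L2[~d], L3[~d]
    Lc = logA[~d]
    ne = int(d.sum())

    # event contributions
    ll = float(
        np.sum(np.log(p) + np.log(theta) + (p - 1.0) * logA[d] - x[d])
    )
    g_t = ne / theta + (p - 1.0) * L1e.sum() - te.sum()
    g_p = ne / p + logA[d].sum()
    g_tt = -ne / theta**2 + (p - 1.0) * L2e.sum()
    g_tp = L1e.sum()
    g_pp = -ne / p**2
    g_ttt = 2.0 * ne / theta**3 + (p - 1.0) * L3e.sum()
    g_ttp = L2e.sum()
    g_tpp = 0.0
    g_ppp = 2.0 * ne / p**3

    # censored contributions via F(L, p) = log(1 - exp(p L));
    # pL -> 0- (survival -> 0) legitimately drives the ratios to infinity,
    # surfacing as a non-finite log-likelihood below
    if tc.size:
        pL = p * Lc
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            B_over_S = np.exp(pL - np.log(-np.expm1(pL)))  # B/S
            S = -np.expm1(pL)
            BS2 = B_over_S / S  # B/S^2
            BS3_mix = B_over_S / S**2 * (S + 2.0 * (1.0 - S))  # B(S+2B)/S^3

            ll += float(np.sum(np.log(-np.expm1(pL))))
            F_L = -p * B_over_S
            F_p = -Lc * B_over_S
            F_LL = -(p**2) * BS2
            F_pp = -(Lc**2) * BS2
            F_pL = -B_over_S - p * Lc * BS2
            F_LLL = -(p**3) * BS3_mix
            F_ppp = -(Lc**3) * BS3_mix
            F_pLL = -2.0 * p * BS2 - (p**2) * Lc * BS3_mix
            F_ppL = -2.0 * Lc * BS2 - p * (Lc**2) * BS3_mix

            h_t = np.sum(F_L * L1c)
            h_p = np.sum(F_p)
            h_tt = np.sum(F_LL * L1c**2 + F_L * L2c)
            h_tp = np.sum(F_pL * L1c)
            h_pp = np.sum(F_pp)
            h_ttt = np.sum(
                F_LLL * L1c**3 + 3.0 * F_LL * L1c * L2c + F_L * L3c
            )
            h_ttp = np.sum(F_pLL * L1c**2 + F_pL * L2c)
            h_tpp = np.sum(F_ppL * L1c)
            h_ppp = np.sum(F_ppp)
    else:
        h_t = h_p = h_tt = h_tp = h_pp = 0.0
        h_ttt = h_ttp = h_tpp = h_ppp = 0.0

    if not np.isfinite(ll):
        raise FloatingPointError("non-finite censored log-likelihood")

    gradient = np.array([g_t + h_t, g_p + h_p])
    hessian = np.array(
        [[g_tt + h_tt, g_tp + h_tp], [g_tp + h_tp, g_pp + h_pp]]
    )
    third = None
    if order >= 3:
        l30 = g_ttt + h_ttt
        l21 = g_ttp + h_ttp
        l12 = g_tpp + h_tpp
        l03 = g_ppp + h_ppp
        third = np.empty((2, 2, 2))
        third[0, 0, 0] = l30
        third[1, 1, 1] = l03
        third[0, 0, 1] = third[0, 1, 0] = third[1, 0, 0] = l21
        third[0, 1, 1] = third[1, 0, 1] = third[1, 1, 0] = l12
    return DerivativeBundle(loglik=ll, gradient=gradient, hessian=hessian, third=third)
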