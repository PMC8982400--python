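"""Truncated-normal divergence hazards and competing-event probabilities.

Backward in time, a lineage sampled in a derived population is at risk of
switching its label to the ancestral population.  The switching time is
modelled as a zero-truncated normal random variable with mean ``tau_mean``
and standard deviation ``tau_sd`` (optionally truncated above at ``b1``),
entering the structured coalescent through its hazard function

    lambda_d(t) = phi((t - tau_mean)/tau_sd) / (tau_sd * S(t)),

where ``S(t)`` is the probability that an untruncated normal draw falls in
``[t, b1]``.  The lower truncation at zero cancels from the hazard, so only
the upper bound appears.  Coalescence and migration contribute a constant
competing rate ``lam_cm``; this module computes the hazard, its integral
(the cumulative hazard), the waiting-time density, inverse-transform
sampling of switching times, and the probability ``xi_d`` that a divergence
event precedes every coalescence and migration event in an interval, both
by adaptive quadrature and by the closed-form midpoint approximation

    xi_d ~= lambda_d(t0 + eps) / (lam_cm + lambda_d(t0 + eps)).

All times are mutation-scaled (expected substitutions per site), the same
scale as the mutation-scaled population size Theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import log_ndtr, ndtri, ndtri_exp

__all__ = [
    "DivergenceDistribution",
    "IntervalRates",
    "div_hazard",
    "div_log_hazard",
    "div_cum_hazard",
    "div_waiting_density",
    "sample_div_time",
    "xi_divergence_exact",
    "xi_event_probabilities",
    "xi_divergence_approx",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class DivergenceDistribution:
    """Zero-truncated normal divergence-time distribution.

    Parameters
    ----------
    tau_mean : float
        Mean of the underlying normal (mutation-scaled time), > 0.
    tau_sd : float
        Standard deviation, > 0.
    b1 : float
        Upper truncation bound; ``inf`` for an unbounded right tail.
        The lower bound is fixed at 0.
    """

    tau_mean: float
    tau_sd: float
    b1: float = math.inf

    def __post_init__(self) -> None:
        if not self.tau_sd > 0:
            raise ValueError("tau_sd must be positive")
        if not self.tau_mean > 0:
            raise ValueError("tau_mean must be positive")
        if not self.b1 > 0:
            raise ValueError("b1 must be positive (or inf)")

    def _log_sf(self, t):
        """log P[t <= X <= b1] for the untruncated normal, elementwise."""
        z = (np.asarray(t, dtype=float) - self.tau_mean) / self.tau_sd
        # log Phi_c(z) via the lower-tail log-CDF of -z (stable deep in tails)
        la = log_ndtr(-z)
        if math.isinf(self.b1):
            return la
        zb = (self.b1 - self.tau_mean) / self.tau_sd
        lb = log_ndtr(-zb)
        # log(exp(la) - exp(lb)); la >= lb on the support
        with np.errstate(divide="ignore", invalid="ignore"):
            return la + np.log1p(-np.exp(np.minimum(lb - la, 0.0)))


@dataclass(frozen=True)
class IntervalRates:
    """Constant competing rates over one genealogy interval.

    ``lam_cm`` is the total coalescent-plus-migration rate (constant in
    time); ``t0`` the interval start; ``u`` its length.
    """

    lam_cm: float
    t0: float = 0.0
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.lam_cm < 0 or self.u < 0 or self.t0 < 0:
            raise ValueError("rates, t0 and u must be non-negative")


def div_log_hazard(t, d: DivergenceDistribution):
    """Log of the divergence hazard at time ``t`` (vectorized)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= d.b1):
        raise ValueError("hazard requires 0 <= t < b1")
    z = (t - d.tau_mean) / d.tau_sd
    log_pdf = -0.5 * z * z - _LOG_SQRT_2PI - math.log(d.tau_sd)
    return log_pdf - d._log_sf(t)


def div_hazard(t, d: DivergenceDistribution):
    """Divergence (label-switch) hazard at time ``t``.

    Equals pdf/(1-CDF) of the ``[0, b1]``-truncated normal; the zero lower
    bound cancels, leaving the normal density over the upper-tail mass.
    """
    return np.exp(div_log_hazard(t, d))


def div_cum_hazard(t0, u, d: DivergenceDistribution):
    """Cumulative hazard Lambda_d over ``[t0, t0+u]``.

    Closed form: log of the ratio of upper-tail masses at the two interval
    ends, evaluated in log space so that deep tails (t >> tau_mean) do not
    cancel catastrophically.
    """
    t0 = np.asarray(t0, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(t0 < 0) or np.any(u < 0):
        raise ValueError("t0 and u must be non-negative")
    if np.any(t0 + u >= d.b1):
        raise ValueError("t0 + u must stay below the upper bound b1")
    return d._log_sf(t0) - d._log_sf(t0 + u)


def div_waiting_density(t0, u, d: DivergenceDistribution):
    """Waiting-time density for the next label switch after ``t0``.

    f(u | t0) = exp(-Lambda_d(t0, t0+u)) * lambda_d(t0+u); integrates to 1
    over u in [0, b1 - t0).
    """
    return np.exp(-div_cum_hazard(t0, u, d) + div_log_hazard(np.asarray(t0) + np.asarray(u), d))


def sample_div_time(t0, r, d: DivergenceDistribution):
    """Invert the divergence survival function: draw a waiting interval.

    Returns ``u`` such that exp(-Lambda_d(t0, t0+u)) = 1 - r for a uniform
    variate ``r`` in (0, 1].  Works in log space through the normal
    quantile of the log upper-tail mass, so draws stay accurate for start
    times far beyond ``tau_mean``.
    """
    t0 = np.asarray(t0, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("r must lie in (0, 1]")
    if np.any(t0 >= d.b1):
        raise ValueError("t0 must lie below b1")
    # target upper-tail mass: S(t0+u) = S(t0) * (1 - r)
    log_target = d._log_sf(t0) + np.log1p(-r)
    if math.isinf(d.b1):
        # Phi_c(z) = target  =>  z = -ndtri_exp(log_target)
        z = -ndtri_exp(log_target)
    else:
        zb = (d.b1 - d.tau_mean) / d.tau_sd
        target = np.exp(log_target) + math.exp(log_ndtr(-zb))
        z = -ndtri(target)
    t1 = d.tau_mean + d.tau_sd * z
    return np.maximum(t1 - t0, 0.0)


def _xi_integrand_log(u, rates: IntervalRates, d: DivergenceDistribution):
    t0 = rates.t0
    return (
        -u * rates.lam_cm
        - div_cum_hazard(t0, u, d)
        + div_log_hazard(t0 + u, d)
    )


def xi_divergence_exact(rates: IntervalRates, d: DivergenceDistribution,
                        tol: float = 1e-10) -> float:
    """P[divergence precedes every coalescence/migration], by quadrature.

    Integrates exp(-u*lam_cm) * f_d(u | t0) over u >= 0.  The integrand
    decays at least exponentially; integration stops at the upper bound or
    tau_mean + 10 sd, whichever is smaller, plus an exponential tail bound.

    Raises ``RuntimeError`` when the quadrature error estimate exceeds
    ``tol`` by a wide margin.
    """
    t0 = rates.t0
    hi = min(d.b1, d.tau_mean + 10.0 * d.tau_sd)
    upper = max(hi - t0, 10.0 * d.tau_sd)
    if rates.lam_cm > 0:
        upper = min(upper, max(50.0 / rates.lam_cm, 10.0 * d.tau_sd))
    if d.b1 < math.inf:
        upper = min(upper, d.b1 - t0)

    def f(u):
        return math.exp(_xi_integrand_log(u, rates, d))

    pts = [x for x in (d.tau_mean - t0,) if 0 < x < upper]
    val, err = integrate.quad(f, 0.0, upper * (1 - 1e-12), points=pts or None,
                              limit=200, epsabs=tol, epsrel=1e-10)
    # exponential tail bound beyond the finite window (survival at `upper`
    # times the remaining competing-exponential mass)
    if d.b1 == math.inf and upper < math.inf:
        tail = math.exp(-div_cum_hazard(t0, upper, d))
        if rates.lam_cm > 0:
            tail *= math.exp(-upper * rates.lam_cm)
        val = min(1.0, val + tail)
        err += tail
    if err > max(1e-6, 100 * tol):
        raise RuntimeError(f"xi quadrature did not converge: error estimate {err:g}")
    return min(max(val, 0.0), 1.0)


def xi_event_probabilities(lam_c: float, lam_m: float, rates_t0: float,
                           d: DivergenceDistribution) -> tuple[float, float, float]:
    """Exact (xi_c, xi_m, xi_d) partition for one interval.

    Coalescence and migration are exponential competitors with constant
    rates ``lam_c`` and ``lam_m``; the divergence competitor follows the
    truncated-normal hazard started at ``rates_t0``.  The three values sum
    to 1 up to quadrature error.
    """
    lam_cm = lam_c + lam_m
    rates = IntervalRates(lam_cm=lam_cm, t0=rates_t0)
    xi_d = xi_divergence_exact(rates, d)

    def surv(u):
        return math.exp(-u * lam_cm - div_cum_hazard(rates_t0, u, d))

    hi = min(d.b1, d.tau_mean + 10.0 * d.tau_sd)
    upper = max(hi - rates_t0, 10.0 * d.tau_sd)
    if lam_cm > 0:
        upper = min(max(50.0 / lam_cm, 10.0 * d.tau_sd), upper)
    if d.b1 < math.inf:
        upper = min(upper, d.b1 - rates_t0)
    integral, _ = integrate.quad(surv, 0.0, upper * (1 - 1e-12), limit=200,
                                 epsabs=1e-12)
    if d.b1 == math.inf and lam_cm > 0:
        integral += math.exp(-upper * lam_cm - div_cum_hazard(rates_t0, upper, d)) / lam_cm
    xi_c = lam_c * integral
    xi_m = lam_m * integral
    return xi_c, xi_m, xi_d


def xi_divergence_approx(lam_cm: float, lam_d_eps: float) -> float:
    """Midpoint approximation of xi_d: the simple rate ratio.

    ``lam_d_eps`` is the divergence hazard evaluated at a representative
    point ``t0 + eps`` inside the interval; the hazard is frozen there,
    which turns all competitors into exponentials.
    """
    if lam_cm < 0 or lam_d_eps < 0:
        raise ValueError("rates must be non-negative")
    if lam_cm == 0 and lam_d_eps == 0:
        raise ValueError("at least one rate must be positive")
    return lam_d_eps / (lam_cm + lam_d_eps)
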