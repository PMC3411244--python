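"""Coalescent model of shustring lengths and the diversity estimators.

Under the standard coalescent the time to the most recent common ancestor
of two homologous positions is exponential; integrating it out gives a
heavy-tailed survival function for the homologous match length,
``P{X > x} = 1 / (1 + pi*x)``, where ``pi`` is the expected number of
mismatches per site.  Matches against non-homologous background sequence
of half-length ``ell_S`` and GC-content ``2p`` are governed by the maximal
random-word match CDF ``w_{p,ell_S}(x)``.  The product of the two factors
is the CDF of the shustring length at a single query position, and the
per-length counts ``f(x)`` observed along a query of half-length ``ell_Q``
are modelled as independent Poisson variables with mean
``2 * p_pi(x) * ell_Q``.

Two estimators of ``pi`` are provided:

* ``estimate_pi_d`` — the maximum-likelihood estimator from the full
  shustring-length distribution; robust to coalescence-time fluctuations
  caused by recombination at rates up to roughly ``pi``.
* ``estimate_pi_m`` — the legacy inverse-mean estimator, accurate only
  without recombination and strongly downward biased otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import comb, gammaln, logsumexp

__all__ = [
    "ShustringModel",
    "EstimateResult",
    "homologous_tail",
    "background_cdf",
    "log_background_cdf",
    "shustring_cdf",
    "shustring_pmf",
    "log_likelihood",
    "estimate_pi_d",
    "estimate_pi_m",
]

PI_BOUNDS = (1e-8, 0.75)


def homologous_tail(pi: float, x) -> np.ndarray | float:
    """Survival function 1/(1 + pi*x) of the homologous match length.

    This is the exponential coalescence time integrated out of the
    conditional geometric match-length distribution; it is heavy tailed
    (the conditional excess E[X - x | X > x] diverges), so the match
    length has no finite expectation.
    """
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + pi * x)
    return float(out) if out.ndim == 0 else out


def _log_background_general(p: float, ell_S: float, xs: np.ndarray) -> np.ndarray:
    """Finite-sum form of log w_{p,ell_S}(x), stable in log space.

    Two regimes: deep underflow (log w very negative) is summed in log
    space via logsumexp; values near 1 are re-summed in linear space with
    exact binomial coefficients and ``math.fsum``, which keeps the
    agreement with the equiprobable closed form to ~1e-14.
    """
    q = 0.5 - p
    log_p, log_q = math.log(p), math.log(q)
    two_ls = 2.0 * ell_S
    out = np.empty(len(xs))
    for i, x in enumerate(xs):
        if x <= 0:
            out[i] = -np.inf
            continue
        k = np.arange(x + 1, dtype=float)
        log_weight = (
            gammaln(x + 1.0)
            - gammaln(k + 1.0)
            - gammaln(x - k + 1.0)
            + x * math.log(2.0)
            + k * log_p
            + (x - k) * log_q
        )
        log_match = k * log_p + (x - k) * log_q  # log p^k q^(x-k), < 0 for x >= 1
        val = float(logsumexp(log_weight + two_ls * np.log1p(-np.exp(log_match))))
        if val > -600.0:  # representable in linear space: redo at full accuracy
            terms = []
            for kk in range(int(x) + 1):
                weight = comb(int(x), kk, exact=True) * math.exp(
                    x * math.log(2.0) + kk * log_p + (x - kk) * log_q
                )
                surv = math.exp(two_ls * math.log1p(-math.exp(kk * log_p + (x - kk) * log_q)))
                terms.append(weight * surv)
            val = math.log(min(math.fsum(terms), 1.0))
        out[i] = min(val, 0.0)
    return out


def log_background_cdf(p: float, ell_S: float, x) -> np.ndarray:
    """log w_{p,ell_S}(x), finite for all x >= 1 even when w underflows.

    Needed by the likelihood: near the sequence ends, shustrings are capped
    at lengths whose background probability underflows double precision in
    linear space, yet their (pi-independent) log-probability is a perfectly
    ordinary number.
    """
    if not 0.0 < p < 0.5:
        raise ValueError("p must lie in (0, 1/2)")
    if ell_S <= 0:
        raise ValueError("ell_S must be positive")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.full_like(x_arr, -np.inf)
    active = x_arr > 0
    if abs(p - 0.25) < 1e-12:
        out[active] = 2.0 * ell_S * np.log1p(-np.power(4.0, -x_arr[active]))
        return out
    m = max(p, 0.5 - p)
    # w(x) == 1 to double precision beyond x_sat, so log w(x) == 0 there
    x_sat = int(math.ceil(math.log(2.0 * ell_S / 1e-18) / -math.log(m))) + 1
    out[x_arr > x_sat] = 0.0
    exact = active & (x_arr <= x_sat)
    out[exact] = _log_background_general(p, ell_S, x_arr[exact].astype(int))
    return out


def background_cdf(p: float, ell_S: float, x) -> np.ndarray | float:
    """CDF w_{p,ell_S}(x) of the maximal background match length.

    Probability that the longest match between a query position and all
    2*ell_S non-homologous positions of a random subject with GC-content
    ``2p`` is at most ``x``.  For equiprobable nucleotides (p = 1/4) this
    reduces to ``(1 - 4**-x)**(2*ell_S)``; the general mixture-over-words
    form is evaluated in log space.  Values are saturated to 1 beyond the
    point where they differ from 1 by less than ~1e-18, which keeps the
    cost bounded for long subjects.
    """
    if not 0.0 < p < 0.5:
        raise ValueError("p must lie in (0, 1/2)")
    if ell_S <= 0:
        raise ValueError("ell_S must be positive")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.ones_like(x_arr)
    out[x_arr <= 0] = 0.0
    if abs(p - 0.25) < 1e-12:
        active = x_arr > 0
        out[active] = np.exp(2.0 * ell_S * np.log1p(-np.power(4.0, -x_arr[active])))
    else:
        m = max(p, 0.5 - p)
        # beyond x_sat, 2*ell_S * m**x < 1e-18 so w(x) == 1 to double precision
        x_sat = int(math.ceil(math.log(2.0 * ell_S / 1e-18) / -math.log(m))) + 1
        active = (x_arr > 0) & (x_arr <= x_sat)
        out[active] = np.exp(_log_background_general(p, ell_S, x_arr[active].astype(int)))
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(out[0])
    return out


@dataclass
class ShustringModel:
    """Parameters of the shustring-length distribution.

    pi     : expected mismatches per site, in (0, 1)
    p      : half the GC-content (P(G) = P(C) = p), in (0, 1/2)
    ell_S  : subject single-strand length (strand doubling supplies the 2s)
    ell_Q  : query (or window) single-strand length
    """

    pi: float
    p: float
    ell_S: float
    ell_Q: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        if not 0.0 < self.p < 0.5:
            raise ValueError("p must lie in (0, 1/2)")
        if self.ell_S < 1 or self.ell_Q < 1:
            raise ValueError("ell_S and ell_Q must be >= 1")

    def cdf(self, x):
        return shustring_cdf(self, x)

    def pmf(self, x):
        return shustring_pmf(self, x)

    def expected_counts(self, x):
        """Poisson mean 2 * p_pi(x) * ell_Q of the count at length x."""
        return 2.0 * self.ell_Q * np.asarray(self.pmf(x))


def shustring_cdf(model: ShustringModel, x) -> np.ndarray | float:
    """P{X* <= x}: background CDF damped by the homologous factor."""
    x_arr = np.asarray(x, dtype=float)
    w = background_cdf(model.p, model.ell_S, x_arr)
    out = np.asarray(w) * (model.pi * x_arr) / (1.0 + model.pi * x_arr)
    return float(out) if out.ndim == 0 else out


def shustring_pmf(model: ShustringModel, x) -> np.ndarray | float:
    """P{X* = x} as consecutive CDF differences, clamped at zero."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    vals = shustring_cdf(model, x_arr) - shustring_cdf(model, x_arr - 1.0)
    out = np.maximum(np.asarray(vals), 0.0)
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(out[0])
    return out


def _log_pmf_from_logw(pi: float, log_w: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """log pmf over xs = 0..xi from precomputed (pi-independent) log w(x).

    The log-CDF ``log w(x) + log(pi*x) - log1p(pi*x)`` is strictly
    increasing, so each pmf cell is ``F(x) * (1 - F(x-1)/F(x))`` and can be
    evaluated without linear-space cancellation or underflow; this keeps
    cells with astronomically small background probability (edge-capped
    short shustrings) at finite log-probability.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_cdf = log_w + np.log(pi * xs) - np.log1p(pi * xs)
        d = np.diff(log_cdf)  # > 0 for x >= 1; d[x-1] = logF(x) - logF(x-1)
        out = np.full_like(log_cdf, -np.inf)
        out[1:] = log_cdf[1:] + np.log(-np.expm1(-d))
    return out


def log_likelihood(model: ShustringModel, hist) -> float:
    """Poisson log-likelihood of a shustring histogram, up to a constant.

    Returns ``sum_x f(x) * log p_pi(x)``; the additive Poisson terms not
    depending on ``pi`` are dropped.  Returns ``-inf`` when some observed
    length has zero probability under the model.
    """
    counts = hist.counts
    xs = np.arange(len(counts), dtype=float)
    log_w = log_background_cdf(model.p, model.ell_S, xs)
    log_pmf = _log_pmf_from_logw(model.pi, log_w, xs)
    mask = counts > 0
    if np.any(np.isneginf(log_pmf[mask])):
        return float("-inf")
    return float(np.sum(counts[mask] * log_pmf[mask]))


@dataclass
class EstimateResult:
    """Outcome of a maximum-likelihood fit of pi."""

    pi_hat: float
    log_likelihood: float
    converged: bool
    n_positions: int
    message: str = ""


def estimate_pi_d(
    hist,
    p: float,
    ell_S: float,
    ell_Q: float,
    min_total: int = 100,
    bounds: tuple[float, float] = PI_BOUNDS,
) -> EstimateResult:
    """Maximum-likelihood diversity estimate from a shustring histogram.

    Maximises ``sum_x f(x) log p_pi(x)`` over ``pi`` by bounded scalar
    search on ``log pi`` (relative tolerance 1e-6).  The background CDF,
    which does not depend on ``pi``, is precomputed once.  A fit whose
    optimum sticks to a bound of the search interval — e.g. for identical
    sequences, where every length is capped — is reported with
    ``converged=False``.
    """
    if hist.total < min_total:
        raise ValueError(
            f"histogram has {hist.total} positions; at least {min_total} required"
        )
    counts = hist.counts.astype(float)
    xs = np.arange(len(counts), dtype=float)
    log_w = log_background_cdf(p, ell_S, xs)
    mask = counts > 0

    log_lo, log_hi = math.log(bounds[0]), math.log(bounds[1])

    def neg_ll(t: float) -> float:
        log_pmf = _log_pmf_from_logw(math.exp(t), log_w, xs)
        if np.any(np.isneginf(log_pmf[mask])):
            return 1e300
        return -float(np.sum(counts[mask] * log_pmf[mask]))

    res = minimize_scalar(
        neg_ll, bounds=(log_lo, log_hi), method="bounded", options={"xatol": 1e-6}
    )
    pi_hat = math.exp(res.x)
    ll = -res.fun
    at_bound = res.x - log_lo < 1e-3 or log_hi - res.x < 1e-3
    all_capped = getattr(hist, "n_capped", 0) >= hist.total
    converged = (
        bool(res.success) and math.isfinite(ll) and not at_bound and not all_capped
    )
    message = ""
    if all_capped:
        message = (
            "degenerate histogram: every shustring capped (no unique substring "
            "exists; sequences may be identical)"
        )
    elif at_bound:
        message = "optimum at search bound; estimate unreliable (degenerate histogram?)"
    elif not math.isfinite(ll):
        message = "log-likelihood not finite at optimum"
    return EstimateResult(
        pi_hat=pi_hat,
        log_likelihood=ll,
        converged=converged,
        n_positions=hist.total,
        message=message,
    )


def estimate_pi_m(profile) -> float:
    """Legacy inverse-mean estimator: 1 / mean shustring length.

    Assumes a single coalescence time across the whole comparison, hence
    its strong downward bias under recombination.
    """
    lengths = profile.lengths if hasattr(profile, "lengths") else np.asarray(profile)
    if len(lengths) == 0:
        raise ValueError("profile is empty")
    return float(1.0 / np.mean(lengths))
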