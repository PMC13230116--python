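"""Disproportionality statistics for 2x2 spontaneous-report tables.

Four estimators of reporting disproportionality for a drug-event table
(a, b, c, d), N = a+b+c+d, expected count E = (a+b)(a+c)/N:

ROR
    reporting odds ratio (a*d)/(b*c) with Woolf (log-scale normal) CI
    ``exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d))``.
PRR
    proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
    analogous log-scale CI using variance ``1/a - 1/(a+b) + 1/c - 1/(c+d)``.
chi2
    Pearson statistic ``N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``; Yates
    continuity correction available but off by default.
IC
    BCPNN-style information component.  The default ("shrunk_ratio") form is
    ``log2((a+s)/(E+s))`` with pseudo-count ``s`` (default 0.5), and IC025 is
    the base-2 log of the 2.5th percentile of a Gamma(a+s, rate=E+s)
    posterior.  A second mode, "log2_ebgm", defines IC = log2(EBGM) as some
    published analyses print it; see the methods note.
EBGM
    DuMouchel's gamma-Poisson shrinker: a ~ Poisson(lambda*E) with a
    two-component gamma mixture prior on lambda.  The posterior is again a
    gamma mixture; EBGM = 2**E[log2 lambda | a] and EBGM05 is the 5th
    posterior percentile.  Hyperparameters are fitted by maximising the
    negative-binomial mixture marginal likelihood over all (a, E) cells of a
    database.

Undefined statistics (zero cells where a formula requires support) are
returned as ``nan`` markers, never silently corrected; an optional Haldane
+0.5 correction can be requested explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable

#: Default normal quantile for 95% intervals.
DEFAULT_Z = 1.96
#: Default BCPNN pseudo-count.
DEFAULT_IC_PRIOR_STRENGTH = 0.5

IC_MODES = ("shrunk_ratio", "log2_ebgm")


@dataclass(frozen=True)
class PriorParams:
    """Hyperparameters of the two-component gamma mixture prior on lambda.

    Component j has shape ``alpha_j`` and rate ``beta_j`` (mean alpha/beta);
    ``w`` is the weight of component 1.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate hyperparameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight w must lie strictly in (0, 1)")

    @property
    def mean(self) -> float:
        """Prior mean of lambda."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.w)


#: DuMouchel's canonical starting point for the prior fit.
DEFAULT_PRIOR_INIT = PriorParams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class DisproportionalityResult:
    """All four statistics (with intervals) for one drug-event table."""

    a: int
    expected: float
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    z: float = DEFAULT_Z


class FitError(RuntimeError):
    """Prior fitting failed; carries the best-so-far parameters."""

    def __init__(self, message: str, best: PriorParams | None = None, trace: object = None):
        super().__init__(message)
        self.best = best
        self.trace = trace


def _haldane(t: ContingencyTable) -> tuple[float, float, float, float]:
    return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)


def ror_stat(
    t: ContingencyTable, z: float = DEFAULT_Z, haldane: bool = False
) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% (or z-level) CI.

    Undefined when b=0 or c=0 (point estimate) or any cell is 0 (CI);
    undefined values are returned as ``nan``.  ``haldane=True`` adds 0.5 to
    every cell first.
    """
    a, b, c, d = (_haldane(t) if haldane else (t.a, t.b, t.c, t.d))
    if b == 0 or c == 0:
        return (math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    if min(a, b, c, d) == 0 or ror == 0.0:
        return (ror, math.nan, math.nan)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def prr_stat(
    t: ContingencyTable, z: float = DEFAULT_Z, haldane: bool = False
) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-scale 95% (or z-level) CI."""
    a, b, c, d = (_haldane(t) if haldane else (t.a, t.b, t.c, t.d))
    if a + b == 0 or c == 0 or c + d == 0:
        return (math.nan, math.nan, math.nan)
    prr = (a / (a + b)) / (c / (c + d))
    if a == 0 or prr == 0.0:
        return (prr, math.nan, math.nan)
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    return (prr, prr * math.exp(-z * se), prr * math.exp(z * se))


def chi2_stat(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table; ``nan`` when a margin is zero.

    Default is no continuity correction; with ``yates=True``, |ad-bc| is
    reduced by N/2 (floored at 0) before squaring.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / denom


def bcpnn_ic(
    t: ContingencyTable,
    mode: str = "shrunk_ratio",
    prior_strength: float = DEFAULT_IC_PRIOR_STRENGTH,
    prior: PriorParams | None = None,
) -> tuple[float, float]:
    """Information component and its lower 95% credibility bound.

    mode "shrunk_ratio" (default)
        IC = log2((a+s)/(E+s)) with pseudo-count s; IC025 = log2 of the
        2.5th percentile of a Gamma(shape=a+s, rate=E+s) posterior for the
        reporting-rate ratio.
    mode "log2_ebgm"
        IC = log2(EBGM) and IC025 = log2(EBGM05) under the gamma-Poisson
        shrinker posterior (requires ``prior``).
    """
    if mode not in IC_MODES:
        raise ValueError(f"unknown IC mode {mode!r}; expected one of {IC_MODES}")
    e = t.expected
    if e == 0:
        return (math.nan, math.nan)
    if mode == "log2_ebgm":
        if prior is None:
            raise ValueError("mode 'log2_ebgm' requires a PriorParams")
        ebgm, ebgm05 = ebgm_scores(t, prior)
        return (math.log2(ebgm), math.log2(ebgm05))
    s = prior_strength
    if s <= 0:
        raise ValueError("prior_strength must be positive")
    ic = math.log2((t.a + s) / (e + s))
    q = stats.gamma.ppf(0.025, t.a + s, scale=1.0 / (e + s))
    ic025 = math.log2(q) if q > 0 else -math.inf
    return (ic, ic025)


# --- gamma-Poisson shrinker (EBGM) ---------------------------------------


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """Log marginal P(a | alpha, beta, E): negative binomial with size alpha
    and success probability beta/(beta+E)."""
    p = beta / (beta + e)
    return stats.nbinom.logpmf(a, alpha, p)


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Marginal log-likelihood at unconstrained parameters theta =
    (log a1, log b1, log a2, log b2, logit w)."""
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = special.expit(theta[4])
    l1 = np.log(w) + _nb_logpmf(a, a1, b1, e)
    l2 = np.log1p(-w) + _nb_logpmf(a, a2, b2, e)
    return float(np.sum(np.logaddexp(l1, l2)))


def fit_prior(
    cells: "np.ndarray | list[tuple[float, float]]",
    init: PriorParams = DEFAULT_PRIOR_INIT,
    maxiter: int = 20000,
    tol: float = 1e-6,
) -> PriorParams:
    """Fit the gamma-mixture hyperparameters to (a, E) cells by maximum
    marginal likelihood.

    The likelihood is the product over cells of the two-component
    negative-binomial mixture implied by a ~ Poisson(lambda*E) with the
    mixture prior on lambda.  Optimisation is derivative-free (Powell) on
    log/logit-transformed parameters, boxed to [e^-13.8, e^13.8] so that
    degenerate data (e.g. a pure-null database whose likelihood peaks at a
    point-mass prior) terminate at the box instead of drifting; the achieved
    log-likelihood and convergence status are attached to the returned
    :class:`PriorParams`.

    Raises :class:`FitError` (carrying best-so-far parameters and the
    optimiser result) on non-convergence.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("fit_prior needs at least 2 (a, E) cells")
    a, e = arr[:, 0], arr[:, 1]
    if np.any(e <= 0):
        raise ValueError("all expected counts E must be positive")

    theta0 = np.array(
        [
            math.log(init.alpha1),
            math.log(init.beta1),
            math.log(init.alpha2),
            math.log(init.beta2),
            special.logit(init.w),
        ]
    )

    def nll(theta: np.ndarray) -> float:
        ll = _mixture_loglik(theta, a, e)
        return -ll if np.isfinite(ll) else 1e300

    bound = 13.8  # e^13.8 ~ 1e6 on the natural scale
    res = optimize.minimize(
        nll,
        theta0,
        method="Powell",
        bounds=[(-bound, bound)] * 5,
        options={"maxiter": maxiter, "xtol": 1e-6, "ftol": tol},
    )
    a1, b1, a2, b2 = np.exp(res.x[:4])
    w = float(special.expit(res.x[4]))
    fitted = PriorParams(a1, b1, a2, b2, w, loglik=-float(res.fun), converged=bool(res.success))
    if not res.success:
        raise FitError(f"prior fit did not converge: {res.message}", best=fitted, trace=res)
    return fitted


def _posterior_mixture(
    a: int, e: float, prior: PriorParams
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of lambda given a: weight Q of component 1 and the two
    (shape, rate) gamma components."""
    l1 = math.log(prior.w) + float(_nb_logpmf(np.array(a), prior.alpha1, prior.beta1, np.array(e)))
    l2 = math.log1p(-prior.w) + float(
        _nb_logpmf(np.array(a), prior.alpha2, prior.beta2, np.array(e))
    )
    m = max(l1, l2)
    q1 = math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))
    return q1, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm_scores(t: ContingencyTable, prior: PriorParams) -> tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and EBGM05 (5th posterior
    percentile) for one table under a fitted prior.

    EBGM = 2**E[log2 lambda | a] with E[ln lambda] evaluated by digamma on
    the posterior gamma mixture; EBGM05 solves mixture-CDF(x) = 0.05 by
    bracketed root finding.
    """
    e = t.expected
    if e == 0:
        return (math.nan, math.nan)
    a = t.a
    q1, (s1, r1), (s2, r2) = _posterior_mixture(a, e, prior)
    mean_log = q1 * (special.digamma(s1) - math.log(r1)) + (1 - q1) * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(mean_log)

    # degenerate mixture: posterior mass concentrated on one component
    if q1 >= 1.0 - 1e-12:
        return (ebgm, float(stats.gamma.ppf(0.05, s1, scale=1 / r1)))
    if q1 <= 1e-12:
        return (ebgm, float(stats.gamma.ppf(0.05, s2, scale=1 / r2)))

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    # bracket the 5th percentile by the component quantiles (the mixture CDF
    # is <= 0.05 at the smaller and >= 0.05 at the larger); pad the bracket
    # geometrically to absorb floating-point boundary equality
    q_lo = min(stats.gamma.ppf(0.05, s1, scale=1 / r1), stats.gamma.ppf(0.05, s2, scale=1 / r2))
    q_hi = max(stats.gamma.ppf(0.05, s1, scale=1 / r1), stats.gamma.ppf(0.05, s2, scale=1 / r2))
    if q_lo == q_hi:
        return (ebgm, float(q_lo))
    lo, hi = q_lo * 0.999, q_hi * 1.001
    for _ in range(60):
        if cdf(lo) <= 0.05:
            break
        lo *= 0.5
    for _ in range(60):
        if cdf(hi) >= 0.05:
            break
        hi *= 2.0
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-10)
    return (ebgm, float(ebgm05))


def compute_all(
    t: ContingencyTable,
    prior: PriorParams,
    z: float = DEFAULT_Z,
    ic_mode: str = "shrunk_ratio",
    ic_prior_strength: float = DEFAULT_IC_PRIOR_STRENGTH,
    haldane: bool = False,
) -> DisproportionalityResult:
    """All four statistics for one table under one prior."""
    ror, ror_lo, ror_hi = ror_stat(t, z=z, haldane=haldane)
    prr, prr_lo, prr_hi = prr_stat(t, z=z, haldane=haldane)
    chi2 = chi2_stat(t)
    ebgm, ebgm05 = ebgm_scores(t, prior)
    ic, ic025 = bcpnn_ic(t, mode=ic_mode, prior_strength=ic_prior_strength, prior=prior)
    return DisproportionalityResult(
        a=t.a,
        expected=t.expected,
        ror=ror,
        ror_low=ror_lo,
        ror_high=ror_hi,
        prr=prr,
        prr_low=prr_lo,
        prr_high=prr_hi,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
        z=z,
    )
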