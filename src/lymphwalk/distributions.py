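"""MLE fitting of candidate step-length/speed distributions and model
competition.

The candidate families reflect generative hypotheses about cell motion:
Gaussian and Maxwell speeds arise from Brownian motion (in 2D and 3D
respectively), a power law of step lengths defines a Levy walk, and the
lognormal arises from multiplicative processes.  Families are compared on
raw samples via likelihood (never on binned data): negative log-likelihood,
AICc, BIC, and distance statistics (KS, AD, chi-squared on equal-probability
bins) computed against the fitted CDF.

Power-law tails are fitted Clauset-style: for each candidate ``x_min`` the
continuous power-law exponent is estimated by MLE on the tail and the
``x_min`` with the smallest Kolmogorov-Smirnov distance is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

FAMILIES = ("lognormal", "gaussian", "maxwell", "exponential", "gamma", "powerlaw")

#: Free-parameter count per family (power law: the exponent; x_min is the
#: sample minimum, not a free parameter).
N_PARAMS = {
    "lognormal": 2,
    "gaussian": 2,
    "maxwell": 1,
    "exponential": 1,
    "gamma": 2,
    "powerlaw": 1,
}

_POSITIVE_SUPPORT = {"lognormal", "maxwell", "exponential", "gamma", "powerlaw"}


class InsufficientDataError(ValueError):
    pass


class DegenerateTailError(ValueError):
    """No usable power-law tail (too few samples above the best x_min)."""


@dataclass
class DistributionFit:
    """A fitted distribution family with its MLE parameters.

    ``params`` holds named reals: lognormal mu/sigma (of log values),
    gaussian mu/sigma, maxwell a, exponential rate, gamma shape/scale,
    powerlaw mu/x_min.
    """

    family: str
    params: dict
    n: int
    nlogl: float

    @property
    def k(self) -> int:
        return N_PARAMS[self.family]

    def frozen(self):
        """The fitted scipy frozen distribution (power law: custom CDF)."""
        return _frozen(self.family, self.params)

    def cdf(self, x):
        return _cdf(self.family, self.params, np.asarray(x, dtype=float))

    def logpdf(self, x):
        return _logpdf(self.family, self.params, np.asarray(x, dtype=float))


@dataclass
class GoFPanel:
    """Goodness-of-fit panel for one fitted family."""

    nlogl: float
    aicc: float
    bic: float
    ks: float
    ad: float
    chi2: float
    rank: int = 0


@dataclass
class PowerLawTail:
    """Clauset-style power-law tail fit."""

    mu: float            # exponent, > 1
    x_min: float         # tail start, micrometres
    tail_fraction: float # fraction of samples >= x_min
    ks_at_xmin: float    # KS distance of the selected tail
    n_tail: int = 0


# ---------------------------------------------------------------------------
# family plumbing

def _frozen(family, p):
    if family == "lognormal":
        return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
    if family == "gaussian":
        return stats.norm(loc=p["mu"], scale=p["sigma"])
    if family == "maxwell":
        return stats.maxwell(scale=p["a"])
    if family == "exponential":
        return stats.expon(scale=1.0 / p["rate"])
    if family == "gamma":
        return stats.gamma(a=p["shape"], scale=p["scale"])
    raise ValueError(f"unknown family {family!r}")


def _cdf(family, p, x):
    if family == "powerlaw":
        mu, xm = p["mu"], p["x_min"]
        out = np.zeros_like(x, dtype=float)
        m = x >= xm
        out[m] = 1.0 - (x[m] / xm) ** (1.0 - mu)
        return out
    return _frozen(family, p).cdf(x)


def _logpdf(family, p, x):
    if family == "powerlaw":
        mu, xm = p["mu"], p["x_min"]
        out = np.full_like(x, -np.inf, dtype=float)
        m = x >= xm
        out[m] = np.log(mu - 1.0) - np.log(xm) - mu * (np.log(x[m]) - np.log(xm))
        return out
    return _frozen(family, p).logpdf(x)


def _ppf(family, p, q):
    if family == "powerlaw":
        mu, xm = p["mu"], p["x_min"]
        with np.errstate(divide="ignore"):
            return xm * (1.0 - np.asarray(q, dtype=float)) ** (1.0 / (1.0 - mu))
    return _frozen(family, p).ppf(q)


# ---------------------------------------------------------------------------
# fitting

def fit_mle(samples, family: str) -> DistributionFit:
    """Maximum-likelihood fit of one family to a sample.

    Closed-form estimators are used where they exist (lognormal: mean/SD of
    logs; gaussian: sample mean and MLE standard deviation; maxwell:
    ``a^2 = sum(x^2) / (3 n)``; exponential: ``rate = 1/mean``; power law:
    ``mu = 1 + n / sum(log(x / x_min))`` with ``x_min = min(x)``); the gamma
    family is fitted numerically with the location pinned at zero.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 samples.
    ValueError
        Non-positive samples for a positive-support family, or an unknown
        family name.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise InsufficientDataError(f"need >= 10 samples, got {n}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if family in _POSITIVE_SUPPORT and np.any(x <= 0):
        raise ValueError(f"{family} requires strictly positive samples")

    if family == "lognormal":
        lx = np.log(x)
        params = {"mu": float(lx.mean()), "sigma": float(lx.std(ddof=0))}
    elif family == "gaussian":
        params = {"mu": float(x.mean()), "sigma": float(x.std(ddof=0))}
    elif family == "maxwell":
        params = {"a": float(np.sqrt(np.sum(x**2) / (3.0 * n)))}
    elif family == "exponential":
        params = {"rate": float(1.0 / x.mean())}
    elif family == "gamma":
        shape, _, scale = stats.gamma.fit(x, floc=0.0)
        params = {"shape": float(shape), "scale": float(scale)}
    else:  # powerlaw over the full sample
        xm = float(x.min())
        params = {"mu": float(1.0 + n / np.sum(np.log(x / xm))), "x_min": xm}

    nlogl = float(-np.sum(_logpdf(family, params, x)))
    if not np.isfinite(nlogl):
        raise ValueError(f"{family}: non-finite log-likelihood (degenerate sample?)")
    return DistributionFit(family=family, params=params, n=n, nlogl=nlogl)


def fit_powerlaw_tail(samples, max_candidates: int = 1000,
                      min_tail: int = 10) -> PowerLawTail:
    """Estimate the power-law tail of a sample (Clauset-style).

    Every unique sample value is a candidate ``x_min`` (quantile-subsampled
    to ``max_candidates`` above 1000 candidates); for each, the continuous
    power-law MLE exponent is computed over the tail and the candidate with
    the smallest KS distance between the tail empirical CDF and the fitted
    CDF is selected.

    Raises
    ------
    InsufficientDataError
        Fewer than 50 samples.
    DegenerateTailError
        No candidate leaves at least ``min_tail`` tail samples (e.g. all
        samples identical).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 50:
        raise InsufficientDataError(f"need >= 50 samples, got {n}")
    if np.any(x <= 0):
        raise ValueError("power-law tail requires strictly positive samples")

    cands = np.unique(x)
    # exclude candidates that leave fewer than min_tail tail points
    cands = cands[cands <= x[-min_tail]]
    if len(cands) == 0 or cands[0] == x[-1]:
        raise DegenerateTailError("all samples identical or tail too small")
    if len(cands) > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        cands = np.unique(np.quantile(cands, qs, method="lower"))

    best = None
    for xm in cands:
        start = np.searchsorted(x, xm, side="left")
        tail = x[start:]
        m = len(tail)
        if m < min_tail:
            continue
        denom = np.sum(np.log(tail / xm))
        if denom <= 0:
            continue
        mu = 1.0 + m / denom
        fitted = 1.0 - (tail / xm) ** (1.0 - mu)
        ecdf_hi = np.arange(1, m + 1) / m
        ecdf_lo = np.arange(0, m) / m
        ks = float(np.max(np.maximum(np.abs(fitted - ecdf_hi),
                                     np.abs(fitted - ecdf_lo))))
        if best is None or ks < best[0]:
            best = (ks, mu, xm, m)

    if best is None:
        raise DegenerateTailError("no usable x_min candidate")
    ks, mu, xm, m = best
    return PowerLawTail(mu=float(mu), x_min=float(xm),
                        tail_fraction=m / n, ks_at_xmin=ks, n_tail=m)


# ---------------------------------------------------------------------------
# goodness of fit

def gof(fit: DistributionFit, samples) -> GoFPanel:
    """Goodness-of-fit panel for a fit against the sample it came from.

    AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1); BIC = k ln n - 2 lnL.  KS and AD
    compare the raw sample against the fitted CDF (no binning); chi-squared
    uses ceil(sqrt(n)) equal-probability bins derived from the fitted
    quantile function.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    lnL = -fit.nlogl
    aicc = 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
    bic = k * np.log(n) - 2 * lnL

    F = np.clip(fit.cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    ks = float(np.max(np.maximum(i / n - F, F - (i - 1) / n)))
    ad = float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log(1 - F[::-1]))))

    nbins = int(np.ceil(np.sqrt(n)))
    qs = np.linspace(0, 1, nbins + 1)
    edges = _ppf(fit.family, fit.params, qs)
    edges[0], edges[-1] = -np.inf, np.inf
    obs, _ = np.histogram(x, bins=np.asarray(edges, dtype=float))
    exp = n / nbins
    chi2 = float(np.sum((obs - exp) ** 2 / exp))

    return GoFPanel(nlogl=fit.nlogl, aicc=float(aicc), bic=float(bic),
                    ks=ks, ad=ad, chi2=chi2)


def rank_models(samples, families=("lognormal", "gaussian", "maxwell", "powerlaw")):
    """Fit and rank several families on one sample.

    Fits each family by MLE, computes its goodness-of-fit panel, and sorts
    by negative log-likelihood (AICc as tie-check: if two families'
    likelihoods are equal the one with fewer parameters ranks first).

    Returns
    -------
    list of (DistributionFit, GoFPanel), best first; panel ``rank`` is
    1-based.
    """
    families = tuple(families)
    if len(families) < 2:
        raise ValueError("need at least 2 families to rank")
    results = []
    for fam in families:
        f = fit_mle(samples, fam)
        results.append((f, gof(f, samples)))
    results.sort(key=lambda fp: (fp[0].nlogl, fp[1].aicc))
    for r, (_, panel) in enumerate(results, start=1):
        panel.rank = r
    return results
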