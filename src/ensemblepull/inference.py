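"""Group-level tests: t tests, Pearson correlation, JZS Bayes factor.

The statistics are computed from their textbook formulas (so that general
statistics libraries remain independent cross-checks); p-values come from
scipy's t distribution.  The Bayes factor is the default-prior
(Jeffreys-Zellner-Siow) two-sample Bayes factor: a Cauchy prior with scale
``r`` on the standardized effect size, evaluated by numerical integration
over Zellner's g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import t as t_dist


class DegenerateInputError(ValueError):
    """Input with no variance (or too few points) for the requested test."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]


@dataclass(frozen=True)
class BayesResult:
    """JZS Bayes factor; ``bf01`` is evidence for the null, ``1 / bf10``."""

    bf10: float
    prior_scale: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _clean(values, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise DegenerateInputError(f"{name}: need at least {min_n} values")
    return arr


def one_sample_t(values, mu0: float) -> TestResult:
    """Two-sided one-sample t test of ``mean(values) == mu0``; df = n - 1."""
    x = _clean(values, "values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance in values")
    n = x.size
    stat = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * t_dist.sf(abs(stat), df)
    return TestResult(float(stat), float(df), float(p), (float(x.mean()),), (float(sd),))


def independent_t(a, b) -> TestResult:
    """Two-sided pooled-variance two-sample t test; df = n_a + n_b - 2."""
    x, y = _clean(a, "a"), _clean(b, "b")
    na, nb = x.size, y.size
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise DegenerateInputError("zero pooled variance")
    stat = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * t_dist.sf(abs(stat), df)
    return TestResult(
        float(stat),
        float(df),
        float(p),
        (float(x.mean()), float(y.mean())),
        (float(x.std(ddof=1)), float(y.std(ddof=1))),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value."""
    xa, ya = _clean(x, "x", 3), _clean(y, "y", 3)
    if xa.size != ya.size:
        raise DegenerateInputError("x and y must have equal length")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise DegenerateInputError("zero variance in x or y")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    n = xa.size
    if abs(r) == 1.0:
        return r, 0.0
    stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * t_dist.sf(abs(stat), n - 2)
    return r, float(p)


def jzs_bayes_factor_from_t(
    t: float, n1: int, n2: int, prior_scale: float = 0.707
) -> BayesResult:
    """JZS Bayes factor for an observed two-sample t statistic.

    Effective sample size N = n1 n2 / (n1 + n2), df = n1 + n2 - 2.  BF10 is
    the ratio of the marginal likelihood under a Cauchy(0, prior_scale)
    prior on the effect size to the likelihood at effect size 0, computed
    by adaptive quadrature of the g-integral (the Cauchy written as a
    scale mixture of normals).
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("need n >= 2 in both groups")
    neff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    r = prior_scale

    def integrand(g: float) -> float:
        shrink = 1.0 + neff * g
        like = shrink**-0.5 * (1.0 + t * t / (nu * shrink)) ** (-(nu + 1) / 2.0)
        prior = r / np.sqrt(2.0 * np.pi) * g**-1.5 * np.exp(-r * r / (2.0 * g))
        return like * prior

    null_like = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * max(num, 1e-12):
        raise ArithmeticError(
            f"g-integral did not converge (value={num!r}, abserr={err!r})"
        )
    return BayesResult(bf10=float(num / null_like), prior_scale=prior_scale)


def jzs_bayes_factor(a, b, prior_scale: float = 0.707) -> BayesResult:
    """JZS default-prior Bayesian independent-samples t test on raw data."""
    x, y = _clean(a, "a"), _clean(b, "b")
    t = independent_t(x, y).statistic
    return jzs_bayes_factor_from_t(t, x.size, y.size, prior_scale)
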