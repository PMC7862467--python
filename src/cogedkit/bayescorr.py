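"""Bayes factors and posterior summaries for (partial) Pearson correlations.

The observed correlation coefficient ``r`` of ``n`` bivariate-normal pairs is
a sufficient summary for the population correlation ``rho``; its exact
sampling density (up to r-only factors that cancel in likelihood ratios) is

    f(r | rho, n)  proportional to  (1 - rho^2)^((n-1)/2)
                                    * (1 - rho*r)^(-(n - 3/2))
                                    * 2F1(1/2, 1/2; n - 1/2; (1 + rho*r)/2)

The Bayes factor contrasting a correlated model against the point null is
the prior-weighted average likelihood ratio

    BF10 = integral  f(r | rho, n) / f(r | 0, n)  pi(rho)  drho

computed by adaptive quadrature (relative tolerance 1e-8, well under the
documented 1e-6).  Posterior summaries (median, 95% credible interval) come
from the normalized integrand evaluated on a tanh-transformed grid, which
concentrates nodes near the endpoints where the likelihood can peak.

Two prior families over (-1, 1) are provided:

* ``truncated-cauchy`` (default): a zero-centered Cauchy with scale
  ``sqrt(2)/2``, truncated to (-1, 1) and renormalized — the literal reading
  of a "Cauchy (mu = 0, r = sqrt(2)/2)" prior on a correlation;
* ``stretched-beta``: rho = 2*Beta(1/k, 1/k) - 1 with k the scale, the
  convention of common Bayes-factor software (k = 1 is uniform).

Either family may be restricted to positive correlations (``sided =
"positive"``), which renormalizes the prior on [0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, special

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
)

__all__ = ["PriorSpec", "BFResult", "correlation_bf", "partial_correlation_bf"]

SQRT2_2 = math.sqrt(2) / 2

_FAMILIES = ("truncated-cauchy", "stretched-beta")
_SIDES = ("two", "positive")


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the population correlation under the alternative."""

    family: str = "truncated-cauchy"
    scale: float = SQRT2_2
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"family must be one of {_FAMILIES}")
        if self.sided not in _SIDES:
            raise ConfigurationError(f"sided must be one of {_SIDES}")
        if not self.scale > 0:
            raise ConfigurationError("prior scale must be positive")

    @property
    def support(self) -> Tuple[float, float]:
        return (0.0, 1.0) if self.sided == "positive" else (-1.0, 1.0)

    def pdf(self, rho):
        """Normalized prior density on the support (vectorized)."""
        rho = np.asarray(rho, dtype=float)
        if self.family == "truncated-cauchy":
            s = self.scale
            dens = 1.0 / (math.pi * s * (1.0 + (rho / s) ** 2))
            z = 2.0 / math.pi * math.atan(1.0 / s)  # mass of the Cauchy on (-1, 1)
        else:
            a = 1.0 / self.scale
            dens = (1.0 - rho**2) ** (a - 1.0) / special.beta(a, a) / 2 ** (2 * a - 1)
            z = 1.0
        lo, _ = self.support
        out = dens / z
        if self.sided == "positive":
            out = np.where(rho >= 0, 2.0 * out, 0.0)
        out = np.where((rho <= -1) | (rho >= 1), 0.0, out)
        return out if out.ndim else float(out)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from the prior (inverse-CDF for the Cauchy, beta otherwise)."""
        if self.family == "truncated-cauchy":
            s = self.scale
            amax = math.atan(1.0 / s)
            lo = 0.0 if self.sided == "positive" else -amax
            u = rng.uniform(lo, amax, size)
            return s * np.tan(u)
        a = 1.0 / self.scale
        draws = 2.0 * rng.beta(a, a, size) - 1.0
        if self.sided == "positive":
            draws = np.abs(draws)
        return draws


@dataclass
class BFResult:
    """Bayes factor and posterior summaries for one correlation test."""

    bf10: float
    posterior_median_rho: float
    credible_interval_95: Tuple[float, float]
    n: int
    sample_r: float
    prior: PriorSpec
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.credible_interval_95
        if not lo <= self.posterior_median_rho <= hi:
            raise RuntimeError("credible interval does not contain the median")

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "sample_r": self.sample_r,
            "n": self.n,
            "bf10": self.bf10,
            "posterior_median_rho": self.posterior_median_rho,
            "ci_lower": self.credible_interval_95[0],
            "ci_upper": self.credible_interval_95[1],
            "prior_family": self.prior.family,
            "prior_scale": self.prior.scale,
            "prior_sided": self.prior.sided,
        }

    def __str__(self) -> str:
        lo, hi = self.credible_interval_95
        return (
            f"r = {self.sample_r:.4f} (n = {self.n}): BF10 = {self.bf10:.4g}, "
            f"posterior median rho = {self.posterior_median_rho:.4f} "
            f"[{lo:.4f}, {hi:.4f}]"
        )


def log_likelihood_ratio(rho, r: float, n: int):
    """log f(r | rho, n) - log f(r | 0, n) for the Pearson r sampling density."""
    rho = np.asarray(rho, dtype=float)
    h1 = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    h0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return (
        0.5 * (n - 1) * np.log1p(-rho**2)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(h1)
        - np.log(h0)
    )


def _validate(r: float, n: int) -> None:
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 observations, got {n}")
    if not np.isfinite(r) or abs(r) >= 1:
        raise DegenerateInputError(f"sample correlation must satisfy |r| < 1, got {r}")


def _posterior_grid(r: float, n: int, prior: PriorSpec, m: int = 4001):
    """(rho, unnormalized posterior density) on a tanh-transformed grid."""
    lo, _ = prior.support
    zlo = 0.0 if lo == 0.0 else -8.0
    z = np.linspace(zlo, 8.0, m)
    rho = np.tanh(z)
    logpost = log_likelihood_ratio(rho, r, n) + np.log(prior.pdf(rho) + 1e-300)
    dens = np.exp(logpost - logpost.max())
    return rho, dens


def posterior_quantiles(r: float, n: int, prior: PriorSpec, qs=(0.025, 0.5, 0.975)):
    """Posterior quantiles of rho from the normalized grid density."""
    rho, dens = _posterior_grid(r, n, prior)
    cdf = integrate.cumulative_trapezoid(dens, rho, initial=0.0)
    cdf /= cdf[-1]
    return tuple(float(np.interp(q, cdf, rho)) for q in qs)


def posterior_density_at(rho0: float, r: float, n: int, prior: PriorSpec) -> float:
    """Normalized posterior density at one point (Savage-Dickey ingredient)."""
    rho, dens = _posterior_grid(r, n, prior)
    norm = integrate.trapezoid(dens, rho)
    logs = log_likelihood_ratio(rho, r, n) + np.log(prior.pdf(rho) + 1e-300)
    log_at = log_likelihood_ratio(np.array([rho0]), r, n)[0] + math.log(
        float(prior.pdf(rho0)) + 1e-300
    )
    return float(np.exp(log_at - logs.max()) / norm)


def correlation_bf(
    sample_r: float, n: int, prior: Optional[PriorSpec] = None, label: str = ""
) -> BFResult:
    """Bayes factor and posterior for a Pearson correlation.

    Parameters
    ----------
    sample_r
        Observed correlation, |r| < 1.
    n
        Number of observation pairs (>= 4).
    prior
        Prior on rho under the alternative; defaults to the two-sided
        truncated Cauchy with scale sqrt(2)/2.
    """
    prior = prior or PriorSpec()
    _validate(sample_r, n)
    lo, hi = prior.support

    def integrand(rho: float) -> float:
        return float(
            np.exp(log_likelihood_ratio(rho, sample_r, n)) * prior.pdf(rho)
        )

    points = [sample_r] if lo < sample_r < hi else None
    bf10, _ = integrate.quad(
        integrand, lo, hi, points=points, limit=400, epsrel=1e-8, epsabs=0
    )
    ci_lo, med, ci_hi = posterior_quantiles(sample_r, n, prior)
    if abs(sample_r) < 1e-15 and prior.sided == "two":
        med = 0.0  # exact by symmetry; the grid median is within one node of 0
    return BFResult(
        bf10=float(bf10),
        posterior_median_rho=med,
        credible_interval_95=(ci_lo, ci_hi),
        n=n,
        sample_r=float(sample_r),
        prior=prior,
        label=label,
    )


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), controls])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation_bf(
    x_resid: pd.Series,
    y_resid: pd.Series,
    controls: pd.DataFrame,
    prior: Optional[PriorSpec] = None,
    label: str = "",
) -> BFResult:
    """Bayes factor for the partial correlation of two participant-keyed vectors.

    Both vectors are residualized on the control columns (with intercept),
    the Pearson correlation of the residuals is computed, and
    :func:`correlation_bf` is applied with an effective sample size of
    ``n - n_controls`` to account for the fitted control coefficients.
    """
    prior = prior or PriorSpec()
    x_keys, y_keys, c_keys = set(x_resid.index), set(y_resid.index), set(controls.index)
    if not (x_keys == y_keys == c_keys):
        offenders = sorted((x_keys | y_keys | c_keys) - (x_keys & y_keys & c_keys))
        raise AlignmentError(
            f"participant keys do not align; offenders: {offenders[:10]}",
            offenders=offenders,
        )
    idx = sorted(x_keys)
    k = controls.shape[1]
    if len(idx) < 4 + k:
        raise InsufficientDataError(
            f"need at least {4 + k} observations for {k} controls, got {len(idx)}"
        )
    C = controls.loc[idx].to_numpy(float)
    rx = _residualize(x_resid.loc[idx].to_numpy(float), C)
    ry = _residualize(y_resid.loc[idx].to_numpy(float), C)
    # a vector fully explained by the controls has no residual variance left
    # to correlate; its partial correlation is taken as exactly zero
    if np.std(rx) < 1e-12 or np.std(ry) < 1e-12:
        r = 0.0
    else:
        r = float(np.corrcoef(rx, ry)[0, 1])
    return correlation_bf(r, len(idx) - k, prior=prior, label=label)


# ---------------------------------------------------------------------------
# fast fixed-grid evaluator used by the sequential design simulator
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _gauss_nodes(prior: PriorSpec, order: int = 200):
    lo, hi = prior.support
    x, w = np.polynomial.legendre.leggauss(order)
    nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    weights = 0.5 * (hi - lo) * w * prior.pdf(nodes)
    return nodes, weights


def bf10_fixed_grid(r: float, n: int, prior: Optional[PriorSpec] = None) -> float:
    """BF10 by fixed-order Gauss-Legendre quadrature (vectorized, no adaptivity).

    Used inside simulation loops; agrees with :func:`correlation_bf` to well
    under 0.1% over the (r, n) ranges exercised there (checked in the test
    suite).
    """
    prior = prior or PriorSpec()
    _validate(r, n)
    nodes, weights = _gauss_nodes(prior)
    return float(np.exp(log_likelihood_ratio(nodes, r, n)) @ weights)
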