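"""Box-Cox Cole-Green (BCCG / LMS) distribution math and normal-theory
centile precision.

The BCCG distribution underlies the LMS method of centile construction: a
measurement ``y > 0`` at a given age is described by its median ``mu``, its
generalised coefficient of variation ``sigma`` (so the generalised SD is
``mu * sigma``) and a Box-Cox skewness power ``nu``.  After the Box-Cox
transform the measurement is a standard normal z-score, which is what makes
centile curves and their standard errors tractable on the z-score scale.

This module is pure math: the centile <-> z-score transforms, the BCCG
log-density used by the penalized-likelihood fitter, random generation, and
the single-age-group normal-theory precision formulas

    SE_z(z, n) = sqrt((1 + z^2/2) / n)        and its inverse for n.

Everything downstream (simulation, fitting, bootstrap, design) builds on
these few functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BCCGParams",
    "CentileSpec",
    "NINE_CENTILE_ZS",
    "centile_from_z",
    "z_from_measurement",
    "se_z_normal",
    "n_from_se",
    "bccg_logdensity",
    "random_bccg",
    "bccg_quantile_arrays",
]

# The nine standard chart centiles, spaced two-thirds of a z-score apart,
# 0.4th to 99.6th.  By the usual rounded-centile convention z = +/-2 is
# labelled the 2nd/98th centile and z = +/-2.67 the 0.4th/99.6th.
NINE_CENTILE_ZS: tuple[float, ...] = (
    -2.67, -2.0, -1.33, -0.67, 0.0, 0.67, 1.33, 2.0, 2.67,
)


@dataclass(frozen=True)
class BCCGParams:
    """BCCG parameters at a single age.

    Attributes
    ----------
    mu : float
        Median, in measurement units; must be positive.
    sigma : float
        Generalised coefficient of variation (dimensionless, positive).
        The generalised SD is ``mu * sigma``.
    nu : float
        Box-Cox skewness power; ``nu = 1`` is (shifted) normal,
        ``nu = 0`` lognormal.
    """

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class CentileSpec:
    """A centile identified both as a proportion and a normal deviate.

    ``z_alpha`` must equal the standard-normal quantile of ``alpha`` except
    for the conventional rounded centiles: the "2nd"/"98th" are z = -/+2
    exactly and the "0.4th"/"99.6th" are z = -/+2.67 exactly.
    """

    alpha: float
    z_alpha: float

    _ROUNDED = {-2.67, -2.0, 2.0, 2.67}

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.z_alpha in self._ROUNDED:
            # rounded-centile aliases: alpha only has to match loosely
            if abs(stats.norm.cdf(self.z_alpha) - self.alpha) > 0.01:
                raise ValueError(
                    f"alpha={self.alpha} inconsistent with rounded z={self.z_alpha}"
                )
        elif abs(stats.norm.ppf(self.alpha) - self.z_alpha) > 1e-10:
            raise ValueError(
                f"z_alpha={self.z_alpha} is not the normal quantile of alpha={self.alpha}"
            )

    @classmethod
    def from_z(cls, z: float) -> "CentileSpec":
        return cls(alpha=float(stats.norm.cdf(z)), z_alpha=float(z))

    @classmethod
    def from_percent(cls, percent: float) -> "CentileSpec":
        alpha = percent / 100.0
        return cls(alpha=alpha, z_alpha=float(stats.norm.ppf(alpha)))

    @property
    def percent(self) -> float:
        return 100.0 * self.alpha


# below this, the Box-Cox branch is numerically indistinguishable from the
# lognormal (nu=0) branch: the leading correction is O(nu*(sigma*z)^2/2)
_NU_EPS = 1e-10


def _check_domain(params: BCCGParams, z: np.ndarray) -> None:
    if abs(params.nu) > _NU_EPS:
        bad = 1.0 + params.nu * params.sigma * np.asarray(z) <= 0.0
        if np.any(bad):
            raise ValueError(
                "z outside the BCCG domain: 1 + nu*sigma*z must be positive "
                f"(nu={params.nu}, sigma={params.sigma})"
            )


def centile_from_z(params: BCCGParams, z):
    """Measurement centile corresponding to normal deviate ``z``.

    ``C = mu * (1 + nu*sigma*z)**(1/nu)`` for ``nu != 0``, and
    ``C = mu * exp(sigma*z)`` for ``nu = 0``.  Strictly increasing in z,
    equal to the median at z = 0.
    """
    z = np.asarray(z, dtype=float)
    _check_domain(params, z)
    if abs(params.nu) <= _NU_EPS:
        out = params.mu * np.exp(params.sigma * z)
    else:
        # (1 + nu*sigma*z)^(1/nu) via log1p for stability at small |nu|
        out = params.mu * np.exp(np.log1p(params.nu * params.sigma * z) / params.nu)
    return out if out.ndim else float(out)


def z_from_measurement(params: BCCGParams, y):
    """z-score of measurement ``y`` under BCCG parameters (inverse of
    :func:`centile_from_z`)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0):
        raise ValueError("measurements must be positive")
    if abs(params.nu) <= _NU_EPS:
        out = np.log(y / params.mu) / params.sigma
    else:
        # ((y/mu)^nu - 1)/(nu*sigma) via expm1 for stability at small |nu|
        out = np.expm1(params.nu * np.log(y / params.mu)) / (
            params.nu * params.sigma
        )
    return out if out.ndim else float(out)


def se_z_normal(z_alpha: float, n: float) -> float:
    """Normal-theory SE of a sample centile in z-score units for a single
    age group of size ``n``: ``sqrt((1 + z^2/2)/n)``.

    Independent of mu and sigma, hence of the measurement; even in z.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return math.sqrt((1.0 + z_alpha**2 / 2.0) / n)


def n_from_se(z_alpha: float, se_z: float) -> float:
    """Single-age-group sample size achieving target SE_z for a centile:
    ``n = (1 + z^2/2)/SE_z^2`` (exact inverse of :func:`se_z_normal`)."""
    if se_z <= 0:
        raise ValueError(f"se_z must be positive, got {se_z}")
    return (1.0 + z_alpha**2 / 2.0) / se_z**2


def bccg_logdensity(params: BCCGParams, y):
    """Log-density of the BCCG distribution at ``y``.

    The density of y such that the Box-Cox z-score is standard normal,
    with Jacobian ``y^(nu-1) / (mu^nu * sigma)``; the (negligible for
    moderate sigma*|nu|) y>0 truncation mass is ignored, as is standard
    in LMS practice.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0):
        raise ValueError("measurements must be positive")
    z = z_from_measurement(params, y)
    out = (
        (params.nu - 1.0) * np.log(y)
        - params.nu * math.log(params.mu)
        - math.log(params.sigma)
        - 0.5 * z**2
        - 0.5 * math.log(2.0 * math.pi)
    )
    return out if out.ndim else float(out)


def random_bccg(
    params_at_ages: Sequence[BCCGParams],
    rng: np.random.Generator,
    uniforms: np.ndarray | None = None,
) -> np.ndarray:
    """One random BCCG measurement per parameter set.

    Draws a uniform proportion alpha per age, converts it to a normal
    deviate and then to a measurement through the centile transform — so
    the z-scores of the output under the generating parameters are exactly
    standard normal.  ``uniforms`` overrides the draws (for tests).
    """
    m = len(params_at_ages)
    if uniforms is None:
        uniforms = rng.uniform(size=m)
    else:
        uniforms = np.asarray(uniforms, dtype=float)
        if uniforms.shape != (m,):
            raise ValueError("uniforms must have one value per parameter set")
    zs = stats.norm.ppf(uniforms)
    mu = np.array([p.mu for p in params_at_ages])
    sigma = np.array([p.sigma for p in params_at_ages])
    nu = np.array([p.nu for p in params_at_ages])
    return bccg_quantile_arrays(mu, sigma, nu, zs)


def bccg_quantile_arrays(mu, sigma, nu, z) -> np.ndarray:
    """Vectorised centile transform for elementwise (mu, sigma, nu, z)
    arrays; the workhorse behind dataset simulation and centile tables."""
    mu, sigma, nu, z = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu, sigma, nu, z))
    )
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("mu and sigma must be positive")
    arg = nu * sigma * z
    nz = np.abs(nu) > _NU_EPS
    if np.any(arg[nz] <= -1.0):
        raise ValueError("z outside the BCCG domain: 1 + nu*sigma*z <= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            nz,
            mu * np.exp(np.log1p(np.where(nz, arg, 0.0)) / np.where(nz, nu, 1.0)),
            mu * np.exp(sigma * z),
        )
    return out
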