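"""Base models: age-varying BCCG moment curves.

A :class:`MomentCurveSet` bundles smooth curves mu(t), sigma(t), nu(t) over
an age domain.  It serves two roles: (i) the "base model" from which
synthetic cross-sectional datasets are simulated, and (ii) the scoring
model that converts measurements to z-scores.  Models can be read from and
written to standard LMS reference tables (CSV with columns age, L, M, S as
published by WHO/CDC, where L = nu, M = mu, S = sigma).

The bundled fixtures are synthetic: deterministic parametric curves on
[0, 20] years that emulate the qualitative shape of boys' weight, height,
BMI and head-circumference references — a median steep in infancy and
decelerating through childhood (with a mild pubertal inflection for height
and weight), and slowly varying CV and skewness.  Each fixture's median is
built to be closest to linear on the age^lambda scale near the age power
typical for its measurement (0.75 weight, 0.50 height, 0.31 BMI and head
circumference).  They make no claim of numerical equality with any
published reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .bccg import BCCGParams, CentileSpec, NINE_CENTILE_ZS, bccg_quantile_arrays

__all__ = [
    "MomentCurveSet",
    "eval_moments",
    "read_lms_table",
    "write_lms_table",
    "make_fixture",
    "centile_table",
    "curvature_minimizing_lambda",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("weight", "height", "bmi", "headcirc")

_DOMAIN_TOL = 1e-9


@dataclass
class MomentCurveSet:
    """Smooth BCCG moment curves over an age domain (decimal years)."""

    age_min: float
    age_max: float
    mu_curve: Callable[[np.ndarray], np.ndarray]
    sigma_curve: Callable[[np.ndarray], np.ndarray]
    nu_curve: Callable[[np.ndarray], np.ndarray]
    label: str = "measurement"
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.age_max > self.age_min):
            raise ValueError("age_max must exceed age_min")

    def _check_ages(self, ages: np.ndarray) -> None:
        if np.any(ages < self.age_min - _DOMAIN_TOL) or np.any(
            ages > self.age_max + _DOMAIN_TOL
        ):
            raise ValueError(
                f"age outside model domain [{self.age_min}, {self.age_max}]"
            )

    def moments(self, ages) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu, sigma, nu) arrays at the given ages; no extrapolation."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        self._check_ages(ages)
        mu = np.asarray(self.mu_curve(ages), dtype=float)
        sigma = np.asarray(self.sigma_curve(ages), dtype=float)
        nu = np.asarray(self.nu_curve(ages), dtype=float)
        if np.any(mu <= 0) or np.any(sigma <= 0):
            raise ValueError("model invalid: mu and sigma must stay positive")
        return mu, sigma, nu


def eval_moments(model: MomentCurveSet, ages) -> list[BCCGParams]:
    """One :class:`BCCGParams` per age (ages must lie in the model domain)."""
    mu, sigma, nu = model.moments(ages)
    return [BCCGParams(m, s, n) for m, s, n in zip(mu, sigma, nu)]


# ---------------------------------------------------------------------------
# LMS table I/O (CSV: age,L,M,S; L = nu, M = mu, S = sigma)
# ---------------------------------------------------------------------------

def read_lms_table(path) -> MomentCurveSet:
    """Read an LMS reference table into a moment-curve model.

    Rows are interpolated with monotone (shape-preserving) cubics, so the
    fitted curves pass through every tabulated value without overshoot;
    the model domain is [first age, last age].
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [k for k in ("age", "l", "m", "s") if k not in cols]
    if missing:
        raise ValueError(
            f"LMS table {path} is missing column(s): {', '.join(m.upper() for m in missing)}"
        )
    age = df[cols["age"]].to_numpy(dtype=float)
    L = df[cols["l"]].to_numpy(dtype=float)
    M = df[cols["m"]].to_numpy(dtype=float)
    S = df[cols["s"]].to_numpy(dtype=float)
    if len(age) < 2:
        raise ValueError("LMS table needs at least two rows")
    bad = np.where(np.diff(age) <= 0)[0]
    if bad.size:
        raise ValueError(f"LMS table ages not strictly increasing at row {bad[0] + 2}")
    for name, v in (("M", M), ("S", S)):
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise ValueError(f"non-positive {name} at row {bad[0] + 2}")
    mu_f = PchipInterpolator(age, M, extrapolate=False)
    sigma_f = PchipInterpolator(age, S, extrapolate=False)
    nu_f = PchipInterpolator(age, L, extrapolate=False)
    return MomentCurveSet(
        age_min=float(age[0]),
        age_max=float(age[-1]),
        mu_curve=mu_f,
        sigma_curve=sigma_f,
        nu_curve=nu_f,
        label="lms_table",
    )


def write_lms_table(model: MomentCurveSet, ages, path) -> None:
    """Write the model evaluated on an age grid as a CSV LMS table
    (header ``age,L,M,S``, 6 significant digits)."""
    ages = np.asarray(ages, dtype=float)
    mu, sigma, nu = model.moments(ages)
    df = pd.DataFrame({"age": ages, "L": nu, "M": mu, "S": sigma})
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def _sigmoid(t, centre, scale):
    return 1.0 / (1.0 + np.exp(-(t - centre) / scale))


def _fixture_curves(kind: str):
    # Median: a + b*age^p (the dominant term, linear on the age^p scale)
    # plus, for height/weight, a mild pubertal logistic inflection.
    if kind == "height":
        mu = lambda t: 51.0 + 27.5 * np.power(t, 0.50) + 5.0 * _sigmoid(t, 13.0, 0.9)
        sigma = lambda t: 0.037 + 0.008 * np.exp(-t / 3.0)
        nu = lambda t: 1.0 - 0.02 * t
        units = "cm"
    elif kind == "weight":
        mu = lambda t: 3.5 + 7.0 * np.power(t, 0.70) + 2.5 * _sigmoid(t, 13.0, 1.2)
        # weight CV: infancy hump, mid-childhood dip, pubertal rise
        sigma = PchipInterpolator(
            [0.0, 1.0, 4.0, 8.0, 13.0, 20.0],
            [0.125, 0.135, 0.115, 0.120, 0.150, 0.135],
        )
        nu = PchipInterpolator(
            [0.0, 1.0, 4.0, 8.0, 13.0, 20.0],
            [0.2, 0.1, -0.1, -0.25, -0.45, -0.35],
        )
        units = "kg"
    elif kind == "bmi":
        mu = lambda t: 13.2 + 2.5 * np.power(t, 0.31)
        sigma = lambda t: 0.08 + 0.05 * (t / 20.0)
        nu = lambda t: -0.3 - 1.0 * (t / 20.0)
        units = "kg/m^2"
    elif kind == "headcirc":
        mu = lambda t: 35.0 + 7.3 * np.power(t, 0.31)
        sigma = lambda t: 0.031 - 0.004 * (t / 20.0)
        nu = lambda t: 1.0 - 0.5 * (t / 20.0)
        units = "cm"
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return mu, sigma, nu, units


def make_fixture(kind: str) -> MomentCurveSet:
    """Deterministic synthetic base model on [0, 20] years.

    ``kind`` is one of ``weight``, ``height``, ``bmi``, ``headcirc``.
    """
    mu, sigma, nu, units = _fixture_curves(kind)
    return MomentCurveSet(
        age_min=0.0,
        age_max=20.0,
        mu_curve=mu,
        sigma_curve=sigma,
        nu_curve=nu,
        label=kind,
        units=units,
    )


def curvature_minimizing_lambda(
    model: MomentCurveSet,
    lambdas: Sequence[float] | None = None,
    n_grid: int = 201,
) -> float:
    """Age power making the median closest to linear on the age^lambda scale.

    For each candidate power, regress mu(t) on [1, t^lambda] by least
    squares over an even age grid and record the residual sum of squares;
    return the argmin.  Used to characterise fixtures and fitted models.
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 1.0001, 0.01)
    t = np.linspace(model.age_min, model.age_max, n_grid)
    mu, _, _ = model.moments(t)
    best_lam, best_rss = None, np.inf
    for lam in lambdas:
        X = np.column_stack([np.ones_like(t), np.power(t, lam)])
        _, rss, *_ = np.linalg.lstsq(X, mu, rcond=None)
        rss = float(rss[0]) if len(rss) else float(
            np.sum((mu - X @ np.linalg.lstsq(X, mu, rcond=None)[0]) ** 2)
        )
        if rss < best_rss:
            best_lam, best_rss = float(lam), rss
    return best_lam


# ---------------------------------------------------------------------------
# Centile tables
# ---------------------------------------------------------------------------

def centile_table(
    model: MomentCurveSet,
    centiles: Sequence[CentileSpec] | None = None,
    ages=None,
) -> pd.DataFrame:
    """Centile matrix: one row per age, one column per centile.

    Default centiles are the nine chart centiles (z from -2.67 to 2.67 in
    steps of 2/3, rounded convention).  Columns are guaranteed strictly
    increasing across centiles at every age by construction (the centile
    transform is monotone in z).
    """
    if centiles is None:
        centiles = [CentileSpec.from_z(z) for z in NINE_CENTILE_ZS]
    if ages is None:
        ages = np.arange(model.age_min, model.age_max + 1e-9, 0.1)
    ages = np.asarray(ages, dtype=float)
    mu, sigma, nu = model.moments(ages)
    data = {"age": ages}
    for spec in centiles:
        data[f"P{spec.percent:g}"] = bccg_quantile_arrays(mu, sigma, nu, spec.z_alpha)
    return pd.DataFrame(data)
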