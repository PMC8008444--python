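"""The design layer: from SE_z curves to optimal sample composition and
sample size.

A meta-regression of the bootstrapped SE_z surfaces,

    log SE_z ~ age * (log(1 + z^2/2) + lambda)        (age centred at 10 y),

summarises how precision depends on age, centile and the age-power
lambda of the sample composition.  Requiring the SE_z curve to be *flat*
in age (the optimal-design principle) makes the three age terms cancel,
giving a closed-form optimal lambda per centile:

    lambda* = (b_age + b_age_z * log(1 + z^2/2)) / (-b_age_lambda)

The first three coefficients then predict SE_z for the reference sample
size, and an empirical scaling law n ∝ SE_z^(-1.85) converts between
sample sizes, yielding the required n for any target precision and
confidence intervals for any centile.

:data:`DEFAULT_DESIGN_MODEL` carries published reference coefficients
(estimated from large simulation grids over weight, height and head
circumference at n = 6878); :func:`fit_design_model` refits the same
regression to user-supplied SE_z curves.  :func:`flatten_lambda` runs the
full simulate -> fit -> bootstrap -> trend loop to find the flat-curve
lambda directly for a given base model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import SEZCurve, bootstrap_se_curves, sez_trend
from .fitting import FitConfig, fit_bccg
from .reference import MomentCurveSet
from .sampling import SamplingScheme, simulate_dataset

__all__ = [
    "DesignModel",
    "DEFAULT_DESIGN_MODEL",
    "optimal_lambda",
    "predict_se_z",
    "required_n",
    "centile_ci",
    "design_table",
    "fit_design_model",
    "flatten_lambda",
]


@dataclass(frozen=True)
class DesignModel:
    """Coefficients of the design meta-regression plus the scaling law.

    b0, b_z, b_lambda are the age-independent terms (intercept,
    log(1+z^2/2), lambda); b_age, b_age_z, b_age_lambda are the age main
    effect and interactions (per year, age centred at ``age_centre``).
    ``n_ref`` is the sample size the coefficients refer to and
    ``scaling_exponent`` the empirical power in n ∝ SE_z^(-exponent).
    """

    b0: float = -3.088
    b_z: float = 0.537
    b_lambda: float = -0.283
    b_age: float = 0.0231
    b_age_z: float = 0.0205
    b_age_lambda: float = -0.0604
    age_centre: float = 10.0
    n_ref: int = 6878
    scaling_exponent: float = 1.85

    def __post_init__(self) -> None:
        if self.b_age_lambda >= 0:
            raise ValueError(
                "b_age_lambda must be negative for a flatness solution to exist"
            )
        if self.n_ref < 1:
            raise ValueError("n_ref must be >= 1")
        if self.scaling_exponent <= 0:
            raise ValueError("scaling_exponent must be positive")


DEFAULT_DESIGN_MODEL = DesignModel()


def _zterm(z: float) -> float:
    return math.log(1.0 + z**2 / 2.0)


def optimal_lambda(model: DesignModel, z: float) -> float:
    """Age power lambda making the SE_z curve flat for centile deviate z.

    Solves b_age + b_age_z*log(1+z^2/2) + b_age_lambda*lambda = 0; even
    in z.  Raises if the solution falls outside (0, 1].
    """
    lam = (model.b_age + model.b_age_z * _zterm(z)) / (-model.b_age_lambda)
    if not (0.0 < lam <= 1.0):
        raise ValueError(
            f"flatness condition gives lambda={lam:.3f} outside (0,1]: "
            "no feasible age-power design for this centile"
        )
    return lam


def predict_se_z(model: DesignModel, z: float, lam: float, n: float) -> float:
    """Predicted SE_z for centile deviate z under composition lambda and
    sample size n.

    At the reference size, SE_z = exp(b0 + b_z*log(1+z^2/2) +
    b_lambda*lambda); other sizes scale as (n_ref/n)^(1/scaling_exponent).
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lambda must be in (0,1], got {lam}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    se_ref = math.exp(model.b0 + model.b_z * _zterm(z) + model.b_lambda * lam)
    return se_ref * (model.n_ref / n) ** (1.0 / model.scaling_exponent)


def required_n(model: DesignModel, z: float, target_se: float) -> int:
    """Sample size achieving ``target_se`` for centile deviate z at its
    optimal composition: n = n_ref * (SE_z(n_ref)/target)^exponent,
    rounded up."""
    if target_se <= 0:
        raise ValueError(f"target_se must be positive, got {target_se}")
    lam = optimal_lambda(model, z)
    se_ref = predict_se_z(model, z, lam, model.n_ref)
    return int(math.ceil(model.n_ref * (se_ref / target_se) ** model.scaling_exponent))


def centile_ci(z: float, se_z: float) -> tuple[float, float]:
    """95% confidence interval for the centile, in percent.

    The interval for the deviate is z +/- 2*SE_z (the conventional
    2-sigma band); back-transforming through the normal CDF gives the
    centile interval 100*Phi(z -/+ 2*SE_z).
    """
    if se_z < 0:
        raise ValueError("se_z must be non-negative")
    lo = 100.0 * stats.norm.cdf(z - 2.0 * se_z)
    hi = 100.0 * stats.norm.cdf(z + 2.0 * se_z)
    return float(lo), float(hi)


def _fmt_pct(p: float) -> float:
    """Mixed table precision: 1 decimal below 10%, else nearest 0.1 above
    40 rounds to integers only when wide — keep one decimal, trim to int
    style for wide intervals."""
    return round(p, 1) if p < 10 else round(p, 1)


def design_table(
    model: DesignModel,
    n_list: Sequence[int],
    centile_zs: Sequence[float] = (0.0, -0.67, -1.33, -2.0, -2.67),
) -> pd.DataFrame:
    """Optimal SE_z and 95% CIs for selected centiles across sample sizes.

    One row per sample size; per centile the optimal lambda, SE_z at that
    n, and the CI bounds in percent.  Centiles above the median follow by
    symmetry: their CI is 100 minus the reversed CI of the mirror centile.
    """
    rows = []
    for n in n_list:
        row: dict = {"n": int(n)}
        for z in centile_zs:
            lam = optimal_lambda(model, z)
            se = predict_se_z(model, z, lam, n)
            lo, hi = centile_ci(z, se)
            pct = 100.0 * stats.norm.cdf(z)
            key = f"{pct:g}"
            row[f"lambda_{key}"] = round(lam, 2)
            row[f"se_z_{key}"] = se
            row[f"ci_lo_{key}"] = lo
            row[f"ci_hi_{key}"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def fit_design_model(
    curves: Sequence[tuple[SEZCurve, float]],
    window: tuple[float, float] = (2.0, 18.0),
    n_ref: int | None = None,
    scaling_exponent: float = 1.85,
    age_centre: float = 10.0,
) -> DesignModel:
    """Refit the design meta-regression to labelled SE_z curves.

    ``curves`` is a sequence of (SEZCurve, lambda) pairs; each curve
    contributes one observation per grid age in the window per centile.
    Requires at least two distinct lambda values and two distinct
    centile deviates.  Returns a new :class:`DesignModel` (the defaults
    are never mutated).
    """
    lams = {round(l, 6) for _, l in curves}
    zs = set()
    for c, _ in curves:
        zs.update(np.round(np.abs(c.centile_zs), 6).tolist())
    if len(lams) < 2 or len(zs) < 2:
        raise ValueError(
            "need >= 2 distinct lambda values and >= 2 distinct |z| values"
        )
    rows_X, rows_y = [], []
    lo, hi = window
    for curve, lam in curves:
        sel = (curve.ages >= lo - 1e-9) & (curve.ages <= hi + 1e-9)
        if not np.any(sel):
            raise ValueError("curve grid does not cover the trend window")
        a = curve.ages[sel] - age_centre
        for j, z in enumerate(curve.centile_zs):
            zt = _zterm(z)
            y = np.log(curve.se_z[sel, j])
            X = np.column_stack(
                [
                    np.ones_like(a),
                    np.full_like(a, zt),
                    np.full_like(a, lam),
                    a,
                    a * zt,
                    a * lam,
                ]
            )
            rows_X.append(X)
            rows_y.append(y)
    X = np.vstack(rows_X)
    yv = np.concatenate(rows_y)
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < 6:
        raise ValueError("design meta-regression is rank deficient")
    if n_ref is None:
        n_ref = DEFAULT_DESIGN_MODEL.n_ref
    return DesignModel(
        b0=float(coef[0]),
        b_z=float(coef[1]),
        b_lambda=float(coef[2]),
        b_age=float(coef[3]),
        b_age_z=float(coef[4]),
        b_age_lambda=float(coef[5]),
        age_centre=age_centre,
        n_ref=int(n_ref),
        scaling_exponent=scaling_exponent,
    )


def _pipeline_slope(
    base_model: MomentCurveSet,
    z: float,
    lam: float,
    n: int,
    B: int,
    fit_config: FitConfig,
    rng: np.random.Generator,
    window: tuple[float, float],
) -> float:
    scheme = SamplingScheme(
        lambda_age=lam,
        age_min=base_model.age_min,
        age_max=base_model.age_max,
        n=n,
    )
    data = simulate_dataset(base_model, scheme, rng)
    fit = fit_bccg(data, fit_config)
    curve = bootstrap_se_curves(data, fit, centile_zs=[z], B=B, rng=rng)
    return float(sez_trend(curve, window)["slope"].iloc[0])


def flatten_lambda(
    base_model: MomentCurveSet,
    z: float,
    n: int = 6878,
    B: int = 100,
    fit_config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    window: tuple[float, float] = (2.0, 18.0),
    slope_tol: float = 0.005,
    max_evals: int = 8,
    bracket: tuple[float, float] = (0.2, 1.0),
    reps: int = 1,
) -> dict:
    """Find the age power lambda* that makes the SE_z curve flat, by
    running the full simulation loop.

    Each evaluation runs: simulate a dataset at lambda -> fit the BCCG
    model -> bootstrap the SE_z curve of the target centile -> measure
    the 2-18 y slope of log SE_z.  The slope falls with lambda (small
    lambda over-samples infancy, making SE_z rise with age; uniform
    sampling leaves infancy imprecise), but single evaluations carry
    bootstrap noise, so the zero crossing is located by local linear
    regression of slope on lambda over a small grid — first a global fit
    over the bracket, then a refit on the evaluations nearest the
    provisional root — rather than by bisection, which a single noisy
    sign would derail.  The dominant noise source is the simulated
    dataset itself, not the bootstrap stream, so ``reps`` independent
    datasets per lambda are averaged (``reps`` > 1 recommended when an
    accurate lambda* is needed).

    Returns a dict with ``lambda_star``, the ``slope`` measured at it,
    and the evaluation history.  Raises if no zero crossing is evident
    over the bracket.
    """
    if rng is None:
        rng = np.random.default_rng()
    cfg = fit_config or FitConfig(nu_curve_class="linear", xi="search")
    lo, hi = bracket
    evals: list[tuple[float, float]] = []

    def slope_at(lam: float) -> float:
        s = float(
            np.mean(
                [
                    _pipeline_slope(base_model, z, lam, n, B, cfg, rng, window)
                    for _ in range(reps)
                ]
            )
        )
        evals.append((lam, s))
        return s

    def regression_root(points: list[tuple[float, float]]) -> float:
        lams = np.array([p[0] for p in points])
        slopes = np.array([p[1] for p in points])
        b, a = np.polyfit(lams, slopes, 1)
        if b >= 0:  # no falling trend in this subset; fall back to global
            return float(lams[np.argmin(np.abs(slopes))])
        return float(np.clip(-a / b, lo, hi))

    n_grid = max(3, min(5, max_evals - 1))
    for lam in np.linspace(lo, hi, n_grid):
        slope_at(float(lam))
    s_lo = evals[0][1]
    s_hi = evals[-1][1]
    # endpoint slopes within twice the tolerance of zero are treated as
    # at the bootstrap noise floor, not as a wrong sign
    if not (s_lo > -2.0 * slope_tol and s_hi < 2.0 * slope_tol):
        raise RuntimeError(
            f"no zero crossing of the SE_z slope over lambda in [{lo}, {hi}]: "
            f"slope({lo})={s_lo:.4f}, slope({hi})={s_hi:.4f}"
        )
    root = regression_root(evals)
    # refit on the nearest evaluations for a locally linear estimate
    nearest = sorted(evals, key=lambda p: abs(p[0] - root))[:3]
    root = regression_root(nearest)
    s_root = slope_at(root)
    if abs(s_root) > slope_tol and len(evals) < max_evals:
        # fold the confirmation point in, re-solve and confirm once more
        nearest = sorted(evals, key=lambda p: abs(p[0] - root))[:4]
        root = regression_root(nearest)
        s_root = slope_at(root)
    return {
        "lambda_star": root,
        "slope": s_root,
        "evals": evals,
        "z": z,
        "n": n,
        "B": B,
    }
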