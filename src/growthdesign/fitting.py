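"""Penalized maximum-likelihood BCCG fitting with P-splines.

Estimates the age-varying median mu(t), generalised CV sigma(t) and
Box-Cox power nu(t) of a cross-sectional dataset by cyclic penalized
IRLS (an RS-type backfitting over the three moments):

* each moment gets a design matrix — a cubic B-spline basis with
  equally spaced knots and a difference penalty on adjacent coefficients
  (P-spline, default 20 segments, 2nd-order penalty), or a plain linear
  or constant design;
* mu uses an identity link (with positivity safeguarding), sigma a log
  link, nu an identity link;
* per cycle, each moment is updated by one penalized weighted
  least-squares step on the working response built from the BCCG score
  and (approximate expected) information, with step-halving so the
  penalized log-likelihood never decreases at fixed smoothing;
* smoothing parameters are updated per cycle by a Schall-type
  marginal-likelihood ratio, with an optional BIC-grid fallback.

The mu curve may be fitted on a transformed age scale age^xi with
0 < xi <= 1; the hyperparameter xi is chosen by golden-section search at
(approximately) constant mu-curve degrees of freedom, which straightens
the steep infancy rise and lowers the curvature the spline has to absorb.
sigma and nu are fitted on untransformed age.

The nu curve class can be selected automatically among constant, linear
and smooth by GAIC(3), mirroring common practice of keeping the skewness
curve as simple as the data allow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .bccg import bccg_quantile_arrays
from .reference import MomentCurveSet

__all__ = [
    "FitConfig",
    "BCCGFit",
    "FitError",
    "fit_bccg",
    "refit_fixed",
    "select_xi",
    "information_criteria",
    "residual_zscores",
    "mu_se_z_curve",
]

CurveClass = Literal["smooth", "linear", "constant", "select"]


class FitError(RuntimeError):
    """Raised when the penalized fit cannot be completed."""


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the penalized BCCG fit.

    n_knots is the number of equally spaced B-spline segments (basis
    dimension n_knots + 3 for cubic splines).  xi is the mu-curve age
    power, or "search" to optimise it.  smoothing_selection "ml" uses
    Schall marginal-likelihood updates; "bic-grid" refines the smooth
    terms on a BIC grid afterwards.
    """

    n_knots: int = 20
    penalty_order: int = 2
    mu_curve_class: CurveClass = "smooth"
    sigma_curve_class: CurveClass = "smooth"
    nu_curve_class: CurveClass = "select"
    xi: float | str = "search"
    smoothing_selection: Literal["ml", "bic-grid"] = "ml"
    max_iter: int = 50
    tol: float = 1e-6
    # fixed smoothing parameters per moment (mu, sigma, nu); None = estimate
    fixed_lambdas: tuple[float | None, float | None, float | None] = (None, None, None)
    # hold nu at a known value instead of estimating it (nu=1: normal case)
    nu_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_knots < 4:
            raise ValueError("n_knots must be >= 4")
        if isinstance(self.xi, str):
            if self.xi != "search":
                raise ValueError("xi must be a number in (0,1] or 'search'")
        elif not (0.0 < self.xi <= 1.0):
            raise ValueError(f"xi must be in (0,1], got {self.xi}")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

_DEGREE = 3


def _bspline_knots(lo: float, hi: float, n_seg: int) -> np.ndarray:
    inner = np.linspace(lo, hi, n_seg + 1)
    return np.concatenate(
        [np.full(_DEGREE, lo), inner, np.full(_DEGREE, hi)]
    )


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, knots, _DEGREE).toarray()


@dataclass
class _Term:
    """One moment's linear predictor: design builder + penalty."""

    kind: str  # smooth | linear | constant
    knots: np.ndarray | None  # for smooth
    xref: tuple[float, float] | None  # centring for linear
    penalty: np.ndarray | None
    lam: float
    beta: np.ndarray
    edf: float = 0.0

    def design(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "smooth":
            return _bspline_design(x, self.knots)
        if self.kind == "linear":
            lo, hi = self.xref
            return np.column_stack(
                [np.ones_like(x), (x - lo) / (hi - lo)]
            )
        return np.ones((len(x), 1))

    @property
    def null_dim(self) -> int:
        if self.kind == "smooth":
            return self.penalty_order_null
        return self.beta.size

    penalty_order_null: int = 2


def _make_term(kind: str, x: np.ndarray, cfg: FitConfig, init_value: float) -> _Term:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-8:
        kind = "constant"
    if kind == "smooth":
        knots = _bspline_knots(lo, hi, cfg.n_knots)
        p = cfg.n_knots + _DEGREE
        D = np.diff(np.eye(p), n=cfg.penalty_order, axis=0)
        P = D.T @ D
        beta = np.full(p, init_value)
        return _Term(
            "smooth", knots, None, P, 10.0, beta,
            penalty_order_null=cfg.penalty_order,
        )
    if kind == "linear":
        beta = np.array([init_value, 0.0])
        return _Term("linear", None, (lo, hi), None, 0.0, beta)
    return _Term("constant", None, None, None, 0.0, np.array([init_value]))


# ---------------------------------------------------------------------------
# BCCG score functions (approximate expected information weights)
# ---------------------------------------------------------------------------

def _zscores(y, mu, sigma, nu):
    r = y / mu
    small = np.abs(nu) < 1e-5
    with np.errstate(all="ignore"):
        z = np.where(
            small,
            np.log(r) / sigma,
            (np.power(r, np.where(small, 1.0, nu)) - 1.0)
            / (np.where(small, 1.0, nu) * sigma),
        )
    return z


def _loglik(y, mu, sigma, nu):
    z = _zscores(y, mu, sigma, nu)
    return float(
        np.sum(
            (nu - 1.0) * np.log(y)
            - nu * np.log(mu)
            - np.log(sigma)
            - 0.5 * z**2
            - 0.5 * math.log(2.0 * math.pi)
        )
    )


def _scores_weights(which: str, y, mu, sigma, nu):
    """Score and expected information of the predictor for one moment
    (mu: identity link; sigma: log link; nu: identity link)."""
    z = _zscores(y, mu, sigma, nu)
    if which == "mu":
        s = np.power(y / mu, nu)
        score = (z * s / sigma - nu) / mu
        w = (1.0 + 2.0 * sigma**2 * nu**2) / (mu**2 * sigma**2)
    elif which == "sigma":
        score = z**2 - 1.0  # d loglik / d log(sigma)
        w = np.full_like(z, 2.0)
    else:  # nu
        logr = np.log(y / mu)
        small = np.abs(nu) < 1e-5
        with np.errstate(all="ignore"):
            s = np.power(y / mu, nu)
            dzdnu = np.where(
                small,
                (logr**2 / 2.0 + nu * logr**3 / 3.0) / sigma,
                s * logr / (np.where(small, 1.0, nu) * sigma)
                - z / np.where(small, 1.0, nu),
            )
        # d loglik / d nu = log r - z * dz/dnu (dz/dnu already carries -z/nu)
        score = logr - z * dzdnu
        # expected information for nu (gamlss BCCG approximation)
        w = 7.0 * sigma**2 / 4.0
        w = np.broadcast_to(w, z.shape).copy()
    return score, w


# ---------------------------------------------------------------------------
# Fit object
# ---------------------------------------------------------------------------

@dataclass
class BCCGFit:
    """A converged penalized BCCG fit."""

    terms: dict  # {"mu": _Term, "sigma": _Term, "nu": _Term}
    xi_hat: float
    age_range: tuple[float, float]
    loglik: float
    n_obs: int
    cov_mu: np.ndarray  # sandwich covariance of mu-term coefficients
    n_cycles: int
    config: FitConfig
    loglik_history: list = field(default_factory=list)

    @property
    def edf_mu(self) -> float:
        return self.terms["mu"].edf

    @property
    def edf_sigma(self) -> float:
        return self.terms["sigma"].edf

    @property
    def edf_nu(self) -> float:
        return self.terms["nu"].edf

    @property
    def edf_total(self) -> float:
        return self.edf_mu + self.edf_sigma + self.edf_nu

    def _check_range(self, ages: np.ndarray) -> None:
        lo, hi = self.age_range
        if np.any(ages < lo - 1e-6) or np.any(ages > hi + 1e-6):
            raise ValueError(f"age outside fitted range [{lo}, {hi}]")

    def moments(self, ages) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        self._check_range(ages)
        mu = self.terms["mu"].design(ages**self.xi_hat) @ self.terms["mu"].beta
        sigma = np.exp(self.terms["sigma"].design(ages) @ self.terms["sigma"].beta)
        nu = self.terms["nu"].design(ages) @ self.terms["nu"].beta
        return mu, sigma, nu

    def to_moment_curves(self, label: str = "bccg_fit") -> MomentCurveSet:
        lo, hi = self.age_range
        return MomentCurveSet(
            age_min=lo,
            age_max=hi,
            mu_curve=lambda t: self.moments(t)[0],
            sigma_curve=lambda t: self.moments(t)[1],
            nu_curve=lambda t: self.moments(t)[2],
            label=label,
        )

    def centiles(self, ages, zs) -> np.ndarray:
        """Centile matrix (len(ages) x len(zs)) under the fitted model."""
        mu, sigma, nu = self.moments(ages)
        zs = np.atleast_1d(np.asarray(zs, dtype=float))
        return bccg_quantile_arrays(
            mu[:, None], sigma[:, None], nu[:, None], zs[None, :]
        )

    def summary(self) -> str:
        bic = information_criteria(self, k=3.0)
        return (
            f"BCCG penalized fit: n={self.n_obs}, cycles={self.n_cycles}\n"
            f"  xi (mu age power)  = {self.xi_hat:.2f}\n"
            f"  edf mu/sigma/nu    = {self.edf_mu:.1f} / {self.edf_sigma:.1f} / "
            f"{self.edf_nu:.1f}  ({self.terms['nu'].kind} nu)\n"
            f"  loglik = {self.loglik:.1f}  BIC = {bic['bic']:.1f}  "
            f"GAIC(3) = {bic['gaic_k']:.1f}"
        )


# ---------------------------------------------------------------------------
# The cyclic penalized IRLS
# ---------------------------------------------------------------------------

def _penalized_loglik(y, mu, sigma, nu, terms) -> float:
    ll = _loglik(y, mu, sigma, nu)
    for t in terms.values():
        if t.kind == "smooth":
            ll -= 0.5 * t.lam * float(t.beta @ t.penalty @ t.beta)
    return ll


def _eval_all(terms, x_mu, age):
    mu = terms["mu"].design(x_mu) @ terms["mu"].beta
    sigma = np.exp(
        np.clip(terms["sigma"].design(age) @ terms["sigma"].beta, -20, 5)
    )
    nu = terms["nu"].design(age) @ terms["nu"].beta
    return mu, sigma, nu


def _schall_update(term: _Term, X, w, u, resid) -> float:
    A = X.T @ (w[:, None] * X) + term.lam * term.penalty
    H = np.linalg.solve(A, X.T @ (w[:, None] * X))
    edf = float(np.trace(H))
    n = len(u)
    pen = float(term.beta @ term.penalty @ term.beta)
    sig2_e = float(np.sum(w * resid**2)) / max(n - edf, 1.0)
    d = term.penalty_order_null
    sig2_b = pen / max(edf - d, 1e-3)
    if sig2_b <= 1e-12 * sig2_e:
        return min(term.lam * 10.0, 1e10)
    lam_new = sig2_e / sig2_b
    # damp: at most a factor 10 change per cycle
    lam_new = float(np.clip(lam_new, term.lam / 10.0, term.lam * 10.0))
    return float(np.clip(lam_new, 1e-7, 1e10))


def _fit_inner(
    y: np.ndarray,
    age: np.ndarray,
    cfg: FitConfig,
    xi: float,
    classes: dict,
    warm: dict | None = None,
) -> BCCGFit:
    n = len(y)
    x_mu = age**xi
    # --- initialisation ---
    terms: dict[str, _Term] = {}
    if warm is not None:
        for k, t in warm.items():
            terms[k] = replace(t, beta=t.beta.copy())
    else:
        mu_term = _make_term(classes["mu"], x_mu, cfg, 0.0)
        X0 = mu_term.design(x_mu)
        if mu_term.kind == "smooth":
            A0 = X0.T @ X0 + mu_term.lam * mu_term.penalty
        else:
            A0 = X0.T @ X0 + 1e-10 * np.eye(X0.shape[1])
        mu_term.beta = np.linalg.solve(A0, X0.T @ y)
        mu0 = X0 @ mu_term.beta
        mu0 = np.maximum(mu0, 1e-6 * np.median(y))
        terms["mu"] = mu_term
        cv0 = float(np.std((y - mu0) / np.maximum(mu0, 1e-12)))
        cv0 = min(max(cv0, 1e-3), 1.0)
        terms["sigma"] = _make_term(classes["sigma"], age, cfg, math.log(cv0))
        nu0 = cfg.nu_value if cfg.nu_value is not None else 1.0
        terms["nu"] = _make_term(classes["nu"], age, cfg, nu0)
    for i, k in enumerate(("mu", "sigma", "nu")):
        if cfg.fixed_lambdas[i] is not None and terms[k].kind == "smooth":
            terms[k].lam = float(cfg.fixed_lambdas[i])

    mu, sigma, nu = _eval_all(terms, x_mu, age)
    if np.any(mu <= 0):
        mu = np.maximum(mu, 1e-6 * np.median(y))
    pll = _penalized_loglik(y, mu, sigma, nu, terms)
    history = [pll]
    designs = {"mu": terms["mu"].design(x_mu),
               "sigma": terms["sigma"].design(age),
               "nu": terms["nu"].design(age)}

    converged = False
    cycle = 0
    lam_frozen = False
    lams_prev = {k: t.lam for k, t in terms.items()}
    update_order = ("mu", "sigma") if cfg.nu_value is not None else (
        "mu", "sigma", "nu"
    )
    for cycle in range(1, cfg.max_iter + 1):
        for which in update_order:
            t = terms[which]
            X = designs[which]
            score, w = _scores_weights(which, y, mu, sigma, nu)
            bad = ~np.isfinite(score) | ~np.isfinite(w) | (w <= 0)
            if np.any(bad):
                score = np.where(bad, 0.0, score)
                w = np.where(bad, 1e-8, w)
            eta = X @ t.beta
            u = eta + score / w
            if t.kind == "smooth":
                A = X.T @ (w[:, None] * X) + t.lam * t.penalty
            else:
                A = X.T @ (w[:, None] * X) + 1e-10 * np.eye(X.shape[1])
            try:
                beta_new = np.linalg.solve(A, X.T @ (w * u))
            except np.linalg.LinAlgError as e:
                raise FitError(f"singular basis in {which} update") from e
            # step-halving: never decrease the penalized log-likelihood
            beta_old = t.beta.copy()
            step = 1.0
            for _ in range(20):
                t.beta = beta_old + step * (beta_new - beta_old)
                mu_c, sigma_c, nu_c = _eval_all(terms, x_mu, age)
                if np.all(mu_c > 0) and np.all(np.isfinite(mu_c)):
                    pll_c = _penalized_loglik(y, mu_c, sigma_c, nu_c, terms)
                    if np.isfinite(pll_c) and pll_c >= pll - 1e-9 * abs(pll):
                        break
                step /= 2.0
            else:
                t.beta = beta_old
                mu_c, sigma_c, nu_c = _eval_all(terms, x_mu, age)
                pll_c = pll
            mu, sigma, nu = mu_c, sigma_c, nu_c
            pll = pll_c
            # smoothing update (Schall), unless fixed or frozen
            i = ("mu", "sigma", "nu").index(which)
            if (
                t.kind == "smooth"
                and cfg.fixed_lambdas[i] is None
                and not lam_frozen
            ):
                resid = u - X @ t.beta
                lam_new = _schall_update(t, X, w, u, resid)
                t.lam = lam_new
        history.append(pll)
        rel = abs(history[-1] - history[-2]) / (abs(history[-2]) + 1e-12)
        lam_stable = all(
            abs(math.log10(max(t.lam, 1e-12)) - math.log10(max(lams_prev[k], 1e-12)))
            < 0.05
            for k, t in terms.items()
            if t.kind == "smooth"
        )
        lams_prev = {k: t.lam for k, t in terms.items()}
        if rel < 1e-3 and lam_stable and not lam_frozen:
            lam_frozen = True  # freeze smoothing, polish coefficients
        elif rel < cfg.tol and lam_frozen:
            converged = True
            break
    if not converged and cfg.max_iter >= 10:
        # accept slow tail convergence if the objective has stabilised
        rel = abs(history[-1] - history[-2]) / (abs(history[-2]) + 1e-12)
        if rel < 1e-5:
            converged = True
    if not converged:
        raise FitError(
            f"BCCG fit did not converge in {cfg.max_iter} cycles "
            f"(last rel change {rel:.2e})"
        )

    # final edf and mu covariance at convergence
    if cfg.nu_value is not None:
        terms["nu"].edf = 0.0  # held fixed, not estimated
    for which in update_order:
        t = terms[which]
        X = designs[which]
        _, w = _scores_weights(which, y, mu, sigma, nu)
        w = np.where(np.isfinite(w) & (w > 0), w, 1e-8)
        XtWX = X.T @ (w[:, None] * X)
        if t.kind == "smooth":
            A = XtWX + t.lam * t.penalty
        else:
            A = XtWX + 1e-10 * np.eye(X.shape[1])
        Ainv = np.linalg.inv(A)
        t.edf = float(np.trace(Ainv @ XtWX))
        if which == "mu":
            cov_mu = Ainv @ XtWX @ Ainv

    return BCCGFit(
        terms=terms,
        xi_hat=xi,
        age_range=(float(age.min()), float(age.max())),
        loglik=_loglik(y, mu, sigma, nu),
        n_obs=n,
        cov_mu=cov_mu,
        n_cycles=cycle,
        config=cfg,
        loglik_history=history,
    )


def _validate_data(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not {"age", "y"} <= set(data.columns):
        raise ValueError("data must have columns 'age' and 'y'")
    age = data["age"].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    if len(y) < 50:
        raise ValueError("at least 50 observations required")
    if np.any(y <= 0):
        raise ValueError("all measurements must be positive")
    if not np.all(np.isfinite(age)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in data")
    return age, y


def fit_bccg(data: pd.DataFrame, config: FitConfig | None = None) -> BCCGFit:
    """Fit BCCG moment curves to a dataset with columns ``age`` and ``y``.

    Follows the configuration's curve classes; ``nu_curve_class="select"``
    compares constant/linear/smooth nu by GAIC(3).  ``xi="search"``
    optimises the mu-curve age power by golden-section search.
    """
    cfg = config or FitConfig()
    age, y = _validate_data(data)
    single_age = float(np.ptp(age)) < 1e-8
    classes = {
        "mu": "constant" if single_age else cfg.mu_curve_class,
        "sigma": "constant" if single_age else cfg.sigma_curve_class,
        "nu": "constant" if single_age else cfg.nu_curve_class,
    }

    if cfg.xi == "search":
        xi = select_xi(data, replace(cfg, xi=1.0))
    else:
        xi = float(cfg.xi)

    if cfg.nu_value is not None:
        nu_options = ("constant",)
        classes["nu"] = "constant"
    elif classes["nu"] == "select":
        nu_options = ("constant", "linear", "smooth")
    else:
        nu_options = (classes["nu"],)
    best = None
    for nu_class in nu_options:
        cl = dict(classes, nu=nu_class)
        fit = _fit_inner(y, age, cfg, xi, cl)
        crit = information_criteria(fit, k=3.0)["gaic_k"]
        # ties toward fewer edf: strict improvement required
        if best is None or crit < best[0] - 1e-9:
            best = (crit, fit)
    fit = best[1]
    if cfg.smoothing_selection == "bic-grid":
        fit = _bic_grid_refine(y, age, cfg, xi, fit)
    return fit


def _bic_grid_refine(y, age, cfg: FitConfig, xi: float, fit: BCCGFit) -> BCCGFit:
    """Refine the smooth-term smoothing parameters on a BIC grid around
    the marginal-likelihood solution (full refits at fixed lambdas)."""
    classes = {k: t.kind for k, t in fit.terms.items()}
    best = fit
    best_bic = information_criteria(fit, k=math.log(fit.n_obs))["gaic_k"]
    for which, i in (("mu", 0), ("sigma", 1)):
        if fit.terms[which].kind != "smooth" or cfg.fixed_lambdas[i] is not None:
            continue
        lam0 = best.terms[which].lam
        for factor in (0.1, 0.316, 3.16, 10.0):
            lams: list[float | None] = list(cfg.fixed_lambdas)
            lams[0] = best.terms["mu"].lam
            lams[1] = (
                best.terms["sigma"].lam
                if best.terms["sigma"].kind == "smooth"
                else None
            )
            lams[i] = lam0 * factor
            try:
                cand = _fit_inner(
                    y, age, replace(cfg, fixed_lambdas=tuple(lams)), xi, classes
                )
            except FitError:
                continue
            bic = information_criteria(cand, k=math.log(cand.n_obs))["gaic_k"]
            if bic < best_bic - 1e-9:
                best, best_bic = cand, bic
    return best


def refit_fixed(base: BCCGFit, data: pd.DataFrame) -> BCCGFit:
    """Refit holding all hyperparameters of ``base`` fixed (knots, curve
    classes, smoothing parameters, xi), warm-starting from its
    coefficients.  This is the fast path used by the bootstrap."""
    age = data["age"].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("all measurements must be positive")
    cfg = replace(
        base.config,
        fixed_lambdas=(
            base.terms["mu"].lam if base.terms["mu"].kind == "smooth" else None,
            base.terms["sigma"].lam if base.terms["sigma"].kind == "smooth" else None,
            base.terms["nu"].lam if base.terms["nu"].kind == "smooth" else None,
        ),
        max_iter=30,
    )
    fit = _fit_inner(
        y, age, cfg, base.xi_hat,
        {k: t.kind for k, t in base.terms.items()},
        warm=base.terms,
    )
    # keep the base age range so centiles can be evaluated on the full grid
    fit.age_range = base.age_range
    return fit


def select_xi(data: pd.DataFrame, config: FitConfig | None = None) -> float:
    """Golden-section search for the mu-curve age power xi in (0, 1].

    The mu-curve degrees of freedom are held (approximately) constant
    across candidates: a reference fit at xi = 1 sets a target edf, and at
    each candidate the mu smoothing parameter is solved by bisection to
    hit that target before refitting.  Returns xi rounded to 2 decimals.
    """
    cfg = config or FitConfig(xi=1.0)
    if cfg.xi == "search":
        cfg = replace(cfg, xi=1.0)
    age, y = _validate_data(data)
    if float(np.ptp(age)) < 1e-8:
        return 1.0
    classes = {
        "mu": cfg.mu_curve_class,
        "sigma": cfg.sigma_curve_class,
        "nu": cfg.nu_curve_class if cfg.nu_curve_class != "select" else "linear",
    }
    if cfg.nu_value is not None:
        classes["nu"] = "constant"
    ref = _fit_inner(y, age, cfg, 1.0, classes)
    if ref.terms["mu"].kind != "smooth":
        return 1.0
    target_edf = ref.terms["mu"].edf
    _, w_mu = _scores_weights(
        "mu", y, *_eval_all(
            ref.terms, age**1.0, age
        )
    )
    w_mu = np.where(np.isfinite(w_mu) & (w_mu > 0), w_mu, 1e-8)

    def lam_for_edf(xi: float) -> float:
        term = _make_term("smooth", age**xi, cfg, 0.0)
        X = term.design(age**xi)
        XtWX = X.T @ (w_mu[:, None] * X)
        P = term.penalty

        def edf_at(loglam: float) -> float:
            A = XtWX + 10.0**loglam * P
            return float(np.trace(np.linalg.solve(A, XtWX)))

        lo, hi = -7.0, 10.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if edf_at(mid) > target_edf:
                lo = mid
            else:
                hi = mid
        return 10.0 ** (0.5 * (lo + hi))

    cache: dict[float, float] = {}

    def crit(xi: float) -> float:
        xi = round(xi, 4)
        if xi in cache:
            return cache[xi]
        lam = lam_for_edf(xi)
        c = replace(cfg, fixed_lambdas=(lam, None, None))
        try:
            fit = _fit_inner(y, age, c, xi, classes)
            val = information_criteria(fit, k=3.0)["gaic_k"]
        except FitError:
            val = np.inf
        cache[xi] = val
        return val

    # golden-section on (0.05, 1]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.05, 1.0
    c_, d_ = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = crit(c_), crit(d_)
    while b - a > 0.02:
        if fc < fd:
            b, d_, fd = d_, c_, fc
            c_ = b - invphi * (b - a)
            fc = crit(c_)
        else:
            a, c_, fc = c_, d_, fd
            d_ = a + invphi * (b - a)
            fd = crit(d_)
    xi_hat = round(0.5 * (a + b), 2)
    # never worse than no transform
    if crit(xi_hat) > crit(1.0):
        xi_hat = 1.0
    return float(min(max(xi_hat, 0.01), 1.0))


def information_criteria(fit: BCCGFit, k: float = 3.0) -> dict:
    """BIC and GAIC(k) of a converged fit:
    BIC = -2*loglik + log(n)*edf_total, GAIC(k) = -2*loglik + k*edf_total."""
    dev = -2.0 * fit.loglik
    return {
        "bic": dev + math.log(fit.n_obs) * fit.edf_total,
        "gaic_k": dev + k * fit.edf_total,
    }


def residual_zscores(fit: BCCGFit, data: pd.DataFrame) -> np.ndarray:
    """z-scores of the data under the fitted moment curves; ~N(0,1) when
    the model is correct."""
    age = data["age"].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("all measurements must be positive")
    mu, sigma, nu = fit.moments(age)
    return _zscores(y, mu, sigma, nu)


def mu_se_z_curve(fit: BCCGFit, ages) -> np.ndarray:
    """Pointwise SE of the fitted median curve, expressed in z-score units.

    The SE of mu-hat(t) follows from the penalized-fit sandwich covariance
    of the mu coefficients; dividing by the fitted generalised SD
    mu(t)*sigma(t) converts it to the z-score scale (delta z = delta y / SD).
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    fit._check_range(ages)
    B = fit.terms["mu"].design(ages**fit.xi_hat)
    var = np.einsum("ij,jk,ik->i", B, fit.cov_mu, B)
    se_mu = np.sqrt(np.maximum(var, 0.0))
    mu, sigma, _ = fit.moments(ages)
    return se_mu / (mu * sigma)
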