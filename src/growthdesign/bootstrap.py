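"""Bootstrap standard-error curves for centiles, on the z-score scale.

The median curve has an analytic SE band (see
:func:`growthdesign.fitting.mu_se_z_curve`), but other centiles are
nonlinear functions of all three moment curves, so their SE curves are
estimated by the bootstrap: resample the data rows with replacement,
refit the model, evaluate each requested centile on an age grid, convert
the centile values to z-scores *using the original fit's moment curves*,
and take the SD across replicates at each grid age.  Working on the
z-score scale makes the result comparable across measurements and
symmetric for centile pairs equidistant from the median.

SE_z curves are summarised as linear trends of log SE_z on age over
2-18 years (age centred at 10), which avoids edge effects and feeds the
design meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bccg import NINE_CENTILE_ZS
from .fitting import BCCGFit, FitError, refit_fixed, _zscores

__all__ = ["SEZCurve", "bootstrap_se_curves", "sez_trend"]


@dataclass
class SEZCurve:
    """Bootstrap SE_z surface: grid ages x centile z values."""

    ages: np.ndarray
    centile_zs: np.ndarray
    se_z: np.ndarray  # shape (len(ages), len(centile_zs))
    n_replicates: int
    n_skipped: int = 0
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.centile_zs = np.asarray(self.centile_zs, dtype=float)
        self.se_z = np.asarray(self.se_z, dtype=float)
        if self.se_z.shape != (len(self.ages), len(self.centile_zs)):
            raise ValueError("se_z must be (n_ages, n_centiles)")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be strictly increasing")

    def column(self, z: float) -> np.ndarray:
        j = np.argmin(np.abs(self.centile_zs - z))
        if abs(self.centile_zs[j] - z) > 1e-6:
            raise KeyError(f"centile z={z} not in curve set {self.centile_zs}")
        return self.se_z[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV form: columns age, z_centile, se_z."""
        a, z = np.meshgrid(self.ages, self.centile_zs, indexing="ij")
        return pd.DataFrame(
            {"age": a.ravel(), "z_centile": z.ravel(), "se_z": self.se_z.ravel()}
        )


def bootstrap_se_curves(
    data: pd.DataFrame,
    base_fit: BCCGFit,
    centile_zs: Sequence[float] = NINE_CENTILE_ZS,
    B: int = 500,
    ages=None,
    rng: np.random.Generator | None = None,
    stratify_breaks: Sequence[float] | None = None,
    resample: bool = True,
) -> SEZCurve:
    """Bootstrap the SE_z curves of the requested centiles.

    Each replicate resamples the rows of ``data`` with replacement
    (unstratified by default; pass ``stratify_breaks`` to resample within
    age groups), refits the model with the base fit's hyperparameters
    held fixed, evaluates the centiles on the grid and converts them to
    z-scores under the *original* fit.  ``resample=False`` refits the
    original data each time (a degenerate identity bootstrap, for tests).

    Replicates whose refit fails to converge are skipped; more than 10%
    skipped is an error.
    """
    if B < 50 and resample:
        raise ValueError("B must be >= 50")
    if rng is None:
        rng = np.random.default_rng()
    if ages is None:
        lo, hi = base_fit.age_range
        ages = np.arange(max(0.0, lo), hi + 1e-9, 0.1)
    ages = np.asarray(ages, dtype=float)
    zs = np.asarray(centile_zs, dtype=float)
    n = len(data)

    strata = None
    if stratify_breaks is not None:
        b = np.asarray(stratify_breaks, dtype=float)
        idx_by_stratum = []
        agev = data["age"].to_numpy()
        for lo_, hi_ in zip(b[:-1], b[1:]):
            sel = np.where((agev >= lo_) & (agev < hi_))[0]
            if sel.size:
                idx_by_stratum.append(sel)
        strata = idx_by_stratum

    mu0, sigma0, nu0 = base_fit.moments(ages)
    reps = []
    skipped = 0
    for b_ in range(B):
        if resample:
            if strata is None:
                idx = rng.integers(0, n, n)
            else:
                idx = np.concatenate(
                    [s[rng.integers(0, len(s), len(s))] for s in strata]
                )
            sample = data.iloc[idx]
        else:
            sample = data
        try:
            fit_b = refit_fixed(base_fit, sample)
        except (FitError, np.linalg.LinAlgError):
            skipped += 1
            continue
        cent = fit_b.centiles(ages, zs)  # (n_ages, n_z)
        zmat = _zscores(cent, mu0[:, None], sigma0[:, None], nu0[:, None])
        reps.append(zmat)
    if skipped > 0.1 * B:
        raise FitError(f"{skipped}/{B} bootstrap replicates failed to converge")
    arr = np.stack(reps)  # (B_ok, n_ages, n_z)
    se = arr.std(axis=0, ddof=1)
    return SEZCurve(
        ages=ages,
        centile_zs=zs,
        se_z=se,
        n_replicates=len(reps),
        n_skipped=skipped,
    )


def sez_trend(
    curve: SEZCurve, window: tuple[float, float] = (2.0, 18.0)
) -> pd.DataFrame:
    """Per-centile linear trend of log SE_z on age over the window.

    Ordinary least squares of log SE_z on (age - 10); returns a frame
    with columns ``z_centile``, ``intercept``, ``slope``.  The intercept
    is log SE_z at age 10 y; the slope is per year.  A flat trend
    (slope ~ 0) is the design optimum.
    """
    lo, hi = window
    if lo < curve.ages[0] - 1e-9 or hi > curve.ages[-1] + 1e-9:
        raise ValueError("trend window outside the curve's age grid")
    sel = (curve.ages >= lo - 1e-9) & (curve.ages <= hi + 1e-9)
    t = curve.ages[sel] - 10.0
    X = np.column_stack([np.ones_like(t), t])
    rows = []
    for j, z in enumerate(curve.centile_zs):
        y = np.log(curve.se_z[sel, j])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rows.append({"z_centile": z, "intercept": coef[0], "slope": coef[1]})
    return pd.DataFrame(rows)
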