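"""Sample composition and dataset simulation.

Sample composition — the distribution of measurement ages in a
cross-sectional reference study — is parameterised as *uniform on the
age^lambda scale*: ages are drawn by sampling u ~ U(age_min^lambda,
age_max^lambda) and back-transforming t = u^(1/lambda).  lambda = 1 gives
a uniform age distribution; smaller lambda over-samples infancy, which is
where growth is fastest and centiles are least precise.

The module also allocates a total sample size to discrete age groups
(``nagegp``), with counts proportional to the age^lambda measure of each
group, optionally inflated at the first/last group to counter edge
effects; and it simulates full (age, measurement) datasets from a base
moment-curve model, so that the z-scores of the simulated data under the
generating model are exactly standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bccg import bccg_quantile_arrays
from .reference import MomentCurveSet
from scipy import stats

__all__ = [
    "SamplingScheme",
    "AgeGroupPlan",
    "sample_ages",
    "age_cdf",
    "nagegp",
    "grouped_ages",
    "simulate_dataset",
    "cuban_style_plan",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Age-composition scheme: uniform on the age^lambda scale.

    ``edge_multiplier_low``/``edge_multiplier_high`` inflate the first and
    last age group (only meaningful for grouped allocation) before the
    counts are renormalised to sum to ``n``.
    """

    lambda_age: float
    age_min: float
    age_max: float
    n: int
    edge_multiplier_low: float = 1.0
    edge_multiplier_high: float = 1.0
    group_breaks: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_age <= 1.0):
            raise ValueError(f"lambda_age must be in (0,1], got {self.lambda_age}")
        if self.age_min < 0:
            raise ValueError("age_min must be >= 0")
        if not (self.age_max > self.age_min):
            raise ValueError("age_max must exceed age_min")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.edge_multiplier_low < 1 or self.edge_multiplier_high < 1:
            raise ValueError("edge multipliers must be >= 1")
        if self.group_breaks is not None:
            b = np.asarray(self.group_breaks, dtype=float)
            if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
                raise ValueError("group_breaks must be strictly increasing")
            if abs(b[0] - self.age_min) > 1e-9 or abs(b[-1] - self.age_max) > 1e-9:
                raise ValueError("group_breaks must span [age_min, age_max]")


@dataclass(frozen=True)
class AgeGroupPlan:
    """Discrete allocation: ``counts[i]`` subjects uniform in
    [breaks[i], breaks[i+1])."""

    breaks: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.breaks) - 1:
            raise ValueError("need one count per group interval")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    def to_frame(self) -> pd.DataFrame:
        b = np.asarray(self.breaks)
        return pd.DataFrame(
            {"age_lo": b[:-1], "age_hi": b[1:], "count": self.counts}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def read_csv(cls, path) -> "AgeGroupPlan":
        df = pd.read_csv(path)
        missing = {"age_lo", "age_hi", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"plan CSV missing column(s): {sorted(missing)}")
        lo = df["age_lo"].to_numpy(dtype=float)
        hi = df["age_hi"].to_numpy(dtype=float)
        if not np.allclose(lo[1:], hi[:-1]):
            raise ValueError("plan groups must be contiguous")
        return cls(
            breaks=tuple(np.append(lo, hi[-1])),
            counts=tuple(int(c) for c in df["count"]),
        )


def age_cdf(scheme: SamplingScheme, ages) -> np.ndarray:
    """Closed-form CDF of the age^lambda sampling distribution:
    (t^lam - a^lam) / (b^lam - a^lam) on [age_min, age_max]."""
    t = np.clip(np.asarray(ages, dtype=float), scheme.age_min, scheme.age_max)
    lam = scheme.lambda_age
    lo, hi = scheme.age_min**lam, scheme.age_max**lam
    return (t**lam - lo) / (hi - lo)


def sample_ages(scheme: SamplingScheme, rng: np.random.Generator) -> np.ndarray:
    """Draw ``scheme.n`` measurement ages by inverse-transform sampling:
    u ~ U(age_min^lam, age_max^lam), t = u^(1/lam)."""
    if scheme.group_breaks is not None:
        raise ValueError("scheme has group_breaks; use nagegp + grouped_ages")
    lam = scheme.lambda_age
    u = rng.uniform(scheme.age_min**lam, scheme.age_max**lam, size=scheme.n)
    return u ** (1.0 / lam)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerise ``total * weights/sum(weights)`` preserving the total."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def nagegp(
    scheme: SamplingScheme, breaks: Sequence[float] | None = None
) -> AgeGroupPlan:
    """Numbers per age group under the age^lambda composition.

    Counts are proportional to the group's measure on the age^lambda
    scale, ``b_i^lam - a_i^lam``, times the edge multipliers for the
    first/last group, then integerised by largest-remainder rounding so
    they sum exactly to ``scheme.n``.
    """
    if breaks is None:
        breaks = scheme.group_breaks
    if breaks is None:
        raise ValueError("age-group breaks required")
    b = np.asarray(breaks, dtype=float)
    if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
        raise ValueError("breaks must be strictly increasing")
    if b[0] < scheme.age_min - 1e-9 or b[-1] > scheme.age_max + 1e-9:
        raise ValueError("breaks must lie within the scheme age range")
    lam = scheme.lambda_age
    w = np.diff(b**lam)
    w[0] *= scheme.edge_multiplier_low
    w[-1] *= scheme.edge_multiplier_high
    counts = _largest_remainder(w, scheme.n)
    return AgeGroupPlan(breaks=tuple(b), counts=tuple(int(c) for c in counts))


def grouped_ages(plan: AgeGroupPlan, rng: np.random.Generator) -> np.ndarray:
    """Simulate measurement ages for a grouped design: exactly
    ``counts[i]`` uniform deviates within each group interval."""
    parts = [
        rng.uniform(lo, hi, size=c)
        for lo, hi, c in zip(plan.breaks[:-1], plan.breaks[1:], plan.counts)
    ]
    return np.concatenate(parts) if parts else np.empty(0)


def simulate_dataset(
    model: MomentCurveSet,
    scheme: SamplingScheme | AgeGroupPlan,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a cross-sectional dataset (columns ``age``, ``y``).

    Ages come from the scheme (or a pre-computed group plan); at each age
    a uniform proportion is converted to a normal deviate and then to a
    measurement through the BCCG centile transform of the base model, so
    the generating-model z-scores of the output are standard normal.
    """
    if isinstance(scheme, AgeGroupPlan):
        ages = grouped_ages(scheme, rng)
    elif scheme.group_breaks is not None:
        ages = grouped_ages(nagegp(scheme), rng)
    else:
        ages = sample_ages(scheme, rng)
    if ages.size and (
        ages.min() < model.age_min - 1e-9 or ages.max() > model.age_max + 1e-9
    ):
        raise ValueError("sampling scheme range extends beyond the model domain")
    mu, sigma, nu = model.moments(ages)
    z = stats.norm.ppf(rng.uniform(size=ages.size))
    y = bccg_quantile_arrays(mu, sigma, nu, z)
    return pd.DataFrame({"age": ages, "y": y})


def cuban_style_plan(n: int = 6878) -> AgeGroupPlan:
    """Illustrative 27-group plan in the style of the 1972 Cuban Growth
    Study design: three 4-month groups in the first year, half-year groups
    to age 2, then one-year groups with renewed over-sampling through the
    pubertal years.  The published per-group targets are not reproduced;
    the shape (infant over-sampling, a pubertal bump peaking near 14 y)
    is a documented synthetic stand-in.
    """
    breaks = [0, 1 / 3, 2 / 3]  # 4-month groups in the first year
    breaks += [1 + 0.5 * k for k in range(11)]  # half-year groups 1-6 y
    breaks += list(range(7, 17))  # one-year groups 6-16 y
    breaks += [16.5, 17.5, 18.5, 20.0]  # 27 groups in all
    b = np.asarray(breaks, dtype=float)
    width = np.diff(b)
    mid = (b[:-1] + b[1:]) / 2
    # density: high in infancy, falling through childhood, pubertal bump
    dens = 1.0 + 2.5 * np.exp(-mid / 1.2) + 1.2 * np.exp(-((mid - 14.0) ** 2) / 8.0)
    counts = _largest_remainder(width * dens, n)
    return AgeGroupPlan(breaks=tuple(b), counts=tuple(int(c) for c in counts))
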