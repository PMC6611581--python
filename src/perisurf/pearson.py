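"""Pearson distribution system: type selection from the first four moments
and pseudo-random sampling.

The Pearson system classifies densities by the criterion

    kappa = b1 (b2 + 3)^2 / (4 (4 b2 - 3 b1) (2 b2 - 3 b1 - 6))

where b1 = skewness^2 and b2 = (non-excess) kurtosis.  kappa < 0 selects
Type I (a four-parameter beta, bounded); kappa in (0, 1) Type IV; kappa = 1
Type V; kappa > 1 Type VI; the b1 = 0 axis holds the normal (b2 = 3),
Type II (b2 < 3, symmetric beta) and Type VII (b2 > 3, scaled Student t);
a vanishing denominator gives Type III (gamma).

Sampling matches all four moments exactly in population: Types I/II are
realized as shifted/scaled betas by closed-form moment matching, Type III
as a standardized gamma, Type VII as a variance-scaled t, the normal
directly, and Types IV/V/VI by numerical inverse-CDF of the Pearson density
defined by the system's differential equation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["PearsonSpec", "PearsonCriterion", "pearson_criterion",
           "sample_pearson", "InfeasibleMomentsError"]

_EPS = 1e-12


class InfeasibleMomentsError(ValueError):
    """Raised when (skewness, kurtosis) violate b2 > 1 + b1."""


class PearsonCriterion(NamedTuple):
    kappa: float
    type_label: str


@dataclass
class PearsonSpec:
    """First four moments defining a Pearson-system member.

    mean and standard deviation are in the height unit (μm here);
    skewness and kurtosis (non-excess) are dimensionless.
    """

    mean: float = 0.0
    std: float = 1.0
    skewness: float = -0.3
    kurtosis: float = 3.0

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("standard deviation must be positive")
        if self.kurtosis <= 1.0 + self.skewness ** 2:
            raise InfeasibleMomentsError(
                f"kurtosis {self.kurtosis} must exceed 1 + skewness^2 = "
                f"{1 + self.skewness ** 2}")

    @property
    def beta1(self) -> float:
        return self.skewness ** 2

    @property
    def beta2(self) -> float:
        return self.kurtosis

    @property
    def criterion(self) -> PearsonCriterion:
        return pearson_criterion(self.skewness, self.kurtosis)

    @property
    def kappa(self) -> float:
        return self.criterion.kappa

    @property
    def type_label(self) -> str:
        return self.criterion.type_label


def pearson_criterion(skewness: float, kurtosis: float) -> PearsonCriterion:
    """Evaluate the Pearson criterion kappa and the density type it selects.

    For the shape pair adopted for the reverse-engineered surfaces
    (skewness -0.3, kurtosis 3.0) this gives kappa = -0.256, Type I.
    """
    b1 = skewness ** 2
    b2 = kurtosis
    if b2 <= 1.0 + b1:
        raise InfeasibleMomentsError("infeasible moments: need kurtosis > 1 + skewness^2")
    denom = 4.0 * (4.0 * b2 - 3.0 * b1) * (2.0 * b2 - 3.0 * b1 - 6.0)
    if abs(b1) < _EPS:
        if abs(b2 - 3.0) < _EPS:
            return PearsonCriterion(0.0, "normal")
        return PearsonCriterion(0.0, "II" if b2 < 3.0 else "VII")
    if abs(denom) < _EPS:
        return PearsonCriterion(np.inf, "III")
    kappa = b1 * (b2 + 3.0) ** 2 / denom
    if kappa < 0.0:
        label = "I"
    elif kappa < 1.0 - _EPS:
        label = "IV"
    elif kappa <= 1.0 + _EPS:
        label = "V"
    else:
        label = "VI"
    return PearsonCriterion(float(kappa), label)


def _quadratic_coeffs(b1: float, b2: float, skew_sign: float):
    """Standardized Pearson ODE coefficients: p'/p = -(a + x)/(c0 + c1 x + c2 x^2)."""
    A = 10.0 * b2 - 12.0 * b1 - 18.0
    if abs(A) < 1e-9:
        # measure-zero degeneracy of the standardized parametrization (e.g.
        # the uniform member b1=0, b2=1.8); the limit is continuous, so a
        # tiny nudge reproduces it
        b2 = b2 + 1e-7
        A = 10.0 * b2 - 12.0 * b1 - 18.0
    g1 = skew_sign * np.sqrt(b1)
    a = c1 = g1 * (b2 + 3.0) / A
    c0 = (4.0 * b2 - 3.0 * b1) / A
    c2 = (2.0 * b2 - 3.0 * b1 - 6.0) / A
    return a, c0, c1, c2


def _sample_beta_type(spec: PearsonSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Types I and II: standardized four-parameter beta by moment matching."""
    a, c0, c1, c2 = _quadratic_coeffs(spec.beta1, spec.beta2,
                                      np.sign(spec.skewness) or 1.0)
    disc = c1 ** 2 - 4.0 * c0 * c2
    r1 = (-c1 - np.sqrt(disc)) / (2.0 * c2)
    r2 = (-c1 + np.sqrt(disc)) / (2.0 * c2)
    a1, a2 = min(r1, r2), max(r1, r2)
    m1 = (a + a1) / (c2 * (a2 - a1))
    m2 = -(a + a2) / (c2 * (a2 - a1))
    x = a1 + (a2 - a1) * rng.beta(m1 + 1.0, m2 + 1.0, size=n)
    return x


def _sample_numeric(spec: PearsonSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Types IV, V, VI: inverse-CDF sampling of the Pearson ODE density.

    The log-density is integrated numerically on a compactified grid
    (x = tan(theta) for unbounded support; shifted-log spacing next to a
    finite support edge), then inverted by interpolation on the CDF.
    """
    a, c0, c1, c2 = _quadratic_coeffs(spec.beta1, spec.beta2,
                                      np.sign(spec.skewness) or 1.0)
    disc = c1 ** 2 - 4.0 * c0 * c2
    if disc < 0:  # Type IV: support is the whole line
        theta = np.linspace(-np.pi / 2 + 1e-4, np.pi / 2 - 1e-4, 20001)
        x = 20.0 * np.tan(theta)  # stretch to cover heavy tails
    else:  # Types V / VI: support beyond the outer root
        r1 = (-c1 - np.sqrt(disc)) / (2.0 * c2)
        r2 = (-c1 + np.sqrt(disc)) / (2.0 * c2)
        lo, hi = min(r1, r2), max(r1, r2)
        # the mode sits at x = -a; take the side of the roots containing it
        if -a > hi:
            edge, sgn = hi, 1.0
        else:
            edge, sgn = lo, -1.0
        t = np.linspace(np.log(1e-9), np.log(1e4), 20001)
        x = edge + sgn * np.exp(t)
        x = np.sort(x)
    q = c0 + c1 * x + c2 * x ** 2
    integrand = -(a + x) / q
    logp = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                            * np.diff(x))])
    logp -= logp.max()
    p = np.exp(logp)
    p[~np.isfinite(p)] = 0.0
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x))])
    cdf /= cdf[-1]
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf, np.concatenate([[x[0]], 0.5 * (x[1:] + x[:-1])]))


def sample_pearson(n: int, spec: PearsonSpec, seed=None) -> np.ndarray:
    """Draw `n` values from the Pearson member matching spec's four moments.

    Deterministic for a fixed seed; accepts an int seed or a Generator.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    label = spec.type_label
    if label == "normal":
        x = rng.standard_normal(n)
    elif label in ("I", "II"):
        x = _sample_beta_type(spec, n, rng)
    elif label == "VII":
        nu = (4.0 * spec.beta2 - 6.0) / (spec.beta2 - 3.0)
        x = rng.standard_t(nu, size=n) * np.sqrt((nu - 2.0) / nu)
    elif label == "III":
        k = 4.0 / spec.beta1
        sgn = np.sign(spec.skewness) or 1.0
        x = sgn * (rng.gamma(k, 1.0, size=n) - k) / np.sqrt(k)
    else:  # IV, V, VI
        x = _sample_numeric(spec, n, rng)
    return spec.mean + spec.std * x


def type_i_support(spec: PearsonSpec) -> tuple[float, float]:
    """Closed support [a1, a2] of a standardized Type I/II member (before
    rescaling by mean/std).  Useful for diagnostics."""
    a, c0, c1, c2 = _quadratic_coeffs(spec.beta1, spec.beta2,
                                      np.sign(spec.skewness) or 1.0)
    disc = c1 ** 2 - 4.0 * c0 * c2
    if disc < 0:
        raise ValueError("spec is not a bounded (Type I/II) member")
    r1 = (-c1 - np.sqrt(disc)) / (2.0 * c2)
    r2 = (-c1 + np.sqrt(disc)) / (2.0 * c2)
    return min(r1, r2), max(r1, r2)
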