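"""Closed-form and regression estimators of biallelic mutation counts.

The number of infinite-sites violations behaves like a birthday problem: with
a burden of n mutations over N mutable positions, the expected number of
mutations sharing a locus with another is n - n(1 - 1/N)^(n-1), approximately
n^2/N for 1/N -> 0. Empirical tumour types deviate from the uniform model by a
type-specific coefficient C_type (violations ~ C_type m^2/N), and the excess
of violations over the uniform expectation defines a reduced effective genome
size, analogous to effective population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BirthdayInput:
    """Total burden n over a genome of N mutable positions."""

    n: int
    N: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("burden must be non-negative")
        if self.N < 1:
            raise ValueError("genome size must be at least 1")


@dataclass(frozen=True)
class BirthdayResult:
    exact: float
    approx: float


def birthday_expectation(inp: BirthdayInput) -> BirthdayResult:
    """Expected number of violating mutations, exact and n^2/N approximation.

    ``exact`` counts mutations that share their locus with at least one
    other: n - n(1 - 1/N)^(n-1). Always 0 <= exact <= approx = n^2/N.
    """
    n, N = inp.n, inp.N
    if n == 0:
        return BirthdayResult(exact=0.0, approx=0.0)
    exact = n - n * (1.0 - 1.0 / N) ** (n - 1)
    return BirthdayResult(exact=float(exact), approx=n * n / N)


@dataclass(frozen=True)
class TypeCoefficient:
    """Tumour-type coefficient of the m^2/N violation law."""

    label: str
    c_type: float
    n_points: int
    residual_scale: float


def fit_c_type(
    burdens: Sequence[float],
    violations: Sequence[float],
    N: float,
    label: str = "",
) -> TypeCoefficient:
    """Through-origin least squares of mean violations on m^2/N.

    Predictions must vanish at zero burden, so no intercept is fitted.
    """
    m = np.asarray(burdens, dtype=float)
    y = np.asarray(violations, dtype=float)
    if m.shape != y.shape or m.size == 0:
        raise ValueError("need aligned, non-empty burden/violation arrays")
    if np.all(m == 0):
        raise ValueError("all burdens are zero; coefficient is unidentifiable")
    x = m * m / N
    c = float(np.dot(x, y) / np.dot(x, x))
    if c < 0:
        c = 0.0
    resid = y - c * x
    scale = float(np.sqrt(np.mean(resid**2))) if y.size else 0.0
    return TypeCoefficient(
        label=label, c_type=c, n_points=int(m.size), residual_scale=scale
    )


def effective_genome_size(
    e_uniform: float,
    e_neighbour: float,
    n_callable: float,
) -> Optional[float]:
    """Effective genome size implied by the two simulators' expectations.

    Violations scale as 1/N, so an excess of neighbour-resampling violations
    over the uniform model implies a proportionally smaller effective size:
    N_eff = N_callable * E_uniform / E_neighbour. Returns None (missing) when
    either expectation is degenerate.
    """
    if e_neighbour == 0:
        logger.warning("effective genome size undefined: zero neighbour expectation")
        return None
    if e_uniform == 0:
        logger.warning("effective genome size degenerate: zero uniform expectation")
        return None
    if e_uniform < 0 or e_neighbour < 0:
        raise ValueError("expectations must be non-negative")
    return float(n_callable * e_uniform / e_neighbour)
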