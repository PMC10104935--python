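"""Post-data severity (SEV) for a one-sample normal-mean test with known sigma.

The error-statistical severity of a claim ``C: mu >= mu1`` after a one-sided
significance test is the probability, computed at the boundary point
``mu = mu1`` (the representative of "C is false" closest to the null), of
observing a sample mean at or below the one actually observed:

    SEV = P(Xbar <= xbar ; mu = mu1),   Xbar ~ Normal(mu1, sigma / sqrt(n)).

A claim passes the first severity hurdle (S-1) when the observed mean clears
the usual rejection cutoff ``mu0 + z_{1-alpha} * sigma/sqrt(n)``; the SEV
value quantifies the second hurdle (S-2).  Note that SEV depends on the null
value ``mu0`` only through the pass/fail flag: the severity number itself is
invariant to what is taken as the default state of affairs, which is the
conceptual weakness this package exists to quantify alternatives to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, UsageError

__all__ = [
    "NormalTestSpec",
    "SeverityQuery",
    "SeverityResult",
    "rejection_threshold",
    "sev",
    "severity_curve",
]


@dataclass(frozen=True)
class NormalTestSpec:
    """One-sided test of H0: mu <= mu0 for a normal mean with known sigma.

    Parameters
    ----------
    mu0 : float
        Null value of the mean, in measurement units.
    sigma : float
        Known population standard deviation (> 0), same units.
    n : int
        Sample size (>= 1).
    alpha : float
        Type-I error rate, in (0, 1).
    direction : str
        Only ``"greater"`` (H1: mu > mu0) is implemented; the field exists
        so a lesser/two-sided extension stays additive.
    """

    mu0: float
    sigma: float
    n: int
    alpha: float
    direction: str = "greater"

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu0):
            raise DomainError(f"mu0 must be finite, got {self.mu0!r}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise DomainError(f"sigma must be positive and finite, got {self.sigma!r}")
        if int(self.n) != self.n or self.n < 1:
            raise DomainError(f"n must be an integer >= 1, got {self.n!r}")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha must lie strictly in (0, 1), got {self.alpha!r}")
        if self.direction != "greater":
            raise DomainError(
                f"only direction='greater' is implemented, got {self.direction!r}"
            )

    @property
    def se(self) -> float:
        """Standard error of the sample mean, sigma / sqrt(n)."""
        return self.sigma / math.sqrt(self.n)


@dataclass(frozen=True)
class SeverityQuery:
    """A severity question: claim threshold mu1 and observed mean xbar."""

    mu1: float
    xbar: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu1):
            raise DomainError(f"mu1 must be finite, got {self.mu1!r}")
        if not math.isfinite(self.xbar):
            raise DomainError(f"xbar must be finite, got {self.xbar!r}")


@dataclass(frozen=True)
class SeverityResult:
    """SEV value, the S-1 pass flag, and the rejection cutoff used for it."""

    sev: float
    rejected: bool
    critical_mean: float


def rejection_threshold(spec: NormalTestSpec) -> float:
    """Smallest sample mean that rejects H0 at level ``spec.alpha``.

    Returns ``mu0 + z_{1-alpha} * se`` exactly (e.g. 151.96 for the
    mu0=150, sigma=10, n=100, alpha=0.025 test, conventionally rounded
    to 152 when quoted).
    """
    z = stats.norm.ppf(1.0 - spec.alpha)
    return spec.mu0 + z * spec.se


def sev(spec: NormalTestSpec, query: SeverityQuery) -> SeverityResult:
    """Severity with which the claim ``mu >= mu1`` has passed the test.

    ``sev`` is P(Xbar <= xbar) under Xbar ~ Normal(mu1, se); it does not
    depend on ``spec.mu0``.  ``rejected`` records whether the observed mean
    cleared the rejection cutoff (hurdle S-1).
    """
    critical = rejection_threshold(spec)
    value = float(stats.norm.cdf(query.xbar, loc=query.mu1, scale=spec.se))
    return SeverityResult(
        sev=value,
        rejected=bool(query.xbar >= critical),
        critical_mean=float(critical),
    )


def severity_curve(
    spec: NormalTestSpec, xbar: float, mu1_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Evaluate ``sev`` over a grid of claim thresholds.

    The grid must be non-empty and sorted ascending; the returned severity
    values are non-increasing in mu1 (strictly decreasing for distinct
    thresholds).
    """
    grid = np.asarray(list(mu1_grid), dtype=float)
    if grid.size == 0:
        raise UsageError("mu1_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise UsageError("mu1_grid must be sorted ascending")
    return [(float(m), sev(spec, SeverityQuery(mu1=float(m), xbar=xbar)).sev) for m in grid]
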