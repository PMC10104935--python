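"""Pre-experimental evidential value: the expected absolute log Bayes factor.

How severely can a planned experiment probe a hypothesis?  One answer: take
the Bayes factor the experiment would produce at every possible outcome,
weight each outcome by how probable it is a priori (under a mixture of the
competing models), and average the absolute log Bayes factor,

    E_y[ |log BF| ] = sum_y p(y) |log BF(y)|,
    p(y) = w_c p(y | H_constrained) + w_e p(y | H_encompassing).

A design with E|log BF| near zero cannot discriminate the hypotheses no
matter what data arrive; specific hypotheses earn larger expected evidence
(for or against combined) than vague ones.  The outcome space here is the
finite binomial lattice, so the expectation is an exact finite sum in nats.

The module also carries two small companions: posterior-odds updating
(posterior odds = prior odds x BF) and Meehl-style empirical-content counts
for binary prediction spaces (how many of the 2^n conceivable data patterns
a theory tolerates).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CapabilityError, DomainError, UsageError
from .informative_binomial import (
    ENCOMPASSING,
    BinomialDesign,
    IntervalHypothesis,
    PredictiveDistribution,
    bf_lattice,
    prior_predictive,
    prior_region_mass,
)

__all__ = [
    "MixtureWeights",
    "EvidentialValueResult",
    "PredictionSpace",
    "mixture_marginal",
    "expected_abs_log_bf",
    "update_odds",
    "empirical_content",
    "exactly_k_pattern",
    "fixed_pattern",
]

_WEIGHT_TOL = 1e-9
_ENUM_LIMIT = 25  # largest n for brute-force enumeration of 2^n sequences


@dataclass(frozen=True)
class MixtureWeights:
    """Prior model probabilities (p(H_constrained), p(H_encompassing))."""

    w_constrained: float = 0.5
    w_encompassing: float = 0.5

    def __post_init__(self) -> None:
        if self.w_constrained < 0 or self.w_encompassing < 0:
            raise UsageError("mixture weights must be nonnegative")
        if abs(self.w_constrained + self.w_encompassing - 1.0) > _WEIGHT_TOL:
            raise UsageError(
                f"mixture weights must sum to 1, got "
                f"{self.w_constrained} + {self.w_encompassing}"
            )


@dataclass(frozen=True)
class EvidentialValueResult:
    """E|log BF| in nats plus its full per-outcome decomposition."""

    expectation: float
    per_outcome: pd.DataFrame = field(repr=False)


def mixture_marginal(
    h: IntervalHypothesis,
    d: BinomialDesign,
    weights: MixtureWeights = MixtureWeights(),
) -> PredictiveDistribution:
    """Marginal outcome distribution p(y) under the two-model mixture.

    The convex combination of the constrained and encompassing prior
    predictives; its per-arm marginals are recomputed from the joint since
    a mixture of products is not itself a product.
    """
    pc = prior_predictive(h, d)
    pe = prior_predictive(ENCOMPASSING, d)
    joint = weights.w_constrained * pc.pmf + weights.w_encompassing * pe.pmf
    return PredictiveDistribution(
        design=d,
        label=f"{weights.w_constrained:g}*{h.label} + {weights.w_encompassing:g}*H_e",
        pmf=joint,
        marginal_a=joint.sum(axis=1),
        marginal_b=joint.sum(axis=0),
    )


def expected_abs_log_bf(
    h: IntervalHypothesis,
    d: BinomialDesign,
    weights: MixtureWeights = MixtureWeights(),
) -> EvidentialValueResult:
    """Expected absolute log Bayes factor of the design, by exact enumeration.

    Sums p(y) |ln BF(y)| over the whole (N_A+1) x (N_B+1) lattice -- no
    Monte Carlo.  Outcomes with p(y) = 0 contribute nothing even if their
    Bayes factor underflows; a zero Bayes factor at an outcome with
    positive mixture mass would make the expectation infinite, which is
    reported as such rather than masked.
    """
    prior_region_mass(h)  # raises for degenerate hypotheses up front
    bf = bf_lattice(h, d)
    py = mixture_marginal(h, d, weights).pmf

    with np.errstate(divide="ignore"):
        log_bf = np.log(bf)
    abs_log = np.abs(log_bf)
    contrib = np.where(py > 0, py * abs_log, 0.0)
    expectation = float(contrib.sum())

    sa, sb = np.meshgrid(np.arange(d.n_a + 1), np.arange(d.n_b + 1), indexing="ij")
    table = pd.DataFrame(
        {
            "s_a": sa.ravel(),
            "s_b": sb.ravel(),
            "p_y": py.ravel(),
            "log_bf": log_bf.ravel(),
            "abs_log_bf": abs_log.ravel(),
        }
    )
    return EvidentialValueResult(expectation=expectation, per_outcome=table)


def update_odds(prior_odds: float, bf: float) -> float:
    """Posterior odds from prior odds and a Bayes factor (their product)."""
    for name, v in (("prior_odds", prior_odds), ("bf", bf)):
        if not (isinstance(v, (int, float)) and math.isfinite(v)) or v <= 0:
            raise DomainError(f"{name} must be a positive finite number, got {v!r}")
    return prior_odds * bf


@dataclass(frozen=True)
class PredictionSpace:
    """A theory's predictions over ``n_slots`` binary observation slots.

    ``predicate`` maps a tuple of 0/1 outcomes to True when the theory
    tolerates that sequence; ``closed_form_count`` short-circuits the
    2^n enumeration when the count is known analytically (use the
    ``exactly_k_pattern`` / ``fixed_pattern`` constructors).
    """

    n_slots: int
    description: str
    predicate: Callable[[tuple[int, ...]], bool] | None = None
    closed_form_count: int | None = None

    def __post_init__(self) -> None:
        if int(self.n_slots) != self.n_slots or self.n_slots < 1:
            raise DomainError(f"n_slots must be an integer >= 1, got {self.n_slots!r}")
        if self.predicate is None and self.closed_form_count is None:
            raise UsageError("provide a predicate or a closed-form count")
        if self.closed_form_count is not None and not (
            0 <= self.closed_form_count <= 2**self.n_slots
        ):
            raise DomainError("closed-form count must lie in [0, 2^n_slots]")


def exactly_k_pattern(n_slots: int, k: int) -> PredictionSpace:
    """Theory allowing any sequence with exactly k positive slots: C(n, k) sequences.

    Meehl's vague weather theory -- "it will rain on three days next
    month" -- is ``exactly_k_pattern(30, 3)`` with 4060 tolerated patterns.
    """
    if not (0 <= k <= n_slots):
        raise DomainError(f"k must lie in [0, n_slots], got {k!r}")
    return PredictionSpace(
        n_slots=n_slots,
        description=f"exactly {k} of {n_slots} slots positive",
        predicate=lambda seq: sum(seq) == k,
        closed_form_count=math.comb(n_slots, k),
    )


def fixed_pattern(n_slots: int, positive_slots: Sequence[int]) -> PredictionSpace:
    """Theory allowing exactly one fully specified sequence (count 1).

    Meehl's risky weather theory -- "it will rain on days 3, 4 and 7 and on
    no others" -- tolerates a single pattern out of 2^n.
    """
    slots = frozenset(positive_slots)
    if not all(0 <= s < n_slots for s in slots):
        raise DomainError("positive_slots must be valid 0-based slot indices")
    return PredictionSpace(
        n_slots=n_slots,
        description=f"positive exactly on slots {sorted(slots)} of {n_slots}",
        predicate=lambda seq: frozenset(i for i, v in enumerate(seq) if v) == slots,
        closed_form_count=1,
    )


def empirical_content(space: PredictionSpace) -> tuple[int, int, Fraction]:
    """Count the binary sequences a theory tolerates: (consistent, total, ratio).

    Exact integer arithmetic throughout; the smaller the ratio, the riskier
    (more falsifiable) the prediction.  Predicates without a closed form
    are enumerated, which is refused above 25 slots.
    """
    total = 2**space.n_slots
    if space.closed_form_count is not None:
        consistent = space.closed_form_count
    else:
        if space.n_slots > _ENUM_LIMIT:
            raise CapabilityError(
                f"enumeration of 2^{space.n_slots} sequences exceeds the "
                f"{_ENUM_LIMIT}-slot limit; supply a closed-form count"
            )
        consistent = sum(
            1 for seq in itertools.product((0, 1), repeat=space.n_slots)
            if space.predicate(seq)  # type: ignore[misc]
        )
    return consistent, total, Fraction(consistent, total)
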