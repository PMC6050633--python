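"""Compositional balances: definition and evaluation.

A balance between two disjoint groups of parts X+ (indexed by I+, size k+)
and X- (indexed by I-, size k-) is the normalised log-ratio of their
geometric means,

    B(X+, X-) = sqrt(k+ k- / (k+ + k-)) * log( g(X+) / g(X-) ),

with g(.) the geometric mean and natural logarithms throughout.  Expanding
the logarithm, B is proportional to the difference between the arithmetic
means of the log parts,

    B(X+, X-) ∝ mean(log X+) - mean(log X-),

which is the cheaper form used inside the search; the proportionality
constant is exactly :func:`balance_coefficient`.  A balance is a
log-contrast (its log coefficients sum to zero), hence scale invariant:
rescaling a sample's composition leaves its balance score unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import Composition

__all__ = [
    "BalanceDefinition",
    "BalanceScores",
    "balance_coefficient",
    "evaluate_balance",
    "canonicalize",
]


def balance_coefficient(k_plus: int, k_minus: int) -> float:
    """Normalisation constant sqrt(k+ * k- / (k+ + k-))."""
    if k_plus < 1 or k_minus < 1:
        raise ValueError("both group sizes must be >= 1")
    return float(np.sqrt(k_plus * k_minus / (k_plus + k_minus)))


@dataclass(frozen=True)
class BalanceDefinition:
    """Two disjoint groups of taxon ids, numerator (I+) and denominator (I-).

    Taxon ids are stored sorted so that equal balances compare and hash
    equal regardless of construction order.
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num = tuple(sorted(str(t) for t in self.numerator))
        den = tuple(sorted(str(t) for t in self.denominator))
        if not num or not den:
            raise ValueError("numerator and denominator must each contain a taxon")
        if len(set(num)) != len(num) or len(set(den)) != len(den):
            raise ValueError("duplicate taxon within a balance group")
        overlap = set(num) & set(den)
        if overlap:
            raise ValueError(f"taxa in both groups: {sorted(overlap)}")
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)

    @property
    def k_plus(self) -> int:
        return len(self.numerator)

    @property
    def k_minus(self) -> int:
        return len(self.denominator)

    @property
    def size(self) -> int:
        return self.k_plus + self.k_minus

    @property
    def normalization(self) -> float:
        return balance_coefficient(self.k_plus, self.k_minus)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.numerator) | frozenset(self.denominator)

    def swap(self) -> "BalanceDefinition":
        """The sign-flipped balance B(X-, X+) = -B(X+, X-)."""
        return BalanceDefinition(self.denominator, self.numerator)

    def add(self, taxon: str, side: str) -> "BalanceDefinition":
        if side == "numerator":
            return BalanceDefinition(self.numerator + (taxon,), self.denominator)
        if side == "denominator":
            return BalanceDefinition(self.numerator, self.denominator + (taxon,))
        raise ValueError(f"unknown side {side!r}")

    def to_json(self) -> str:
        return json.dumps(
            {"numerator": list(self.numerator), "denominator": list(self.denominator)}
        )

    @classmethod
    def from_json(cls, text: str) -> "BalanceDefinition":
        obj = json.loads(text)
        return cls(tuple(obj["numerator"]), tuple(obj["denominator"]))

    def __str__(self) -> str:
        return (
            "NUM{" + ", ".join(self.numerator) + "} / "
            "DEN{" + ", ".join(self.denominator) + "}"
        )


@dataclass(frozen=True)
class BalanceScores:
    """Per-sample balance values; ``proportional_form`` records whether the
    normalisation constant was left off (search-internal convention)."""

    values: np.ndarray
    proportional_form: bool


def _indices(comp: Composition, taxa: Iterable[str]) -> np.ndarray:
    lookup = {t: i for i, t in enumerate(comp.taxon_ids)}
    idx = []
    for t in taxa:
        if t not in lookup:
            raise KeyError(f"taxon {t!r} not present in the composition")
        idx.append(lookup[t])
    return np.asarray(idx, dtype=int)


def evaluate_balance(
    comp: Composition, bal: BalanceDefinition, proportional: bool = False
) -> BalanceScores:
    """Per-sample balance scores.

    ``proportional=True`` returns mean(log X+) - mean(log X-); otherwise the
    result is multiplied by the normalisation constant.
    """
    log_values = np.log(comp.values)
    plus = _indices(comp, bal.numerator)
    minus = _indices(comp, bal.denominator)
    scores = log_values[:, plus].mean(axis=1) - log_values[:, minus].mean(axis=1)
    if not proportional:
        scores = scores * bal.normalization
    return BalanceScores(values=scores, proportional_form=proportional)


def canonicalize(bal: BalanceDefinition, coefficient_sign: float) -> BalanceDefinition:
    """Orient a balance so that its fitted regression coefficient is positive.

    B(X-, X+) = -B(X+, X-), so a negative coefficient simply means the two
    groups should swap roles.
    """
    if coefficient_sign == 0 or not np.isfinite(coefficient_sign):
        raise ValueError("cannot canonicalise a balance with a zero/degenerate "
                         "regression coefficient")
    return bal.swap() if coefficient_sign < 0 else bal
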