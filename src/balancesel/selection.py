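"""Greedy forward search for the single most predictive balance.

The search has two phases.  Step 1 evaluates exhaustively all k(k-1)/2
two-taxon balances B_ij = (1/sqrt(2)) (log X_i - log X_j) and keeps the one
whose regression criterion is best; the winning pair is oriented so that
its regression coefficient is positive.  Each subsequent step considers,
for every taxon p not yet in the balance, the two candidates obtained by
averaging log X_p into the numerator group or into the denominator group,
and accepts the best candidate if it improves the training criterion by
more than ``threshold`` (default 0: strict improvement).  The search stops
when no candidate improves enough, when ``max_components`` taxa are in the
balance, or when no taxa remain.

All candidate fits use the proportional (unnormalised) form of the balance,
mean(log X+) - mean(log X-); regression criteria are invariant to the
missing constant because it is absorbed by the slope.  Ties between
candidates (criterion equal to within 1e-10) are broken deterministically:
the candidate whose new taxon id sorts first wins, and numerator placement
wins over denominator placement for the same taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .balance import BalanceDefinition, canonicalize
from .io import StudyFrame
from .models import (
    CRITERIA,
    CollinearityError,
    CriterionSpec,
    FitResult,
    default_criterion,
    fit_linear,
    fit_logistic,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "SelbalResult",
    "first_pair_search",
    "extend_balance",
    "run_selbal",
]

_TIE_TOL = 1e-10


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the greedy search.

    criterion
        ``None`` auto-selects (auc for dichotomous, mse for continuous).
    max_components
        Largest number of taxa allowed in the balance (default 20).
    threshold
        Minimum improvement of the training criterion required to accept a
        forward step (``th.imp``; default 0, i.e. strictly better).
    """

    criterion: str | None = None
    max_components: int = 20
    threshold: float = 0.0
    ridge_fallback: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_components < 2:
            raise ValueError("max_components must be >= 2")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.criterion is not None and self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")

    def resolve_criterion(self, response_type: str) -> CriterionSpec:
        if self.criterion is None:
            return default_criterion(response_type)
        return CRITERIA[self.criterion]


@dataclass
class SelbalResult:
    """The full greedy path plus the canonicalised final balance."""

    balance_path: list[BalanceDefinition]
    criterion_path: list[float]
    fits: list[FitResult]
    stop_reason: str  # "threshold" | "max_components" | "exhausted"
    criterion: CriterionSpec
    final_balance: BalanceDefinition = field(init=False)
    final_fit: FitResult = field(init=False)

    def __post_init__(self) -> None:
        last_fit = self.fits[-1]
        self.final_balance = canonicalize(self.balance_path[-1], last_fit.beta1)
        if last_fit.beta1 < 0:
            flipped = FitResult(
                beta0=last_fit.beta0,
                beta1=-last_fit.beta1,
                gamma=last_fit.gamma,
                criterion_name=last_fit.criterion_name,
                criterion_value=last_fit.criterion_value,
                fitted_values=last_fit.fitted_values,
                converged=last_fit.converged,
                loglik=last_fit.loglik,
                loglik_null=last_fit.loglik_null,
            )
            self.final_fit = flipped
        else:
            self.final_fit = last_fit

    @property
    def sizes(self) -> list[int]:
        return [b.size for b in self.balance_path]

    def balance_at(self, size: int) -> tuple[BalanceDefinition, FitResult]:
        for bal, fit in zip(self.balance_path, self.fits):
            if bal.size == size:
                return bal, fit
        raise KeyError(f"no balance of size {size} on the path")

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion.name,
            "stop_reason": self.stop_reason,
            "balance_path": [
                {"numerator": list(b.numerator), "denominator": list(b.denominator)}
                for b in self.balance_path
            ],
            "criterion_path": [float(v) for v in self.criterion_path],
            "final_balance": {
                "numerator": list(self.final_balance.numerator),
                "denominator": list(self.final_balance.denominator),
            },
            "coefficients": {
                "beta0": self.final_fit.beta0,
                "beta1": self.final_fit.beta1,
                "gamma": list(map(float, self.final_fit.gamma)),
            },
        }


class _Search:
    """Shared state for one search: log matrix, response, covariates."""

    def __init__(self, frame: StudyFrame, config: SearchConfig):
        if frame.n_taxa < 2:
            raise ValueError("need at least 2 taxa to form a balance")
        self.frame = frame
        self.config = config
        self.spec = config.resolve_criterion(frame.response_type)
        self.log_values = np.log(frame.composition.values)
        self.index = {t: i for i, t in enumerate(frame.taxon_ids)}
        # enumeration order sorted by taxon id, for deterministic tie-breaks
        self.sorted_taxa = sorted(frame.taxon_ids)
        self.y = frame.y
        self.z = frame.covariates if frame.covariates.size else None

    def scores(self, bal: BalanceDefinition) -> np.ndarray:
        plus = [self.index[t] for t in bal.numerator]
        minus = [self.index[t] for t in bal.denominator]
        return (
            self.log_values[:, plus].mean(axis=1)
            - self.log_values[:, minus].mean(axis=1)
        )

    def fit(self, scores: np.ndarray) -> FitResult:
        if self.frame.response_type == "dichotomous":
            return fit_logistic(
                scores,
                self.y,
                self.z,
                criterion=self.spec.name,
                ridge_fallback=self.config.ridge_fallback,
            )
        return fit_linear(scores, self.y, self.z, criterion=self.spec.name)

    def better(self, value: float, best: float | None) -> bool:
        if best is None:
            return True
        return self.spec.sign * (value - best) > _TIE_TOL


def first_pair_search(
    frame: StudyFrame, config: SearchConfig | None = None
) -> tuple[BalanceDefinition, FitResult]:
    """Exhaustive scan of all two-taxon balances; returns the best pair
    oriented so that its regression coefficient is positive."""
    config = config or SearchConfig()
    search = _Search(frame, config)
    return _first_pair(search)


def _first_pair(search: _Search) -> tuple[BalanceDefinition, FitResult]:
    best: tuple[BalanceDefinition, FitResult] | None = None
    best_value: float | None = None
    taxa = search.sorted_taxa
    n_failed = 0
    for a_pos, a in enumerate(taxa):
        for b in taxa[a_pos + 1 :]:
            scores = (
                search.log_values[:, search.index[a]]
                - search.log_values[:, search.index[b]]
            )
            try:
                fit = search.fit(scores)
            except (ValueError, CollinearityError) as exc:
                n_failed += 1
                logger.warning("pair (%s, %s) skipped: %s", a, b, exc)
                continue
            if fit.beta1 == 0 or not np.isfinite(fit.beta1):
                n_failed += 1
                continue
            # pairs are enumerated in sorted order, so strict improvement
            # keeps the lexicographically smallest pair on ties
            if search.better(fit.criterion_value, best_value):
                bal = canonicalize(BalanceDefinition((a,), (b,)), fit.beta1)
                if fit.beta1 < 0:
                    fit = FitResult(
                        beta0=fit.beta0,
                        beta1=-fit.beta1,
                        gamma=fit.gamma,
                        criterion_name=fit.criterion_name,
                        criterion_value=fit.criterion_value,
                        fitted_values=fit.fitted_values,
                        converged=fit.converged,
                        loglik=fit.loglik,
                        loglik_null=fit.loglik_null,
                    )
                best = (bal, fit)
                best_value = fit.criterion_value
    if best is None:
        raise RuntimeError(
            f"all {len(taxa) * (len(taxa) - 1) // 2} candidate pairs produced "
            "degenerate fits"
        )
    return best


def extend_balance(
    frame: StudyFrame,
    current: BalanceDefinition,
    config: SearchConfig | None = None,
) -> tuple[BalanceDefinition, FitResult] | None:
    """Best single-taxon extension of ``current``, or None when no taxon
    remains.  Every remaining taxon is tried on both sides."""
    config = config or SearchConfig()
    search = _Search(frame, config)
    return _extend(search, current)


def _extend(
    search: _Search, current: BalanceDefinition
) -> tuple[BalanceDefinition, FitResult] | None:
    used = current.taxa
    remaining = [t for t in search.sorted_taxa if t not in used]
    if not remaining:
        return None
    plus = [search.index[t] for t in current.numerator]
    minus = [search.index[t] for t in current.denominator]
    sum_plus = search.log_values[:, plus].sum(axis=1)
    sum_minus = search.log_values[:, minus].sum(axis=1)
    k_plus, k_minus = len(plus), len(minus)
    best: tuple[BalanceDefinition, FitResult] | None = None
    best_value: float | None = None
    for taxon in remaining:
        col = search.log_values[:, search.index[taxon]]
        for side, scores in (
            ("numerator", (sum_plus + col) / (k_plus + 1) - sum_minus / k_minus),
            ("denominator", sum_plus / k_plus - (sum_minus + col) / (k_minus + 1)),
        ):
            try:
                fit = search.fit(scores)
            except (ValueError, CollinearityError) as exc:
                logger.warning(
                    "candidate %s->%s skipped: %s", taxon, side, exc
                )
                continue
            # enumeration is (taxon sorted, numerator before denominator), so
            # strict improvement implements the deterministic tie-break
            if search.better(fit.criterion_value, best_value):
                best = (current.add(taxon, side), fit)
                best_value = fit.criterion_value
    return best


def run_selbal(frame: StudyFrame, config: SearchConfig | None = None) -> SelbalResult:
    """The full greedy search: exhaustive pair, then forward extensions."""
    config = config or SearchConfig()
    search = _Search(frame, config)
    spec = search.spec
    bal, fit = _first_pair(search)
    path = [bal]
    crits = [fit.criterion_value]
    fits = [fit]
    max_size = min(config.max_components, frame.n_taxa)
    stop_reason = "max_components" if bal.size >= max_size else None
    while stop_reason is None:
        candidate = _extend(search, path[-1])
        if candidate is None:
            stop_reason = "exhausted"
            break
        cand_bal, cand_fit = candidate
        improvement = spec.sign * (cand_fit.criterion_value - crits[-1])
        if improvement <= config.threshold:
            stop_reason = "threshold"
            break
        path.append(cand_bal)
        crits.append(cand_fit.criterion_value)
        fits.append(cand_fit)
        if cand_bal.size >= max_size:
            stop_reason = "max_components"
    return SelbalResult(
        balance_path=path,
        criterion_path=crits,
        fits=fits,
        stop_reason=stop_reason,
        criterion=spec,
    )
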