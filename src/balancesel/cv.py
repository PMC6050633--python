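"""Repeated K-fold cross-validation around the balance search.

The CV loop serves two purposes: choosing the number of taxa in the balance
and gauging how stable the selected balance is.  For each of M iterations
the samples are split into K folds (stratified by class for a dichotomous
response).  The greedy search runs on every training set, producing a
nested sequence of balances of sizes 2..C; each prefix balance, with its
training-fold coefficients, is scored on the held-out fold.  Per component
count c this yields up to M*K held-out criterion values whose mean and
standard error drive model-size selection:

one-standard-error rule (default)
    the smallest c whose mean held-out criterion is within one standard
    error of the best mean (the standard error taken at the best c, as in
    cross-validated lasso);
optimum rule
    the c achieving the best mean.

The *global balance* is then the search re-run on all samples capped at
k_opt taxa, and the *cv accuracy* is the mean held-out criterion at the
global balance's size.  Robustness is summarised by the relative
frequencies of the distinct size-k_opt balances seen across folds and by
each taxon's inclusion frequency and modal side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import KFold, StratifiedKFold

from .balance import BalanceDefinition, canonicalize
from .io import StudyFrame
from .models import criterion_auc, criterion_pseudo_r2, criterion_tjur
from .selection import SearchConfig, SelbalResult, run_selbal

logger = logging.getLogger(__name__)

__all__ = [
    "CvConfig",
    "CvGrid",
    "RobustnessSummary",
    "CvResult",
    "make_folds",
    "run_cv",
    "one_se_rule",
    "global_and_cv_accuracy",
    "summarize_robustness",
    "selbal_cv",
]


@dataclass(frozen=True)
class CvConfig:
    n_iter: int = 10  # M
    n_folds: int = 5  # K
    max_components: int = 20  # C
    rule: str = "one_se"  # "one_se" | "optimum"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.max_components < 2:
            raise ValueError("max_components must be >= 2")
        if self.rule not in ("one_se", "optimum"):
            raise ValueError(f"unknown rule {self.rule!r}")


def make_folds(
    frame: StudyFrame, n_folds: int, n_iter: int, seed: int | None
) -> list[np.ndarray]:
    """Per iteration, an array assigning each sample to a fold 0..K-1.

    Folds are near-equal in size and, for a dichotomous response,
    stratified by class so every held-out fold contains both classes.
    """
    n = frame.n_samples
    if frame.response_type == "dichotomous":
        y = frame.y01
        smallest = int(min(np.sum(y == 1), np.sum(y == 0)))
        if smallest < n_folds:
            raise ValueError(
                f"the smaller response class has {smallest} samples, fewer than "
                f"{n_folds} folds; reduce n_folds"
            )
    seeds = np.random.SeedSequence(seed).generate_state(n_iter) % (2**31 - 1)
    assignments = []
    for m in range(n_iter):
        rs = int(seeds[m])
        fold_of = np.empty(n, dtype=int)
        if frame.response_type == "dichotomous":
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
            split = splitter.split(np.zeros(n), frame.y01)
        else:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
            split = splitter.split(np.zeros(n))
        for k, (_, test_idx) in enumerate(split):
            fold_of[test_idx] = k
        assignments.append(fold_of)
    return assignments


@dataclass
class CvGrid:
    """Held-out criterion values per (iteration, fold, component count)."""

    records: pd.DataFrame  # columns: m, k, c, value
    paths: dict[tuple[int, int], SelbalResult]
    criterion_name: str
    direction: str

    def mean_se(self) -> pd.DataFrame:
        """Mean, standard error (sd/sqrt(n)) and count per component count."""
        grouped = self.records.dropna(subset=["value"]).groupby("c")["value"]
        out = grouped.agg(mean="mean", sd="std", n="count")
        out["se"] = out["sd"] / np.sqrt(out["n"])
        out["se"] = out["se"].fillna(0.0)
        return out[["mean", "se", "n"]]

    def balances_at(self, size: int) -> list[tuple[BalanceDefinition, float]]:
        """Canonically oriented fold balances of the given size, with the
        sign of the training-fold coefficient applied."""
        out = []
        for key in sorted(self.paths):
            result = self.paths[key]
            try:
                bal, fit = result.balance_at(size)
            except KeyError:
                continue
            out.append((canonicalize(bal, fit.beta1), fit.beta1))
        return out


def _test_value(
    result_fit,
    balance: BalanceDefinition,
    test_frame: StudyFrame,
    criterion_name: str,
) -> float:
    log_values = np.log(test_frame.composition.values)
    index = {t: i for i, t in enumerate(test_frame.taxon_ids)}
    plus = [index[t] for t in balance.numerator]
    minus = [index[t] for t in balance.denominator]
    scores = log_values[:, plus].mean(axis=1) - log_values[:, minus].mean(axis=1)
    z = test_frame.covariates if test_frame.covariates.size else None
    eta = result_fit.predict(scores, z)
    if criterion_name == "mse":
        return float(np.mean((test_frame.y - eta) ** 2))
    probs = expit(np.clip(eta, -35, 35))
    y = test_frame.y01
    if not (np.any(y == 1) and np.any(y == 0)):
        return float("nan")
    if criterion_name == "auc":
        return criterion_auc(probs, y)
    if criterion_name == "tjur_d":
        return criterion_tjur(probs, y)
    # pseudo_r2 on held-out data: likelihood ratio against the test-fold null
    eta_c = np.clip(eta, -35, 35)
    loglik = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
    pbar = float(np.mean(y))
    loglik_null = float(np.sum(y) * np.log(pbar) + np.sum(1 - y) * np.log(1 - pbar))
    return criterion_pseudo_r2(loglik, loglik_null)


def run_cv(
    frame: StudyFrame,
    cv: CvConfig | None = None,
    search: SearchConfig | None = None,
) -> CvGrid:
    """Run the search on every training set and score every prefix balance
    on its held-out fold."""
    cv = cv or CvConfig()
    search = search or SearchConfig()
    search_capped = SearchConfig(
        criterion=search.criterion,
        max_components=cv.max_components,
        threshold=search.threshold,
        ridge_fallback=search.ridge_fallback,
    )
    spec = search_capped.resolve_criterion(frame.response_type)
    folds = make_folds(frame, cv.n_folds, cv.n_iter, cv.seed)
    rows = []
    paths: dict[tuple[int, int], SelbalResult] = {}
    for m, fold_of in enumerate(folds):
        for k in range(cv.n_folds):
            train_idx = np.flatnonzero(fold_of != k)
            test_idx = np.flatnonzero(fold_of == k)
            train = frame.take(train_idx)
            test = frame.take(test_idx)
            result = run_selbal(train, search_capped)
            paths[(m, k)] = result
            for bal, fit in zip(result.balance_path, result.fits):
                value = _test_value(fit, bal, test, spec.name)
                if np.isnan(value):
                    logger.warning(
                        "iteration %d fold %d: held-out fold lacks a class at "
                        "size %d; value recorded as missing",
                        m,
                        k,
                        bal.size,
                    )
                rows.append((m, k, bal.size, value))
    records = pd.DataFrame(rows, columns=["m", "k", "c", "value"])
    return CvGrid(
        records=records,
        paths=paths,
        criterion_name=spec.name,
        direction=spec.direction,
    )


def one_se_rule(grid: CvGrid, rule: str = "one_se") -> int:
    """Pick the number of components from the held-out criterion curve.

    ``one_se``: smallest c whose mean is within one standard error (taken at
    the best c) of the best mean.  ``optimum``: the best-mean c itself (ties
    going to the smallest c).
    """
    table = grid.mean_se()
    if table.empty:
        raise ValueError("cross-validation grid holds no finite criterion values")
    maximize = grid.direction == "maximize"
    means = table["mean"]
    best_c = means.idxmax() if maximize else means.idxmin()
    if rule == "optimum":
        best = means.max() if maximize else means.min()
        hits = means.index[np.isclose(means, best)]
        return int(hits.min())
    se_best = float(table.loc[best_c, "se"])
    if maximize:
        threshold = float(means.max()) - se_best
        eligible = means.index[means >= threshold]
    else:
        threshold = float(means.min()) + se_best
        eligible = means.index[means <= threshold]
    return int(eligible.min())


def global_and_cv_accuracy(
    frame: StudyFrame,
    k_opt: int,
    grid: CvGrid,
    search: SearchConfig | None = None,
) -> tuple[SelbalResult, float]:
    """Search the whole dataset capped at k_opt taxa, and report the mean
    held-out criterion at the size actually reached."""
    search = search or SearchConfig()
    capped = SearchConfig(
        criterion=search.criterion,
        max_components=max(k_opt, 2),
        threshold=search.threshold,
        ridge_fallback=search.ridge_fallback,
    )
    result = run_selbal(frame, capped)
    size = result.final_balance.size
    table = grid.mean_se()
    if size not in table.index:
        raise ValueError(
            f"no cross-validated values at the global balance's size {size}"
        )
    cv_accuracy = float(table.loc[size, "mean"])
    return result, cv_accuracy


@dataclass
class RobustnessSummary:
    """Frequencies of the CV balances of size k_opt and of taxon inclusion."""

    k_opt: int
    global_balance: BalanceDefinition
    balance_freqs: list[tuple[BalanceDefinition, float]]  # sorted, desc
    taxon_freqs: pd.DataFrame  # index taxon, columns: frequency, modal_side
    n_balances: int

    def global_balance_frequency(self) -> float:
        for bal, freq in self.balance_freqs:
            if bal == self.global_balance:
                return freq
        return 0.0

    def to_dict(self) -> dict:
        return {
            "k_opt": self.k_opt,
            "n_cv_balances": self.n_balances,
            "global_balance": {
                "numerator": list(self.global_balance.numerator),
                "denominator": list(self.global_balance.denominator),
            },
            "balance_frequencies": [
                {
                    "numerator": list(b.numerator),
                    "denominator": list(b.denominator),
                    "frequency": f,
                }
                for b, f in self.balance_freqs
            ],
            "taxon_frequencies": {
                t: {
                    "frequency": float(row["frequency"]),
                    "modal_side": row["modal_side"],
                }
                for t, row in self.taxon_freqs.iterrows()
            },
        }

    def to_text(self, top: int = 3) -> str:
        """Plain-text analogue of the balance-frequency figure: rows are the
        most frequent taxa, columns the global and top CV balances, cells
        '+' (numerator), '-' (denominator) or '.' (absent)."""
        shown = self.balance_freqs[:top]
        taxa = [
            t
            for t in self.taxon_freqs.index
            if self.taxon_freqs.loc[t, "frequency"] > 0
            or t in self.global_balance.taxa
        ]
        width = max([len(t) for t in taxa] + [10])
        headers = ["TAXON".ljust(width), "FREQ".rjust(6), "GLOBAL".rjust(7)] + [
            f"BAL{i + 1}".rjust(6) for i in range(len(shown))
        ]
        lines = ["  ".join(headers)]

        def mark(bal: BalanceDefinition, taxon: str) -> str:
            if taxon in bal.numerator:
                return "+"
            if taxon in bal.denominator:
                return "-"
            return "."

        for taxon in taxa:
            freq = float(self.taxon_freqs.loc[taxon, "frequency"])
            cells = [taxon.ljust(width), f"{freq:6.2f}",
                     mark(self.global_balance, taxon).rjust(7)]
            cells += [mark(b, taxon).rjust(6) for b, _ in shown]
            lines.append("  ".join(cells))
        tail = ["FREQ".ljust(width), "      ", "       "] + [
            f"{f:6.2f}" for _, f in shown
        ]
        lines.append("  ".join(tail))
        return "\n".join(lines)


def summarize_robustness(
    grid: CvGrid, k_opt: int, global_balance: BalanceDefinition
) -> RobustnessSummary:
    """Tabulate the distinct CV balances of size k_opt and per-taxon
    inclusion frequencies, for comparison against the global balance."""
    balances = [b for b, _ in grid.balances_at(k_opt)]
    if not balances:
        raise ValueError(f"no cross-validation fold reached {k_opt} components")
    n = len(balances)
    counts: dict[BalanceDefinition, int] = {}
    for bal in balances:
        counts[bal] = counts.get(bal, 0) + 1
    freqs = sorted(
        ((bal, c / n) for bal, c in counts.items()),
        key=lambda item: (-item[1], item[0].numerator, item[0].denominator),
    )
    all_taxa = sorted({t for bal in balances for t in bal.taxa})
    rows = {}
    for taxon in all_taxa:
        num = sum(1 for b in balances if taxon in b.numerator)
        den = sum(1 for b in balances if taxon in b.denominator)
        rows[taxon] = {
            "frequency": (num + den) / n,
            "modal_side": "numerator" if num >= den else "denominator",
        }
    taxon_freqs = (
        pd.DataFrame.from_dict(rows, orient="index")
        .sort_values("frequency", ascending=False, kind="stable")
    )
    return RobustnessSummary(
        k_opt=k_opt,
        global_balance=global_balance,
        balance_freqs=freqs,
        taxon_freqs=taxon_freqs,
        n_balances=n,
    )


@dataclass
class CvResult:
    """Everything the CV pipeline produces, bundled for reporting."""

    grid: CvGrid
    k_opt: int
    global_result: SelbalResult
    cv_accuracy: float
    robustness: RobustnessSummary
    config: CvConfig

    def to_dict(self) -> dict:
        table = self.grid.mean_se()
        return {
            "criterion": self.grid.criterion_name,
            "config": {
                "n_iter": self.config.n_iter,
                "n_folds": self.config.n_folds,
                "max_components": self.config.max_components,
                "rule": self.config.rule,
                "seed": self.config.seed,
            },
            "mean_se": {
                int(c): {
                    "mean": float(row["mean"]),
                    "se": float(row["se"]),
                    "n": int(row["n"]),
                }
                for c, row in table.iterrows()
            },
            "k_opt": self.k_opt,
            "global": self.global_result.to_dict(),
            "cv_accuracy": self.cv_accuracy,
            "robustness": self.robustness.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def selbal_cv(
    frame: StudyFrame,
    cv: CvConfig | None = None,
    search: SearchConfig | None = None,
) -> CvResult:
    """The full pipeline: CV grid, model-size rule, global balance,
    cv accuracy and robustness summary."""
    cv = cv or CvConfig()
    search = search or SearchConfig()
    grid = run_cv(frame, cv, search)
    k_opt = one_se_rule(grid, rule=cv.rule)
    global_result, cv_accuracy = global_and_cv_accuracy(frame, k_opt, grid, search)
    robustness = summarize_robustness(grid, k_opt, global_result.final_balance)
    return CvResult(
        grid=grid,
        k_opt=k_opt,
        global_result=global_result,
        cv_accuracy=cv_accuracy,
        robustness=robustness,
        config=cv,
    )
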