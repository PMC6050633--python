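"""Model/Results surface over the balance-selection pipeline.

:class:`BalanceSelection` is built from a count table and a response (plus
optional covariates); construction applies zero replacement once, so every
downstream fit works on the same strictly positive composition.  ``fit()``
runs the greedy search and returns :class:`BalanceSelectionResults`;
``fit_cv()`` runs the repeated cross-validation pipeline and returns
:class:`BalanceCVResults`.  Both results objects expose the estimates,
their context (criterion path, CV curve, robustness tables) and a
``summary()`` text table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .balance import BalanceDefinition, evaluate_balance
from .cv import CvConfig, CvResult, selbal_cv
from .io import Composition, CountTable, StudyFrame, assemble_study
from .models import FitResult
from .selection import SearchConfig, SelbalResult, run_selbal
from .zeros import ZeroReplacementConfig, replace_zeros

__all__ = ["BalanceSelection", "BalanceSelectionResults", "BalanceCVResults"]


class BalanceSelection:
    """Find the compositional balance most predictive of a response.

    Parameters
    ----------
    counts
        Sample-by-taxon table of non-negative abundances: a
        :class:`~balancesel.io.CountTable`, a pandas DataFrame (samples in
        rows), or an already zero-replaced :class:`~balancesel.io.Composition`.
    response
        Per-sample response keyed by sample id (Series or mapping);
        continuous, or dichotomous with exactly two observed levels.
    covariates
        Optional per-sample DataFrame of adjustment variables; categorical
        columns are indicator-encoded against the first sorted level.
    response_type
        "auto" (default: dichotomous iff exactly two levels), "continuous"
        or "dichotomous".
    zero_method, gbm_prior_strength
        Zero replacement applied once at construction ("gbm" default, or
        "add_one"); ignored when ``counts`` is already a Composition.
    """

    def __init__(
        self,
        counts,
        response,
        covariates: pd.DataFrame | None = None,
        *,
        response_type: str = "auto",
        positive_level=None,
        zero_method: str = "gbm",
        gbm_prior_strength: float = 0.5,
    ) -> None:
        if isinstance(counts, pd.DataFrame):
            counts = CountTable.from_dataframe(counts)
        if isinstance(counts, Composition):
            composition = counts
        else:
            composition = replace_zeros(
                counts,
                ZeroReplacementConfig(
                    method=zero_method, gbm_prior_strength=gbm_prior_strength
                ),
            )
        self.frame: StudyFrame = assemble_study(
            composition,
            response,
            covariates,
            response_type=response_type,
            positive_level=positive_level,
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response_col: str,
        taxon_cols: list[str] | None = None,
        covariate_cols: list[str] | None = None,
        **kwargs,
    ) -> "BalanceSelection":
        """Build from a single DataFrame holding counts, response and
        covariates; ``taxon_cols`` defaults to every column not otherwise
        claimed."""
        covariate_cols = covariate_cols or []
        if taxon_cols is None:
            claimed = set(covariate_cols) | {response_col}
            taxon_cols = [c for c in data.columns if c not in claimed]
        counts = data[taxon_cols]
        covariates = data[covariate_cols] if covariate_cols else None
        return cls(counts, data[response_col], covariates, **kwargs)

    def fit(
        self,
        n_components: int = 20,
        threshold: float = 0.0,
        criterion: str | None = None,
    ) -> "BalanceSelectionResults":
        """Greedy search capped at ``n_components`` taxa (th.imp =
        ``threshold``); returns the selected balance and its fit."""
        config = SearchConfig(
            criterion=criterion, max_components=n_components, threshold=threshold
        )
        return BalanceSelectionResults(self, run_selbal(self.frame, config), config)

    def fit_cv(
        self,
        n_iter: int = 10,
        n_folds: int = 5,
        max_components: int = 20,
        rule: str = "one_se",
        seed: int | None = None,
        criterion: str | None = None,
        threshold: float = 0.0,
    ) -> "BalanceCVResults":
        """Repeated K-fold CV: pick the number of components, refit the
        global balance, and summarise robustness."""
        cv_config = CvConfig(
            n_iter=n_iter,
            n_folds=n_folds,
            max_components=max_components,
            rule=rule,
            seed=seed,
        )
        search = SearchConfig(criterion=criterion, threshold=threshold)
        return BalanceCVResults(self, selbal_cv(self.frame, cv_config, search))


def _coef_table(fit: FitResult, covariate_names) -> pd.Series:
    index = ["intercept", "balance"] + list(covariate_names)
    return pd.Series([fit.beta0, fit.beta1, *fit.gamma], index=index, name="coef")


class BalanceSelectionResults:
    """Results of one greedy search on the full dataset."""

    def __init__(
        self, model: BalanceSelection, result: SelbalResult, config: SearchConfig
    ) -> None:
        self.model = model
        self._result = result
        self.config = config

    @property
    def balance(self) -> BalanceDefinition:
        return self._result.final_balance

    @property
    def params(self) -> pd.Series:
        return _coef_table(self._result.final_fit, self.model.frame.covariate_names)

    @property
    def criterion_name(self) -> str:
        return self._result.criterion.name

    @property
    def criterion_value(self) -> float:
        return self._result.criterion_path[-1]

    @property
    def stop_reason(self) -> str:
        return self._result.stop_reason

    @property
    def path(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self._result.sizes,
                "criterion": self._result.criterion_path,
                "balance": [str(b) for b in self._result.balance_path],
            }
        )

    @property
    def selbal_result(self) -> SelbalResult:
        return self._result

    def balance_scores(self, normalized: bool = True) -> np.ndarray:
        """Per-sample scores of the selected balance."""
        return evaluate_balance(
            self.model.frame.composition, self.balance, proportional=not normalized
        ).values

    def summary(self) -> str:
        frame = self.model.frame
        lines = [
            "Balance selection results",
            "=" * 60,
            f"samples: {frame.n_samples}    taxa: {frame.n_taxa}    "
            f"response: {frame.response_type}",
            f"criterion: {self.criterion_name}    "
            f"value: {self.criterion_value:.4f}    stop: {self.stop_reason}",
            "",
            f"numerator   (X+): {', '.join(self.balance.numerator)}",
            f"denominator (X-): {', '.join(self.balance.denominator)}",
            "",
            "coefficients:",
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:<16s} {value: .4f}")
        lines += ["", "search path (size : criterion):"]
        for size, crit in zip(self._result.sizes, self._result.criterion_path):
            lines.append(f"  {size:>3d} : {crit:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self._result.to_dict()


class BalanceCVResults:
    """Results of the cross-validated pipeline."""

    def __init__(self, model: BalanceSelection, result: CvResult) -> None:
        self.model = model
        self._result = result

    @property
    def k_opt(self) -> int:
        return self._result.k_opt

    @property
    def global_balance(self) -> BalanceDefinition:
        return self._result.global_result.final_balance

    @property
    def params(self) -> pd.Series:
        return _coef_table(
            self._result.global_result.final_fit, self.model.frame.covariate_names
        )

    @property
    def cv_accuracy(self) -> float:
        """Mean held-out criterion at the global balance's size."""
        return self._result.cv_accuracy

    @property
    def apparent_accuracy(self) -> float:
        """Criterion of the global balance on the full dataset (optimistic)."""
        return self._result.global_result.criterion_path[-1]

    @property
    def cv_curve(self) -> pd.DataFrame:
        """Mean, SE and count of the held-out criterion per component count."""
        return self._result.grid.mean_se()

    @property
    def robustness(self):
        return self._result.robustness

    @property
    def cv_result(self) -> CvResult:
        return self._result

    def summary(self) -> str:
        res = self._result
        frame = self.model.frame
        lines = [
            "Cross-validated balance selection",
            "=" * 60,
            f"samples: {frame.n_samples}    taxa: {frame.n_taxa}    "
            f"response: {frame.response_type}",
            f"criterion: {res.grid.criterion_name}    "
            f"M: {res.config.n_iter}    K: {res.config.n_folds}    "
            f"rule: {res.config.rule}",
            "",
            "held-out criterion by number of components:",
        ]
        for c, row in res.grid.mean_se().iterrows():
            marker = "  <- k_opt" if c == res.k_opt else ""
            lines.append(
                f"  {int(c):>3d} : {row['mean']:.4f} +/- {row['se']:.4f}"
                f" (n={int(row['n'])}){marker}"
            )
        bal = self.global_balance
        lines += [
            "",
            f"k_opt = {res.k_opt}",
            f"global balance numerator   (X+): {', '.join(bal.numerator)}",
            f"global balance denominator (X-): {', '.join(bal.denominator)}",
            f"apparent {res.grid.criterion_name}: {self.apparent_accuracy:.4f}",
            f"cv {res.grid.criterion_name}:       {self.cv_accuracy:.4f}",
            "",
            "robustness (CV balances at k_opt):",
            res.robustness.to_text(),
        ]
        return "\n".join(lines)

    def plot_cv_curve(self, ax=None):
        """Mean held-out criterion vs number of components (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.cv_curve
        ax.errorbar(table.index, table["mean"], yerr=table["se"], marker="o")
        ax.axvline(self.k_opt, linestyle="--", color="grey")
        ax.set_xlabel("number of components")
        ax.set_ylabel(f"mean held-out {self._result.grid.criterion_name}")
        return ax

    def to_dict(self) -> dict:
        return self._result.to_dict()

    def to_json(self) -> str:
        return self._result.to_json()
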