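"""Dirichlet Monte Carlo propagation of sequencing-count uncertainty.

An observed count row is one multinomial realisation of the sample's true
relative abundances, so the posterior of those abundances under a Dirichlet
prior (default 0.5 per part, Jeffreys-style) is Dirichlet(counts + prior).
Each Monte Carlo draw samples a proportion vector per sample from that
posterior and rescales it by the observed row total, giving an alternative
abundance table that is strictly positive (no zero replacement needed) and
conserves every row total.  Re-running the balance search on many draws,
with the number of components held fixed at the cross-validated k_opt,
shows how stable the selected signature is under count noise: the summary
tabulates the distinct selected balances, per-taxon selection frequencies,
and the per-side Jaccard agreement of every draw with a reference balance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .balance import BalanceDefinition
from .io import Composition, CountTable, StudyFrame, ValidationError, assemble_study
from .selection import SearchConfig, run_selbal

__all__ = ["McConfig", "McSummary", "sample_tables", "mc_robustness"]


@dataclass(frozen=True)
class McConfig:
    n_draws: int = 100
    prior: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.prior <= 0:
            raise ValueError("prior must be positive")


def sample_tables(
    table: CountTable, config: McConfig | None = None
) -> Iterator[Composition]:
    """Yield ``n_draws`` posterior abundance tables.

    Per draw and per sample: proportions ~ Dirichlet(counts + prior), then
    rescaled by the sample's observed total.  Draws are almost surely
    strictly positive, so they feed the log-ratio machinery directly.
    """
    config = config or McConfig()
    totals = table.values.sum(axis=1)
    if np.any(totals <= 0):
        i = int(np.argmax(totals <= 0))
        raise ValidationError(
            f"sample {table.sample_ids[i]!r} has zero total count"
        )
    alpha = table.values + config.prior
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_draws):
        gammas = rng.standard_gamma(alpha)
        props = gammas / gammas.sum(axis=1, keepdims=True)
        yield Composition(
            values=props * totals[:, None],
            sample_ids=table.sample_ids,
            taxon_ids=table.taxon_ids,
        )


def _jaccard(a: tuple[str, ...], b: tuple[str, ...]) -> float:
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb)


@dataclass
class McSummary:
    reference: BalanceDefinition
    draws: list[BalanceDefinition]
    balance_freqs: list[tuple[BalanceDefinition, float]]
    taxon_freqs: pd.DataFrame
    concordance: pd.DataFrame  # per draw: jaccard_numerator/denominator/mean

    @property
    def modal_balance(self) -> BalanceDefinition:
        return self.balance_freqs[0][0]

    def to_dict(self) -> dict:
        return {
            "n_draws": len(self.draws),
            "reference": {
                "numerator": list(self.reference.numerator),
                "denominator": list(self.reference.denominator),
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
                t: float(v) for t, v in self.taxon_freqs["frequency"].items()
            },
            "concordance_mean": float(self.concordance["mean"].mean()),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def mc_robustness(
    table: CountTable,
    response,
    covariates,
    k_opt: int,
    search: SearchConfig | None = None,
    config: McConfig | None = None,
    reference: BalanceDefinition | None = None,
    response_type: str = "auto",
    positive_level: object | None = None,
) -> McSummary:
    """Re-run the search on Monte Carlo abundance tables and compare every
    selected balance to the reference signature.

    ``k_opt`` (from CV on the original table) caps the balance size of each
    draw; it is held fixed across draws.  When ``reference`` is omitted it
    is computed by running the capped search on the Dirichlet posterior
    *mean* table, a zero-free stand-in for the observed table.
    """
    search = search or SearchConfig()
    config = config or McConfig()
    capped = SearchConfig(
        criterion=search.criterion,
        max_components=max(k_opt, 2),
        threshold=search.threshold,
        ridge_fallback=search.ridge_fallback,
    )

    def frame_for(comp: Composition) -> StudyFrame:
        return assemble_study(
            comp,
            response,
            covariates,
            response_type=response_type,
            positive_level=positive_level,
        )

    if reference is None:
        totals = table.values.sum(axis=1, keepdims=True)
        alpha = table.values + config.prior
        mean_comp = Composition(
            values=alpha / alpha.sum(axis=1, keepdims=True) * totals,
            sample_ids=table.sample_ids,
            taxon_ids=table.taxon_ids,
        )
        reference = run_selbal(frame_for(mean_comp), capped).final_balance

    draws: list[BalanceDefinition] = []
    conc_rows = []
    for comp in sample_tables(table, config):
        result = run_selbal(frame_for(comp), capped)
        bal = result.final_balance
        draws.append(bal)
        j_num = _jaccard(bal.numerator, reference.numerator)
        j_den = _jaccard(bal.denominator, reference.denominator)
        conc_rows.append((j_num, j_den, (j_num + j_den) / 2))

    n = len(draws)
    counts: dict[BalanceDefinition, int] = {}
    for bal in draws:
        counts[bal] = counts.get(bal, 0) + 1
    freqs = sorted(
        ((b, c / n) for b, c in counts.items()),
        key=lambda item: (-item[1], item[0].numerator, item[0].denominator),
    )
    taxa = sorted({t for b in draws for t in b.taxa})
    taxon_freqs = pd.DataFrame(
        {
            "frequency": [
                sum(1 for b in draws if t in b.taxa) / n for t in taxa
            ]
        },
        index=taxa,
    ).sort_values("frequency", ascending=False, kind="stable")
    concordance = pd.DataFrame(
        conc_rows, columns=["jaccard_numerator", "jaccard_denominator", "mean"]
    )
    return McSummary(
        reference=reference,
        draws=draws,
        balance_freqs=freqs,
        taxon_freqs=taxon_freqs,
        concordance=concordance,
    )
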