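"""Zero replacement for count compositions.

Log-ratio methods require strictly positive parts, but sequencing count
tables are full of *rounded* zeros: taxa present below the detection limit
of the realised sequencing depth.  Two replacement strategies are provided:

``replace_add_one``
    Add 1 to every cell.  Crude, but transparent and occasionally requested.

``replace_gbm``
    Geometric Bayesian multiplicative replacement.  Each sample row is
    treated as a multinomial draw whose proportion vector carries a
    Dirichlet prior; each zero cell is imputed by its posterior expected
    proportion (times the observed row total) and the nonzero cells are
    multiplicatively shrunk by one common factor so that (i) the ratios
    between all originally nonzero parts are exactly preserved and (ii) the
    row total is exactly preserved.

    The prior mean of the Dirichlet is the *geometric* column profile of the
    dataset: per taxon, the geometric mean of its observed nonzero
    proportions across samples, normalised to a composition.  The prior
    carries ``prior_strength`` pseudo-counts per part on average (default
    0.5, a Jeffreys-like weight), i.e. a total prior mass of
    ``prior_strength * n_taxa`` per row.

Both methods treat every observed zero as a rounded zero; structural
(true-absence) zeros are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Composition, CountTable, ValidationError

__all__ = ["ZeroReplacementConfig", "replace_add_one", "replace_gbm", "replace_zeros"]


class DegeneratePriorError(ValueError):
    """The imputed zero mass would rival or exceed the observed mass."""


@dataclass(frozen=True)
class ZeroReplacementConfig:
    method: str = "gbm"  # "gbm" | "add_one"
    gbm_prior_strength: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("gbm", "add_one"):
            raise ValueError(f"unknown zero replacement method {self.method!r}")
        if self.gbm_prior_strength <= 0:
            raise ValueError("gbm_prior_strength must be positive")


def replace_add_one(table: CountTable) -> Composition:
    """Add 1 to every cell of the table."""
    return Composition(
        values=table.values + 1.0,
        sample_ids=table.sample_ids,
        taxon_ids=table.taxon_ids,
    )


def _geometric_prior_mean(values: np.ndarray) -> np.ndarray:
    """Column prior composition: geometric mean of observed nonzero proportions.

    Taxa never observed (all-zero columns) get the smallest nonzero prior
    weight so the prior mean stays strictly positive.
    """
    totals = values.sum(axis=1, keepdims=True)
    props = values / totals
    with np.errstate(divide="ignore"):
        logp = np.log(np.where(props > 0, props, 1.0))
    counts = (props > 0).sum(axis=0)
    sums = logp.sum(axis=0)
    gm = np.where(counts > 0, np.exp(sums / np.maximum(counts, 1)), np.nan)
    if np.any(np.isnan(gm)):
        floor = np.nanmin(gm) if np.any(~np.isnan(gm)) else 1.0
        gm = np.where(np.isnan(gm), floor, gm)
    return gm / gm.sum()


def replace_gbm(
    table: CountTable, config: ZeroReplacementConfig | None = None
) -> Composition:
    """Geometric Bayesian multiplicative replacement of zero counts.

    Per row i with total ``N_i`` and total prior mass ``S = strength * k``:
    a zero cell j is imputed as ``N_i * S * t_j / (N_i + S)`` where ``t`` is
    the geometric column prior composition; nonzero cells are scaled by the
    common factor ``1 - (imputed mass) / N_i``.  Rows without zeros are
    returned unchanged.
    """
    config = config or ZeroReplacementConfig()
    values = table.values
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        i = int(np.argmax(totals <= 0))
        raise ValidationError(
            f"sample {table.sample_ids[i]!r} has an all-zero row; "
            "zero replacement is undefined"
        )
    out = values.astype(float).copy()
    zero_mask = values == 0
    if zero_mask.any():
        t = _geometric_prior_mean(values)
        strength_total = config.gbm_prior_strength * table.n_taxa
        # posterior expected proportion contributed by the prior alone
        prior_prop = strength_total * t[None, :] / (totals[:, None] + strength_total)
        imputed_frac = np.where(zero_mask, prior_prop, 0.0).sum(axis=1)
        observed_frac = 1.0 - imputed_frac
        bad = imputed_frac >= observed_frac
        if np.any(bad):
            i = int(np.argmax(bad))
            raise DegeneratePriorError(
                f"sample {table.sample_ids[i]!r}: imputed zero mass "
                f"({imputed_frac[i]:.3g} of the total) reaches the observed "
                "nonzero mass; reduce gbm_prior_strength"
            )
        out = np.where(
            zero_mask,
            totals[:, None] * prior_prop,
            values * observed_frac[:, None],
        )
    return Composition(
        values=out, sample_ids=table.sample_ids, taxon_ids=table.taxon_ids
    )


def replace_zeros(
    table: CountTable, config: ZeroReplacementConfig | None = None
) -> Composition:
    """Dispatch on the configured method (default GBM)."""
    config = config or ZeroReplacementConfig()
    if config.method == "add_one":
        return replace_add_one(table)
    return replace_gbm(table, config)
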