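"""Synthetic microbiome studies with a planted balance signal.

The generator mimics the statistical structure the balance model assumes:
each sample has a latent, zero-free composition; the response depends on
the latent data only through one planted balance; observed counts are a
multinomial thinning of the latent composition at a finite sequencing
depth, which is what creates rounded zeros in rare taxa.

Per sample i and taxon j the latent log abundance is

    w_ij = mu_j + e_ij,   e_ij ~ N(0, latent_sd^2),

with ``mu`` a fixed baseline log-abundance profile (planted taxa abundant,
noise taxa spanning six natural-log units down to rare).  The planted
balance score B_i is computed on the latent composition (equivalently on
``w``, balances being scale invariant).  The response follows

    continuous:   y_i = b0 + b1 B_i + g z_i + N(0, noise_sd^2)
    dichotomous:  y_i ~ Bernoulli(expit(b0 + b1 B_i + g z_i))

and counts are Multinomial(depth_i, softmax(w_i)).  An optional binary
covariate z can shift the numerator taxa directly (``confounding``),
correlating it with the balance, and/or enter the response (``covariate_effect``).
The returned truth record carries the planted balance, coefficients and the
latent balance scores, so recovery tests can score themselves against an
exact oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .balance import BalanceDefinition
from .io import CountTable

__all__ = ["GeneratorSpec", "SimulatedStudy", "generate", "generate_null"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard test-bed: 200 samples, a 2-taxon balance
    planted among 10 noise taxa, a strong dichotomous effect (b1 = 2 on the
    logit scale) and 10,000 reads per sample.
    """

    n_samples: int = 200
    n_taxa: int = 12
    numerator: tuple[str, ...] | None = None  # default: first taxon
    denominator: tuple[str, ...] | None = None  # default: second taxon
    effect: float = 2.0  # b1, on the normalised-balance scale
    intercept: float = 0.0
    response_type: str = "dichotomous"  # "dichotomous" | "continuous"
    noise_sd: float = 0.5  # continuous responses only
    latent_sd: float = 1.0
    baseline: tuple[float, ...] | None = None  # per-taxon mean log abundance
    covariate_effect: float = 0.0
    confounding: float = 0.0
    depth: int | tuple[int, ...] = 10_000
    zero_inflation: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_taxa < 2:
            raise ValueError("need at least 2 samples and 2 taxa")
        if self.response_type not in ("dichotomous", "continuous"):
            raise ValueError(f"unknown response type {self.response_type!r}")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        ids = self.taxon_ids
        if self.numerator is None:
            object.__setattr__(self, "numerator", (ids[0],))
        if self.denominator is None:
            object.__setattr__(self, "denominator", (ids[1],))
        for t in self.numerator + self.denominator:
            if t not in ids:
                raise ValueError(
                    f"planted taxon {t!r} outside the table's taxa"
                )
        if set(self.numerator) & set(self.denominator):
            raise ValueError("planted groups must be disjoint")

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_taxa))
        return tuple(f"taxon_{i + 1:0{width}d}" for i in range(self.n_taxa))

    @property
    def balance(self) -> BalanceDefinition:
        return BalanceDefinition(self.numerator, self.denominator)

    def baseline_profile(self) -> np.ndarray:
        """Planted taxa sit at the abundant end (mu = 0); noise taxa span
        0 down to -6 natural-log units so the rare end yields rounded
        zeros at realistic sequencing depths."""
        if self.baseline is not None:
            if len(self.baseline) != self.n_taxa:
                raise ValueError("baseline length must equal n_taxa")
            return np.asarray(self.baseline, dtype=float)
        mu = np.zeros(self.n_taxa)
        planted = set(self.numerator) | set(self.denominator)
        noise_positions = [
            i for i, t in enumerate(self.taxon_ids) if t not in planted
        ]
        if noise_positions:
            mu[noise_positions] = np.linspace(0.0, -6.0, len(noise_positions))
        return mu


@dataclass
class SimulatedStudy:
    table: CountTable
    response: pd.Series
    covariates: pd.DataFrame | None
    truth: dict = field(default_factory=dict)

    def truth_json(self) -> str:
        out = {
            k: [float(x) for x in v] if isinstance(v, np.ndarray) else v
            for k, v in self.truth.items()
        }
        return json.dumps(out, indent=2, sort_keys=True)


def _depths(spec: GeneratorSpec) -> np.ndarray:
    if np.isscalar(spec.depth):
        return np.full(spec.n_samples, int(spec.depth))
    depths = np.asarray(spec.depth, dtype=int)
    if depths.shape != (spec.n_samples,):
        raise ValueError("depth must be a scalar or one total per sample")
    return depths


def generate(spec: GeneratorSpec) -> SimulatedStudy:
    """Draw one synthetic study from the spec (seeded, fully reproducible)."""
    rng = np.random.default_rng(spec.seed)
    mu = spec.baseline_profile()
    ids = spec.taxon_ids
    w = mu[None, :] + rng.normal(0.0, spec.latent_sd, (spec.n_samples, spec.n_taxa))

    z = None
    if spec.covariate_effect != 0.0 or spec.confounding != 0.0:
        z = rng.integers(0, 2, spec.n_samples).astype(float)
        if spec.confounding != 0.0:
            num_idx = [ids.index(t) for t in spec.numerator]
            w[:, num_idx] += spec.confounding * z[:, None]

    bal = spec.balance
    num_idx = [ids.index(t) for t in bal.numerator]
    den_idx = [ids.index(t) for t in bal.denominator]
    scores = (
        w[:, num_idx].mean(axis=1) - w[:, den_idx].mean(axis=1)
    ) * bal.normalization

    eta = spec.intercept + spec.effect * scores
    if z is not None:
        eta = eta + spec.covariate_effect * z
    if spec.response_type == "continuous":
        y = eta + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    else:
        from scipy.special import expit

        y = rng.binomial(1, expit(eta)).astype(int)

    props = np.exp(w - w.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    depths = _depths(spec)
    counts = np.empty((spec.n_samples, spec.n_taxa), dtype=float)
    for i in range(spec.n_samples):
        counts[i] = rng.multinomial(depths[i], props[i])
    if spec.zero_inflation > 0:
        drop = rng.random(counts.shape) < spec.zero_inflation
        counts = np.where(drop, 0.0, counts)
    # every sample must keep at least one read
    empty = counts.sum(axis=1) == 0
    if np.any(empty):
        top = np.argmax(props[empty], axis=1)
        counts[np.flatnonzero(empty), top] = 1.0

    sample_ids = tuple(f"sample_{i + 1:03d}" for i in range(spec.n_samples))
    table = CountTable(values=counts, sample_ids=sample_ids, taxon_ids=ids)
    response = pd.Series(y, index=list(sample_ids), name="response")
    covariates = (
        pd.DataFrame({"z": z}, index=list(sample_ids)) if z is not None else None
    )
    truth = {
        "numerator": list(bal.numerator),
        "denominator": list(bal.denominator),
        "effect": spec.effect,
        "intercept": spec.intercept,
        "covariate_effect": spec.covariate_effect,
        "confounding": spec.confounding,
        "response_type": spec.response_type,
        "balance_scores": scores,
        "linear_predictor": eta,
    }
    return SimulatedStudy(
        table=table, response=response, covariates=covariates, truth=truth
    )


def generate_null(spec: GeneratorSpec) -> SimulatedStudy:
    """Same marginals, but the response is independent of the table (b1=0)."""
    return generate(replace(spec, effect=0.0))
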