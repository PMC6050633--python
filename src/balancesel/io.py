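"""Reading, validation and alignment of count tables, responses and covariates.

The canonical in-memory orientation is samples in rows, taxa in columns.
Tables arriving taxa-in-rows are transposed at read time.  A :class:`CountTable`
holds raw (possibly zero) non-negative abundances; a :class:`Composition` is the
strictly positive table obtained after zero replacement; a :class:`StudyFrame`
bundles a composition with an aligned response and optional covariates and is
the object every downstream stage consumes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "Composition",
    "StudyFrame",
    "read_count_table",
    "read_metadata",
    "assemble_study",
]


class ValidationError(ValueError):
    """Raised when an input table or metadata frame violates an invariant."""


def _check_labels(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass(frozen=True)
class CountTable:
    """A samples-by-taxa matrix of non-negative abundances.

    Raw sequencing counts are integers; tables produced by Dirichlet
    resampling are positive reals, so values are stored as floats.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("count table must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", _check_labels(self.sample_ids, "sample"))
        object.__setattr__(self, "taxon_ids", _check_labels(self.taxon_ids, "taxon"))
        n, k = values.shape
        if n != len(self.sample_ids) or k != len(self.taxon_ids):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if n < 2 or k < 2:
            raise ValidationError("need at least 2 samples and 2 taxa")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value {values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=tuple(str(i) for i in df.index),
            taxon_ids=tuple(str(c) for c in df.columns),
        )

    def write(self, path: str | os.PathLike, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")


@dataclass(frozen=True)
class Composition(CountTable):
    """A strictly positive abundance table (zero replacement already applied)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise ValidationError(
                f"composition entries must be strictly positive; found "
                f"{self.values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r} (apply zero replacement first)"
            )

    def take(self, indices: np.ndarray) -> "Composition":
        indices = np.asarray(indices)
        return Composition(
            values=self.values[indices],
            sample_ids=tuple(self.sample_ids[i] for i in indices),
            taxon_ids=self.taxon_ids,
        )


@dataclass(frozen=True)
class StudyFrame:
    """A composition aligned with its response and covariates.

    ``response`` is the raw per-sample response; for a dichotomous response
    ``y01`` holds the 0/1 encoding with ``positive_level`` mapped to 1.
    ``covariates`` is an n-by-r design block (indicator-encoded categoricals)
    with ``covariate_names``; it may have zero columns.
    """

    composition: Composition
    response: np.ndarray
    response_type: str  # "continuous" | "dichotomous"
    covariates: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    covariate_names: tuple[str, ...] = ()
    positive_level: object | None = None
    y01: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.response_type not in ("continuous", "dichotomous"):
            raise ValidationError(f"unknown response type {self.response_type!r}")
        resp = np.asarray(self.response)
        object.__setattr__(self, "response", resp)
        n = self.composition.n_samples
        if resp.shape[0] != n:
            raise ValidationError("response not aligned with composition samples")
        cov = np.asarray(self.covariates, dtype=float)
        if cov.size == 0:
            cov = np.empty((n, 0))
        if cov.shape[0] != n:
            raise ValidationError("covariates not aligned with composition samples")
        object.__setattr__(self, "covariates", cov)
        if self.response_type == "dichotomous":
            levels = pd.unique(resp)
            if len(levels) != 2:
                raise ValidationError(
                    f"dichotomous response must have exactly 2 observed levels, "
                    f"found {sorted(map(str, levels))}"
                )
            pos = self.positive_level
            if pos is None:
                pos = sorted(levels, key=str)[1]
                object.__setattr__(self, "positive_level", pos)
            elif pos not in set(levels):
                raise ValidationError(f"positive level {pos!r} not among {levels}")
            object.__setattr__(
                self, "y01", (resp == pos).astype(float)
            )
        else:
            y = resp.astype(float)
            if np.any(~np.isfinite(y)):
                raise ValidationError("continuous response contains non-finite values")
            object.__setattr__(self, "response", y)

    @property
    def n_samples(self) -> int:
        return self.composition.n_samples

    @property
    def n_taxa(self) -> int:
        return self.composition.n_taxa

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.composition.sample_ids

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return self.composition.taxon_ids

    @property
    def y(self) -> np.ndarray:
        """The numeric response used for fitting (0/1 for dichotomous)."""
        return self.y01 if self.response_type == "dichotomous" else self.response

    def take(self, indices: np.ndarray) -> "StudyFrame":
        indices = np.asarray(indices)
        return StudyFrame(
            composition=self.composition.take(indices),
            response=self.response[indices],
            response_type=self.response_type,
            covariates=self.covariates[indices],
            covariate_names=self.covariate_names,
            positive_level=self.positive_level,
        )


def _infer_sep(path: str | os.PathLike, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_count_table(
    path: str | os.PathLike,
    orientation: str = "samples_in_rows",
    sep: str | None = None,
) -> CountTable:
    """Read a delimited count table with one header row and one label column.

    Parameters
    ----------
    orientation
        ``"samples_in_rows"`` (canonical) or ``"taxa_in_rows"``; the latter is
        transposed on read so the returned table is always samples-in-rows.
    sep
        Field delimiter; inferred from the file suffix when omitted
        (``.csv`` -> comma, otherwise tab).
    """
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    if orientation == "taxa_in_rows":
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise ValidationError(
                    f"non-numeric value {df[col][bad].iloc[0]!r} at row {row!r}, "
                    f"column {col!r} in {path}"
                ) from exc
        raise
    return CountTable(
        values=values,
        sample_ids=tuple(str(i) for i in df.index),
        taxon_ids=tuple(str(c) for c in df.columns),
    )


def read_metadata(path: str | os.PathLike, sep: str | None = None) -> pd.DataFrame:
    """Read a per-sample metadata table keyed by sample id (first column)."""
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    df.index = df.index.map(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample label: {dup!r}")
    return df


def _encode_covariates(
    cov: pd.DataFrame,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Indicator-encode categorical columns, dropping the first sorted level."""
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in cov.columns:
        series = cov[col]
        if pd.api.types.is_numeric_dtype(series):
            blocks.append(series.to_numpy(dtype=float)[:, None])
            names.append(str(col))
        else:
            levels = sorted(map(str, pd.unique(series.astype(str))))
            reference = levels[0]
            logger.info(
                "covariate %r encoded with reference level %r", col, reference
            )
            for lev in levels[1:]:
                blocks.append(
                    (series.astype(str) == lev).to_numpy(dtype=float)[:, None]
                )
                names.append(f"{col}[{lev}]")
    if not blocks:
        return np.empty((len(cov), 0)), ()
    return np.hstack(blocks), tuple(names)


def assemble_study(
    composition: Composition,
    response: Mapping | pd.Series,
    covariates: pd.DataFrame | None = None,
    response_type: str = "auto",
    positive_level: object | None = None,
    drop_missing: bool = True,
) -> StudyFrame:
    """Align a composition with its response (and covariates) into a StudyFrame.

    Samples are kept in the composition's order.  Samples lacking a response
    value (or any covariate value) are dropped with a warning when
    ``drop_missing`` is true, otherwise an error lists them.
    """
    resp = pd.Series(response)
    resp.index = resp.index.map(str)
    ids = list(composition.sample_ids)
    missing = [s for s in ids if s not in resp.index or pd.isna(resp.get(s))]
    if covariates is not None:
        covariates = covariates.copy()
        covariates.index = covariates.index.map(str)
        for s in ids:
            if s in missing:
                continue
            if s not in covariates.index or covariates.loc[s].isna().any():
                missing.append(s)
    if missing:
        if not drop_missing:
            raise ValidationError(
                f"samples missing response/covariates: {sorted(missing)}"
            )
        logger.warning(
            "dropping %d sample(s) with missing response/covariates: %s",
            len(missing),
            sorted(missing),
        )
        keep = [i for i, s in enumerate(ids) if s not in set(missing)]
        if len(keep) < 2:
            raise ValidationError("fewer than 2 samples remain after alignment")
        composition = composition.take(np.asarray(keep))
        ids = list(composition.sample_ids)
    resp_values = resp.loc[ids].to_numpy()
    if response_type == "auto":
        n_levels = len(pd.unique(resp_values))
        response_type = "dichotomous" if n_levels == 2 else "continuous"
    if covariates is not None:
        cov_matrix, cov_names = _encode_covariates(covariates.loc[ids])
    else:
        cov_matrix, cov_names = np.empty((len(ids), 0)), ()
    return StudyFrame(
        composition=composition,
        response=resp_values,
        response_type=response_type,
        covariates=cov_matrix,
        covariate_names=cov_names,
        positive_level=positive_level,
    )
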