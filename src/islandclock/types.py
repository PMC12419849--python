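"""Core domain types shared across the pipeline.

The universal payload is a :class:`MethylationMatrix` — a samples x CpGs
numeric array on either the beta scale (methylation fractions in (0, 1))
or the M scale (logit2 of beta, the modelling scale).  Sample metadata
travels as a plain :class:`pandas.DataFrame` validated by
:func:`validate_sample_sheet`; a trained clock is a :class:`ClockModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BETA_CLIP = 1e-6  # clipping bound for beta values before the logit transform

#: required sample-sheet columns
SHEET_REQUIRED = ("sample_id", "age", "tissue", "dataset")
#: optional sample-sheet columns
SHEET_OPTIONAL = ("replicate_group", "population_doublings", "condition")


class IslandClockError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(IslandClockError):
    """Malformed input data (duplicate ids, non-numeric cells, ...)."""


class ModelFormatError(IslandClockError):
    """Unreadable or schema-incompatible clock-model file."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise DataFormatError(f"duplicate {what}: {', '.join(map(str, dups.index[:10]))}")


@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation matrix with identifier vectors.

    Parameters
    ----------
    values
        Float array of shape ``(n_samples, n_cpgs)``; ``NaN`` marks missing.
    sample_ids, cpg_ids
        Ordered unique identifiers for rows and columns.
    scale
        ``"beta"`` (fractions in (0, 1)) or ``"m"`` (logit2 scale).
    """

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        if self.scale not in ("beta", "m"):
            raise DataFormatError(f"unknown scale {self.scale!r}; expected 'beta' or 'm'")
        if self.values.ndim != 2:
            raise DataFormatError("matrix values must be 2-dimensional")
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise DataFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.cpg_ids, "CpG ids")
        if self.scale == "beta":
            obs = self.values[~np.isnan(self.values)]
            if obs.size and (obs.min() <= 0.0 or obs.max() >= 1.0):
                raise DataFormatError(
                    "beta values must lie strictly in (0, 1); "
                    "clip or convert before constructing the matrix"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "MethylationMatrix":
        """Return a matrix restricted (and reordered) to ``cpg_ids``."""
        index = pd.Index(self.cpg_ids)
        missing = [c for c in cpg_ids if c not in index]
        if missing:
            raise DataFormatError(f"CpGs absent from matrix: {missing[:10]}")
        cols = index.get_indexer(list(cpg_ids))
        return MethylationMatrix(
            self.values[:, cols], list(self.sample_ids), [str(c) for c in cpg_ids], self.scale
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        index = pd.Index(self.sample_ids)
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise DataFormatError(f"samples absent from matrix: {missing[:10]}")
        rows = index.get_indexer(list(sample_ids))
        return MethylationMatrix(
            self.values[rows, :], [str(s) for s in sample_ids], list(self.cpg_ids), self.scale
        )


def validate_sample_sheet(sheet: pd.DataFrame, matrix: MethylationMatrix | None = None) -> pd.DataFrame:
    """Validate a sample sheet and return it with a canonical column order.

    Required columns: ``sample_id``, ``age`` (years, >= 0), ``tissue``,
    ``dataset``.  Optional: ``replicate_group``, ``population_doublings``,
    ``condition``.  If ``matrix`` is given, every matrix sample must have
    exactly one sheet row.
    """
    missing = [c for c in SHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise DataFormatError(f"sample sheet missing required columns: {missing}")
    sheet = sheet.copy()
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    _check_unique(sheet["sample_id"], "sample ids in sheet")
    ages = pd.to_numeric(sheet["age"], errors="coerce")
    if ages.isna().any():
        bad = sheet.loc[ages.isna(), "sample_id"].tolist()
        raise DataFormatError(f"non-numeric ages for samples: {bad[:10]}")
    if (ages < 0).any():
        bad = sheet.loc[ages < 0, "sample_id"].tolist()
        raise DataFormatError(f"negative ages for samples: {bad[:10]}")
    sheet["age"] = ages.astype(float)
    if matrix is not None:
        sheet_ids = set(sheet["sample_id"])
        absent = [s for s in matrix.sample_ids if s not in sheet_ids]
        if absent:
            raise DataFormatError(f"matrix samples without sheet rows: {absent[:10]}")
    cols = [c for c in SHEET_REQUIRED] + [c for c in SHEET_OPTIONAL if c in sheet.columns]
    extra = [c for c in sheet.columns if c not in cols]
    return sheet[cols + extra]


def align_sheet(sheet: pd.DataFrame, matrix: MethylationMatrix) -> pd.DataFrame:
    """Return the sheet rows reordered to match ``matrix.sample_ids``."""
    sheet = validate_sample_sheet(sheet, matrix)
    return sheet.set_index("sample_id").loc[matrix.sample_ids].reset_index()


@dataclass
class ClockModel:
    """A trained principal-component clock.

    Prediction of a new sample: restrict its M-values to ``cpg_ids``,
    subtract ``center``, project onto ``loadings``, apply the linear model
    ``intercept + scores @ coefficients`` on the transformed-age scale and
    invert the age transform (piecewise log/linear with junction at
    ``adult_age``).
    """

    cpg_ids: list[str]
    center: np.ndarray
    loadings: np.ndarray  # (n_cpgs, n_components), orthonormal columns
    intercept: float
    coefficients: np.ndarray  # (n_components,)
    adult_age: float = 20.0
    training_metadata: dict = field(default_factory=dict)

    ORTHO_TOL = 1e-8

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        p, c = self.loadings.shape
        if len(self.cpg_ids) != p or len(self.center) != p:
            raise ModelFormatError("cpg_ids, center and loadings rows must align")
        if len(self.coefficients) != c:
            raise ModelFormatError("one coefficient per principal component required")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(c), atol=self.ORTHO_TOL):
            raise ModelFormatError("loadings columns must be orthonormal")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]
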