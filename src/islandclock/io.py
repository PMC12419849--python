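"""Readers and writers for matrices, sample sheets, annotations and models.

On disk a methylation matrix is CpG x sample (first column CpG ids, header
row of sample ids); in memory it is sample x CpG.  The transpose happens
only at this boundary.  A trained clock is stored as a single
self-describing JSON container with a schema version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BETA_CLIP,
    ClockModel,
    DataFormatError,
    MethylationMatrix,
    ModelFormatError,
    validate_sample_sheet,
)

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def read_matrix(path: str | Path, scale: str) -> MethylationMatrix:
    """Read a delimited CpG x sample matrix (CSV or TSV) from ``path``.

    Empty cells become missing values.  Beta values outside ``(0, 1)`` are
    clipped into ``[1e-6, 1 - 1e-6]`` with a logged warning count; duplicate
    ids or non-numeric cells are hard errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    cpg_ids = [str(c) for c in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataFormatError(
                f"non-numeric cell at CpG {cpg_ids[i]!r}, sample {col!r}: {raw[col].iloc[i]!r}"
            )
        values[:, j] = parsed.to_numpy()
    values = values.T  # -> samples x CpGs
    if scale == "beta":
        obs = ~np.isnan(values)
        out_of_range = obs & ((values <= 0.0) | (values >= 1.0))
        n_clip = int(out_of_range.sum())
        if n_clip:
            logger.warning("clipped %d beta values into [%g, %g]", n_clip, BETA_CLIP, 1 - BETA_CLIP)
            values = np.where(obs, np.clip(values, BETA_CLIP, 1.0 - BETA_CLIP), values)
    return MethylationMatrix(values, sample_ids, cpg_ids, scale)


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write a matrix as CpG x sample delimited text (inverse of read_matrix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.DataFrame(matrix.values.T, index=matrix.cpg_ids, columns=matrix.sample_ids)
    frame.to_csv(path, sep=sep, index_label="cpg_id", float_format="%.17g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path))


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation CSV: cpg_id, chromosome, snp_within_2bp, cross_hybridising."""
    ann = pd.read_csv(path)
    required = ["cpg_id", "chromosome", "snp_within_2bp", "cross_hybridising"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise DataFormatError(f"annotation missing columns: {missing}")
    ann = ann.copy()
    ann["cpg_id"] = ann["cpg_id"].astype(str)
    if ann["cpg_id"].duplicated().any():
        dups = ann.loc[ann["cpg_id"].duplicated(), "cpg_id"].tolist()
        raise DataFormatError(f"duplicate annotation CpG ids: {dups[:10]}")
    for col in ("snp_within_2bp", "cross_hybridising"):
        ann[col] = ann[col].astype(bool)
    return ann


def write_model(model: ClockModel, path: str | Path) -> None:
    """Serialize a clock model to a single self-describing JSON container."""
    payload = {
        "schema": "islandclock.model",
        "schema_version": MODEL_SCHEMA_VERSION,
        "cpg_ids": list(model.cpg_ids),
        "center": model.center.tolist(),
        "loadings": model.loadings.tolist(),
        "intercept": float(model.intercept),
        "coefficients": model.coefficients.tolist(),
        "adult_age": float(model.adult_age),
        "training_metadata": model.training_metadata,
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path: str | Path) -> ClockModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"unreadable model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != "islandclock.model":
        raise ModelFormatError(f"{path} is not an islandclock model container")
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"model schema version {version!r} unsupported (expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        return ClockModel(
            cpg_ids=[str(c) for c in payload["cpg_ids"]],
            center=np.asarray(payload["center"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            intercept=float(payload["intercept"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            adult_age=float(payload["adult_age"]),
            training_metadata=payload.get("training_metadata", {}),
        )
    except KeyError as exc:
        raise ModelFormatError(f"model file {path} missing field {exc}") from exc
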