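"""Probe filtering, scale conversion, imputation, age transform, splits
and the per-tissue correlation pre-filter feeding the genetic algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .types import BETA_CLIP, DataFormatError, IslandClockError, MethylationMatrix, align_sheet

logger = logging.getLogger(__name__)

ADULT_AGE = 20.0


# ---------------------------------------------------------------- filtering

def filter_probes(
    matrix: MethylationMatrix,
    annotation: pd.DataFrame | None = None,
    detection_p: MethylationMatrix | pd.DataFrame | None = None,
    p_threshold: float = 0.01,
    max_fail_fraction: float = 0.0,
    missing_annotation: str = "warn",
) -> tuple[MethylationMatrix, dict[str, int]]:
    """Remove unreliable probes; returns the filtered matrix and a report.

    A CpG is removed if it (a) exceeds the detection p-value threshold in
    more than ``max_fail_fraction`` of samples (default: any sample), (b) is
    flagged as lying within 2 bp of a SNP, (c) maps to chromosome X or Y,
    or (d) is flagged as cross-hybridising.  The report counts removals per
    rule (a CpG may be counted under several rules).
    """
    if missing_annotation not in ("warn", "error"):
        raise IslandClockError("missing_annotation must be 'warn' or 'error'")
    n = matrix.n_cpgs
    drop = np.zeros(n, dtype=bool)
    report = {"detection_p": 0, "snp": 0, "chrXY": 0, "cross_hybridising": 0}

    if detection_p is not None:
        if isinstance(detection_p, MethylationMatrix):
            pvals = detection_p.to_frame()
        else:
            pvals = detection_p
        pvals = pvals.reindex(index=matrix.sample_ids, columns=matrix.cpg_ids)
        if pvals.isna().any().any():
            raise DataFormatError("detection p-value matrix does not cover all samples x CpGs")
        fail_frac = (pvals.to_numpy() > p_threshold).mean(axis=0)
        bad = fail_frac > max_fail_fraction
        report["detection_p"] = int(bad.sum())
        drop |= bad

    if annotation is not None:
        ann = annotation.set_index("cpg_id")
        covered = pd.Index(matrix.cpg_ids).isin(ann.index)
        if not covered.all():
            n_missing = int((~covered).sum())
            if missing_annotation == "error":
                raise DataFormatError(f"{n_missing} CpGs lack annotation rows")
            logger.warning("%d CpGs lack annotation; kept", n_missing)
        sub = ann.reindex(matrix.cpg_ids)
        snp = sub["snp_within_2bp"].fillna(False).to_numpy(dtype=bool)
        xy = sub["chromosome"].isin(["X", "Y", "chrX", "chrY"]).to_numpy()
        xhyb = sub["cross_hybridising"].fillna(False).to_numpy(dtype=bool)
        report["snp"] = int(snp.sum())
        report["chrXY"] = int(xy.sum())
        report["cross_hybridising"] = int(xhyb.sum())
        drop |= snp | xy | xhyb

    keep = [c for c, d in zip(matrix.cpg_ids, drop) if not d]
    report["removed_total"] = int(drop.sum())
    report["retained"] = len(keep)
    return matrix.subset_cpgs(keep), report


# ---------------------------------------------------------- scale conversion

def beta_to_m(matrix: MethylationMatrix) -> MethylationMatrix:
    """M = log2(beta / (1 - beta)); missing values preserved."""
    if matrix.scale != "beta":
        raise DataFormatError(f"expected a beta-scale matrix, got scale={matrix.scale!r}")
    b = matrix.values
    m = np.log2(b / (1.0 - b))
    return MethylationMatrix(m, list(matrix.sample_ids), list(matrix.cpg_ids), "m")


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse logit2, clipped into [1e-6, 1 - 1e-6]."""
    if matrix.scale != "m":
        raise DataFormatError(f"expected an M-scale matrix, got scale={matrix.scale!r}")
    m = matrix.values
    with np.errstate(over="ignore"):
        b = 1.0 / (1.0 + np.power(2.0, -m))
    b = np.where(np.isnan(m), np.nan, np.clip(b, BETA_CLIP, 1.0 - BETA_CLIP))
    return MethylationMatrix(b, list(matrix.sample_ids), list(matrix.cpg_ids), "beta")


# ------------------------------------------------------------------ imputing

def knn_impute(matrix: MethylationMatrix, k: int = 10, max_missing_fraction: float = 0.5) -> MethylationMatrix:
    """Impute missing entries from the k nearest samples.

    Distances are Euclidean over mutually observed CpGs, rescaled by the
    number of CpGs used; each missing value becomes the mean of that CpG in
    the k nearest samples where it is observed.  Observed values are never
    altered.
    """
    values = matrix.values
    miss = np.isnan(values)
    if not miss.any():
        return matrix
    if miss.all(axis=1).any():
        bad = [s for s, m in zip(matrix.sample_ids, miss.all(axis=1)) if m]
        raise DataFormatError(f"samples with all values missing: {bad[:10]}")
    cpg_miss = miss.mean(axis=0)
    if (cpg_miss > max_missing_fraction).any():
        worst = [c for c, f in zip(matrix.cpg_ids, cpg_miss) if f > max_missing_fraction]
        raise DataFormatError(
            f"{len(worst)} CpGs exceed the {max_missing_fraction:.0%} missingness ceiling: {worst[:10]}"
        )
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    imputed = imputer.fit_transform(values)
    if imputed.shape[1] != values.shape[1]:  # pragma: no cover - guarded above
        raise DataFormatError("imputer dropped all-missing CpG columns")
    out = values.copy()
    out[miss] = imputed[miss]
    return MethylationMatrix(out, list(matrix.sample_ids), list(matrix.cpg_ids), matrix.scale)


# -------------------------------------------------------------- age transform

def transform_age(age_years, adult_age: float = ADULT_AGE):
    """Piecewise log/linear age transform, continuous at ``adult_age``.

    ``F(a) = log(a + 1) - log(adult_age + 1)`` below the junction and
    ``(a - adult_age) / (adult_age + 1)`` above it (natural log).
    """
    a = np.asarray(age_years, dtype=float)
    if np.any(a < 0):
        raise IslandClockError("ages must be non-negative")
    out = np.where(
        a < adult_age,
        np.log(a + 1.0) - np.log(adult_age + 1.0),
        (a - adult_age) / (adult_age + 1.0),
    )
    return float(out) if np.isscalar(age_years) else out


def inverse_transform_age(f, adult_age: float = ADULT_AGE):
    """Inverse of :func:`transform_age`."""
    x = np.asarray(f, dtype=float)
    out = np.where(
        x < 0,
        np.exp(x + np.log(adult_age + 1.0)) - 1.0,
        (adult_age + 1.0) * x + adult_age,
    )
    return float(out) if np.isscalar(f) else out


# ------------------------------------------------------------------ splitting

@dataclass
class SplitAssignment:
    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    strata: pd.Series  # sample_id -> stratum label


def stratified_split(
    sheet: pd.DataFrame,
    fraction: float = 0.7,
    seed: int = 0,
    by_dataset: bool = True,
) -> SplitAssignment:
    """Random train/test partition within each tissue (x dataset) stratum.

    Within each stratum the train share is ``round(fraction * size)``.
    Singleton strata are a hard error (they cannot be split).
    """
    if not 0.0 < fraction < 1.0:
        raise IslandClockError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cols = ["tissue", "dataset"] if by_dataset else ["tissue"]
    strata = sheet[cols].astype(str).agg("/".join, axis=1)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for stratum in sorted(strata.unique()):
        ids = sheet.loc[strata == stratum, "sample_id"].astype(str).tolist()
        if len(ids) < 2:
            raise IslandClockError(f"stratum {stratum!r} has a single sample and cannot be split")
        n_train = int(np.floor(fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[i] for i in sorted(perm[:n_train]))
        test_ids.extend(ids[i] for i in sorted(perm[n_train:]))
    return SplitAssignment(
        train_ids=train_ids,
        test_ids=test_ids,
        fraction=fraction,
        strata=pd.Series(strata.to_numpy(), index=sheet["sample_id"].astype(str).to_numpy()),
    )


# ------------------------------------------------------ correlation pre-filter

def _pearson_by_tissue(values: np.ndarray, ages: np.ndarray, tissues: np.ndarray, min_n: int = 3):
    """Per-tissue Pearson r between each CpG column and age; zero-variance -> 0."""
    out = {}
    for t in np.unique(tissues):
        rows = tissues == t
        if rows.sum() < min_n:
            logger.warning("tissue %r has < %d samples; excluded from pre-filter", t, min_n)
            continue
        x = values[rows]
        a = ages[rows]
        xc = x - x.mean(axis=0)
        ac = a - a.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sa = np.sqrt((ac**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * ac[:, None]).sum(axis=0) / (sx * sa)
        r[~np.isfinite(r)] = 0.0
        out[t] = r
    return out


def correlation_prefilter(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    threshold: float = 0.3,
    rule: str = "max",
) -> tuple[list[str], pd.DataFrame]:
    """Retain CpGs correlated with age, judged per tissue on the M scale.

    ``rule`` picks how per-tissue correlations combine: ``max`` keeps a CpG
    if any tissue shows |r| >= threshold (default — the downstream selector
    adjudicates multi-tissue utility), ``mean`` uses the mean |r| over
    tissues, ``pooled`` a single correlation over all samples.

    Returns the retained CpG ids and the tissue x CpG table of r values.
    """
    if rule not in ("max", "mean", "pooled"):
        raise IslandClockError("rule must be 'max', 'mean' or 'pooled'")
    if matrix.scale != "m":
        raise DataFormatError("pre-filter operates on the M scale; convert first")
    meta = align_sheet(sheet, matrix)
    ages = meta["age"].to_numpy()
    tissues = meta["tissue"].to_numpy()
    values = matrix.values
    if np.isnan(values).any():
        raise DataFormatError("matrix contains missing values; impute before pre-filtering")
    per_tissue = _pearson_by_tissue(values, ages, tissues)
    if not per_tissue:
        raise IslandClockError("no tissue has enough samples for the pre-filter")
    r_table = pd.DataFrame(per_tissue, index=matrix.cpg_ids).T  # tissues x CpGs
    if rule == "max":
        score = r_table.abs().max(axis=0).to_numpy()
    elif rule == "mean":
        score = r_table.abs().mean(axis=0).to_numpy()
    else:
        xc = values - values.mean(axis=0)
        ac = ages - ages.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * ac[:, None]).sum(axis=0) / (
                np.sqrt((xc**2).sum(axis=0)) * np.sqrt((ac**2).sum())
            )
        r[~np.isfinite(r)] = 0.0
        score = np.abs(r)
    retained = [c for c, s in zip(matrix.cpg_ids, score) if s >= threshold]
    return retained, r_table
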