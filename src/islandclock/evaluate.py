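"""Evaluation statistics for a trained clock.

Age acceleration is defined throughout as predicted minus chronological
age (not the residual from a regression on age); every function here
consumes the same per-sample accelerations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import IslandClockError

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "DoublingFit",
    "accelerations",
    "evaluation_report",
    "replicate_concordance",
    "doubling_regression",
    "group_acceleration_test",
]


@dataclass
class EvaluationReport:
    overall_median_abs_error: float
    per_tissue_median_abs_error: dict[str, float]
    r_squared: float
    error_as_pct_of_age: np.ndarray
    n_by_tissue: dict[str, int]


@dataclass
class DoublingFit:
    slope: float  # years per population doubling
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    fdr: float | None = None


def accelerations(predictions: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Join predictions with the sheet and add ``age_acceleration``."""
    merged = predictions.merge(sheet, on="sample_id", how="left", suffixes=("", "_sheet"))
    if merged["age"].isna().any():
        bad = merged.loc[merged["age"].isna(), "sample_id"].tolist()
        raise IslandClockError(f"no chronological age for samples: {bad[:10]}")
    merged["age_acceleration"] = merged["predicted_age"] - merged["age"]
    return merged


def evaluation_report(predictions: pd.DataFrame, sheet: pd.DataFrame) -> EvaluationReport:
    """Median absolute errors (overall and per tissue), R² and % errors.

    R² is from the linear regression of predicted on chronological age;
    percentage errors are 100 |acceleration| / age, with age-0 samples
    excluded (warned).
    """
    merged = accelerations(predictions, sheet)
    abs_err = merged["age_acceleration"].abs()
    per_tissue = {}
    n_by_tissue = {}
    for t, grp in merged.groupby("tissue"):
        if len(grp) == 0:  # pragma: no cover
            logger.warning("tissue %r has no samples; omitted", t)
            continue
        per_tissue[str(t)] = float(grp["age_acceleration"].abs().median())
        n_by_tissue[str(t)] = int(len(grp))
    if merged["age"].nunique() > 1:
        fit = stats.linregress(merged["age"], merged["predicted_age"])
        r2 = float(fit.rvalue**2)
    else:
        r2 = float("nan")
    nonzero = merged["age"] > 0
    if (~nonzero).any():
        logger.warning("%d samples with age 0 excluded from percentage errors", int((~nonzero).sum()))
    pct = (100.0 * abs_err[nonzero] / merged.loc[nonzero, "age"]).to_numpy()
    return EvaluationReport(
        overall_median_abs_error=float(abs_err.median()),
        per_tissue_median_abs_error=per_tissue,
        r_squared=r2,
        error_as_pct_of_age=pct,
        n_by_tissue=n_by_tissue,
    )


def replicate_concordance(predictions: pd.DataFrame, sheet: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Signed prediction differences within technical-replicate pairs.

    Pairs are defined by ``replicate_group``; within a pair the difference
    is second minus first in sample-id order.  Returns the per-pair table
    and the median signed difference.
    """
    if "replicate_group" not in sheet.columns:
        raise IslandClockError("sheet has no replicate_group column")
    merged = predictions.merge(sheet, on="sample_id", how="left", suffixes=("", "_sheet"))
    merged = merged[merged["replicate_group"].notna()]
    rows = []
    for group, grp in merged.groupby("replicate_group"):
        if len(grp) != 2:
            raise IslandClockError(f"replicate group {group!r} has {len(grp)} members; expected 2")
        grp = grp.sort_values("sample_id")
        a, b = grp["predicted_age"].to_numpy()
        rows.append({"replicate_group": group, "difference": float(b - a)})
    if not rows:
        raise IslandClockError("no replicate pairs found")
    table = pd.DataFrame(rows)
    return table, float(table["difference"].median())


def doubling_regression(
    predictions: pd.DataFrame | dict[str, pd.DataFrame],
    sheet: pd.DataFrame,
) -> DoublingFit | dict[str, DoublingFit]:
    """OLS of predicted age on population doublings.

    The slope is the clock's tick rate in years per population doubling.
    When a dict of named prediction frames is given (several clocks on the
    same series), p-values are Benjamini-Hochberg adjusted across them.
    """
    if isinstance(predictions, dict):
        fits = {name: doubling_regression(p, sheet) for name, p in predictions.items()}
        names = list(fits)
        fdr = multipletests([fits[n].p_value for n in names], method="fdr_bh")[1]
        for n, q in zip(names, fdr):
            fits[n].fdr = float(q)
        return fits
    if "population_doublings" not in sheet.columns:
        raise IslandClockError("sheet has no population_doublings column")
    merged = predictions.merge(sheet, on="sample_id", how="left", suffixes=("", "_sheet"))
    merged = merged[merged["population_doublings"].notna()]
    if len(merged) < 3:
        raise IslandClockError("need at least 3 samples with population doublings")
    x = merged["population_doublings"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise IslandClockError("population doublings are constant; slope undefined")
    fit = stats.linregress(x, merged["predicted_age"].to_numpy(dtype=float))
    return DoublingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


def group_acceleration_test(
    predictions: pd.DataFrame,
    sheet: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    group_col: str = "condition",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise acceleration contrasts between condition groups.

    For each requested (a, b) contrast: mean acceleration difference
    (a minus b), Student's t p-value and Benjamini-Hochberg FDR across the
    requested family.  Groups with fewer than 2 samples are skipped with a
    warning.
    """
    merged = accelerations(predictions, sheet)
    if group_col not in merged.columns:
        raise IslandClockError(f"sheet has no {group_col!r} column")
    rows = []
    for a, b in contrasts:
        va = merged.loc[merged[group_col] == a, "age_acceleration"].to_numpy()
        vb = merged.loc[merged[group_col] == b, "age_acceleration"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            logger.warning("contrast %r vs %r skipped: group with < 2 samples", a, b)
            continue
        if np.array_equal(va, vb):
            p = 1.0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=equal_var).pvalue)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(va),
                "n_b": len(vb),
                "mean_diff": float(va.mean() - vb.mean()),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
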