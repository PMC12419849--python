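"""Random-CpG baseline: the error distribution of repeated elastic nets
on randomly drawn CpG subsets, and the comparison statistics against it.

The baseline answers "how well does an arbitrary handful of CpGs predict
age in this compendium?" — a clock is only interesting if it beats this
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import IslandClockError, MethylationMatrix, align_sheet
from .preprocess import SplitAssignment
from .clock import elastic_net_cv_mae

__all__ = ["BaselineDistribution", "run_random_baseline", "compare_errors"]


@dataclass
class BaselineDistribution:
    per_iteration_mae: np.ndarray  # test-set median absolute age acceleration per iteration
    per_iteration_tissue_mae: pd.DataFrame  # iterations x tissues
    n_iterations: int
    n_cpgs_per_iteration: int
    seed: int

    @property
    def median_mae(self) -> float:
        return float(np.median(self.per_iteration_mae))


def _one_iteration(values, y_train, y_test, tissues_test, universe_size, n_cpgs, train_rows, test_rows, seed, cv_folds, l1_ratio, n_alphas):
    rng = np.random.default_rng(seed)
    cols = rng.choice(universe_size, size=n_cpgs, replace=False)
    Xtr = values[np.ix_(train_rows, cols)]
    Xte = values[np.ix_(test_rows, cols)]
    model, _ = elastic_net_cv_mae(
        Xtr, y_train, l1_ratio=l1_ratio, cv_folds=cv_folds, seed=int(seed % (2**31)), n_alphas=n_alphas
    )
    abs_err = np.abs(model.predict(Xte) - y_test)
    overall = float(np.median(abs_err))
    per_tissue = {str(t): float(np.median(abs_err[tissues_test == t])) for t in np.unique(tissues_test)}
    return overall, per_tissue


def run_random_baseline(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    split: SplitAssignment,
    n_iterations: int = 2500,
    n_cpgs: int = 350,
    seed: int = 0,
    cv_folds: int = 10,
    l1_ratio: float = 0.5,
    n_alphas: int = 30,
    n_jobs: int = 1,
) -> BaselineDistribution:
    """Repeatedly fit elastic nets on random CpG subsets.

    Per iteration: draw ``n_cpgs`` CpGs without replacement, fit a
    ``cv_folds``-fold cross-validated elastic net of age on their M-values
    in the training split and record the median absolute test-set error,
    overall and per tissue.  Iteration sub-seeds are spawned from ``seed``
    by index, so the first k iterations of a long run equal a k-iteration
    run and the computation parallelises deterministically.
    """
    if n_cpgs > matrix.n_cpgs:
        raise IslandClockError(f"n_cpgs={n_cpgs} exceeds the CpG universe ({matrix.n_cpgs})")
    meta = align_sheet(sheet, matrix)
    ids = pd.Index(matrix.sample_ids)
    train_rows = ids.get_indexer(split.train_ids)
    test_rows = ids.get_indexer(split.test_ids)
    if (train_rows < 0).any() or (test_rows < 0).any():
        raise IslandClockError("split refers to samples absent from the matrix")
    y = meta["age"].to_numpy()
    tissues = meta["tissue"].to_numpy()
    child_seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n_iterations)]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_iteration)(
            matrix.values, y[train_rows], y[test_rows], tissues[test_rows],
            matrix.n_cpgs, n_cpgs, train_rows, test_rows, s, cv_folds, l1_ratio, n_alphas,
        )
        for s in child_seeds
    )
    overall = np.array([r[0] for r in results])
    tissue_frame = pd.DataFrame([r[1] for r in results])
    return BaselineDistribution(
        per_iteration_mae=overall,
        per_iteration_tissue_mae=tissue_frame,
        n_iterations=n_iterations,
        n_cpgs_per_iteration=n_cpgs,
        seed=seed,
    )


def _mean_diff_ci(a: np.ndarray, b: np.ndarray, equal_var: bool, level: float = 0.95):
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    if equal_var:
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    return diff, diff - tcrit * se, diff + tcrit * se


def compare_errors(
    clock_errors: dict[str, np.ndarray] | np.ndarray,
    reference: BaselineDistribution | np.ndarray,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-tests of error vectors against a reference distribution.

    ``clock_errors`` may be a single vector of absolute age accelerations
    or a mapping of named vectors; each is compared with the reference by a
    Student's t-test (Welch via ``equal_var=False``) with a 95% CI for the
    mean difference, and p-values are Benjamini-Hochberg adjusted across
    the family.  Zero-variance comparisons are flagged degenerate and get
    no test.
    """
    if isinstance(reference, BaselineDistribution):
        ref = np.asarray(reference.per_iteration_mae, dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
    if not isinstance(clock_errors, dict):
        clock_errors = {"clock": np.asarray(clock_errors)}
    if ref.size == 0 or any(np.asarray(v).size == 0 for v in clock_errors.values()):
        raise IslandClockError("empty error vector")
    rows = []
    for name, vec in clock_errors.items():
        vec = np.asarray(vec, dtype=float)
        degenerate = vec.var(ddof=1) == 0 and ref.var(ddof=1) == 0 if (len(vec) > 1 and len(ref) > 1) else True
        if degenerate:
            rows.append({"comparison": name, "mean_diff": float(vec.mean() - ref.mean()),
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "degenerate": True})
            continue
        t, p = stats.ttest_ind(vec, ref, equal_var=equal_var)
        diff, lo, hi = _mean_diff_ci(vec, ref, equal_var)
        rows.append({"comparison": name, "mean_diff": float(diff), "ci_low": float(lo),
                     "ci_high": float(hi), "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out
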