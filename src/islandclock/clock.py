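"""The final clock: principal components of the selected CpGs' M-values,
elastic net against transformed age, and projection-based prediction.

The selected CpG columns are centered by their training means (no variance
scaling — M-values share a scale) and decomposed by SVD; every component up
to numerical rank is retained and the elastic net is left to shrink the
unhelpful ones.  New samples are projected into the training component
space with the stored center and loadings, so batch-specific per-CpG noise
that is orthogonal to the training structure is largely discarded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .types import ClockModel, DataFormatError, IslandClockError, MethylationMatrix, align_sheet
from .preprocess import inverse_transform_age, transform_age

logger = logging.getLogger(__name__)

__all__ = ["fit_pcs", "train_clock", "predict_age", "baseline_pca_clock", "elastic_net_cv_mae"]


def fit_pcs(M_selected: MethylationMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center-only PCA by SVD.

    Returns ``(center, loadings, scores)`` with orthonormal loading columns
    (one per component up to numerical rank), signs fixed so each column's
    largest-magnitude entry is positive, and ``scores = (X - center) @ loadings``.
    """
    X = M_selected.values
    if np.isnan(X).any():
        raise DataFormatError("matrix contains missing values; run knn_impute first")
    if X.shape[0] < 2:
        raise IslandClockError("need at least 2 samples to fit principal components")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    # deterministic sign: largest |entry| of each loading column positive
    flip = np.sign(Vt[np.arange(rank), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    loadings = (Vt * flip[:, None]).T  # (p, rank)
    scores = U * s[None, :] * flip[None, :]
    return center, loadings, scores


def elastic_net_cv_mae(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    eps: float = 1e-3,
) -> tuple[ElasticNet, float]:
    """Elastic net with penalty strength chosen by K-fold CV minimising MAE.

    The alpha grid is log-spaced from the data-driven ``alpha_max`` down by
    a factor ``eps``; out-of-fold predictions come from the coordinate
    descent path fitted on centered data within each fold.  Returns the
    refitted model (on all data) and the chosen alpha.
    """
    n = len(y)
    folds = min(cv_folds, n)
    if folds < cv_folds:
        logger.warning("only %d samples; CV folds reduced to %d", n, folds)
    if folds < 2:
        raise IslandClockError("need at least 2 samples for cross-validation")
    alpha_max = np.max(np.abs((X - X.mean(axis=0)).T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    alpha_max = max(alpha_max, 1e-12)
    alphas = np.logspace(np.log10(alpha_max * eps), np.log10(alpha_max), n_alphas)[::-1]
    oof = np.empty((n, n_alphas))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        mu = X[tr].mean(axis=0)
        ybar = y[tr].mean()
        _, coefs, _ = enet_path(
            X[tr] - mu, y[tr] - ybar, l1_ratio=l1_ratio, alphas=alphas, max_iter=3000, tol=1e-3
        )
        oof[te] = (X[te] - mu) @ coefs + ybar
    mae = np.abs(oof - y[:, None]).mean(axis=0)
    k = int(np.argmin(mae))
    best = float(alphas[k])
    # refit on all data along the warm-started path down to the chosen alpha
    mu = X.mean(axis=0)
    ybar = y.mean()
    _, coefs, _ = enet_path(
        X - mu, y - ybar, l1_ratio=l1_ratio, alphas=alphas[: k + 1], max_iter=10000, tol=1e-4
    )
    model = ElasticNet(alpha=best, l1_ratio=l1_ratio)
    model.coef_ = coefs[:, -1]
    model.intercept_ = float(ybar - mu @ coefs[:, -1])
    model.n_features_in_ = X.shape[1]
    return model, best


def train_clock(
    M_train: MethylationMatrix,
    sheet_train: pd.DataFrame,
    selected_cpgs: list[str],
    en_alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    adult_age: float = 20.0,
) -> ClockModel:
    """Fit the principal-component clock on the selected CpGs.

    ``en_alpha`` is the elastic-net mixing parameter (L1 share); the
    outcome is the piecewise log/linear transform of age, so paediatric and
    adult errors are weighted comparably during fitting.
    """
    if not selected_cpgs:
        raise IslandClockError("selected CpG set is empty")
    if M_train.scale != "m":
        raise DataFormatError("the clock is trained on M-values; convert first")
    sub = M_train.subset_cpgs(selected_cpgs)
    meta = align_sheet(sheet_train, sub)
    y = transform_age(meta["age"].to_numpy(), adult_age=adult_age)
    center, loadings, scores = fit_pcs(sub)
    model, alpha = elastic_net_cv_mae(scores, y, l1_ratio=en_alpha, cv_folds=cv_folds, seed=seed)
    tissues, counts = np.unique(meta["tissue"].to_numpy(), return_counts=True)
    return ClockModel(
        cpg_ids=list(selected_cpgs),
        center=center,
        loadings=loadings,
        intercept=float(model.intercept_),
        coefficients=np.asarray(model.coef_, dtype=float),
        adult_age=adult_age,
        training_metadata={
            "n_train": int(sub.n_samples),
            "tissues": {str(t): int(c) for t, c in zip(tissues, counts)},
            "en_alpha": en_alpha,
            "en_lambda": alpha,
            "cv_folds": cv_folds,
            "seed": seed,
        },
    )


def predict_age(
    model: ClockModel,
    M_new: MethylationMatrix,
    sheet: pd.DataFrame | None = None,
    max_missing_fraction: float = 0.05,
) -> pd.DataFrame:
    """Predict ages by projection into the training component space.

    CpGs absent from ``M_new`` are filled with the training mean (zero
    contribution after centering); more than ``max_missing_fraction`` of
    the model's CpGs missing is a hard error.  Returns a frame with
    ``sample_id``, ``predicted_age`` and — when a sheet provides
    chronological ages — ``age_acceleration`` (predicted minus
    chronological).
    """
    if M_new.scale != "m":
        raise DataFormatError("predictions require M-values; convert first")
    have = pd.Index(M_new.cpg_ids)
    present = [c for c in model.cpg_ids if c in have]
    n_missing = len(model.cpg_ids) - len(present)
    if n_missing > max_missing_fraction * len(model.cpg_ids):
        raise DataFormatError(
            f"{n_missing}/{len(model.cpg_ids)} model CpGs missing from input "
            f"(ceiling {max_missing_fraction:.0%})"
        )
    if n_missing:
        logger.warning("%d model CpGs missing; filled with training means", n_missing)
    X = np.tile(model.center, (M_new.n_samples, 1))
    pos = {c: j for j, c in enumerate(model.cpg_ids)}
    cols = have.get_indexer(present)
    X[:, [pos[c] for c in present]] = M_new.values[:, cols]
    if np.isnan(X).any():
        raise DataFormatError("input contains missing values; run knn_impute first")
    scores = (X - model.center) @ model.loadings
    f = model.intercept + scores @ model.coefficients
    predicted = inverse_transform_age(f, adult_age=model.adult_age)
    out = pd.DataFrame({"sample_id": M_new.sample_ids, "predicted_age": predicted})
    if sheet is not None:
        ages = sheet.set_index("sample_id")["age"].reindex(M_new.sample_ids)
        out["age_acceleration"] = out["predicted_age"].to_numpy() - ages.to_numpy()
    return out


def baseline_pca_clock(
    M_train: MethylationMatrix,
    sheet_train: pd.DataFrame,
    all_candidate_cpgs: list[str] | None = None,
    **kwargs,
) -> ClockModel:
    """Reference clock on the full candidate matrix (no feature selection).

    Identical to :func:`train_clock` but skipping the selection step; used
    to quantify what the selection stage buys.
    """
    cpgs = list(all_candidate_cpgs) if all_candidate_cpgs is not None else list(M_train.cpg_ids)
    return train_clock(M_train, sheet_train, cpgs, **kwargs)
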