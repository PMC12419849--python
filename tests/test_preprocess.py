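"""Probe filtering, scale conversion, imputation, splits and pre-filter."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from islandclock import (
    DataFormatError,
    IslandClockError,
    MethylationMatrix,
    beta_to_m,
    correlation_prefilter,
    filter_probes,
    inverse_transform_age,
    knn_impute,
    m_to_beta,
    simulate_dataset,
    stratified_split,
    transform_age,
)
from .conftest import two_tissue_truth


# ------------------------------------------------------------------ filtering

@pytest.fixture()
def probe_fixture():
    """10 CpGs: 2 SNP-flagged, 1 on chrY, 1 failing detection in one sample."""
    rng = np.random.default_rng(0)
    cpgs = [f"cg{i}" for i in range(10)]
    matrix = MethylationMatrix(rng.standard_normal((4, 10)), [f"s{i}" for i in range(4)], cpgs, "m")
    ann = pd.DataFrame(
        {
            "cpg_id": cpgs,
            "chromosome": ["1"] * 4 + ["Y"] + ["2"] * 5,
            "snp_within_2bp": [True, True] + [False] * 8,
            "cross_hybridising": [False] * 10,
        }
    )
    detp = pd.DataFrame(np.zeros((4, 10)), index=matrix.sample_ids, columns=cpgs)
    detp.iloc[2, 7] = 0.5  # cg7 fails detection in one sample
    return matrix, ann, detp


def test_filter_probes_removes_by_each_rule(probe_fixture):
    matrix, ann, detp = probe_fixture
    filtered, report = filter_probes(matrix, ann, detp)
    assert filtered.n_cpgs == 6
    assert report == {
        "detection_p": 1,
        "snp": 2,
        "chrXY": 1,
        "cross_hybridising": 0,
        "removed_total": 4,
        "retained": 6,
    }
    assert "cg7" not in filtered.cpg_ids and "cg4" not in filtered.cpg_ids


def test_filter_probes_identity_and_idempotence(probe_fixture):
    matrix, ann, detp = probe_fixture
    clean_ann = ann.assign(snp_within_2bp=False, chromosome="1")
    clean_p = detp * 0.0
    same, report = filter_probes(matrix, clean_ann, clean_p)
    assert same.cpg_ids == matrix.cpg_ids
    assert report["removed_total"] == 0
    once, _ = filter_probes(matrix, ann, detp)
    twice, rep2 = filter_probes(once, ann, detp.loc[:, once.cpg_ids])
    assert twice.cpg_ids == once.cpg_ids
    assert rep2["removed_total"] == 0


# ----------------------------------------------------------- scale conversion

def test_beta_to_m_reference_points():
    m = MethylationMatrix(np.array([[0.5, 0.8]]), ["s"], ["c1", "c2"], "beta")
    out = beta_to_m(m)
    assert out.values[0, 0] == pytest.approx(0.0, abs=1e-12)
    assert out.values[0, 1] == pytest.approx(2.0, abs=1e-12)  # log2(0.8/0.2)
    with pytest.raises(DataFormatError):
        beta_to_m(out)


@settings(deadline=None)
@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_beta_m_roundtrip(beta):
    m = MethylationMatrix(np.array([[beta]]), ["s"], ["c"], "beta")
    back = m_to_beta(beta_to_m(m))
    assert back.values[0, 0] == pytest.approx(beta, abs=1e-12)


def test_scale_conversion_preserves_missing():
    m = MethylationMatrix(np.array([[0.5, np.nan]]), ["s"], ["c1", "c2"], "beta")
    out = beta_to_m(m)
    assert np.isnan(out.values[0, 1])


# ------------------------------------------------------------------- imputing

def test_knn_impute_recovers_duplicate_row():
    vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
    vals_masked = vals.copy()
    vals_masked[0, 1] = np.nan
    m = MethylationMatrix(vals_masked, ["s1", "s2", "s3"], ["c1", "c2", "c3"], "m")
    out = knn_impute(m, k=1)
    assert out.values[0, 1] == pytest.approx(2.0)
    # observed values untouched
    mask = ~np.isnan(vals_masked)
    np.testing.assert_array_equal(out.values[mask], vals_masked[mask])


def test_knn_impute_identity_on_complete_matrix(small_dataset):
    matrix, _, _ = small_dataset
    out = knn_impute(matrix)
    np.testing.assert_array_equal(out.values, matrix.values)


def test_knn_impute_mask_and_recover_rmse():
    """Imputation RMSE on 5% masked cells stays below 2x the noise SD."""
    truth = two_tissue_truth(seed=5, noise_sd=0.1)
    matrix, _, _ = simulate_dataset(truth)
    rng = np.random.default_rng(1)
    mask = rng.random(matrix.values.shape) < 0.05
    masked = matrix.values.copy()
    masked[mask] = np.nan
    m = MethylationMatrix(masked, matrix.sample_ids, matrix.cpg_ids, "m")
    out = knn_impute(m, k=10)
    rmse = np.sqrt(np.mean((out.values[mask] - matrix.values[mask]) ** 2))
    assert rmse < 2 * truth.noise_sd


def test_knn_impute_rejects_hopeless_input():
    all_missing_row = np.array([[np.nan, np.nan], [1.0, 2.0]])
    with pytest.raises(DataFormatError, match="all values missing"):
        knn_impute(MethylationMatrix(all_missing_row, ["s1", "s2"], ["c1", "c2"], "m"))
    heavy_col = np.array([[np.nan, 1.0], [np.nan, 2.0], [0.5, 3.0]])
    with pytest.raises(DataFormatError, match="ceiling"):
        knn_impute(MethylationMatrix(heavy_col, ["s1", "s2", "s3"], ["c1", "c2"], "m"))


# --------------------------------------------------------------- age transform

def test_age_transform_reference_points():
    assert transform_age(20.0) == 0.0
    assert transform_age(41.0) == pytest.approx(1.0, abs=1e-12)  # (41-20)/21
    assert transform_age(0.0) == pytest.approx(np.log(1) - np.log(21), abs=1e-12)
    with pytest.raises(IslandClockError):
        transform_age(-1.0)


@settings(deadline=None)
@given(st.floats(min_value=0.0, max_value=120.0))
def test_age_transform_roundtrip(age):
    assert inverse_transform_age(transform_age(age)) == pytest.approx(age, abs=1e-12)


def test_age_transform_monotone_and_continuous():
    ages = np.linspace(0, 120, 4001)  # includes the junction at 20
    f = transform_age(ages)
    assert np.all(np.diff(f) > 0)
    eps = 1e-9
    assert transform_age(20.0 + eps) - transform_age(20.0 - eps) < 1e-6


# ------------------------------------------------------------------ splitting

def test_stratified_split_counts_and_determinism():
    sheet = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(16)],
            "age": 30.0,
            "tissue": ["a"] * 10 + ["b"] * 6,
            "dataset": "d",
        }
    )
    split = stratified_split(sheet, fraction=0.7, seed=0)
    in_a = [s for s in split.train_ids if split.strata[s] == "a/d"]
    in_b = [s for s in split.train_ids if split.strata[s] == "b/d"]
    assert len(in_a) == 7 and len(in_b) == 4  # round(0.7 * 10), round(0.7 * 6)
    assert set(split.train_ids) | set(split.test_ids) == set(sheet["sample_id"])
    assert not set(split.train_ids) & set(split.test_ids)
    again = stratified_split(sheet, fraction=0.7, seed=0)
    assert again.train_ids == split.train_ids
    assert stratified_split(sheet, fraction=0.7, seed=1).train_ids != split.train_ids


def test_stratified_split_training_frequency_unbiased():
    """Over 200 seeds, every sample of a 10-strong stratum trains 60-80%
    of the time (resampling check of per-stratum uniformity)."""
    sheet = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(10)], "age": 30.0, "tissue": "a", "dataset": "d"}
    )
    counts = {s: 0 for s in sheet["sample_id"]}
    n_seeds = 200
    for seed in range(n_seeds):
        for s in stratified_split(sheet, fraction=0.7, seed=seed).train_ids:
            counts[s] += 1
    freqs = np.array(list(counts.values())) / n_seeds
    assert freqs.min() >= 0.6 and freqs.max() <= 0.8


def test_stratified_split_rejects_singleton_stratum():
    sheet = pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3"], "age": 30.0, "tissue": ["a", "a", "b"], "dataset": "d"}
    )
    with pytest.raises(IslandClockError, match="b/d"):
        stratified_split(sheet)


# ------------------------------------------------------ correlation pre-filter

def test_prefilter_recovers_planted_set_exactly(noiseless_dataset):
    """Without noise the retained set equals the planted age-CpGs: in-scope
    CpGs correlate perfectly, all others have zero variance or no trend."""
    matrix, sheet, truth = noiseless_dataset
    retained, r_table = correlation_prefilter(matrix, sheet, threshold=0.3)
    assert set(retained) == set(truth.planted_age_cpgs)
    shared = next(c for c, s in truth.age_cpg_scope.items() if s == "shared")
    assert abs(r_table.loc["a", shared]) == pytest.approx(1.0, abs=1e-9)


def test_prefilter_zero_variance_and_threshold_monotonicity(small_dataset):
    matrix, sheet, _ = small_dataset
    vals = matrix.values.copy()
    vals[:, 0] = 5.0  # constant CpG -> r = 0 -> removed
    m = MethylationMatrix(vals, matrix.sample_ids, matrix.cpg_ids, "m")
    kept_03, _ = correlation_prefilter(m, sheet, threshold=0.3)
    assert matrix.cpg_ids[0] not in kept_03
    kept_05, _ = correlation_prefilter(m, sheet, threshold=0.5)
    kept_08, _ = correlation_prefilter(m, sheet, threshold=0.8)
    assert set(kept_08) <= set(kept_05) <= set(kept_03)


def test_prefilter_rules_nest(small_dataset):
    """A CpG passing the mean-|r| rule necessarily passes the max rule."""
    matrix, sheet, _ = small_dataset
    by_max, _ = correlation_prefilter(matrix, sheet, rule="max")
    by_mean, _ = correlation_prefilter(matrix, sheet, rule="mean")
    assert set(by_mean) <= set(by_max)
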