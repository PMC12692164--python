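"""normalization module: Eq. (1), median scaling, rollup, CV diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polarsurf import IntensityMatrix
from polarsurf.normalize import (
    cv_summary,
    normalize_median,
    normalize_replicate_average,
    rollup_protein,
)
from tests.conftest import make_design, make_matrix


# ----------------------------------------------------- Eq. (1) worked examples
def test_eq1_hand_example(design4=None):
    design = make_design(2)
    mat = make_matrix([[200.0, 100.0, 60.0, 40.0]], n_pairs=2)
    res = normalize_replicate_average(mat, design)
    got = res.normalized.data.iloc[0].to_numpy()
    np.testing.assert_allclose(got, [400 / 3, 200 / 3, 120.0, 80.0], rtol=1e-12)
    assert abs(got.mean() - 100.0) < 1e-9


def test_eq1_identity_case():
    design = make_design(2)
    mat = make_matrix([[100.0, 100.0, 100.0, 100.0]], n_pairs=2)
    res = normalize_replicate_average(mat, design)
    np.testing.assert_allclose(res.normalized.data.to_numpy(), 100.0, rtol=1e-12)


def test_eq1_half_missing_pair_dropped():
    design = make_design(2)
    mat = make_matrix([[200.0, np.nan, 60.0, 40.0]], n_pairs=2)
    res = normalize_replicate_average(mat, design)
    row = res.normalized.data.iloc[0]
    assert np.isnan(row["A1"]) and np.isnan(row["B1"])
    np.testing.assert_allclose(row[["A2", "B2"]].to_numpy(), [60.0, 40.0], rtol=1e-12)
    assert res.dropped_pairs == [("P1", "R1", "missing basolateral")]


def _random_matrix(rng, n_feat, n_pairs, missing=0.2):
    vals = np.power(2.0, rng.normal(20, 2, size=(n_feat, 2 * n_pairs)))
    mask = rng.random(vals.shape) < missing
    vals[mask] = np.nan
    return make_matrix(vals, n_pairs)


def test_eq1_conservation_ratio_idempotence_random():
    rng = np.random.default_rng(42)
    design = make_design(5)
    for _ in range(50):
        mat = _random_matrix(rng, 30, 5)
        res = normalize_replicate_average(mat, design)
        norm = res.normalized.data.to_numpy()
        raw = mat.data.to_numpy()
        complete = ~np.isnan(norm)
        # per-feature overall mean preserved to 1e-9 relative (over kept pairs)
        kept_raw = np.where(complete, raw, np.nan)
        rows = complete.any(axis=1)
        np.testing.assert_allclose(
            np.nanmean(norm[rows], axis=1), np.nanmean(kept_raw[rows], axis=1), rtol=1e-9
        )
        # within-replicate side ratio preserved
        for j in range(5):
            a, b = 2 * j, 2 * j + 1
            ok = complete[:, a] & complete[:, b]
            np.testing.assert_allclose(
                norm[ok, a] / norm[ok, b], raw[ok, a] / raw[ok, b], rtol=1e-12
            )
        # idempotence
        again = normalize_replicate_average(res.normalized, design).normalized.data
        np.testing.assert_allclose(
            again.to_numpy(), norm, rtol=1e-9, equal_nan=True
        )


def test_eq1_factors_immune_to_contaminant_spike():
    rng = np.random.default_rng(3)
    design = make_design(4)
    base = _random_matrix(rng, 20, 4, missing=0.0)
    res_before = normalize_replicate_average(base, design)
    spiked = pd.concat(
        [base.data, pd.DataFrame([np.full(8, 1e12)], index=["CONT1"], columns=base.data.columns)]
    )
    res_after = normalize_replicate_average(IntensityMatrix(spiked, "protein"), design)
    # bit-identical on the original features
    assert (
        res_after.normalized.data.loc[base.feature_ids].to_numpy().tobytes()
        == res_before.normalized.data.to_numpy().tobytes()
    )


# --------------------------------------------------------- median normalization
def test_median_scale_factors():
    mat = make_matrix(
        [[5.0, 10.0], [10.0, 20.0], [15.0, 30.0]], n_pairs=1
    )  # medians 10 and 20, target 15
    res = normalize_median(mat)
    np.testing.assert_allclose(res.scale_factors.to_numpy().ravel(), [1.5, 0.75])
    assert (res.normalized.data.median(axis=0) == 15.0).all()


def test_median_already_equal_and_single_sample():
    mat = make_matrix([[10.0, 10.0], [20.0, 20.0]], n_pairs=1)
    res = normalize_median(mat)
    pd.testing.assert_frame_equal(res.normalized.data, mat.data)
    single = IntensityMatrix(pd.DataFrame({"s1": [1.0, 2.0, 3.0]}), "protein")
    res = normalize_median(single)
    pd.testing.assert_frame_equal(res.normalized.data, single.data)


def test_median_all_missing_sample_errors():
    mat = make_matrix([[np.nan, 2.0]], n_pairs=1)
    with pytest.raises(ValueError, match="no present values"):
        normalize_median(mat)


# ------------------------------------------------------------------- rollup
def test_rollup_top3_and_sum():
    data = pd.DataFrame(
        {"s1": [10.0, 20.0, 30.0, 40.0], "s2": [10.0, np.nan, np.nan, np.nan],
         "s3": [np.nan] * 4},
        index=["q1", "q2", "q3", "q4"],
    )
    pep = IntensityMatrix(data, "peptide")
    mapping = {q: "P1" for q in data.index}
    top3 = rollup_protein(pep, mapping, method="top3_mean")
    assert top3.data.loc["P1", "s1"] == 30.0  # mean of 20, 30, 40
    assert top3.data.loc["P1", "s2"] == 10.0  # single present peptide
    assert np.isnan(top3.data.loc["P1", "s3"])  # all missing
    total = rollup_protein(pep, mapping, method="sum")
    assert total.data.loc["P1", "s1"] == 100.0
    assert np.isnan(total.data.loc["P1", "s3"])


def test_rollup_errors():
    data = pd.DataFrame({"s1": [1.0]}, index=["q1"])
    pep = IntensityMatrix(data, "peptide")
    with pytest.raises(ValueError, match="unknown rollup method"):
        rollup_protein(pep, {"q1": "P1"}, method="median")
    with pytest.raises(ValueError, match="without protein mapping"):
        rollup_protein(pep, {}, method="sum")
    with pytest.raises(ValueError, match="peptide-level matrix"):
        rollup_protein(IntensityMatrix(data, "protein"), {"q1": "P1"})
    from polarsurf import PeptideRecord

    recs = [
        PeptideRecord("q1", "AAAAK", "P1", 1),
        PeptideRecord("q1", "AAAAK", "P2", 1),
    ]
    with pytest.raises(ValueError, match="multiple proteins"):
        rollup_protein(pep, recs)


# ----------------------------------------------------------------------- CV
def test_cv_hand_example():
    design = make_design(2)
    mat = make_matrix([[90.0, 50.0, 110.0, 50.0]], n_pairs=2)  # apical 90/110
    cv = cv_summary(mat, design)
    apical = cv.per_feature_side[cv.per_feature_side["side"] == "apical"]
    np.testing.assert_allclose(apical["cv_pct"].iloc[0], 14.142, atol=1e-3)
    baso = cv.per_feature_side[cv.per_feature_side["side"] == "basolateral"]
    assert baso["cv_pct"].iloc[0] == 0.0  # constant values


def test_cv_scale_invariance_and_exclusion():
    design = make_design(3)
    rng = np.random.default_rng(0)
    vals = rng.uniform(50, 150, size=(10, 6))
    vals[0, [0, 2, 4]] = np.nan
    vals[0, 0] = 100.0  # apical side of feature 0 has a single present value
    vals[0, 2] = np.nan
    vals[0, 4] = np.nan
    m1 = make_matrix(vals, 3)
    m7 = make_matrix(vals * 7.0, 3)
    c1, c7 = cv_summary(m1, design), cv_summary(m7, design)
    np.testing.assert_allclose(
        c1.per_feature_side["cv_pct"].to_numpy(),
        c7.per_feature_side["cv_pct"].to_numpy(),
        rtol=1e-9,
    )
    assert c1.n_excluded == 1  # the single-value (feature, side) pair


def test_replicate_average_cv_not_worse_than_median():
    # batch sd > 0: the pair-anchored normalization removes per-pair handling
    # variation that median scaling cannot
    from polarsurf.simulate import SimulationParams, simulate_dataset

    ds = simulate_dataset(SimulationParams(
        n_proteins=300, n_contaminants=0, cluster_spec=(), log2_batch_sd=0.6,
        missing_rate_at_low_intensity=0.0, with_peptides=False, seed=4,
    ))
    ra = normalize_replicate_average(ds.protein_matrix, ds.design)
    med = normalize_median(ds.protein_matrix)
    cv_ra = cv_summary(ra.normalized, ds.design).median_cv_pct
    cv_med = cv_summary(med.normalized, ds.design).median_cv_pct
    assert cv_ra <= cv_med
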