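"""covariance_clusters module: correlation, clustering, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from polarsurf.clusters import (
    Candidate,
    ClusterRecord,
    ClusterSet,
    CorrelationMatrix,
    CovarianceClusterModel,
    correlation_matrix,
    crosstab,
    enrich_and_label,
    find_clusters,
    fisher_exact,
    strong_filter,
)
from polarsurf.io import IntensityMatrix


def _mat(rows: dict, columns=None) -> IntensityMatrix:
    df = pd.DataFrame(rows).T.astype(float)
    if columns is not None:
        df.columns = columns
    return IntensityMatrix(df, "protein")


def _corr_from_r(r: np.ndarray, ids=None) -> CorrelationMatrix:
    ids = ids or [f"P{i}" for i in range(r.shape[0])]
    frame = pd.DataFrame(r, index=ids, columns=ids)
    n = pd.DataFrame(10, index=ids, columns=ids)
    return CorrelationMatrix(r=frame, n_shared=n, min_shared=3)


# ------------------------------------------------------------------ correlation
def test_correlation_examples():
    mat = _mat({"P1": [1, 2, 3, 4], "P2": [2, 4, 6, 8], "P3": [1, 2, 3, 5]})
    corr = correlation_matrix(mat, min_shared=3, log2=False)
    assert corr.r.loc["P1", "P2"] == pytest.approx(1.0)
    assert corr.r.loc["P1", "P3"] == pytest.approx(0.9827, abs=1e-4)
    assert (np.diag(corr.r.to_numpy()) == 1.0).all()


def test_correlation_min_shared():
    mat = _mat({
        "P1": [1, 2, 3, 4],
        "P2": [2, 4, np.nan, np.nan],  # only 2 shared samples with P1
    })
    corr = correlation_matrix(mat, min_shared=3, log2=False)
    assert np.isnan(corr.r.loc["P1", "P2"])
    assert corr.n_shared.loc["P1", "P2"] == 2
    with pytest.raises(ValueError, match="min_shared must be >= 3"):
        correlation_matrix(mat, min_shared=2)


# ---------------------------------------------------------------- strong filter
def test_strong_filter_boundary():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.95  # exactly at the threshold: excluded (strict >)
    assert strong_filter(_corr_from_r(r), 0.95) == []
    r[0, 1] = r[1, 0] = 0.96
    assert strong_filter(_corr_from_r(r), 0.95) == ["P0", "P1"]
    assert strong_filter(_corr_from_r(np.eye(3)), 0.95) == []


# ---------------------------------------------------------------- find_clusters
def _block_r(sizes, intra, inter):
    n = sum(sizes)
    r = np.full((n, n), inter)
    start = 0
    for s in sizes:
        r[start : start + s, start : start + s] = intra
        start += s
    np.fill_diagonal(r, 1.0)
    return r


def test_two_block_design():
    corr = _corr_from_r(_block_r([5, 5], 0.99, 0.0))
    cands = find_clusters(corr, corr.protein_ids, r_intra_min=0.9, min_size=5)
    assert sorted(c.members for c in cands) == [
        ("P0", "P1", "P2", "P3", "P4"),
        ("P5", "P6", "P7", "P8", "P9"),
    ]
    for c in cands:
        assert c.mean_intracluster_r == pytest.approx(0.99)


def test_single_block_everything():
    corr = _corr_from_r(_block_r([8], 0.99, 0.0))
    cands = find_clusters(corr, corr.protein_ids, r_intra_min=0.9, min_size=5)
    assert len(cands) == 1 and len(cands[0].members) == 8


def test_find_clusters_order_invariance():
    corr = _corr_from_r(_block_r([5, 5], 0.99, 0.1))
    forward = find_clusters(corr, corr.protein_ids, min_size=5)
    backward = find_clusters(corr, list(reversed(corr.protein_ids)), min_size=5)
    assert forward == backward


def test_find_clusters_empty_and_small():
    corr = _corr_from_r(_block_r([4], 0.99, 0.0))
    assert find_clusters(corr, [], min_size=2) == []
    assert find_clusters(corr, ["P0"], min_size=2) == []
    assert find_clusters(corr, corr.protein_ids, min_size=5) == []


# --------------------------------------------------------------------- fisher
def test_fisher_worked_values():
    two, _ = fisher_exact([[3, 1], [1, 3]])
    assert two == pytest.approx(34 / 70, abs=1e-12)
    two, _ = fisher_exact([[5, 0], [0, 5]])
    assert two == pytest.approx(2 / 252, abs=1e-12)
    two, greater = fisher_exact([[1, 1], [1, 1]])
    assert two == 1.0 and greater == pytest.approx(5 / 6, abs=1e-12)


def test_fisher_validation():
    with pytest.raises(ValueError, match="2x2"):
        fisher_exact([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError, match="negative"):
        fisher_exact([[1, -2], [3, 4]])


# ------------------------------------------------------------------ enrichment
def test_enrichment_toy_hypergeometric_oracle():
    background = {f"P{i}" for i in range(100)}
    core = {f"P{i}" for i in range(20)}
    members = tuple(sorted({f"P{i}" for i in range(6)} | {f"P{i}" for i in range(90, 94)}))
    cand = Candidate(members=members, mean_intracluster_r=0.95)
    cs = enrich_and_label([cand], core, set(), background, alpha=0.05)
    rec = cs.clusters[0]
    # one-sided greater p = P(X >= 6), X ~ Hypergeom(N=100, K=20, n=10)
    assert rec.fisher_p == pytest.approx(hypergeom.sf(5, 100, 20, 10), rel=1e-9)
    assert rec.n_core_members == 6
    assert rec.accepted == (rec.fisher_q < 0.05)


def test_enrichment_zero_core_members_never_enriched():
    background = {f"P{i}" for i in range(50)}
    core = {f"P{i}" for i in range(10)}
    cand = Candidate(members=tuple(f"P{i}" for i in range(40, 45)), mean_intracluster_r=0.99)
    cs = enrich_and_label([cand], core, set(), background)
    rec = cs.clusters[0]
    assert rec.polarity == "none" and not rec.accepted
    assert rec.fisher_p == pytest.approx(1.0)


def test_enrichment_validation():
    with pytest.raises(ValueError, match="empty background"):
        enrich_and_label([], set(), set(), set())
    with pytest.raises(ValueError, match="core not contained"):
        enrich_and_label([], {"X"}, set(), {"P1"})
    cand = Candidate(members=("Z",), mean_intracluster_r=0.99)
    with pytest.raises(ValueError, match="candidate not contained"):
        enrich_and_label([cand], set(), set(), {"P1"})


def test_cluster_set_invariants():
    rec = ClusterRecord(("P1", "P2"), 0.95, "apical", 0.001, 0.01, 2, accepted=True)
    overlap = ClusterRecord(("P2", "P3"), 0.95, "apical", 0.001, 0.01, 2, accepted=True)
    with pytest.raises(ValueError, match="not disjoint"):
        ClusterSet([rec, overlap], alpha=0.05, r_intra_min=0.9)
    bad = ClusterRecord(("P3", "P4"), 0.5, "apical", 0.001, 0.01, 2, accepted=True)
    with pytest.raises(ValueError, match="acceptance invariants"):
        ClusterSet([bad], alpha=0.05, r_intra_min=0.9)


def test_crosstab_toy():
    c1 = ClusterRecord(("P1", "P2", "P3"), 0.95, "apical", 0.001, 0.01, 2, accepted=True)
    c2 = ClusterRecord(("P4", "P5"), 0.95, "basolateral", 0.001, 0.01, 2, accepted=True)
    table = crosstab([c1, c2], {"P1": "junction", "P2": "junction", "P4": "transporter"})
    row1 = table[table["cluster"] == "C1"].iloc[0]
    assert row1["junction"] == 2 and row1["unannotated"] == 1 and row1["size"] == 3
    row2 = table[table["cluster"] == "C2"].iloc[0]
    assert row2["transporter"] == 1 and row2["unannotated"] == 1


# --------------------------------------------------------------------- model
def test_model_excludes_contaminants_before_normalization():
    rng = np.random.default_rng(0)
    vals = np.power(2.0, rng.normal(20, 1, size=(30, 8)))
    ids = [f"P{i}" for i in range(25)] + [f"CONT{i}" for i in range(5)]
    mat = IntensityMatrix(
        pd.DataFrame(vals, index=ids, columns=[f"s{j}" for j in range(8)]), "protein"
    )
    model = CovarianceClusterModel(
        mat, core_apical=set(), core_basolateral=set(),
        exclude={f"CONT{i}" for i in range(5)},
    )
    assert model.n_excluded == 5
    res = model.fit()
    assert len(res.correlation.protein_ids) == 25
    assert not any(p.startswith("CONT") for p in res.correlation.protein_ids)
    assert "proteins in background: 25" in res.summary()
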