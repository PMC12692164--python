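"""Intensity normalization, peptide-to-protein rollup and CV diagnostics.

The central operation is the replicate average-based normalization: for a
feature observed on both sides of bioreplicate *r*,

    I_norm(r, side) = I(r, side) / I(r, average) * I(total, average)

where ``I(r, average)`` is the mean of the feature's apical and basolateral
intensities in that replicate and ``I(total, average)`` the mean of the
feature's present values over all samples (restricted to complete pairs).
Each feature is normalized on its own scale, so the factors are unaffected
by any other feature — in particular by highly abundant medium contaminants
that bias total- or median-intensity normalization.  Within a replicate the
apical/basolateral ratio is preserved exactly, which is what carries the
polarization signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntensityMatrix, SampleDesign, Side

__all__ = [
    "NormalizationResult",
    "normalize_replicate_average",
    "normalize_median",
    "rollup_protein",
    "cv_summary",
    "CVSummary",
]


@dataclass
class NormalizationResult:
    normalized: IntensityMatrix
    #: replicate_average: feature x bioreplicate factors (total_avg / rep_avg);
    #: median: single-row sample factors.
    scale_factors: pd.DataFrame
    method: str
    dropped_pairs: list[tuple[str, str, str]] = field(default_factory=list)


def _paired_arrays(
    matrix: IntensityMatrix, design: SampleDesign
) -> tuple[np.ndarray, np.ndarray, list[str], list[tuple[str, str]]]:
    """Feature x replicate apical and basolateral value arrays (NaN = missing)."""
    pairs = design.pairs()
    missing_cols = [s for ab in pairs.values() for s in ab if s not in matrix.data.columns]
    if missing_cols:
        raise ValueError(f"design samples absent from matrix: {missing_cols}")
    rep_ids = list(pairs)
    ap = matrix.data[[pairs[r][0] for r in rep_ids]].to_numpy(dtype=float)
    baso = matrix.data[[pairs[r][1] for r in rep_ids]].to_numpy(dtype=float)
    return ap, baso, rep_ids, [pairs[r] for r in rep_ids]


def normalize_replicate_average(
    matrix: IntensityMatrix, design: SampleDesign
) -> NormalizationResult:
    """Replicate average-based normalization (per feature, per pair).

    Pairs where either side is missing are dropped for that feature (both
    cells set missing, recorded in ``dropped_pairs``) and excluded from the
    feature's overall average, which keeps the mean-conservation property
    exact.
    """
    ap, baso, rep_ids, pair_samples = _paired_arrays(matrix, design)
    ok = ~np.isnan(ap) & ~np.isnan(baso)
    dropped: list[tuple[str, str, str]] = []
    feats = matrix.feature_ids
    half = ~ok & (~np.isnan(ap) | ~np.isnan(baso))
    for i, j in np.argwhere(half):
        reason = "missing basolateral" if not np.isnan(ap[i, j]) else "missing apical"
        dropped.append((feats[i], rep_ids[j], reason))

    ap_ok = np.where(ok, ap, np.nan)
    baso_ok = np.where(ok, baso, np.nan)
    n_ok = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        total_avg = (np.nansum(ap_ok, axis=1) + np.nansum(baso_ok, axis=1)) / np.maximum(
            2 * n_ok, 1
        )
        total_avg[n_ok == 0] = np.nan
        rep_avg = (ap_ok + baso_ok) / 2.0
        factors = total_avg[:, None] / rep_avg

    norm = matrix.data.copy()
    for j, (a_col, b_col) in enumerate(pair_samples):
        norm[a_col] = ap_ok[:, j] * factors[:, j]
        norm[b_col] = baso_ok[:, j] * factors[:, j]
    extra = [c for c in matrix.data.columns if c not in {s for p in pair_samples for s in p}]
    for c in extra:  # samples outside the design pass through untouched
        norm[c] = matrix.data[c]

    return NormalizationResult(
        normalized=IntensityMatrix(norm, matrix.level),
        scale_factors=pd.DataFrame(factors, index=feats, columns=rep_ids),
        method="replicate_average",
        dropped_pairs=dropped,
    )


def normalize_median(matrix: IntensityMatrix) -> NormalizationResult:
    """Scale each sample so all sample medians equal the median of sample medians."""
    medians = matrix.data.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = medians.index[medians.isna()].tolist()
        raise ValueError(f"sample(s) with no present values: {empty}")
    target = float(medians.median())
    factors = target / medians
    norm = matrix.data * factors
    return NormalizationResult(
        normalized=IntensityMatrix(norm, matrix.level),
        scale_factors=factors.to_frame().T,
        method="median",
    )


def rollup_protein(
    peptide_matrix: IntensityMatrix,
    records,
    method: str = "top3_mean",
) -> IntensityMatrix:
    """Aggregate peptide intensities to protein level.

    ``records`` is either a sequence of :class:`~polarsurf.io.PeptideRecord`
    or a plain ``{peptide_id: protein_id}`` mapping; every peptide must map
    to exactly one protein (shared peptides are excluded upstream).

    ``top3_mean``: per (protein, sample), the mean of the 3 largest present
    peptide intensities (fewer when fewer are present); missing when no
    peptide is present.  ``sum``: sum of present peptide intensities.
    """
    if peptide_matrix.level != "peptide":
        raise ValueError("rollup requires a peptide-level matrix")
    if isinstance(records, dict):
        peptide_to_protein = records
    else:
        peptide_to_protein = {}
        for r in records:
            if peptide_to_protein.get(r.peptide_id, r.protein_id) != r.protein_id:
                raise ValueError(f"peptide {r.peptide_id} maps to multiple proteins")
            peptide_to_protein[r.peptide_id] = r.protein_id
    unmapped = [p for p in peptide_matrix.feature_ids if p not in peptide_to_protein]
    if unmapped:
        raise ValueError(f"peptides without protein mapping: {unmapped[:5]}")
    groups = peptide_matrix.data.groupby(
        [peptide_to_protein[p] for p in peptide_matrix.feature_ids]
    )
    if method == "top3_mean":
        def agg(block: pd.DataFrame) -> pd.Series:
            arr = -np.sort(-block.to_numpy(dtype=float), axis=0)  # descending, NaN last
            top3 = arr[:3]
            n = (~np.isnan(top3)).sum(axis=0)
            out = np.full(top3.shape[1], np.nan)
            if (n > 0).any():  # all-missing sample stays missing, no warning
                out[n > 0] = np.nanmean(top3[:, n > 0], axis=0)
            return pd.Series(out, index=block.columns)
        out = groups.apply(agg)
    elif method == "sum":
        out = groups.sum(min_count=1)
    else:
        raise ValueError(f"unknown rollup method {method!r}")
    out.index.name = "protein_id"
    return IntensityMatrix(out, "protein")


@dataclass
class CVSummary:
    per_feature_side: pd.DataFrame  # columns: feature_id, side, cv_pct, n
    median_cv_pct: float
    n_excluded: int


def cv_summary(matrix: IntensityMatrix, design: SampleDesign) -> CVSummary:
    """Per-(feature, side) coefficient of variation across bioreplicates.

    CV% = sample sd / mean * 100, requiring at least two present values;
    sides are summarized separately since they differ biologically.
    """
    rows = []
    n_excluded = 0
    for side in Side:
        cols = [s for s, sd in zip(design.sample_ids, design.sides) if sd is side]
        block = matrix.data[cols]
        n = block.notna().sum(axis=1)
        mean = block.mean(axis=1, skipna=True)
        sd = block.std(axis=1, ddof=1, skipna=True)
        cv = sd / mean * 100.0
        included = n >= 2
        n_excluded += int((~included).sum())
        sub = pd.DataFrame(
            {
                "feature_id": matrix.data.index[included],
                "side": side.value,
                "cv_pct": cv[included].to_numpy(),
                "n": n[included].to_numpy(),
            }
        )
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    median_cv = float(table["cv_pct"].median()) if len(table) else float("nan")
    return CVSummary(per_feature_side=table, median_cv_pct=median_cv, n_excluded=n_excluded)
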