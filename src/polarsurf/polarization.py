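"""Paired apical-versus-basolateral differential analysis.

Each bioreplicate contributes one apical and one basolateral sample grown
and labeled in parallel, so the natural statistic per feature is the
per-replicate log2 ratio d_r = log2(apical_r) - log2(basolateral_r), tested
against zero with a two-sided one-sample t test.  The per-feature effect
size is reported as the *apical fraction*: the mean over complete pairs of
apical / (apical + basolateral), in percent — 50% means unpolarized.

Features are classed as part of the core polarized proteome when both the
statistical threshold (Benjamini–Hochberg q < alpha) and the biological
threshold (apical fraction >= 60% or <= 40% by default) are met; features
passing only the statistical one are "stat_only".

A permutation procedure (per-replicate side-label swaps, i.e. sign flips of
d_r) estimates the smallest polarization the design can distinguish from
noise at the chosen FDR — the sensitivity floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix, SampleDesign
from .normalize import NormalizationResult, normalize_median, normalize_replicate_average

__all__ = [
    "apical_fraction",
    "paired_test",
    "bh_fdr",
    "classify",
    "randomization_floor",
    "PolarizationModel",
    "PolarizationResults",
    "CLASS_APICAL",
    "CLASS_BASOLATERAL",
    "CLASS_STAT_ONLY",
    "CLASS_UNPOLARIZED",
]

CLASS_APICAL = "apical_core"
CLASS_BASOLATERAL = "basolateral_core"
CLASS_STAT_ONLY = "stat_only"
CLASS_UNPOLARIZED = "unpolarized"

#: p-value reported when all pair log-ratios are identical and non-zero
#: (zero sample variance: the t statistic diverges)
P_UNDERFLOW = 1e-300


def _pair_arrays(matrix: IntensityMatrix, design: SampleDesign):
    pairs = design.pairs()
    rep_ids = list(pairs)
    ap = matrix.data[[pairs[r][0] for r in rep_ids]].to_numpy(dtype=float)
    baso = matrix.data[[pairs[r][1] for r in rep_ids]].to_numpy(dtype=float)
    return ap, baso, rep_ids


def apical_fraction(matrix: IntensityMatrix, design: SampleDesign) -> pd.Series:
    """Mean per-pair apical/(apical+basolateral), in percent.

    Pairs with either side missing are skipped; a feature with no complete
    pair gets NaN (never 100% or 0% by default of a one-sided observation).
    """
    ap, baso, _ = _pair_arrays(matrix, design)
    ok = ~np.isnan(ap) & ~np.isnan(baso)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ok, ap / (ap + baso), np.nan)
    n_ok = ok.sum(axis=1)
    mean_frac = np.full(ap.shape[0], np.nan)
    rows = n_ok > 0
    mean_frac[rows] = np.nanmean(frac[rows], axis=1)
    return pd.Series(mean_frac * 100.0, index=matrix.data.index, name="apical_fraction_pct")


def _d_matrix(matrix: IntensityMatrix, design: SampleDesign) -> np.ndarray:
    """Per-(feature, replicate) log2 apical/basolateral ratios (NaN for incomplete pairs)."""
    ap, baso, _ = _pair_arrays(matrix, design)
    ok = ~np.isnan(ap) & ~np.isnan(baso)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, np.log2(ap) - np.log2(baso), np.nan)


def _t_from_d(d: np.ndarray, min_pairs: int) -> pd.DataFrame:
    """Vectorized one-sample t test of mean(d) = 0 per row."""
    n = (~np.isnan(d)).sum(axis=1)
    mean = np.full(d.shape[0], np.nan)
    sd = np.full(d.shape[0], np.nan)
    if (n >= 1).any():
        mean[n >= 1] = np.nanmean(d[n >= 1], axis=1)
    if (n >= 2).any():
        sd[n >= 2] = np.nanstd(d[n >= 2], axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = np.full(d.shape[0], np.nan)
    valid = n >= min_pairs
    zero_var = valid & (sd == 0)
    reg = valid & (sd > 0)
    p[reg] = 2.0 * stats.t.sf(np.abs(t[reg]), df=n[reg] - 1)
    # all d identical: exact null if d == 0, else underflow floor
    p[zero_var & (mean == 0)] = 1.0
    p[zero_var & (mean != 0)] = P_UNDERFLOW
    t[zero_var & (mean != 0)] = np.sign(mean[zero_var & (mean != 0)]) * np.inf
    t[zero_var & (mean == 0)] = 0.0
    t[~valid] = np.nan
    return pd.DataFrame({"t_stat": t, "p_value": p, "n_pairs": n, "log2_fc": mean})


def paired_test(
    matrix: IntensityMatrix, design: SampleDesign, min_pairs: int = 3
) -> pd.DataFrame:
    """Two-sided paired (one-sample on log2 ratios) t test per feature.

    Returns a DataFrame indexed by feature with columns ``t_stat``,
    ``p_value``, ``n_pairs`` and ``log2_fc`` (mean log2 apical/basolateral
    ratio).  Features with fewer than ``min_pairs`` complete pairs get NaN
    statistics and are counted, not silently dropped.
    """
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    d = _d_matrix(matrix, design)
    out = _t_from_d(d, min_pairs)
    out.index = matrix.data.index
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    NaN entries (untested features) are passed through as NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify(
    apical_fraction_pct: pd.Series,
    q_values: pd.Series,
    alpha: float = 0.05,
    bio_threshold_pct: float = 60.0,
) -> pd.Series:
    """Assign the polarization class per feature.

    apical_core: q < alpha and fraction >= bio_threshold; basolateral_core:
    q < alpha and fraction <= 100 - bio_threshold; stat_only: q < alpha but
    fraction inside the biological band; unpolarized otherwise.
    """
    sig = q_values < alpha
    cls = pd.Series(CLASS_UNPOLARIZED, index=apical_fraction_pct.index, name="class")
    cls[sig & (apical_fraction_pct >= bio_threshold_pct)] = CLASS_APICAL
    cls[sig & (apical_fraction_pct <= 100.0 - bio_threshold_pct)] = CLASS_BASOLATERAL
    stat_only = (
        sig
        & (apical_fraction_pct > 100.0 - bio_threshold_pct)
        & (apical_fraction_pct < bio_threshold_pct)
    )
    cls[stat_only] = CLASS_STAT_ONLY
    cls[q_values.isna() | apical_fraction_pct.isna()] = CLASS_UNPOLARIZED
    return cls


@dataclass
class RandomizationFloor:
    floor_pct: float  # smallest defensible |fraction - 50| among real calls
    null_quantile_pct: float
    n_permutations: int
    n_real_calls: int
    seed: int


def randomization_floor(
    matrix: IntensityMatrix,
    design: SampleDesign,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    min_pairs: int = 3,
) -> RandomizationFloor:
    """Permutation-based minimal detectable polarization.

    Side labels are swapped independently per bioreplicate (a sign flip of
    each d_r, applied to all features of that replicate at once).  For each
    permutation the analysis is recomputed and the |apical fraction - 50| of
    every q < alpha call is pooled into a null distribution; the floor is
    the smallest real-label |fraction - 50| among q < alpha calls exceeding
    the null's (1 - alpha) quantile.
    """
    if n_perm < 100:
        raise ValueError("insufficient permutations (need n_perm >= 100)")
    if design.n_pairs < 2:
        raise ValueError("randomization requires at least 2 bioreplicate pairs")
    rng = np.random.default_rng(seed)
    ap, baso, _ = _pair_arrays(matrix, design)
    ok = ~np.isnan(ap) & ~np.isnan(baso)
    ap = np.where(ok, ap, np.nan)
    baso = np.where(ok, baso, np.nan)

    def _dev_of_calls(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.log2(a) - np.log2(b)
            ratio = a / (a + b)
        n_ok = (~np.isnan(ratio)).sum(axis=1)
        frac = np.full(a.shape[0], np.nan)
        if (n_ok > 0).any():
            frac[n_ok > 0] = np.nanmean(ratio[n_ok > 0], axis=1) * 100.0
        res = _t_from_d(d, min_pairs)
        q = bh_fdr(res["p_value"].to_numpy())
        called = q < alpha
        return np.abs(frac[called] - 50.0)

    real_dev = _dev_of_calls(ap, baso)
    null_dev = []
    n_rep = ap.shape[1]
    for _ in range(n_perm):
        flip = rng.integers(0, 2, size=n_rep).astype(bool)
        a = np.where(flip, baso, ap)
        b = np.where(flip, ap, baso)
        null_dev.append(_dev_of_calls(a, b))
    null_all = np.concatenate(null_dev) if null_dev else np.array([])
    null_q = float(np.quantile(null_all, 1.0 - alpha)) if null_all.size else 0.0
    above = real_dev[real_dev > null_q]
    floor = float(above.min()) if above.size else float("nan")
    return RandomizationFloor(
        floor_pct=floor,
        null_quantile_pct=null_q,
        n_permutations=n_perm,
        n_real_calls=int(real_dev.size),
        seed=seed,
    )


class PolarizationModel:
    """Paired apical/basolateral polarization model for one intensity matrix.

    Parameters
    ----------
    matrix : IntensityMatrix
        Raw (or pre-normalized) peptide- or protein-level intensities.
    design : SampleDesign
        The apical/basolateral pairing per bioreplicate.
    normalization : {"replicate_average", "median", "none"}
        Applied before testing; the default is the replicate average-based
        method, whose per-feature factors are immune to contaminant load.
    min_pairs : int
        Minimum complete pairs for a feature to be tested.
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        design: SampleDesign,
        normalization: str = "replicate_average",
        min_pairs: int = 3,
    ):
        self.matrix = matrix
        self.design = design
        self.normalization = normalization
        self.min_pairs = min_pairs

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, design: SampleDesign, level: str = "protein", **kwargs
    ) -> "PolarizationModel":
        return cls(IntensityMatrix(data, level), design, **kwargs)

    def fit(self, alpha: float = 0.05, bio_threshold_pct: float = 60.0) -> "PolarizationResults":
        if self.normalization == "replicate_average":
            norm = normalize_replicate_average(self.matrix, self.design)
        elif self.normalization == "median":
            norm = normalize_median(self.matrix)
        elif self.normalization == "none":
            norm = NormalizationResult(self.matrix, pd.DataFrame(), "none")
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        table = paired_test(norm.normalized, self.design, self.min_pairs)
        table["apical_fraction_pct"] = apical_fraction(norm.normalized, self.design)
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        table["class"] = classify(
            table["apical_fraction_pct"], table["q_value"], alpha, bio_threshold_pct
        )
        cols = [
            "apical_fraction_pct",
            "log2_fc",
            "t_stat",
            "p_value",
            "q_value",
            "n_pairs",
            "class",
        ]
        return PolarizationResults(
            model=self,
            table=table[cols],
            normalization=norm,
            alpha=alpha,
            bio_threshold_pct=bio_threshold_pct,
        )


@dataclass
class PolarizationResults:
    """Fitted polarization estimates with their tests and classes.

    ``table`` holds one row per feature: apical fraction (%), log2 fold
    change, t statistic, p and BH q value, number of complete pairs, class.
    """

    model: PolarizationModel
    table: pd.DataFrame
    normalization: NormalizationResult
    alpha: float
    bio_threshold_pct: float

    @property
    def core_apical(self) -> set[str]:
        return set(self.table.index[self.table["class"] == CLASS_APICAL])

    @property
    def core_basolateral(self) -> set[str]:
        return set(self.table.index[self.table["class"] == CLASS_BASOLATERAL])

    @property
    def n_significant(self) -> int:
        return int((self.table["q_value"] < self.alpha).sum())

    def randomization_floor(self, n_perm: int = 200, seed: int = 0) -> RandomizationFloor:
        return randomization_floor(
            self.normalization.normalized,
            self.model.design,
            n_perm=n_perm,
            alpha=self.alpha,
            seed=seed,
            min_pairs=self.model.min_pairs,
        )

    def set_biotin_ok(self, ok_ids) -> None:
        """Attach the topology-QC flag (protein has >= 1 extracellular biotin site)."""
        self.table["biotin_ok"] = self.table.index.isin(set(ok_ids))

    def summary(self) -> str:
        t = self.table
        n_tested = int(t["p_value"].notna().sum())
        lines = [
            "Polarization analysis (paired apical vs basolateral t test)",
            "=" * 60,
            f"features: {len(t)}   tested (>= {self.model.min_pairs} pairs): {n_tested}",
            f"normalization: {self.normalization.method}",
            f"alpha (BH FDR): {self.alpha}   biological threshold: "
            f"{self.bio_threshold_pct:.0f}-{100 - self.bio_threshold_pct:.0f}%",
            f"significant (q < {self.alpha}): {self.n_significant}",
            f"apical core: {len(self.core_apical)}   basolateral core: "
            f"{len(self.core_basolateral)}   stat-only: "
            f"{int((t['class'] == CLASS_STAT_ONLY).sum())}",
            f"median apical fraction: {t['apical_fraction_pct'].median():.2f}%",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot: apical fraction (%) vs -log10 q, colored by class."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        t = self.table.dropna(subset=["apical_fraction_pct", "q_value"])
        colors = {
            CLASS_APICAL: "crimson",
            CLASS_BASOLATERAL: "royalblue",
            CLASS_STAT_ONLY: "goldenrod",
            CLASS_UNPOLARIZED: "lightgray",
        }
        for cls, sub in t.groupby("class"):
            ax.scatter(
                sub["apical_fraction_pct"],
                -np.log10(np.clip(sub["q_value"], 1e-300, None)),
                s=8,
                c=colors.get(cls, "k"),
                label=cls,
            )
        ax.axvline(self.bio_threshold_pct, ls="--", c="k", lw=0.6)
        ax.axvline(100 - self.bio_threshold_pct, ls="--", c="k", lw=0.6)
        ax.set_xlabel("apical fraction (%)")
        ax.set_ylabel("-log10 q")
        ax.legend(fontsize=7)
        return ax
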