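"""Synthetic side-selective biotinylation datasets with known ground truth.

The generator emulates the statistical structure of a paired apical /
basolateral label-free quantification experiment:

* per-protein log-normal abundance: the log2 intensity of protein *p* in
  replicate *r* on a given side is
  ``base_p + batch_{p,r} + polar_{p,side} + eps``;
* the polarity term encodes a planted apical fraction ``f``:
  ``polar_apical = log2(2 f)`` and ``polar_baso = log2(2 (1 - f))``, so that
  apical / (apical + basolateral) equals ``f`` exactly when noise is zero;
* multiplicative batch factors ``batch_{p,r}`` are shared by the two sides
  of a replicate (they model per-pair handling differences, which is what
  the replicate-average normalization removes);
* contaminant proteins are unpolarized (f = 0.5) and carry two extra terms:
  a per-sample carry-over factor shared by ALL contaminants (the amount of
  medium residue is a property of each sample's washing, so the whole
  contaminant block moves coherently, which is what drags per-sample
  medians around and wrecks bulk median/total normalization while the
  pair-anchored per-feature normalization is untouched) plus an inflated
  independent per-sample term;
* correlated clusters share a planted batch factor across members, with
  member noise scaled to hit a target intracluster correlation; when the
  clusters fit in the centered replicate space (n_clusters <= n_replicates)
  the factors are planted as a structured frame (orthogonal within the
  smaller polarity group, equiangular within the larger) so that every
  planted inter-cluster correlation is bounded by construction instead of
  depending on chance alignments of random vectors;
* missingness is intensity dependent (logistic in log2 intensity),
  emulating LFQ left-censoring;
* peptides are drawn from an in-silico tryptic digest of generated protein
  sequences, and biotin sites are planted on lysines / peptide N-termini
  inside extracellular topology segments at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contaminants import digest_tryptic
from .io import (
    IntensityMatrix,
    ModType,
    Modification,
    PeptideRecord,
    Proteome,
    SampleDesign,
    Segment,
    SegmentLabel,
    Side,
    TopologyMap,
)

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_biotin_sites",
    "simulate_contaminant_control",
    "DEFAULT_CLUSTER_SPEC",
]

# three apical + four basolateral planted clusters, the pattern the analysis
# is expected to recover on a full-scale run
DEFAULT_CLUSTER_SPEC: tuple[tuple[int, str, float], ...] = (
    (13, "apical", 0.97),
    (12, "apical", 0.97),
    (10, "apical", 0.97),
    (13, "basolateral", 0.97),
    (12, "basolateral", 0.97),
    (11, "basolateral", 0.97),
    (10, "basolateral", 0.97),
)

# apical fraction planted for cluster members (same as the singleton planted
# fractions); the shared side term it induces contributes delta^2/4 to the
# covariance of any two same-polarity cluster proteins, which the larger
# cluster batch scale (cluster_log2_batch_sd) dilutes below an inter-cluster
# correlation of 0.3
CLUSTER_F_APICAL = 0.65

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# roughly uniform with lysine/arginine upweighted so tryptic digests are rich
_AA_W = np.array([1.0] * 20)
_AA_W[_AA == "K"] = 2.0
_AA_W[_AA == "R"] = 2.0
_AA_W = _AA_W / _AA_W.sum()


@dataclass(frozen=True)
class SimulationParams:
    n_proteins: int = 2000
    n_replicates: int = 7
    frac_polarized: float = 0.10
    planted_fractions: tuple[float, ...] = (0.65, 0.35)
    log2_noise_sd: float = 0.25
    log2_batch_sd: float = 0.5
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    missing_rate_at_low_intensity: float = 0.5
    missing_midpoint_log2: float | None = None  # default: mean - 1.5 sd
    missing_scale_log2: float = 1.5
    n_contaminants: int = 290
    contaminant_log2_batch_sd: float = 1.5
    contaminant_carry_log2_sd: float = 1.5
    cluster_spec: tuple[tuple[int, str, float], ...] = DEFAULT_CLUSTER_SPEC
    cluster_log2_batch_sd: float = 0.8
    peptides_per_protein_mean: float = 5.0
    log2_peptide_noise_sd: float = 0.1
    extracellular_site_rate: float = 0.94
    secreted_fraction: float = 0.3  # proteins with a fully extracellular topology
    seed: int = 0
    with_peptides: bool = True

    def __post_init__(self) -> None:
        for name in (
            "frac_polarized",
            "missing_rate_at_low_intensity",
            "extracellular_site_rate",
            "secreted_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for f in self.planted_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"planted fraction {f} outside [0, 1]")
        if min(self.n_proteins, self.n_replicates, self.n_contaminants) < 0:
            raise ValueError("counts must be >= 0")
        for sd in (self.log2_noise_sd, self.log2_batch_sd, self.cluster_log2_batch_sd,
                   self.contaminant_carry_log2_sd, self.log2_peptide_noise_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        if self.peptides_per_protein_mean <= 0:
            raise ValueError("peptides_per_protein_mean must be > 0")
        n_cluster = sum(size for size, _, _ in self.cluster_spec)
        if n_cluster > self.n_proteins:
            raise ValueError("cluster sizes exceed n_proteins")
        for size, polarity, r in self.cluster_spec:
            if polarity not in ("apical", "basolateral"):
                raise ValueError(f"unknown cluster polarity {polarity!r}")
            if not 0.0 < r < 1.0:
                raise ValueError("intracluster r target must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset (one row per protein)."""

    fractions: pd.Series  # planted apical fraction per protein
    batch_log2: pd.DataFrame  # protein x bioreplicate shared batch term
    contaminant_ids: tuple[str, ...]
    cluster_members: dict[str, tuple[str, ...]]
    cluster_polarity: dict[str, str]
    site_truth: pd.DataFrame  # protein_id, residue, planted_extracellular
    seed: int

    @property
    def polarized_ids(self) -> set[str]:
        return set(self.fractions.index[self.fractions != 0.5])

    @property
    def apical_ids(self) -> set[str]:
        return set(self.fractions.index[self.fractions > 0.5])

    @property
    def basolateral_ids(self) -> set[str]:
        return set(self.fractions.index[self.fractions < 0.5])

    def to_frame(self) -> pd.DataFrame:
        cluster_of = {
            pid: name for name, members in self.cluster_members.items() for pid in members
        }
        return pd.DataFrame(
            {
                "protein_id": self.fractions.index,
                "planted_fraction": self.fractions.to_numpy(),
                "is_contaminant": [
                    pid in set(self.contaminant_ids) for pid in self.fractions.index
                ],
                "cluster": [cluster_of.get(pid, "") for pid in self.fractions.index],
            }
        )


@dataclass
class SyntheticDataset:
    protein_matrix: IntensityMatrix
    peptide_matrix: IntensityMatrix | None
    records: list[PeptideRecord]
    topology: TopologyMap
    design: SampleDesign
    truth: SyntheticTruth
    proteome: Proteome | None
    params: SimulationParams


def _make_design(n_replicates: int) -> SampleDesign:
    reps = [f"R{i + 1}" for i in range(n_replicates)]
    samples, rep_ids, sides, batches = [], [], [], []
    for i, r in enumerate(reps):
        batch = f"B{i * 3 // max(n_replicates, 1) + 1}"  # three acquisition batches
        for side, tag in ((Side.APICAL, "A"), (Side.BASOLATERAL, "B")):
            samples.append(f"{tag}{i + 1}")
            rep_ids.append(r)
            sides.append(side)
            batches.append(batch)
    return SampleDesign(tuple(samples), tuple(rep_ids), tuple(sides), tuple(batches))


def _polar_terms(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log2(2.0 * f), np.log2(2.0 * (1.0 - f))


def _simplex_frame(m: int) -> np.ndarray:
    """``m`` unit vectors in ``m - 1`` dimensions with pairwise cosine -1/(m-1)."""
    from scipy.linalg import null_space

    centered = np.eye(m) - 1.0 / m  # columns e_i - mean, norm sqrt((m-1)/m)
    basis = null_space(np.ones((1, m)))  # m x (m-1), orthonormal
    coords = (basis.T @ centered).T  # one row per vector
    return coords / np.linalg.norm(coords, axis=1, keepdims=True)


def _cluster_shared_factors(
    polarities: list[str], n_replicates: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Planted per-cluster batch factors (one row per cluster, centered).

    Batch factors enter the empirical correlation only through their centered
    part, which lives in an (R - 1)-dimensional space for R replicates.  With
    up to R - 1 clusters the factors are planted mutually orthogonal; with
    exactly R clusters the larger polarity group is planted as an equiangular
    simplex frame (pairwise cosine -1/(m - 1)) orthogonal to the other group,
    which is the arrangement with the smallest achievable pairwise alignment.
    A random rotation of the centered space keeps realizations seed-dependent
    without changing any pairwise angle.  Beyond R clusters no such frame
    exists and independent Gaussian draws are used instead.
    """
    from scipy.linalg import null_space

    n = len(polarities)
    R = n_replicates
    if n > R or R < 2:
        return rng.normal(0.0, sd, size=(n, R))
    dim = R - 1
    coords = np.zeros((n, dim))
    groups = [
        [i for i, p in enumerate(polarities) if p == "apical"],
        [i for i, p in enumerate(polarities) if p == "basolateral"],
    ]
    groups.sort(key=len)  # smaller group first; it gets private orthogonal axes
    if n <= dim:  # everything fits orthogonally
        for axis, i in enumerate(groups[0] + groups[1]):
            coords[i, axis] = 1.0
    elif len(groups[1]) >= 2:  # n == R: larger group takes the simplex frame
        axis = 0
        for i in groups[0]:
            coords[i, axis] = 1.0
            axis += 1
        idx = groups[1]
        coords[idx, axis : axis + len(idx) - 1] = _simplex_frame(len(idx))
    else:  # n == R == 2, one cluster per polarity: simplex over the whole set
        coords[groups[0] + groups[1], :1] = _simplex_frame(n)
    rotation = np.linalg.qr(rng.normal(size=(dim, dim)))[0]
    centered_basis = null_space(np.ones((1, R)))  # R x (R - 1), orthonormal
    vectors = coords @ rotation.T @ centered_basis.T
    # unit norm in R^R means empirical variance 1/R; rescale to variance sd^2
    return vectors * (sd * np.sqrt(R))


def simulate_dataset(params: SimulationParams | None = None, **kwargs) -> SyntheticDataset:
    """Generate a complete synthetic dataset plus its ground truth.

    Keyword arguments override fields of ``params`` (or of the defaults).
    Identical parameters and seed give identical outputs.
    """
    if params is None:
        params = SimulationParams(**kwargs)
    elif kwargs:
        params = replace(params, **kwargs)
    p = params
    ss = np.random.SeedSequence(p.seed)
    (abund_ss, miss_ss, seq_ss, pep_ss, site_ss) = ss.spawn(5)
    rng = np.random.default_rng(abund_ss)

    target_ids = [f"P{i + 1:05d}" for i in range(p.n_proteins)]
    cont_ids = [f"CONT{i + 1:04d}" for i in range(p.n_contaminants)]
    all_ids = target_ids + cont_ids
    n_all = len(all_ids)
    R = p.n_replicates
    design = _make_design(R)

    # --- planted fractions -------------------------------------------------
    fractions = pd.Series(0.5, index=all_ids, dtype=float)
    order = rng.permutation(p.n_proteins)
    cursor = 0
    cluster_members: dict[str, tuple[str, ...]] = {}
    cluster_polarity: dict[str, str] = {}
    cluster_rtarget: dict[str, float] = {}
    for ci, (size, polarity, r_target) in enumerate(p.cluster_spec):
        members = tuple(sorted(target_ids[j] for j in order[cursor : cursor + size]))
        cursor += size
        name = f"{polarity}_{ci + 1}"
        cluster_members[name] = members
        cluster_polarity[name] = polarity
        cluster_rtarget[name] = r_target
        f = CLUSTER_F_APICAL if polarity == "apical" else 1.0 - CLUSTER_F_APICAL
        fractions[list(members)] = f
    n_singles = int(round(p.frac_polarized * p.n_proteins))
    single_ids = [target_ids[j] for j in order[cursor : cursor + n_singles]]
    for i, pid in enumerate(single_ids):
        fractions[pid] = p.planted_fractions[i % len(p.planted_fractions)]

    # --- log2 intensity surface -------------------------------------------
    base = rng.normal(p.baseline_log2_mean, p.baseline_log2_sd, size=n_all)
    batch = rng.normal(0.0, p.log2_batch_sd, size=(n_all, R))
    # cluster members share their cluster's planted batch factor
    idx_of = {pid: i for i, pid in enumerate(all_ids)}
    cluster_names = list(cluster_members)
    if cluster_names:
        factors = _cluster_shared_factors(
            [cluster_polarity[name] for name in cluster_names],
            R,
            p.cluster_log2_batch_sd,
            rng,
        )
        for name, shared in zip(cluster_names, factors):
            for pid in cluster_members[name]:
                batch[idx_of[pid]] = shared

    f_arr = fractions.to_numpy()
    pol_ap, pol_ba = _polar_terms(f_arr)

    noise_sd = np.full(n_all, p.log2_noise_sd)
    for name, members in cluster_members.items():
        # shared-signal variance across samples seen by a member pair:
        # batch variance plus the deterministic side-term variance
        f = CLUSTER_F_APICAL if cluster_polarity[name] == "apical" else 1 - CLUSTER_F_APICAL
        delta = abs(np.log2(f / (1.0 - f)))
        v_shared = p.cluster_log2_batch_sd**2 + delta**2 / 4.0
        r = cluster_rtarget[name]
        s = np.sqrt(v_shared * (1.0 - r) / r)
        for pid in members:
            noise_sd[idx_of[pid]] = s

    eps_ap = rng.normal(0.0, 1.0, size=(n_all, R)) * noise_sd[:, None]
    eps_ba = rng.normal(0.0, 1.0, size=(n_all, R)) * noise_sd[:, None]

    log2_ap = base[:, None] + batch + pol_ap[:, None] + eps_ap
    log2_ba = base[:, None] + batch + pol_ba[:, None] + eps_ba

    # contaminants: unpolarized, with a per-sample carry-over factor shared by
    # the whole block plus an extra independent per-sample term
    if p.n_contaminants:
        csl = slice(p.n_proteins, n_all)
        carry_ap = rng.normal(0.0, p.contaminant_carry_log2_sd, size=R)
        carry_ba = rng.normal(0.0, p.contaminant_carry_log2_sd, size=R)
        log2_ap[csl] += carry_ap[None, :]
        log2_ba[csl] += carry_ba[None, :]
        log2_ap[csl] += rng.normal(0.0, p.contaminant_log2_batch_sd, size=(p.n_contaminants, R))
        log2_ba[csl] += rng.normal(0.0, p.contaminant_log2_batch_sd, size=(p.n_contaminants, R))

    # planted f of 0 or 1 yields -inf log intensity on the null side -> missing
    pairs = design.pairs()
    cols: dict[str, np.ndarray] = {}
    for j, rep in enumerate(pairs):
        a_col, b_col = pairs[rep]
        cols[a_col] = log2_ap[:, j]
        cols[b_col] = log2_ba[:, j]
    log2_df = pd.DataFrame(cols, index=all_ids)[list(design.sample_ids)]

    # --- intensity-dependent missingness ------------------------------------
    miss_rng = np.random.default_rng(miss_ss)
    x0 = (
        p.missing_midpoint_log2
        if p.missing_midpoint_log2 is not None
        else p.baseline_log2_mean - 1.5 * p.baseline_log2_sd
    )
    x = log2_df.to_numpy()
    with np.errstate(over="ignore"):
        p_miss = p.missing_rate_at_low_intensity / (
            1.0 + np.exp((x - x0) / p.missing_scale_log2)
        )
    mask = miss_rng.random(size=x.shape) < p_miss
    values = np.power(2.0, x)
    values[mask] = np.nan
    values[np.isinf(x) & (x < 0)] = np.nan  # f = 0 or 1 null side
    protein_matrix = IntensityMatrix(
        pd.DataFrame(values, index=all_ids, columns=log2_df.columns), "protein"
    )

    truth = SyntheticTruth(
        fractions=fractions,
        batch_log2=pd.DataFrame(batch, index=all_ids, columns=list(pairs)),
        contaminant_ids=tuple(cont_ids),
        cluster_members=cluster_members,
        cluster_polarity=cluster_polarity,
        site_truth=pd.DataFrame(columns=["protein_id", "residue", "planted_extracellular"]),
        seed=p.seed,
    )

    if not p.with_peptides:
        return SyntheticDataset(
            protein_matrix=protein_matrix,
            peptide_matrix=None,
            records=[],
            topology=TopologyMap({}),
            design=design,
            truth=truth,
            proteome=None,
            params=p,
        )

    # --- sequences, topology, peptides --------------------------------------
    seq_rng = np.random.default_rng(seq_ss)
    proteome, topology = _make_proteome(all_ids, seq_rng, p.secreted_fraction)
    pep_rng = np.random.default_rng(pep_ss)
    records, pep_rows, pep_index = [], [], []
    for i, pid in enumerate(all_ids):
        products = _digest_with_positions(proteome[pid])
        k = max(1, pep_rng.poisson(p.peptides_per_protein_mean))
        k = min(k, len(products))
        chosen = pep_rng.choice(len(products), size=k, replace=False)
        eff = pep_rng.normal(0.0, 1.0, size=k)  # ionization efficiency (log2)
        for m, ci in enumerate(sorted(chosen)):
            start, seq = products[ci]
            pep_id = f"{pid}_pep{m + 1}"
            records.append(
                PeptideRecord(
                    peptide_id=pep_id, sequence=seq, protein_id=pid, start_in_protein=start
                )
            )
            pep_noise = pep_rng.normal(0.0, p.log2_peptide_noise_sd, size=x.shape[1])
            pep_rows.append(np.power(2.0, np.log2(values[i]) + eff[m] + pep_noise))
            pep_index.append(pep_id)
    pep_arr = np.vstack(pep_rows)
    # peptide-level left-censoring on top of the protein-level mask
    with np.errstate(invalid="ignore", over="ignore"):
        p_miss_pep = p.missing_rate_at_low_intensity / (
            1.0 + np.exp((np.log2(pep_arr) - x0) / p.missing_scale_log2)
        )
    pep_mask = np.random.default_rng(miss_ss.spawn(1)[0]).random(pep_arr.shape) < p_miss_pep
    pep_arr[pep_mask] = np.nan
    peptide_matrix = IntensityMatrix(
        pd.DataFrame(pep_arr, index=pep_index, columns=log2_df.columns), "peptide"
    )

    records, site_truth = simulate_biotin_sites(
        records, topology, p.extracellular_site_rate, np.random.default_rng(site_ss),
        return_truth=True,
    )
    truth.site_truth = site_truth

    return SyntheticDataset(
        protein_matrix=protein_matrix,
        peptide_matrix=peptide_matrix,
        records=records,
        topology=topology,
        design=design,
        truth=truth,
        proteome=proteome,
        params=p,
    )


def _make_proteome(
    ids: list[str], rng: np.random.Generator, secreted_fraction: float
) -> tuple[Proteome, TopologyMap]:
    """Random protein sequences with a single-pass or fully extracellular topology."""
    seqs: dict[str, str] = {}
    segs: dict[str, list[Segment]] = {}
    lengths = rng.integers(200, 600, size=len(ids))
    secreted = rng.random(len(ids)) < secreted_fraction
    for pid, L, sec in zip(ids, lengths, secreted):
        L = int(L)
        seqs[pid] = "".join(rng.choice(_AA, size=L, p=_AA_W))
        if sec:
            segs[pid] = [Segment(1, L, SegmentLabel.EXTRACELLULAR)]
        else:
            a = int(rng.integers(int(0.4 * L), int(0.7 * L)))
            segs[pid] = [
                Segment(1, a, SegmentLabel.EXTRACELLULAR),
                Segment(a + 1, min(a + 21, L - 1), SegmentLabel.TRANSMEMBRANE),
                Segment(min(a + 22, L), L, SegmentLabel.INTRACELLULAR),
            ]
    return Proteome(seqs, species_tag="synthetic"), TopologyMap(segs)


def _digest_with_positions(sequence: str) -> list[tuple[int, str]]:
    """Fully cleaved tryptic products with their 1-based start positions."""
    out = []
    pos = 1
    for pep in digest_tryptic(sequence, missed_cleavages=0, min_len=1, max_len=10**9):
        if 6 <= len(pep) <= 50:
            out.append((pos, pep))
        pos += len(pep)
    return out


def simulate_biotin_sites(
    records: list[PeptideRecord],
    topology: TopologyMap,
    extracellular_site_rate: float,
    seed,
    return_truth: bool = False,
):
    """Plant one biotin site per record on average, at lysines or peptide N-termini.

    Each planted site is extracellular with probability
    ``extracellular_site_rate``; the actual residue is drawn uniformly from
    the candidate positions of the requested compartment across all
    records, so the observed rate is an exact Bernoulli draw.
    """
    if not 0.0 <= extracellular_site_rate <= 1.0:
        raise ValueError("extracellular_site_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing_topo = [r.protein_id for r in records if r.protein_id not in topology]
    if missing_topo:
        raise ValueError(f"proteins absent from topology map: {sorted(set(missing_topo))[:5]}")
    if extracellular_site_rate == 1.0:
        without = sorted(
            {
                r.protein_id
                for r in records
                if not topology.extracellular_positions(r.protein_id)
            }
        )
        if without:
            raise ValueError(
                f"extracellular rate 1.0 but proteins lack extracellular segments: {without[:5]}"
            )

    def _is_extra(pid: str, residue: int) -> bool:
        return topology.label_at(pid, residue) is SegmentLabel.EXTRACELLULAR

    extra_pool: list[tuple[int, int, ModType]] = []  # (record idx, residue, mod type)
    other_pool: list[tuple[int, int, ModType]] = []
    for ri, rec in enumerate(records):
        cands = [(ri, rec.start_in_protein, ModType.BIOTIN_PROTEIN_NTERM)]
        cands += [
            (ri, rec.start_in_protein + off, ModType.BIOTIN_LYSINE)
            for off, aa in enumerate(rec.sequence)
            if aa == "K"
        ]
        for c in cands:
            (extra_pool if _is_extra(rec.protein_id, c[1]) else other_pool).append(c)
    rng.shuffle(extra_pool)
    rng.shuffle(other_pool)

    n_sites = len(records)
    want_extra = rng.random(n_sites) < extracellular_site_rate
    new_mods: dict[int, list[Modification]] = {}
    truth_rows = []
    for w in want_extra:
        pool = extra_pool if w else other_pool
        if not pool:
            continue  # compartment exhausted; site not emitted
        ri, residue, mod_type = pool.pop()
        new_mods.setdefault(ri, []).append(Modification(residue, mod_type))
        truth_rows.append((records[ri].protein_id, residue, bool(w)))

    out = []
    for ri, rec in enumerate(records):
        mods = tuple(rec.modifications) + tuple(new_mods.get(ri, ()))
        out.append(replace(rec, modifications=mods))
    if return_truth:
        truth = pd.DataFrame(
            truth_rows, columns=["protein_id", "residue", "planted_extracellular"]
        )
        return out, truth
    return out


def simulate_contaminant_control(
    n_proteins: int = 290,
    biotin_rate: float = 0.42,
    nterm_rate: float = 0.20,
    peptides_per_protein: int = 3,
    n_target_proteins: int = 200,
    seed: int = 0,
):
    """Emulate a medium-only control run for contaminant-database QC.

    Returns (control_ids, control_peptides, contaminant_proteome,
    target_proteome).  Each control protein carries a biotin site with
    probability ``biotin_rate``; of those, a fraction corresponding to
    ``nterm_rate`` carry it on a peptide N-terminus (N-terminal labeling is
    a kind of biotinylation, so the N-term set nests inside the biotin set).
    """
    if nterm_rate > biotin_rate:
        raise ValueError("nterm_rate cannot exceed biotin_rate")
    ss = np.random.SeedSequence(seed)
    seq_ss, flag_ss = ss.spawn(2)
    seq_rng = np.random.default_rng(seq_ss)
    cont_ids = [f"BOVIN{i + 1:04d}" for i in range(n_proteins)]
    tgt_ids = [f"TARGET{i + 1:04d}" for i in range(n_target_proteins)]
    cont_proteome, _ = _make_proteome(cont_ids, seq_rng, secreted_fraction=1.0)
    cont_proteome.species_tag = "bovine-synthetic"
    tgt_proteome, _ = _make_proteome(tgt_ids, seq_rng, secreted_fraction=1.0)
    tgt_proteome.species_tag = "target-synthetic"

    flag_rng = np.random.default_rng(flag_ss)
    u = flag_rng.random(n_proteins)
    records = []
    for i, pid in enumerate(cont_ids):
        products = _digest_with_positions(cont_proteome[pid])
        k = min(peptides_per_protein, len(products))
        chosen = sorted(flag_rng.choice(len(products), size=k, replace=False))
        recs = []
        for m, ci in enumerate(chosen):
            start, seq = products[ci]
            recs.append(
                PeptideRecord(
                    peptide_id=f"{pid}_pep{m + 1}",
                    sequence=seq,
                    protein_id=pid,
                    start_in_protein=start,
                )
            )
        if u[i] < nterm_rate:
            recs[0] = replace(
                recs[0],
                modifications=(
                    Modification(recs[0].start_in_protein, ModType.BIOTIN_PROTEIN_NTERM),
                ),
            )
        elif u[i] < biotin_rate:
            rec_k = next(
                (r for r in recs if "K" in r.sequence), None
            )
            if rec_k is None:
                rec_k = recs[0]
                mod = Modification(rec_k.start_in_protein, ModType.BIOTIN_PROTEIN_NTERM)
            else:
                off = rec_k.sequence.index("K")
                mod = Modification(rec_k.start_in_protein + off, ModType.BIOTIN_LYSINE)
            idx = recs.index(rec_k)
            recs[idx] = replace(rec_k, modifications=(mod,))
        records.extend(recs)
    return cont_ids, records, cont_proteome, tgt_proteome
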