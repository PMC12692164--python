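# Methods

This note documents the statistical model implemented by `polarsurf`, the
synthetic-data generator used for validation, the numerical conventions,
and known limitations.

## 1. Data model

- **Intensity matrices** (`polarsurf.io.IntensityMatrix`): features
  (proteins or peptides) × samples, strictly positive intensities, `NaN`
  for missing. Zeros in input tables are converted to missing and counted.
- **Sample design** (`SampleDesign`): each biological replicate (filter)
  contributes one apical and one basolateral sample; the design validates
  that every replicate has exactly one sample per side.
- **Topology maps**: per protein, non-overlapping 1-based residue segments
  labeled extracellular / transmembrane / intracellular / unknown.
- **Peptide records**: sequence, parent protein, 1-based start position,
  and modifications (biotin on lysine or the protein N-terminus).

## 2. Normalization

### Replicate average-based (Eq. 1)

For feature *i* with a complete pair in replicate *r*:

```
I_norm(i, r, side) = I(i, r, side) / I(i, r, avg) × I(i, total, avg)
```

`I(i, r, avg)` is the mean of the two sides in that replicate;
`I(i, total, avg)` is the mean over all complete pairs of that feature.
Pairs missing one side are dropped for that feature (both cells set
missing, recorded with a reason) and excluded from the overall average.

Exact invariants (verified to 1e-9 or better in the acceptance tests):

- the within-pair apical/basolateral ratio is unchanged;
- the feature's mean over complete pairs is conserved;
- the transform is idempotent;
- the factors of one feature are bit-identical whatever happens to other
  features (contaminant immunity).

### Median scaling

Each sample is scaled so all sample medians equal the median of sample
medians. Used as the comparison method for the contaminant-bias contrast
and as the internal normalization for covariance clustering, where
per-pair anchoring would destroy the co-abundance signal.

## 3. Polarization inference

Per protein with ≥ `min_pairs` (default 3) complete pairs:

- `d_r = log2(apical_r) − log2(basolateral_r)`; one-sample two-sided t
  test of mean(d) = 0 with `n−1` degrees of freedom.
- Zero-variance edge cases: all `d_r = 0` gives t = 0, p = 1; identical
  nonzero `d_r` gives t = ±inf and p set to an underflow constant
  (`P_UNDERFLOW = 1e-300`) rather than exactly 0.
- Benjamini–Hochberg step-up FDR across tested proteins; `NaN` p-values
  pass through and do not count toward the number of tests.
- Apical fraction = mean over complete pairs of `a/(a+b) × 100`; `NaN`
  (not 100 or 0) when no complete pair exists.
- Classes: `apical_core` (q < α and fraction ≥ 60), `basolateral_core`
  (q < α and fraction ≤ 40), `stat_only` (q < α, fraction between),
  `unpolarized` otherwise. Threshold boundaries are core-inclusive.
- **Randomization floor**: side labels are swapped per replicate (a sign
  flip of `d_r` applied to all features at once, preserving the
  feature-correlation structure); `|fraction − 50|` of every q < α call
  over `n_perm ≥ 100` permutations forms the null; the floor is the
  smallest real-label deviation exceeding the null's (1 − α) quantile.
  `NaN` when no real call clears the quantile.

## 4. Covariance clusters

On log2 median-normalized intensities with contaminants excluded:

- pairwise Pearson correlation, pairwise-complete with ≥ `min_shared`
  (default 6) shared samples;
- strong subset: proteins with at least one partner at r > 0.95 (strict);
- average-linkage hierarchical clustering on distance 1 − r; candidates
  are maximal nodes with mean intra-cluster r ≥ 0.9 and size ≥ 10;
- each candidate is tested for enrichment in the apical and basolateral
  cores by a one-sided (greater) Fisher exact test against the clustered
  background, BH-corrected across all (candidate, core) pairs; a cluster
  is accepted with the polarity of its significant enrichment.

### Exact Fisher test

`polarsurf.clusters.fisher_exact` computes both p-values directly from the
conditional hypergeometric pmf over the first cell's support
(`scipy.stats.hypergeom.pmf`): the two-sided p is the probability-method
sum of point probabilities ≤ the observed one with the standard relative
tie guard of 1e-7 (scipy's documented convention), the one-sided greater p
is the upper-tail sum. Conventions: the all-zero table is the unique table
of its margins (p = 1 both ways); when the tie-guard mask covers the whole
support the two-sided p is exactly 1 (a floating sum would give 1 − 1e-16).
The implementation agrees with `scipy.stats.fisher_exact` to ≤ 1e-12 over
the full enumeration of 2×2 tables with N ≤ 40 and on random spot checks;
it exists because calling scipy per table is ~25× slower (result-object
overhead) on small tables.

## 5. QC utilities

- **Tryptic digest**: cleavage after K/R except before P, configurable
  missed cleavages; peptide space with I/L folding (isobaric residues).
- **Contaminant database**: a medium-only control protein enters the
  database iff ≥ 1 of its evidence peptides is absent from the target
  proteome's tryptic peptide space after I/L folding; proteins with only
  shared evidence are listed separately and not flagged.
- **Labeling efficiency**: fraction of database entries with any biotin
  site and with a protein N-terminal biotin.
- **Topology QC**: each biotin site is mapped to its segment label; OK =
  extracellular, flagged = transmembrane/intracellular, unmapped =
  unknown segment or protein absent from the map (counted separately).
- **TEER**: `(R − R_blank) × area` in Ω·cm²; negative values are returned
  with a flag rather than rejected.

## 6. Synthetic-data generator

`simulate_dataset(SimulationParams(...))` draws, per protein and replicate,

```
log2 I(p, r, side) = base_p + batch_{p,r} + polar_{p,side} + ε
```

- `base_p ~ N(20, 2)` (log2 scale);
- `batch_{p,r} ~ N(0, 0.5)`: shared by both sides of a pair — exactly the
  nuisance Eq. (1) removes;
- `polar`: a planted apical fraction `f` enters as
  `polar_ap = log2(2f)`, `polar_ba = log2(2(1−f))`, so the noiseless
  apical fraction is exactly `f` and the pair sum is unchanged; 10 % of
  proteins are planted at f = 0.65 or 0.35 by default, the rest at 0.5;
- `ε ~ N(0, 0.25)` independent per cell;
- **missingness**: intensity-dependent left censoring, probability
  `rate / (1 + exp((log2 I − midpoint)/scale))` with midpoint 1.5 sd below
  the baseline mean;
- **contaminants** (290 by default): no polarization; a per-sample
  carry-over factor (sd 1.5 log2) shared by all contaminants in that
  sample — modeling that the amount of residual medium is a property of
  each sample's washing — plus an independent per-sample term (sd 1.5).
  The shared factor is what biases median normalization while leaving the
  pair-anchored normalization untouched;
- **planted clusters** (default 3 apical + 4 basolateral, intra-cluster
  r = 0.97, f = 0.65/0.35): each cluster has a shared per-sample batch
  vector; the cluster direction vectors form a structured frame (orthogonal
  axes for the smaller polarity group, an equiangular simplex with cosine
  −1/(m−1) for the larger, randomly rotated) so planted inter-cluster
  correlations stay ≤ 0.3. Member noise is set from the target
  intra-cluster correlation: `s = sqrt(V_shared (1 − r)/r)` with
  `V_shared = 0.8² + Δ²/4`;
- **peptides/topology** (optional): Poisson peptide counts per protein,
  tryptic peptides from a generated proteome, biotin sites planted
  extracellular with a configurable rate (default 0.94), 30 % of proteins
  fully extracellular (secreted-like), the rest with a transmembrane
  topology.

The generator returns the full ground truth (planted fractions, batch
terms, contaminant ids, cluster memberships, site truth) for scoring. Its
scope is validation of the analysis stack, not realism: intensities are
log-normal, noise is homoscedastic, peptide-level effects are minimal.

## 7. Numerical conventions

- All randomness flows through `numpy.random.default_rng` seeds; pipeline
  runs are byte-identical for a fixed seed.
- BH is implemented with a stable mergesort and reverse cumulative
  minimum; agrees with `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`) to 1e-12 on random vectors including ties.
- Apical fractions are means of per-pair ratios (not ratios of means), so
  a side swap complements the fraction to ~1e-15 (two separate float
  roundings), while the t/p/q statistics are exactly antisymmetric /
  invariant.

## 8. Limitations

- The paired t test assumes approximately normal `d_r`; with the default
  7 replicates the type-I error is accurate on the generator's Gaussian
  noise (measured ≈ 0.05) but no claim is made for heavy-tailed data.
- Fraction recovery degrades with intensity-dependent missingness: at the
  default 50 % low-intensity censoring, the share of proteins whose
  observed apical fraction lands within ±5 percentage points of truth is
  right at ~95 % (measured 0.947–0.953 across seeds 0–3 on the default
  2000-protein dataset, scoring proteins with a defined observed
  fraction). This is a property of censoring, not of the estimator;
  without censoring the recovery is comfortably higher.
- The cluster search is greedy on the average-linkage tree and does not
  enumerate overlapping candidates; a protein belongs to at most one
  candidate.
- The randomization floor needs enough replicates for the sign-flip group
  to be informative (2^7 = 128 distinct patterns at 7 pairs includes the
  identity and full flip, so planted effects re-enter the null at rate
  2/128); with strong planted effects and few features the floor can be
  `NaN` (no real call clears the null quantile).
- The contaminant database build assumes the control run shares the
  acquisition setup with the main experiment; no cross-run intensity
  calibration is attempted.
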