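# Methods

This note documents the statistical procedures, the choices made where the
design was genuinely open, and the limits of what the synthetic-data tests
demonstrate.

## Data model and conventions

Peptide intensities are handled in log2 units throughout; a raw intensity
of 0 or a blank cell means "not observed" and is stored as NaN, never as 0.
Each peptide row maps to exactly one protein accession (the search engine's
razor assignment); protein-group inference beyond that column is out of
scope. One LCM voxel = one LC-MS run = one sample = one image pixel, with
(row, col) coordinates 0-based and row 0 at the top. The MaxQuant reader
accepts either the `Intensity <run>` or the `LFQ intensity <run>` column
family (`intensity_prefix`); which family feeds an analysis is a
configuration choice, with raw `Intensity` as the default.

## QC filtering

Decoy ("Reverse") and contaminant rows are dropped before any statistics.
Peptides observed in fewer than `min_obs = 2` runs across the whole study
are removed *before* rollup; data adequacy for testing is then decided
*after* rollup, per protein and group pair:

* **quantitative** (ANOVA track): ≥ `min_anova_obs = 2` observed values in
  each group;
* **qualitative** (g-test track): not quantitative, but each group has
  ≥ `min_gtest_n = 3` samples in total;
* **inadequate**: neither — the pair is not tested.

The thresholds are exposed in configuration. The two-stage order (peptide
filter pre-rollup, protein eligibility post-rollup) keeps weakly observed
peptides from propagating noise into rollup while still letting
presence/absence information reach the qualitative test at protein level.

## RMD-PAV outlier screening

Each run is summarised by five peptide-abundance-vector statistics: median
pairwise Pearson correlation with the other runs (pairwise-complete
peptides), fraction of missing peptides, median absolute deviation,
skewness and kurtosis. A squared Mahalanobis distance RMD² on these
5-vectors flags deviant runs at upper-tail p < 0.001.

**Distance estimator.** The textbook choice — minimum covariance
determinant (MCD) scatter with asymptotic chi-square(k) p-values — is badly
miscalibrated at the sample sizes typical of voxel studies: with n = 15–24
runs and k = 5 metrics, simulated null per-sample flag rates at the
nominal 0.001 level exceed 0.2, because finite-sample MCD distances are
far heavier-tailed than chi-square, and no monotone recalibration of the
distances separates a grossly displaced run from the null tail at n = 15.
The default estimator is therefore the **leave-one-out Mahalanobis
distance**: each run is measured against the mean and covariance of the
*other* runs, so the tested run never contaminates its own reference.
Under a multivariate-normal null this distance has an exact
Hotelling-T²/F distribution at every sample size (T² = d²·m/(m+1) with
m = n−1 reference points; T²(m−k)/(k(m−1)) ~ F(k, m−k)), giving exact
p-values that converge to the chi-square(k) tail as n grows. Simulation at
n = 20, k = 5 gives a null flag rate of ~0.0008 at alpha 0.001 and 99%
detection of a run displaced by 10 SD in one metric (85% at n = 15). The
limitation is masking: two mutually similar outliers inflate each other's
reference covariance; screen iteratively (remove, re-run) if that pattern
is suspected. `estimator="mcd"` (support fraction 0.75) and
`estimator="classical"` remain available with chi-square p-values for
larger studies.

Flagged runs are removed before normalization. The Pearson-correlation
screen (runs whose median correlation falls below median − 1.5·IQR) is
advisory only and never removes samples.

## Rank-invariant median centering

Candidates are the peptides with no missing values. Within each run the
candidates are ranked (average-rank ties); a peptide is *rank-invariant*
if a Kruskal–Wallis test of its per-run ranks against group membership
gives p > 0.2. The deliberately liberal threshold excludes only clearly
group-dependent peptides from the anchor set. Each run's shift is its
median over the selected peptides, so after centering the anchor-set
median is exactly 0 in every run; any per-run loading constant cancels
exactly in all downstream differences. Ranks are computed within the
complete-data candidate set (not the full matrix): the candidate set is
the population the selection statistic describes, and ranking within it
makes selection independent of how incomplete peptides happen to
interleave. Single-group (replicate) studies select all complete peptides.
The centering target is 0 rather than the grand median — any global
constant is irrelevant to group contrasts and to CVs.

## R-rollup

Per protein: the reference peptide has the fewest missing values (ties:
higher median abundance, then lexicographic id — deterministic). Every
other peptide i gets an additive log2 offset f_i = median over shared runs
of (reference − peptide_i); the per-run protein abundance is the median of
the offset-corrected peptides present in that run. Additive offsets in
log2 space correspond to ratio scaling on the linear scale. A peptide
sharing no observed run with the reference has an undefined offset and is
dropped (warned and counted in the provenance). One-hit proteins are
retained by default (`min_peptides_per_protein=1`); set 2 to reproduce
two-unique-peptide identification counting. No outlier-peptide trimming is
applied inside rollup — determinism is preferred over the marginal
robustness gain at these peptide counts.

## Differential testing

The ANOVA track fits the one-way model on **all** groups with ≥ 2 observed
values — the pooled variance uses the full factor even when a single pair
is reported — and pairwise p-values come from the studentized-range
distribution with Kramer's rule for unequal n (scipy's
`studentized_range`). Zero pooled variance is handled explicitly: equal
means give p = 1; exact separation is clamped to machine epsilon rather
than produce NaN or a fabricated 0. The qualitative track computes the
likelihood-ratio G on the 2×2 observed/missing × group table (chi-square,
1 df) and Holm-adjusts across the protein's family of pairwise
comparisons. Multiplicity across proteins is deliberately *not* adjusted
by default — headline tallies count proteins at per-protein adjusted
p < 0.05 — and a Benjamini–Hochberg option across proteins is available
for users who want it. Headline counts are reported from the ANOVA track;
g-test-only significances are tabulated separately.

## EASE enrichment

One-sided Fisher exact test with the list-hit cell decremented by one
(list size unchanged): a category supported by a single list gene can
never score, which is the EASE notion of conservatism; a ≤ 1 gives p = 1
by definition. The background is the set of quantifiable genes in the
study (not the whole annotation universe) — the conservative standard
choice, configurable. Gene-symbol mapping is supplied as a file (2-column
TSV or GAF 2.x); no live database queries. Categories with fewer than
`min_cat = 2` background members are excluded. Scores are −log10 p with no
across-category adjustment (a BH option exists, off by default). GO-graph
propagation is honoured only if the supplied map is pre-propagated.

## Imaging and CV summaries

Protein images place per-run abundances at their voxel coordinates;
unoccupied or missing cells carry NaN and render grey. Displayed values
are normalized abundances by default (configurable raw/normalized,
linear/log2); scaling is min–max or percentile-clip onto a monotone
colormap. Every PNG has a CSV sidecar holding the unscaled grid (exact
round-trip) with the voxel size in the header, from which scale bars
derive. The gallery is a single self-contained HTML index with a
client-side text filter — a static approximation of an interactive
trellis-display server, with deterministic ordering and file naming.
Mixed-content voxels (e.g. a voxel containing both GE and S tissue) are
rendered as ordinary voxels; no deconvolution is attempted.

CVs are computed on **linear-scale** intensities (sd/mean of 2^log2
values, ddof = 1) — a CV of log-scale values is not a coefficient of
variation. Proteins observed in fewer than 2 replicates are excluded.

## Synthetic-data generator

The generator emulates the statistical structure of a voxel study:

| parameter | default | meaning (units) |
|---|---|---|
| `n_proteins` | 2000 | proteins, matching the scale of a full study |
| `lambda_peptides` | 4.0 | peptides/protein = 1 + Poisson(λ) |
| `mu0`, `sigma0` | 25, 2 | protein baseline log2 intensity (MaxQuant-like 2^25 magnitudes) |
| `sigma_pep` | 0.3 | SD of per-peptide ionisation offsets (log2) |
| `fraction_de`, `effect_size` | 0.1, 2.0 | fraction of cell-type-specific proteins; log2 effect (4-fold) in one "up" group |
| `sigma_sample` | 0.3 | SD of per-run loading shifts (log2) |
| `sigma_noise` | 0.25 | residual measurement noise SD (log2) |
| `kappa`, `tau` | 1.0, 21 | MNAR logistic censoring: P(miss) = 1/(1+e^{−κ(τ−x)}); κ = 0 disables |
| `rho` | 0.02 | MCAR dropout rate |

Cell-type mixing happens on the linear scale (ion signal is additive) and
is logged afterwards. The default grid layout mimics a uterine cross
section: stroma background, a contiguous pure-LE band, Poisson-placed
GE/S-mixed spots; `pure_group_design` builds the pooled 3 × n
dominant-cell-population layout. Independent RNG streams (truth, noise,
missingness) are spawned from the master seed, so toggling missingness
never perturbs abundances.

What the generator does **not** emulate: correlated peptide noise within a
run, retention-time or batch drift, match-between-runs transfer artefacts,
interference/co-isolation effects, and real annotation structure. Passing
tests therefore demonstrate the correctness and calibration of the
*procedures* under the stated model, not performance on any particular
real tissue dataset.

## Numerical choices and problem sizes

Tie handling is average-rank everywhere ranks occur; all order-dependent
selections (reference peptides, gallery ordering, group pair enumeration)
have deterministic tie-breaks, and identical config + seed reproduce
byte-identical summary outputs. p-values are clamped into (ε, 1]. The test
suite and `scripts/acceptance.py` use simulation sizes chosen to estimate
each quantity to well inside its assertion tolerance — e.g. 2000 null
proteins for the family-wise error rate (MC SE ≈ 0.5%), 200 replicate
screens of 20 runs for the outlier false-flag rate, 600 proteins for the
pipeline power/bias study — while a full-scale default simulation (2000
proteins, ~10k peptides) remains the generator default.

## Known limitations

* The g-test's chi-square reference is asymptotic; at n = 5 + 5 runs the
  complete-separation p (~2·10⁻⁴) is the smallest attainable, so
  qualitative calls at these group sizes survive Holm only for near-total
  separation — matching the conservative intent.
* The leave-one-out outlier screen can mask pairs of similar outliers
  (see above).
* EASE enrichment treats categories independently; genes in many
  categories create correlated rows.
* No imputation is performed anywhere; abundance-dependent missingness
  biases group means of heavily censored proteins toward their observed
  (upper) tail, which attenuates estimated effects for proteins near the
  detection limit. The parameter-recovery tests quantify the net effect at
  default conditions (median bias < 0.03 log2 units).
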