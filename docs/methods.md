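# Methods

This note documents the models, statistical procedures, parameter
choices, and numerical conventions implemented in sheddex, and what the
synthetic benchmark does and does not establish about real data.

## Data model and coordinate conventions

The central object is a peptide quantification table: one row per
(protein, peptide, start) with nonnegative abundances per sample, sample
groups in {case, control, reference}, and 1-based inclusive residue
coordinates (the UniProt convention, so a literature cleavage site "at
position 688" can be compared directly with a detected boundary).
Missing measurements are represented as absent, never zero; zeros in
input are coerced to missing with a warning because a zero reporter-ion
intensity in isobaric-label data almost always means "not quantified".
A peptide's positional coordinate is its midpoint fraction
(start + end) / (2L); peptides spanning a candidate boundary follow
their midpoint. Peptides mapping to multiple positions within their
protein are dropped rather than assigned to the first occurrence, since
positional ambiguity corrupts the block statistic.

## Preprocessing

- **Rollup**: protein abundance per sample is the sum of its non-missing
  peptide abundances (missing iff all peptides missing). Summation is
  the standard monotone rollup for reporter-ion data.
- **Reference normalization**: each value becomes
  log2(sample / reference) against the pooled reference channel; cells
  with missing or nonpositive reference become missing (with a warning
  in the nonpositive case). The same ratioing is applied at peptide
  level before the cleavage detector. Normalization is invariant to
  rescaling the whole matrix by a positive constant.
- **Completeness filter**: proteins quantified in at least 75% of
  samples within *every* group are retained (the per-peptide analogue
  for the detector uses a strict "over 50% within each group" rule).
- **QC**: per-protein z-scores across samples, then PCA of samples by
  SVD on complete-case proteins (constant proteins enter as zeros — they
  cannot move a PCA). Component signs follow the convention that the
  largest-magnitude loading is positive, making coordinates
  reproducible. A sample is flagged as an outlier when it lies more than
  k·MAD (default k = 4) from the median on PC1 or PC2 — a robust,
  parameter-light formalization of PCA-based outlier removal. With few
  samples the MAD is itself noisy, so borderline neighbours of a gross
  outlier may be co-flagged; flags are advisory, removal is the user's
  decision.
- **Clustering**: samples and proteins are clustered by average linkage
  on 1 − Pearson distance over z-scored values (the common default for
  expression heatmaps; the choice is configurable and tested against a
  brute-force agglomeration oracle). Zero-variance rows are excluded
  with a warning; dendrograms can be exported as Newick.

## Differential expression

Per protein, a pooled-variance two-group comparison on log2 ratios.
Residual variances s²_g with d_g = n₁ + n₂ − 2 degrees of freedom are
shrunk toward a prior via the scaled-F hierarchical model: assuming
s²_g ~ s₀² F(d_g, d₀), the log-variances have closed-form moments in
digamma/trigamma functions, giving moment-matching estimates of
(d₀, s₀²) (trigamma inversion by Newton iteration; zero variances are
excluded from the fit; when the observed spread of log-variances is no
wider than sampling alone explains, d₀ = ∞ and all variances pool). The
moderated statistic t̃ = logFC / (s̃ √(1/n₁ + 1/n₂)) with
s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g) is referred to a t distribution on
d₀ + d_g df (normal when d₀ = ∞). Setting the prior df to 0 recovers the
ordinary Student t exactly — a tested limit. Benjamini–Hochberg step-up
adjustment (via statsmodels, cross-checked against a brute-force oracle)
and calling at adj p < 0.05 with |logFC| ≥ log2(1.5) complete the
analysis. The implementation is verified against Bioconductor limma on a
shared fixture. Pooled variance (not Welch) is used throughout for
fidelity to the linear-model framework; TMT-set blocking and covariates
are out of scope.

## The terminal-block cleavage detector

Peptide-level statistics: peptides quantified in over 50% of samples in
each group get a log2FC (difference of group means of log2 ratios) and a
two-sided pooled-variance Student t p-value. Proteins with ≥ 4 retained
peptides enter the sweep: boundaries b = 0.05, 0.06, …, 0.95 (91 values)
partition peptides by midpoint into an N-anchored block (midpoint ≤ b)
and the rest. Boundaries leaving fewer than 2 peptides on either side
are emitted flagged invalid with p_sep = 1. At each valid boundary:
factor = median block log2FC − median rest log2FC, and p_sep = two-sample
Student t on the peptide log2FC values, block vs rest. Since all
boundaries falling between the same two adjacent midpoints induce the
same partition, each distinct partition is evaluated once and mapped
back to the grid — an exact optimization, not an approximation.

Call criteria (all at one boundary): the *changed segment* — whichever
side has the larger median |log2FC| (ties resolve to the block) — must
contain ≥ 2 individually significant peptides (raw p < 0.05,
|log2FC| ≥ log2 1.5, sign matching the segment median); |factor| ≥
log2 1.5; p_sep < 0.05; and the unchanged segment must be flat
(median |log2FC| < log2 1.5). The flatness guard is what separates
differential cleavage from differential secretion: a uniformly shifted
protein has both segments moved and fails it by construction. The
single N-anchored sweep covers both termini — a C-terminal event simply
presents with the rest as the changed segment — and the terminus is
assigned post hoc by which side moved; both directions (reduced or
increased in case) are detected and labeled. The best boundary minimizes
p_sep with ties to the smallest boundary; because ties within a
between-peptide gap are systematic, the reported boundary is the
smallest grid point giving the winning partition, i.e. essentially the
midpoint of the last changed peptide. Boundary resolution is therefore
limited by peptide spacing (~1–3% of protein length at typical tryptic
coverage).

No multiplicity correction is applied across the 91 boundaries within a
protein; the best-boundary p_sep is descriptive, and the family-wise
consequence is bounded empirically by the null-calibration test (called
fraction ≤ 5% with nothing planted; in practice the compound criteria
drive it to ~0). "Multiple peptides" is read minimally as ≥ 2
(configurable). A site-report layer converts b\*·L to a residue and
reports the distance to user-supplied annotated cleavage sites, without
thresholding.

## Annotation

Topology classification joins each call to a UniProt-style controlled
vocabulary (single-pass type I/II, GPI-anchored, multi-pass, secreted,
other; unannotated → unknown). Protease attribution is set-membership
against a curated MEROPS-style (protease, substrate) table — binary, not
evidence-weighted, matching how such heatmaps are read — and sheddases
are ranked by the number of called substrates they support, ties broken
alphabetically. Annotation never changes the called set or its
statistics. A Fisher exact test of class over-representation against the
background of all quantified proteins is provided as a labeled
extension. Live UniProt/MEROPS retrieval is deliberately out of scope;
tables are plain TSV.

## Correlation maps

Within one group, pairwise-complete Pearson correlations between
proteins, with pairs sharing fewer than n_min = 5 observations masked
(avoiding imputation while bounding unstable estimates) and
zero-variance proteins excluded. Clusters come from cutting the
average-linkage tree on 1 − r distance at a requested count or height;
masked pairs enter the tree at distance 1 (uncorrelated — they carry no
evidence either way). Cluster count is a user parameter; functional
annotation of clusters is out of scope.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- random 300–900 residue protein sequences (uniform over the 20 standard
  residues), digested with the trypsin rule (cleave after K/R except
  before P), peptides of 7–30 residues with up to one missed cleavage,
  ≥ 4 peptides per protein (~68 peptides/protein in practice);
- protein baselines lognormal with log10-sd 1.0 (~4 orders of magnitude
  across proteins, stressing normalization), per-peptide lognormal
  ionization factors (ln-sd 1.0) decoupling peptide from protein
  abundance — the within-protein variability the block test must beat;
- planted events: shed proteins get a fold (default 1/3) applied to
  case-group peptides on one side of a boundary (uniform in [0.2, 0.8],
  placed so ≥ 3 peptide midpoints fall on the changed side — otherwise
  the event would be undetectable by construction); secretion proteins
  get a uniform fold (default 2) on all case-group peptides; side
  membership uses the same midpoint convention as the detector so
  boundary-recovery error is well-defined;
- multiplicative lognormal noise with cv 0.2 and independent 10%
  missingness by default. The study data carry no stated noise or
  missingness magnitudes, so these are calibration choices fixed once at
  values typical for deep TMT experiments, not fitted quantities. An
  intensity-independent missingness model is the simplest that exercises
  the completeness filters;
- a pooled-reference column, the geometric mean of all sample
  intensities per peptide (emulating a physically pooled reference
  channel), never missing.

Default design is 15 vs 15 samples for the benchmark (the package also
supports the 18 vs 20 clinical-style design). All randomness flows from
integer seeds; fixed-seed outputs are byte-identical.

What the generator does *not* model: spectra, retention time,
search-engine FDR, isotopic interference/ratio compression, shared
(razor) peptides, intensity-dependent missingness (available as an
option but off by default), batch structure across TMT sets, and real
protein sequence composition. Passing the recovery benchmarks therefore
shows the detector is correct and calibrated *under its own
assumptions*; on real data, ratio compression and peptide-level
interference will compress factors toward zero, and the 50% completeness
rule interacts with informative missingness. Sensitivity on real data
should be expected to be lower than on the benchmark at equal fold.

## Benchmark results the test suite computes

Under the default conditions (300 proteins, 15/group, cv 0.2, 10%
missing, 30 shed events at fold 1/3 with ≥ 3 block peptides, 30 uniform
2-fold secretion shifts), the acceptance tests assert sensitivity ≥ 0.8,
empirical FDR ≤ 0.1, and median boundary error ≤ 5 percentage points
(measured values in recent runs: 1.0, 0.0, ≈ 0.8 pp); called fraction
≤ 5% on each of ten null simulations; secretion-only call rate ≤ 5%
with shifts up to 3-fold; DE sensitivity ≥ 0.9 at FDR ≤ 0.1 for 50
planted 2-fold proteins among 500 nulls; exact agreement of the detector,
BH adjustment, and average-linkage clustering with independent
brute-force oracles; ordinary-t and pooled-variance limits of the
moderated t; and bit-identical fixed-seed reruns with lossless table
round-trips. Problem sizes were chosen so the whole suite completes in a
few minutes on one CPU while keeping every binomial bound meaningful.

## Numerical conventions and degenerate inputs

Student t with zero pooled variance returns p = 1 for equal means and
p = 0 otherwise (the limit); identical groups give t = 0, p = 1,
log2FC = 0. Boundary grid values are rounded to 10 decimals to keep
midpoint comparisons exact. Trigamma inversion starts at the asymptotic
0.5 + 1/y and is Newton-iterated to 1e-10 relative. Medians of
even-sized sets are midpoint averages (the numpy/statistics convention,
shared by implementation and oracles). Empty call sets, empty databases,
missing annotations, and proteins below the peptide minimum are all
legal inputs yielding empty (not error) outputs; malformed tables,
unknown vocabulary tokens, negative abundances, and coordinate
violations are hard errors naming the offending row or column.

## Known limitations

Isoform-unaware (one sequence per accession); no semi-tryptic
neo-terminus inference from spectra (cleavage sites are localized only
to the peptide grid); no TMT-set batch correction beyond reference
ratioing; no imputation anywhere by design; the boundary is reported at
the resolution of peptide coverage, biased toward the changed segment's
last peptide midpoint; and protease attribution inherits whatever
ascertainment bias the supplied substrate database carries.
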