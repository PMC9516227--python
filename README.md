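# sheddex

Peptide-centric detection of impaired ectodomain shedding from two-group
quantitative proteomics.

## The problem

Sheddases (membrane proteases such as ADAM10, ADAM17, BACE1) release the
extracellular domains of single-pass membrane proteins into the
surrounding fluid. When shedding activity changes between two clinical
groups — for example between proliferative diabetic retinopathy (case)
and epiretinal membrane (control) vitreous — the released ectodomain
fragments change in abundance, but only on *one side* of the cleavage
site. A protein that is simply secreted more or less changes uniformly
along its whole length. Protein-level differential expression cannot tell
these apart; the positional pattern of the protein's *peptides* can.

sheddex implements that peptide-centric analysis for anyone with a
peptide-level quantification table from an isobaric-label (TMT-style)
case/control experiment: proteomics cores, degradomics groups, and method
developers who want a tested, scriptable reference implementation with a
calibrated synthetic benchmark.

## The method

For each protein with at least 4 quantified peptides (each quantified in
over 50% of samples within each group), every peptide *i* gets a log2
fold change Δᵢ (case − control mean of log2 reference ratios), a
two-sided pooled-variance Student *t* p-value pᵢ, and a positional
coordinate mᵢ = (startᵢ + endᵢ) / (2L) ∈ (0, 1], the midpoint fraction of
the protein length L.

A candidate cleavage boundary *b* is swept from 5% to 95% of the protein
length in 1% steps (91 boundaries). At each *b* the peptides split into
an N-terminal block B(b) = {i : mᵢ ≤ b} and the rest R(b), and we compute

- **factor(b)** = median{Δᵢ : i ∈ B} − median{Δᵢ : i ∈ R}, and
- **p_sep(b)**, a two-sample Student t-test of {Δᵢ : i ∈ B} vs {Δᵢ : i ∈ R}.

The *changed segment* at *b* is whichever of B, R has the larger median
|Δᵢ|. A protein is called a putative cleavage substrate if some boundary
satisfies all of:

1. ≥ 2 peptides in the changed segment are individually significant
   (pᵢ < 0.05, |Δᵢ| ≥ log₂ 1.5, sign matching the segment median);
2. |factor(b)| ≥ log₂ 1.5;
3. p_sep(b) < 0.05;
4. the unchanged segment is flat: median |Δᵢ| < log₂ 1.5 — the guard that
   rejects proteins that are only differentially secreted.

The reported boundary b\* minimizes p_sep; the changed terminus (N or C)
and direction (reduced/increased in case) are read off the winning
segment. Upstream of the detector, the package provides reference-channel
normalization (log2 sample/reference), protein rollup, 75% per-group
completeness filtering, PCA outlier QC, limma-style empirical-Bayes
moderated-t differential expression with Benjamini–Hochberg adjustment
(adj p < 0.05, ≥ 1.5-fold), within-group Pearson correlation maps with
dendrogram cluster extraction, topology classification, and
protease–substrate attribution. A synthetic-data module generates
two-group peptide tables with planted shedding and secretion events so
every claim is testable against known truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic dataset (300 proteins of 300–900 residues, 15 case and
15 control samples, lognormal noise cv 0.2, 10% missing cells, 30 planted
shed events at fold 1/3 and 30 uniform 2-fold secretion shifts):

```sh
python analysis/01_simulate.py              # writes results/sim/
python analysis/02_preprocess_qc.py
python analysis/03_differential_expression.py
python analysis/04_shedding_detection.py
python analysis/05_annotate_substrates.py
python analysis/06_correlation_map.py
```

Output from a run with the default seed:

```
simulated 20368 peptides over 300 proteins (67.9 peptides/protein)
300 proteins rolled up; 300 pass the 75% per-group completeness filter
moderated t: prior df d0 = 8.42, s0^2 = 0.0113
38 of 300 proteins differentially expressed (adj p < 0.05, |FC| >= 1.5)
30 of 30 planted secretion shifts recovered at the protein level
30 substrate calls; sensitivity 1.00, empirical FDR 0.000, median boundary error 0.84 percentage points
17 N-terminal and 13 C-terminal events; directions: {'reduced_in_case': 30}
single-pass type I enrichment: 24 called vs 4.4 expected (Fisher p = 3.82e-18)
top sheddases:
  ADAM10: 18 substrates
```

Reading this: the protein-level analysis finds the uniformly shifted
(secretion) proteins, while the terminal-block detector finds exactly the
30 planted cleavage events — none of the secretion decoys — and localizes
each planted boundary to within about one percent of the protein length.
The annotation stage then recovers the planted topology enrichment and
ranks the focal sheddase first. The same machinery is available as a CLI
(`sheddex simulate|preprocess|de|shed|annotate|corrmap|run`) and as a
library (`sheddex.detect_substrates`, `sheddex.de_analysis`, ...).

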