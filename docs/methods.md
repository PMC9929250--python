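# Methods

This note documents the statistical procedures implemented in `multiprot`,
the conventions fixed where the field leaves choices open, what the
synthetic cohort generator does and does not emulate, and the package's
known limitations.

## Data model

Three abundance layers (proteome, phospho-proteome, TF DNA-binding
activity) are features × samples matrices sharing one sample table; each
patient contributes at most one tumor and one NAT sample and has a single
Lauren histology (DGC / IGC / MGC). Missing entries mean "not detected".
Identifiers are opaque case-sensitive symbols; phospho-sites render as
`PROTEIN_S123` with 1-based residue positions on the protein sequence. No
identifier mapping, genomic coordinates, or spectra processing exists
anywhere in the package — the pipeline starts at quantified intensity
matrices.

## Normalization and QC

- **FOT** (proteome): each column is divided by its sum over observed
  entries and scaled by 10⁶, so every sample's observed values sum to 1e6.
  Missing entries stay missing. Column scaling removes per-sample loading
  and acquisition offsets exactly on the log scale.
- **Quantile normalization** (phospho, TF layers): every column is forced
  onto the cross-column mean of order statistics. Columns with missing
  entries contribute (and receive) their empirical quantile function by
  linear interpolation on a common grid. Ties within a column receive the
  mean of the reference values they span, so tied inputs stay tied. The
  procedure is idempotent up to tie handling and is cross-checked against
  `limma::normalizeQuantiles` in the test-suite.
- **Imputation**: missing values take the layer-wide minimum observed
  value. This convention presumes missingness concentrates at low
  abundance (detection limits), which is exactly how the generator creates
  it; with a minimum-value imputer, imputing before or after the log2
  transform gives identical values.
- **Sample QC**: a sample is flagged when the median of its observed log2
  values exceeds Q3 + 1.5·IQR of the cohort's median distribution.
  Quartiles use linear interpolation between order statistics (the common
  "type 7" convention), fixed here because the rule is otherwise not
  reproducible. An opt-in bimodality screen (Hartigan-style dip statistic,
  greatest-convex-minorant construction, configurable threshold) is
  disabled by default since no printed criterion exists for it. Exclusions
  propagate to the tumor/NAT partner (`partner_failed`); the retained set
  contains only complete pairs.

## Differential screens

Paired tumor-vs-NAT contrasts use the Wilcoxon signed-rank test
(zero differences dropped; exact null for n ≤ 25 without ties in the
absolute differences, otherwise the normal approximation with continuity
and tie correction). Unpaired contrasts use the Mann–Whitney rank-sum test
(exact when min(n) ≤ 10 without ties). Multiplicity is controlled with
Benjamini–Hochberg step-up adjustment. Fold changes are computed on the
linear scale; the default aggregator is the median of per-pair ratios for
paired screens and the ratio of group medians for unpaired screens —
medians for robustness, with the mean-ratio variant selectable. DEPs are
called at FC > 2 (strict) and adjusted p < 0.05.

The six-group partition first requires a ≥ 2-fold difference between the
DGC and IGC tumor/NAT ratios, then splits concordantly regulated features
by which histology dominates (ratio-of-ratios ≥ 2, which under the entry
filter is equivalent to the direction of the ratio-of-ratios) and assigns
discordant features to the two converse groups. The within-partition
dominance rule is a declared convention validated by group disjointness.

## KSEA

A kinase with m ≥ 3 quantified substrate sites scores
z = (s̄ − p̄)·√m / δ, where s̄ is the mean substrate log2 fold change and
p̄, δ the mean and SD of all quantified site log2 fold changes. The score
is antisymmetric under negating all fold changes and invariant to positive
rescaling. Significance uses a permutation null — substrate sets of size m
redrawn without replacement from all sites — with add-one correction
p = (b+1)/(n+1). Sites mapped to several kinases contribute to each.
Per-patient kinase activity matrices (for the kinase→TF network) apply the
same score to each patient's site-level tumor/NAT log2 ratios.

## TF activity

TFRE enrichment compares each protein's mean normalized abundance in the
TF (DNA pull-down) layer to the proteome; mean across samples is the
aggregator, enrichment is strict ratio > 4, and annotated TFs are always
reported. Master-TF nomination is the conjunction of (a) paired
tumor-vs-NAT activity up (signed-rank p < 0.05, FC > 1.5), (b) one-vs-rest
subtype activity up (rank-sum p < 0.05, FC > 1.5), and (c) upper-tail
hypergeometric enrichment (p < 0.05) of the TF's network targets among the
caller-supplied DEP set. The FC bars for (a)/(b) sit below the 2× DEP bar
because TF activities are noisier than protein abundances; both are
configurable. The hypergeometric universe defaults to all quantified
proteins (not network targets), and the DEP set may be the up- or
down-regulated side per query, which covers repressor-style TFs. The
kinase–TF network keeps Spearman correlations with rho > 0 and p < 0.05
(exact permutation null for n ≤ 9, t-approximation otherwise).

## Consensus clustering and k selection

Monti-style consensus: 1000 repetitions, each subsampling 80% of samples
and cutting an average-linkage Euclidean dendrogram at each k in 2…6;
consensus(i,j) = co-clustered / co-sampled counts; final labels cut the
average-linkage tree of 1 − consensus. Feature selection is the caller's
(e.g. tumor-upregulated proteins; the ">50% detection" pre-filter belongs
upstream). k is the argmax of the delta-area of the consensus CDF
(Δ(2) = A(2), Δ(k) = (A(k) − A(k−1))/A(k−1)). A selection is flagged
ambiguous when PAC (share of consensus entries in (0.1, 0.9)) exceeds 0.3
at the chosen k, or when the chosen partition is degenerate — a cluster
holding under 10% of samples, the signature of structureless data where
hierarchical cuts peel off stable outlier singletons. Survival, when
supplied, yields an advisory log-rank p per k and never overrides the
delta-area choice. Subset percentages in concordance reports round half
away from zero.

## LPS classifier

Features (by default the two discriminating TFs' activities) are z-scored
on the training cohort; each feature's weight is its two-sample pooled
t-statistic between classes; a sample's LPS is the weighted z sum. Each
class's LPS distribution is fitted as a Gaussian (MLE), priors are uniform
(the predictor targets external cohorts of unknown composition), and
Bayes' rule yields the posterior; calls require ≥ 75% certainty by default
with a strict argmax mode behind a flag. External cohorts are standardized
with their own per-feature mean/SD, following the per-cohort z-score
convention; training-parameter standardization is available. In the far
tails where both class densities underflow, the nearer class in SD units
receives posterior 1.

## Immune scoring and cell cycle

The cell-type engine is a single-sample rank-based enrichment score: genes
ranked by descending expression; score = Σ(weighted in-set ECDF − out-set
ECDF)/(n − m) with in-set weights |value|^α, α = 0.25 (α = 0 makes the
score a pure rank statistic, invariant to monotone transforms). The
normalizing constant only fixes the scale; every downstream use (ranks,
ratios, clustering) is scale-free. Aggregates follow the
microenvironment-score convention: immune score = mean of immune-category
cell scores, stroma likewise, microenvironment = immune + stroma. The
published 64-signature compendium and its spillover compensation are *not*
reimplemented; signatures are user-supplied GMT sets and the validation
surface is recovery of planted profiles, never numeric parity with
published scores. The Th1/Th2 ratio divides the two cell scores (defined
when the Th2 score is positive).

Cell-cycle module scores bin genes into 24 equal-frequency bins of average
expression and draw 100 control genes (with replacement, excluding set
genes) from each set gene's bin; score = mean(set) − mean(controls) per
sample, seeded. Phases: S if s > g2m and s > 0; G2M if g2m ≥ s and
g2m > 0; else G1.

## Clinical statistics

Kaplan–Meier product-limit estimates with Greenwood bands, the
observed-minus-expected log-rank chi-square, and Cox partial-likelihood
hazard ratios with Efron tie handling and Wald 95% CIs (all via lifelines,
validated against independently coded oracles in the test-suite). The
optimal cutpoint scans candidate splits between the marker's 10th and 90th
percentiles and maximizes the standardized log-rank score sum — per-subject
log-rank scores (event indicator minus Nelson–Aalen cumulative hazard)
standardized by their permutation mean and variance, the
maximally-selected-rank-statistic construction. The multiple-testing
correction for the maximally selected statistic is deliberately not
applied; an optional permutation reference reports how often an unrelated
marker reaches the observed maximum. Cis/trans screening runs a two-sided
Fisher exact test per (mutated gene, protein) on mutated/WT × up/not-up
tables under a caller-supplied dichotomization, BH-adjusted within each
gene; cis means the protein symbol equals the mutated gene.

## Synthetic cohorts

The generator draws per-feature baselines μ_f ~ U(16, 24) on the log2
scale with per-sample offsets N(0, 0.15) and residual noise N(0, 0.5),
then adds planted effects and exponentiates. Defaults define the reference
conditions used throughout the tests: 40 DGC + 50 IGC patients (tumor/NAT
pairs), 2000 proteins, 3000 phospho-sites, 150 TF features.

- **Differential program**: 10% of proteins per histology at ±2 log2
  (60% up), plus three proteomic subtypes per histology carried by 60
  signature proteins each (tumor-wide +2 with a +1.5 boost in the own
  subtype). All planted programs are drawn from the lower-abundance half
  of the proteome (baseline μ ≤ 20), so the stable high-abundance
  background dominates column totals and FOT ratios are not distorted by
  the planted mass — the standard "most protein mass unchanged" assumption
  of relative quantification, made explicit.
- **TF layer**: each TF's activity is its protein row plus N(0, 0.4) —
  binding activity tracks abundance noisily — with two TF subtypes per
  histology carried by 15 boosted TFs each (tumor-wide +1.5, own-subtype
  +2.0). The first boosted TF per subtype is the master: its 15 network
  targets shift +1.5 in that subtype's tumors. Non-master TFs receive
  random targets drawn away from master-target genes, so target enrichment
  separates masters by construction rather than by luck.
- **Kinases**: 30 kinases × 15 disjoint substrate sites; 5 active kinases
  shift their substrates ±1.2 in all tumor samples (two planted down).
  Shifts are cohort-wide because activity recovery is measured on
  cohort-level tumor/NAT ratios; a per-kinase scope hook exists in the
  ground truth.
- **Mutations**: a 20-gene panel; two effect genes mutate in ~25% of
  patients with a −2 cis effect on their own protein and +1.5 trans
  effects on 10 target proteins; the rest mutate at 10% with no effect.
- **Microenvironment**: six toy cell types (Th1, Th2, macrophage, NK
  immune; fibroblast stroma; epithelial other) with 25 markers each;
  patient weights are Dirichlet(1) and tumor marker intensities shift by
  2·weight.
- **Missingness**: P(missing | x) = 1/(1 + exp((x − 14.5)/1)) in log2
  abundance — logistic detection limits giving ~3% overall missingness
  concentrated in the lowest deciles, matching the minimum-value
  imputation convention (MNAR).
- **Survival**: exponential DFS/OS with per-subtype hazard multipliers
  (1.0, 2.0, 3.5) on a 0.02/month baseline and uniform censoring on
  [0, 60] months — the simplest model under which KM/log-rank/Cox recover
  the planted ratios.
- **Randomness**: two fixed-order `numpy` Generator streams — structure
  (feature identities, planted sets, network, kinase map) and noise
  (patients, intensities, labels, mutations, survival) — so cohorts
  sharing a structure seed share their planted contrasts and form
  training/validation pairs for the classifier.

`CohortParams.null()` zeroes every planted effect and equalizes hazards
for type-I-error calibration.

What the generator does **not** emulate: batch effects and run-order
drift, peptide-level quantification and razor-protein ambiguity,
correlated co-regulation beyond the planted blocks, informative censoring,
and intratumor heterogeneity. Passing recovery tests therefore
demonstrates the pipeline's correctness under its stated assumptions, not
robustness to real-data artifacts outside them.

## Problem sizes and runtime

Unit tests run on a reduced cohort (12 + 14 patients, 400 proteins, 500
sites, 40 TFs) for speed; end-to-end recovery and calibration tests use
the full default generator. The complete suite runs in about a minute and
a half on one CPU; `scripts/acceptance.py` takes about one minute. Exact
small-sample tests (signed-rank n ≤ 8, rank-sum ≤ 6 per arm, Fisher
n ≤ 12, hypergeometric tails, BH, KM, log-rank) are compared against
enumeration oracles at 1e-10; Cox estimates match an independent Newton
solver within the fitter's convergence tolerance (1e-4).

## Known limitations

- The signed-rank exact path requires tie-free absolute differences; with
  ties it falls back to the corrected normal approximation even at small n.
- Consensus clustering treats never-co-sampled pairs as consensus 0 (with
  a count recorded); at the default 0.8 subsampling and ≥ 100 repetitions
  this is vanishingly rare.
- The delta-area argmax can prefer k = 2 when a coarser merge of the true
  clusters is itself highly stable; the ambiguity flag and the advisory
  survival report are the guard rails, mirroring how the choice is made in
  practice.
- The maximally selected cutpoint statistic is reported without the
  asymptotic selection-bias correction; use the permutation reference when
  an honest p-value is needed.
- The exact Fisher and small-sample rank tests are conservative by
  construction; their null positive rates sit below the nominal level.
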