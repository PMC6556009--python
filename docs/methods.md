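# Methods

## Normalization model

nCounter counts are digital hybridization counts for four probe classes.
The pipeline applies, in order:

1. **Background correction** — per sample, background = mean of the eight
   negative-control probes (alternatives `mean2sd`, `max` via config);
   endogenous and reference counts become `max(count - background, 1)`.
   The floor of 1 keeps later log transforms finite and makes geometric
   means well defined; negative controls are retained for QC reporting.
2. **Positive-control scaling** — per sample, all non-negative-control
   counts are multiplied by (grand geometric mean of per-sample
   positive-control geometric means) / (sample's positive-control
   geometric mean), equalizing hybridization efficiency across lanes.
3. **Sample QC** — a sample fails if its total endogenous+reference count
   is below `min_total_counts` (default 2000) or if fewer than
   `min_frac_above_background` (default 50%) of endogenous probes exceed
   its background. The defaults are deliberately permissive: they catch
   degraded/failed assays, not biological outliers.
4. **Reference-gene normalization** — per sample,
   `value(g) = log2(count g) - mean over reference genes of log2(count)`,
   i.e. log2 expression relative to the geometric mean of the chosen
   housekeepers. Reference genes therefore average exactly 0 in every
   sample, and the chain is exactly invariant to per-sample multiplicative
   scaling of the raw counts.

Scores are evaluated on **per-score normalizations**: each signature's
expression is re-normalized against that signature's own reference genes
(3 for RISK, 5 for RS, 3 for EP, 5 for the classifier), not the pooled
12-gene set. The pooled set is used for the cohort-wide expression matrix
and clustering.

## Scores and subscores

A signature is groups of (gene, gene-weight) members with a group weight
and an optional intercept; the score is the group-weight-weighted sum of
gene-weight-weighted group means. Genes absent from the panel are dropped
with a warning and the remaining gene weights renormalized — the same
policy applied to the two classifier genes (CDC6, NUF2) missing from the
panel. RS keeps its published research form: group thresholds and the
0–100 rescaling are omitted (an off-by-default config flag restores
clipping). RS and EP are only reported for ER+/HER2− tumours as judged by
IHC; other samples carry NaN, never an imputed value. Groups tagged
PRO/ER/PR/HER2 are additionally emitted as named subscores; ROR-P's
PRO-subscore is the mean expression of the classifier's proliferation
subset.

ROR-P correlates each sample with the five subtype centroids (Spearman by
default, Pearson via config; minimum gene overlap 30) and combines the
correlations linearly with a proliferation term.

## Subtyping

PAM50-style calls standardize each gene across the cohort — robust mode:
median-centred, scaled by the 5–95% inner-quantile range (quantiles
configurable); z-score and passthrough modes provided — then take the
argmax of the Spearman correlations to the centroids. Exact ties (near
impossible on continuous data) break by the fixed priority
basal > Her2 > lumB > lumA > normal, logged. Because the cohort-level
standardization depends on cohort composition, calls on very small
cohorts are noisier than on ~100+ samples.

IHC surrogates use the standard rule table: hormone-receptor-positive
(ER and/or PR at ≥1% labelling) tumours are lumA when HER2− and Ki-67
low (<14%), lumB when HER2− and Ki-67 high or when HER2+; receptor-
negative tumours are Her2-enriched when HER2+ and basal otherwise. An
unresolved HER2 2+ (no FISH) or a missing needed marker yields
`unknown`; normal-like is never assigned by IHC, so IHC-vs-PAM50 kappa
excludes normal-like molecular calls and unknown surrogates.

## Statistics

- Spearman matrices are pairwise-complete with per-cell n; cells with
  n < 3 are undefined.
- Tertile dichotomization labels the ceil(n/3) largest values "high";
  ties at the cut resolve by stable sample-id order with a warning.
- Cohen's kappa is unweighted, any number of categories, with the
  convention kappa = 1 when both raters are constant and identical
  (chance agreement 1 would otherwise divide by zero).
- Mann-Whitney is exact (scipy enumeration) when combined n ≤ 12 without
  ties, else the normal approximation with tie and continuity correction;
  the mode is recorded. The exact mode is property-tested against an
  independent full enumeration of label assignments.
- The per-gene group screen reports unadjusted two-tailed p-values by
  default (matching a priori alpha = 0.05 single-comparison usage), with
  optional Benjamini–Hochberg q-values.

## Clustering and matched pairs

Samples are clustered agglomeratively (average linkage by default;
complete/ward via config) on Euclidean distance over the 74-gene union of
the signatures' measured test genes. "Pairs clustering in the vicinity of
each other" is formalized as leaf-order distance ≤ w (default w = 2) on
the standard scipy leaf ordering (no optimal-leaf-ordering, which would
change vicinity counts), and assessed against a permutation null: sample
positions are permuted and the p-value is the add-one-smoothed fraction
of permutations reaching the observed vicinity count.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis consumes,
not the biology generating it:

- **Panel**: 84 endogenous test genes, 12 reference genes, 8 negative and
  6 positive controls; the union of the four signatures' measured test
  genes is 74; CDC6/NUF2 are declared by the classifier but unmeasured.
- **Expression**: per-gene log2 mean = frozen base level (uniform 6–9)
  + subtype centroid deviation + per-group program shifts + an individual
  tumour deviation (SD 0.3 log2). Five programs (proliferation, oestrogen
  response, ERBB2/GRB7, basal keratins, luminal epithelial) define the
  centroid structure, with per-gene jitter (SD 0.25) so genes within a
  program carry distinct ranks.
- **Counts**: negative binomial around `library_size * 2^mu`, dispersion
  0.1 (overdispersed, as digital counts of heterogeneous tissue are);
  library sizes log-normal (sigma 0.25); reference genes constant-mean;
  negative controls Poisson(4); positive controls a fixed spike-in ladder
  scaled by lane efficiency. Degraded samples shrink endogenous/reference
  counts by 250x while positives stay — the signature of degraded RNA
  with intact spike-ins.
- **Cohort**: group sizes 43/25/20/19/25 with subtype mixtures matching
  the clinical picture (brain-metastasis groups enriched for
  HER2-enriched/basal and high proliferation); the brain-metastasis
  groups additionally carry a +1.1 log2 proliferation shift (about +2 SD
  of per-gene noise). 19 local and 19 brain matched pairs: the recurrence
  re-draws the primary's subtype with concordance 0.3 (local) / 0.9
  (brain) and shares its individual deviation with correlation 0.2 / 0.8.
- **IHC**: markers drawn from subtype-canonical ranges; at zero noise the
  surrogate rules recover every non-normal subtype exactly; each marker
  is independently randomized with probability 0.15 (default), placing
  IHC-vs-truth agreement in the moderate kappa band (~0.5–0.7); small
  missing rates produce unresolved 2+ and missing Ki-67 entries.

What passing tests on this generator do **not** show: robustness to real
FFPE artefacts (strand breaks, cross-hybridization), to real PAM50
centroids and coefficient sets (the packaged ones are synthetic
stand-ins), or to batch structure; the generator has no gene–gene
correlation beyond the program structure and no clonal evolution in
matched pairs (recurrences are re-draws, not evolved genomes).

## Problem sizes and determinism

All stochastic steps take explicit seeds (numpy `default_rng`); identical
config + seed reproduces every table byte for byte, and each output
carries the run-manifest hash. Simulation-based checks use cohorts of
120–300 samples, 24–36 replicate cohorts for calibration (~2000–3000 null
p-values) and 2000–10000 permutations for the pair-proximity null — sizes
at which Monte-Carlo error is small against the tested margins while the
whole suite runs in seconds.

## Known limitations

- Packaged RISK/EP weights, ROR-P coefficients and centroids are
  synthetic; absolute score values are not comparable to commercial
  assays, only the pipeline's relative statements are meaningful.
- Clinical risk categories (low/intermediate/high), EPclin and
  survival modelling are out of scope.
- RCC vendor archives are not parsed; input is a delimited count table
  with a probe-class column.
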