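# Methods

This note documents the models, rules and numerical choices behind
`egcstrat`, and what the synthetic cohorts it tests itself on do and do not
emulate.

## Setting

Early gastric cancer (EGC) — carcinoma confined to mucosa/submucosa — is
usually indolent, but the Kodama Pen A subtype (nodular massive submucosal
invasion) carries a markedly worse prognosis than Pen B (sawtooth invasion).
The package implements a stratification analysis for small surgical EGC
series profiled with a targeted oncology panel: somatic variant filtering,
tumor mutational burden (TMB) and microsatellite instability (MSI) calling,
pathway-level disruption scoring, unsupervised patient clustering, and
disease-free-survival (DFS) modelling, with group comparisons throughout.

## Variant model and filtering

A variant is a per-patient annotated call: gene, 1-based coordinates,
ref/alt, protein-effect class (missense, nonsense, frameshift/in-frame
indel, splice, synonymous, noncoding), read depth, variant allele fraction
(VAF) and an ACMG/AMP tier (pathogenic, likely pathogenic, VUS, likely
benign, benign). Effect and tier vocabularies are closed enums; unknown
labels are rejected at parse time with the offending row, never coerced.

Retention requires depth ≥ 100 reads and VAF ≥ 5% (both inclusive: a call at
exactly 100x / 5% passes), and an effect outside {synonymous, noncoding}.
Splice variants are retained — the exclusion targets non-exonic,
non-splicing and synonymous calls, not splice sites. The VAF comparison
absorbs a 1e-12 tolerance so "5%" converted to 0.05 in text never trips
float noise. The reader keeps every ACMG class; downstream stages decide
what to exclude (benign calls count toward cohort composition summaries,
never toward pathway scores or oncoprints; TMB counts them by default, with
a switch to exclude them, since panel TMB definitions differ on this point).

The transition/transversion split is computed over single-nucleotide
substitutions only: purine↔purine or pyrimidine↔pyrimidine is a transition,
anything crossing the classes a transversion; multi-base alleles are
excluded from the denominator.

## TMB and MSI

TMB = (filtered eligible mutations) / (panel megabases). The panel footprint
is an explicit parameter (default 1.33 Mb, the order of a ~500-gene design's
effective coding territory); TMB is meaningless without it, so it is never
inferred. Class high means TMB ≥ 10 mut/Mb, inclusive at the boundary.

MSI is the fraction of usable microsatellite sites called unstable. A
patient is MSI when the fraction strictly exceeds 20% (exactly 20% is MSS),
and undetermined when fewer than 40 sites are usable — the minimum at which
the fraction is considered estimable. Patients without site data are
undetermined, not MSS.

## Pathway instability (PI) scores

Gene sets come from GMT files; each set carries a top-level label (the root
of its hierarchy, e.g. "Immune System"). Scoring proceeds in two steps.

1. **Alteration profiles.** Per patient, each gene gets the maximum weight
   over its alterations: 1.0 for a pathogenic/likely-pathogenic variant or
   any copy-number event, 0.5 (configurable) when its only non-benign
   alterations are VUS, 0 otherwise. Benign/likely-benign calls contribute
   nothing. The max rule keeps redundant calls from inflating a gene.

2. **Panel-restricted averaging.** For patient *p* and pathway *w*,

       PI(p, w) = Σ_{g ∈ genes(w) ∩ panel} weight_p(g) / |genes(w) ∩ panel|

   Restriction to measured genes avoids deflating scores of large pathways
   the panel barely covers; pathways with no measured gene are dropped with
   a warning rather than scored 0, since an unmeasurable pathway is not
   evidence of stability. Scores lie in [0, 1], with 1 iff every measured
   gene carries a full-weight alteration.

This weighted altered-gene fraction is the package's normative PI
definition; weight scheme, VUS weight and panel restriction are
configurable. Published PI analyses in this area cite supplementary method
definitions that vary in detail, so cross-study numerical identity of PI
values should not be assumed — the in-package properties (oracle equality,
benign invariance, boundedness) are what the tests guarantee.

Pooled top-level comparisons treat each (patient, pathway) score as one
observation: a group of *m* patients against a top level of *k* scored
pathways yields *m·k* points, compared across groups with the Wilcoxon
rank-sum test and Benjamini-Hochberg correction within each grouping
(Kodama class, relapse status, TMB class).

## Statistics

* **2x2 tables**: Fisher's exact test when any expected count under
  independence is below 5, else Pearson chi-square. The two-sided Fisher p
  is the point-probability sum (all tables with fixed margins whose
  probability is at most the observed table's); the chi-square uses the
  closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1 df and no continuity
  correction. These two conventions jointly reproduce, from printed counts,
  the published comparisons this package was validated against (e.g. a
  6/7 vs 0/14 carrier split gives p = 0.0058 → 0.006). Tables wider than
  2x2 (cluster comparisons) use the Pearson chi-square; no exact test for
  general r×k tables is provided.
* **Rank tests**: two-sided Mann-Whitney/Wilcoxon rank-sum; exact
  enumeration when both samples have ≤ 10 observations without ties, else
  normal approximation with tie correction.
* **Multiple testing**: Benjamini-Hochberg step-up, capped at 1,
  order-equivariant.
* **Survival**: univariate Cox proportional hazards on DFS (time from
  surgery to recurrence or death from any cause). Ties use the Breslow
  approximation (the default of the standard survival stacks this mirrors;
  Efron available via statsmodels). Wald hazard ratios with 95% CIs; the
  proportional-hazards assumption is checked by the scaled-Schoenfeld
  residual correlation test (rank time transform). Categorical covariates
  are coded two-level against an explicit reference. Group curves are
  Kaplan-Meier with the k-group log-rank test.
* A pooled-variance two-sample t test is provided for continuous baseline
  summaries, but group means/SDs alone do not determine small-sample p
  exactly when the underlying values are unavailable, so it is not a
  reproduction surface.

## Embedding and clustering

The patients × pathways PI matrix is reduced to 2-D with t-SNE: PCA
initialization, exact gradient (cohorts here are tens of patients, so the
O(n²) method costs nothing and avoids tree-approximation nondeterminism),
1000 iterations, perplexity min(30, ⌊(n−1)/3⌋) by default. A fixed
(matrix, perplexity, seed) triple gives bit-identical coordinates.

DBSCAN clusters the embedding. `eps` defaults to the median
4-nearest-neighbour distance (k-distance heuristic), `min_samples` to 3.
Labels are renumbered 1..k by decreasing cluster size for stable reporting;
noise keeps −1 and is excluded from characterization and clinical
comparisons, with counts logged. With unreported original hyperparameters,
the cluster *count* is configuration-dependent; the implementation is
validated against a brute-force density-reachability oracle instead of a
target count.

Cluster characterization compares, per pathway, in-cluster vs out-of-cluster
PI scores by rank-sum test, BH-corrected across pathways within the cluster;
adjusted p < 0.05 defines the cluster's signature pathways. Gene mutation
frequencies per cluster count members with any non-benign alteration of the
gene.

## Oncoprint

Genes altered (non-benign variant or CNV) in at least 4 distinct patients
form the rows; cells show one category with precedence CNV >
pathogenic/likely-pathogenic > VUS. The precedence rule for co-occurring
alterations is this package's choice (oncoprint figures rarely state one);
it favours the rarer, higher-impact event class.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:

* **Sizes**: 13 Pen A + 14 Pen B main-series patients; 54 stage-I
  augmentation patients without Kodama labels; combined 81.
* **Panel**: 60 gastric-cancer-relevant genes (subset of a ~500-gene
  design), 1.33 Mb effective footprint.
* **Burden**: baseline TMB lognormal (median 5.5 mut/Mb, σ = 0.65); MSI
  patients (rate 0.15) are hypermutated (median 25 mut/Mb) with probability
  `msi_tmb_coupling`; at coupling 1.0 every MSI patient exceeds the TMB
  cutoff by construction, matching the perfect MSI→TMB-high association the
  analysis expects.
* **Headline associations**: ARID1A carriers (rate 0.22, ≈ 6 of 27) are
  allocated to Pen A with probability e + (1−e)·|PenA|/n; enrichment e = 1
  confines them to Pen A, and carriers mostly receive likely-pathogenic
  frameshifts (the remainder VUS). LRP1B carriers (rate 0.30) have their DFS
  hazard multiplied by 2.73 over a baseline exponential hazard of
  0.0074/month (≈ 59% events over the 120-month follow-up); independent
  exponential censoring is calibrated to a 40% censoring fraction, matching
  a 10-year surgical series with roughly 60% relapse/death.
* **Composition**: ACMG mixture 7.0/15.1/41.2/18.0/18.7% across the five
  tiers (22.1% pathogenic-or-likely-pathogenic, 36.7% benign-or-likely-
  benign); effect mixture 79.8% missense, 11.4% frameshift, 4.0% splice,
  3.0% nonsense, 1.9% in-frame; 73.4% of SNVs are transitions. Each patient
  additionally receives a Poisson(3) tail of sub-threshold calls (low depth,
  low VAF, or synonymous/noncoding) so the filter always has work to do.
* **Gene sets**: 218 pathways of 4–20 panel genes under 8 top-level labels.

All randomness flows from one master seed through named substreams
(clinical, variants, msi, pathways), so any block regenerates independently
and byte-identically. The augmentation cohort derives its streams from a
fixed offset of the master seed, keeping the two cohorts independent but
jointly reproducible.

**What the generator does not emulate**: mutational signatures and positional
hotspots (positions/alleles are arbitrary valid draws), germline
contamination, inter-gene co-mutation structure beyond the three planted
associations, copy-number segments (gene-level events only), and any
coupling between Pen class and TMB or PI beyond what MSI and ARID1A induce.
Passing tests therefore demonstrate that the pipeline recovers structure
that is present and invents none that is absent — not that real cohorts
will show these effect sizes.

## Numerical choices and degenerate inputs

* Boundary semantics: depth/VAF/TMB cutoffs inclusive, MSI cutoff strict,
  as defined above; VAF tolerance 1e-12.
* Fisher enumeration tolerance: tables within relative 1e-7 of the observed
  point probability are included in the two-sided sum.
* Cox fits require ≥ 2 events and a non-constant covariate; the Schoenfeld
  test degrades to NaN (not an error) when residuals are degenerate on tiny
  fits. Log-rank requires ≥ 2 groups and ≥ 1 event; all-censored groups are
  estimated as flat curves.
* Zero-margin chi-square tables are rejected (statistic undefined); the
  corresponding Fisher case degenerates to p = 1.
* Pathways losing all genes under panel restriction are dropped with a
  warning; a run aborts only if none survive.
* Fewer than 2 DBSCAN clusters: characterization and clinical comparisons
  are emitted as empty tables rather than failing the run.
* Pipeline outputs are written atomically (temp file + rename); reruns with
  the same config are byte-identical except the manifest's wall-clock
  fields.

## Problem sizes used in validation

The self-validation suite runs the full default configuration (81 patients,
218 pathways) end to end; survival parameter recovery uses cohorts scaled to
n = 500 over 50 generator seeds (planted hazard ratio 2.73 recovered within
[2.0, 3.7] in ≥ 80% of seeds, null covariates covered by the CI in ≥ 90%);
PI scoring and DBSCAN are checked against independent brute-force oracles on
100 and ~10 random instances respectively. These sizes were chosen so the
entire suite exercises every stage at full default scale while individual
checks stay small enough to enumerate exactly.

## Known limitations

* The PI default is one member of a family of plausible pathway-burden
  scores; conclusions sensitive to the VUS weight or panel restriction
  should be re-run across settings.
* Two-level-only covariate coding in the univariate Cox wrapper;
  multivariable models and competing risks are out of scope.
* r×k cluster-by-covariate tables fall back to chi-square even when sparse.
* t-SNE determinism is guaranteed per platform/BLAS build; coordinates may
  differ across platforms even at a fixed seed (cluster structure is the
  stable object, and the DBSCAN oracle checks it).
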