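# Methods

## The analysis model

The pipeline treats a TBI cohort as points in a 17-dimensional space of
common data elements: ten binary head-CT findings, the ordinal Marshall and
Rotterdam CT severity scores (1–6), a 6-month PTSD diagnosis (DSM-IV,
binary), the PTSD checklist score (PCL, 17–85), WAIS processing speed
(50–150), and two CVLT verbal-learning z-scores. GOS-E at 3 and 6 months
(1 = dead … 8 = upper good recovery) and six 3-level SNP genotype columns
ride along as coloring/outcome variables but do not enter the clustering.

**Distance.** Columns are standardized by the population convention
(divide by N); the dissimilarity between two patients is one minus the
Pearson correlation of their standardized 17-value profiles. This is
scale-free across mixed variable types, lies in [0, 2], and is *not* a
metric — the triangle inequality is neither asserted nor used. Column
standardization makes the distance exactly invariant to affine changes of
any raw variable. A patient whose standardized profile is constant has no
defined correlation with anyone; such patients are pushed to the maximum
distance 2 with a warning rather than aborting the run.

**Missing data.** Missingness in the study design is confined to the
6-month variables (about 42–50% of patients). The default strategy imputes
the per-column *mean* of observed values before standardization: a
mean-imputed cell standardizes to exactly zero and therefore contributes
nothing to any patient-pair correlation, making unobserved variables
neutral. Median imputation (which, for the binary PTSD flag, writes an
affirmative "no PTSD" into every missing cell and drags incomplete patients
toward the healthy pole) and pairwise-complete correlation (minimum overlap
8 variables, fallback distance 2) are available options; in simulation the
mean default recovers planted subgroup members noticeably better than the
median. Imputed cells are flagged and never fed back into node statistics,
which always average observed values only.

**Lens.** Classical (Torgerson) MDS of the double-centered squared
dissimilarities provides a deterministic start; unweighted SMACOF
majorization then minimizes the raw stress Σ_{i<j}(d_ij − ‖z_i − z_j‖)²,
which is non-increasing per iteration by construction (defaults: max 300
iterations, relative tolerance 1e-6; non-convergence warns and returns the
last iterate). Axes are ordered by sample variance; each axis is flipped so
that the lowest-index patient among those of maximal absolute coordinate is
positive, removing reflection nondeterminism; finally each coordinate is
range-scaled to [0, 1] (Gower scaling), with a flat axis mapped to 0.5.
The published description leaves open whether the range normalization is
applied to input variables or to lens values; applying it to the lens
coordinates is what makes the equalized cover below well-defined, so that
reading is adopted. The pipeline is fully deterministic — the platform that
inspired it resamples its covers in a proprietary ensemble, which is out of
scope here and is why exact node counts are not reproduced.

**Cover.** Resolution r = 30 and gain g = 3, equalized. Equalization works
in quantile units: each patient's axis position is its midrank / n, the r
base intervals are [k/r, (k+1)/r) in that scale (so ~n/r patients each),
and every base interval is dilated about its center to length g/r. Adjacent
dilated intervals overlap by 1 − 1/g of their length and an interior point
falls in exactly g intervals per axis (at most g near the edges), matching
the convention that the gain is the number of bins a point occupies. With
g = 1 the cover is a partition. The 2-D bins are Cartesian products;
interval boundaries are half-open except the last, ties share midranks. An
axis with fewer distinct values than r is rejected with advice to lower the
resolution. Equalization on marginal quantiles (not joint 2-D equalization)
is the standard product-cover construction.

**Clustering.** Within each bin, single-linkage under the global distance;
the dendrogram is cut at the left edge of the first empty bar of a 10-bar
histogram of merge heights (no empty bar, or all heights equal → one
cluster). This is the classical seed-free Mapper heuristic; the platform's
proprietary clusterer is unknown. Every cluster is a node; edges join nodes
sharing ≥ 1 patient; per-node statistics are means over observed member
values.

**Subgroup selection and enrichment.** Regions are selected by predicates
over node statistics. The default,
`(gose_6m - gose_3m) < -1.25 and gose_6m < 5.5 and ct_brain_pathology < 0.5`,
encodes "declining and poor 6-month outcome among CT-negative nodes" — the
study phenotype of interest. The subgroup is the union of selected nodes'
patients; because nodes overlap, any patient also appearing in unselected
nodes is assigned to the subgroup and removed from the comparison set, so
the two-sample tests see a partition. Continuous variables are screened by
the asymptotic two-sample KS test, genotypes by the R×2 chi-square test of
independence without continuity correction (Fisher's exact for 2×2);
Benjamini–Hochberg adjustment is applied within each family. The screen is
exploratory; the published analysis reports unadjusted exploration, so BH
here is a conservative guard.

**Confirmatory GLM.** For a chosen SNP, patients with GOS-E at both
timepoints, the CT indicator, and the genotype observed are included
listwise (exclusions logged). The 3-way time × CT × genotype
repeated-measures analysis is computed through its exact two-timepoint
reduction: within-subject (time-interaction) effects equal between-subjects
effects on the change score, and time-pooled effects appear in the separate
3M/6M columns, so the report carries three response columns, each a full
factorial CT × genotype model. Type III sums of squares are computed by
model comparison on sum-to-zero-coded designs (full vs term-dropped),
which is well-defined under imbalance, invariant to factor relabeling and
row order, and equal to Type I under balance; empty design cells raise an
explicit design error rather than silently aliasing. GOS-E is treated as
numeric (interval scale), matching the original analysis; α = 0.05 with no
correction across the three response columns, a deliberate mirror of the
source design and a known caveat. Tukey–Kramer posthocs use the stratum's
model MS_error, the Kramer harmonic form for unequal group sizes, and the
studentized-range distribution.

## The synthetic cohort

The generator emulates the study conditions so that recovery of known
structure can be scored:

- **Latent severity.** One standard-normal severity score per patient; the
  CT-positive class is its upper 44% tail. Binary CT findings occur only in
  CT-positive patients, via a logistic link to severity (slope 1.5) whose
  intercept is root-solved so each cohort marginal matches the target rate
  (defaults: the study's descriptive table, e.g. subdural hematoma 0.26).
  Marshall/Rotterdam are 1 and 2 for CT-negative patients and discretized
  severity-linked latents for CT-positive ones, targeting overall means
  1.76 and 2.45.
- **6-month outcomes.** PCL is a two-component gamma mixture above the
  scale floor 17, conditional on the PTSD diagnosis (separation 20 points),
  with component moments solved from the target marginal mean/SD
  (32.98 ± 14.80) — the gamma respects the floor without truncation bias.
  WAIS and the CVLT scores are unit-variance latents loading on severity
  (−0.3) plus, for the CVLT pair, a shared verbal-learning factor, scaled
  to the target moments and clipped to their ranges.
- **GOS-E.** A latent recovery score (CT-negative mean 6.5, CT penalty 1.6,
  noise SD 1.1) improves by +0.5 from 3 to 6 months (change noise SD 0.6)
  and is rounded and clipped to 1–8.
- **Planted subgroup.** A fraction (default 37/154 ≈ 0.24) of CT-negative
  patients, the size of the study's selected subgroup within its genotyped
  CT-negative patients. Members are forced PTSD-positive (hence high-PCL
  via the mixture), lose 0.5 SD of each cognitive score (mean-compensated
  so marginals are preserved), and lose 3.0 latent GOS-E points at 6
  months. Their heterozygote odds for one SNP (default PARP1) are
  multiplied by 4, homozygotes keeping their relative proportions. The
  background PTSD rate is lowered so the cohort marginal stays at 0.24.
- **Missingness.** MCAR per variable, defaults equal to the study's missing
  counts (only 6-month variables). Genotypes are complete by default; the
  study's partial genotyping is available through the config.
- **What it does not emulate.** Linkage disequilibrium between SNPs,
  informative missingness, site effects, and MR imaging (MR status is not
  among the 17 CDEs). Passing tests therefore demonstrate that the
  machinery recovers structure of this generative form at these effect
  sizes — not performance on the original data.

## Numerical and design notes

- Determinism everywhere after generation: fixed MDS initialization and
  sign convention, seed-free clustering, stable node ordering; identical
  config + seed ⇒ byte-identical artifacts (checksummed in the pipeline
  manifest).
- Monte Carlo characteristics at the defaults (n = 586): the subgroup
  selection recovers ~89% of planted members on average; the planted SNP is
  the top BH-ranked genotype enrichment with q < 0.05 in roughly nine of
  ten cohorts — the residual misses trace to CT-negative PTSD-positive
  background patients with normal outcomes who share nodes with planted
  members and dilute the genotyped contrast; under a null generator
  (odds ratio 1, no GOS-E decrement) false detections are at the nominal
  level or below. The change-score CT × genotype GLM detects the planted
  3-way effect in ~94% of cohorts with ~5% null size.
- Degenerate inputs: constant variables are zeroed with a warning; constant
  patient profiles get distance 2; flat lens axes normalize to 0.5; a
  constant GLM response yields zero effect SS (F pinned to 0) instead of
  NaN; bins with one member form singleton nodes.
- Problem sizes in the test suite and acceptance script (100 cohorts of
  n = 586 for the mapper stage; 100 + 100 for GLM power/size; 30-cohort
  Monte Carlo in the acceptance script) were chosen to give stable rates
  at study scale.
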