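# syndromap

Topological syndromic mapping for multivariate traumatic-brain-injury (TBI)
phenotyping.

TBI outcome is multifaceted: coded head-CT findings, ordinal CT severity
scores (Marshall, Rotterdam), a 6-month PTSD diagnosis with its checklist
(PCL) score, processing-speed and verbal-learning scores, and the Glasgow
Outcome Scale-Extended (GOS-E) at 3 and 6 months all measure different
facets of one syndrome. `syndromap` clusters patients on 17 such common
data elements (CDEs) *simultaneously*, draws the resulting "syndromic map"
as a Mapper graph, screens map regions for genotype enrichment, and
confirms candidate SNP effects with a repeated-measures factorial GLM.

## Method

1. **Norm-correlation distance.** Each variable is mean-centered and
   variance-normalized (population convention); the distance between
   patients *X*, *Y* is
   `NormCorr(X, Y) = 1 − r(X′, Y′)` where *r* is the Pearson correlation of
   the standardized 17-value profiles — 0 for identical profiles, 2 for
   opposite ones.
2. **MDS lens.** Patients are embedded in the plane by minimizing the raw
   stress `Σ_{i<j} (d_ij − ‖z_i − z_j‖₂)²` (classical-MDS start, SMACOF
   majorization, deterministic sign convention), and each coordinate is
   range-scaled to [0, 1] (Gower scaling). Coordinate 1 carries the most
   variance.
3. **Mapper graph.** The lens is covered by overlapping rectangles
   (resolution 30 intervals per axis, gain 3, equalized: quantile-based
   intervals so each holds ~n/30 patients). Patients within each bin are
   clustered by single linkage under the norm-correlation distance with a
   first-gap histogram cut; every cluster is a node, and nodes sharing at
   least one patient are joined by an edge.
4. **Subgroup enrichment.** A region is selected by a predicate over
   node-level statistics (default: declining and poor 6-month GOS-E among
   CT-negative nodes). Its patients are compared with the rest of the
   cohort by two-sample Kolmogorov–Smirnov tests (continuous variables) and
   R×2 chi-square / Fisher tests (genotypes), with Benjamini–Hochberg
   adjustment within each family.
5. **Confirmatory GLM.** For each SNP, a time × CT pathology × genotype
   repeated-measures model on GOS-E with Type III sums of squares. With two
   timepoints the within-subject effects reduce exactly to between-subjects
   effects on the 6m − 3m change score, so the report has three response
   columns (3M, 6M, change), CT-stratified genotype models, and
   Tukey–Kramer posthocs.

A synthetic-cohort generator reproduces the statistical structure this
pipeline assumes — marginal rates and moments of the 17 CDEs, missingness
concentrated in the 6-month follow-up, genotype frequencies, and a
*planted* CT-negative, PTSD-positive, poor-recovery subgroup enriched for a
chosen heterozygote — so every stage is testable end to end without any
protected data.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_distance_and_lens.py
python analysis/03_build_syndromic_map.py
python analysis/04_subgroup_enrichment.py
python analysis/05_glm_hypothesis.py
```

prints (abridged):

```
cohort: 586 patients, 253 CT-positive, 80 planted poor-recovery members
lens: stress 12240.4 after 160 majorization iterations
syndromic map: 2874 nodes, 14660 edges
CT-positivity coloring is strongly bimodal: 45% of nodes < 0.2, 54% > 0.8
subgroup: 92 patients vs 494 comparison patients
recovers 89% of the 80 planted members
top categorical enrichment: PARP1_rs3219119 (chi-square = 11.00, q = 0.025)
PARP1_rs3219119  N= 586 ... change-score CT x genotype F=5.73 p=0.003*
COMT_rs4680      N= 586 ... change-score CT x genotype F=2.92 p=0.055
```

Reading: the map separates CT-positive from CT-negative patients (bimodal
node coloring); the selected poor-recovery CT-negative region recovers 89%
of the planted subgroup; the planted SNP (PARP1) is the top-ranked genotype
enrichment after BH adjustment and the only SNP whose CT × genotype
interaction on GOS-E change is significant in the confirmatory GLM — the
data-driven screen and the hypothesis test agree.

The same stages are available as a CLI (`syndromap simulate|distance|lens|
map|enrich|glm|run`) and as one call, `syndromap.run_pipeline(...)`, which
writes all artifacts plus a manifest with per-stage checksums (identical
config + seed ⇒ byte-identical outputs).

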