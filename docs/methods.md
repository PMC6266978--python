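# Methods

## Problem setting

Tumor models (cell-line xenografts and patient-derived xenografts, PDXs)
respond heterogeneously to all-trans retinoic acid: some regress, some are
unaffected, and some grow *faster* under treatment. The package's premise
is that CpG methylation measured on Illumina HM450/EPIC arrays carries a
predictive signal for this response. The pipeline has three statistical
stages — response phenotyping, supervised marker discovery, and
reference-panel classification — plus a synthetic-cohort generator that
provides ground truth for testing all of them.

## Response phenotyping

For each model, final tumor weights in treated and control arms are
summarized as a fold change FC = mean(treated)/mean(control) and compared
with a two-sample t-test. The three-way phenotype is a deterministic rule
on (FC, p): *sensitive* if p < α and FC < 1, *promoted* if p < α and
FC > 1, *resistant* otherwise, with α = 0.05 by default. The rule is
exposed as configuration because the partition itself (significance plus
direction on weight fold change) is the only part of the phenotyping that
is a modelling choice. Welch's unequal-variance t is the default — arms are
small (≈8 mice) and variance heterogeneity between a regressing and a
growing arm is the norm — with the pooled-variance Student t available for
strict replication of classical usage; tests are two-sided. Volume time
series are carried through as descriptive columns
(length × width × depth / 2 caliper convention) but never modeled; final
weight is the decision variable. Degenerate arms (zero variance in both)
report p = 1 when means agree and p = 0 otherwise.

Phenotype–covariate association uses Fisher's exact test (two-sided,
hypergeometric tail summation) on the 2×2 table of supervision class
(sensitive vs all-other) against a binary covariate.

## Moderated two-group testing

Expression and methylation share one testing engine. For feature g with
pooled two-group variance s²_g on d degrees of freedom, the variances are
modeled as draws from a scaled inverse-χ² prior with d₀ degrees of freedom
and scale s₀². The posterior variance

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d)

replaces s²_g in the usual pooled t statistic, which is then referred to a
t distribution on d + d₀ degrees of freedom. Hyperparameters are fitted by
method of moments on z = log s²: the excess of var(z) over trigamma(d/2)
determines d₀ through a trigamma inverse (Newton iteration), and the mean
of z fixes s₀². When the observed log-variance spread does not exceed the
sampling component, d₀ = ∞ and every feature is tested against the common
variance with a normal reference — the opposite limit d₀ → 0 recovers the
ordinary per-feature t, and both limits are verified numerically in the
test suite. `moderated=False` gives the plain pooled t exactly.

Methylation is tested on the M scale, M = log2(β/(1−β)) with β clipped to
[10⁻⁶, 1−10⁻⁶], because M is approximately variance-stabilized for linear
modelling; effect sizes are always reported as Δβ = mean β(sensitive) −
mean β(other) on the original scale, which is the scale practitioners
interpret and plot. Testing directly on β is selectable. Raw p-value
cutoffs (p < 0.01; for expression additionally |log2 FC| > 0.7) define the
reported candidate lists, and Benjamini–Hochberg q-values are always
emitted alongside so that FDR-controlled calls are available without
re-running. No covariates beyond the two-class factor are modeled.

The "induced" expression contrast first reduces each model to its
per-feature induction (treated log2 − control log2) and then applies the
two-group test to the inductions, so it compares atRA-*inducibility*
between classes rather than post-treatment levels; testing treated values
directly remains possible by passing them as a baseline matrix.

## Probe annotation

Cross-reactive and SNP-associated probes are removed before any testing;
the blacklist is a manifest column, not a curated resource, so any probe
list can be supplied. CpG island context uses fixed Illumina-style flanks
computed by interval arithmetic on merged island intervals: *shore* for
edge distances in [1, 2000) bp, *shelf* for [2000, 4000) bp, *open sea*
beyond; boundaries are half-open so a probe exactly 2000 bp from an edge is
shelf. North/south follows the convention that north flanks lie at lower
coordinates; exact-tie distances resolve north. Distal (open-sea) probes
are never excluded. Probes map to genes through the manifest's
(possibly multi-valued) associations with union semantics — a probe
annotated to two genes contributes to both — and gene-set comparisons are
exact set algebra over the seven Venn regions, with the triple
intersection (differentially methylated ∩ baseline-DE ∩ induction-DE)
forming the predicted methylation-regulated gene list.

Methylation–expression coupling is quantified by Spearman rank correlation
with average ranks for ties; p-values use the t approximation for n > 9
and full permutation enumeration for n ≤ 9 (at most 9! = 362,880
permutations, evaluated vectorized). Constant inputs are reported as NA
with an explanatory note rather than an arbitrary value.

## Response-element scanning

RAREs are modeled as direct repeats of the canonical nuclear-receptor
half-site RGKTCA with 1, 2 or 5 bp spacers (DR1/DR2/DR5); PPREs as DR1 of
the same half-site — which makes every PPRE hit also a RARE hit by
construction. Matching is exact IUPAC matching on both strands with no
mismatch tolerance or weight-matrix scoring; a genome N matches only an N
pattern code, and spacer positions match anything. Overlapping hits are
all reported, with coordinates on the forward strand (0-based half-open).
Gene proximity is measured from the whole gene span: a gene is
motif-proximal when the gap between its interval and any hit is at most
the window (10 kb default, gap ≤ window inclusive; TSS-anchored distance
is a straightforward alternative the caller can implement by passing
1 bp gene intervals at the TSS).

## Signature refinement and classification

Discovery-stage candidates (significant probes from the cell-line
contrast) are first intersected with the probes present on both HM450 and
EPIC so the signature is portable across platforms. The candidates are
then re-tested with the PDXs added to the sensitive class, and probes with
p below the refinement threshold (0.01) are ranked by ascending p, ties
broken by descending |Δβ| and then probe id — a fully deterministic
ordering — and cut to the top k = 6. If fewer than k pass, all passing
probes are returned with a warning flag; none passing is an error.

A query is classified by appending it alone to the reference β matrix,
clustering hierarchically, and reading the smallest dendrogram cluster
that contains the query and at least one reference: all-sensitive members
give *predicted-sensitive*, all-other give *resistant*, mixed gives
*ambiguous*. Because complete, average and Ward linkages are monotone,
that cluster is simply the first merge involving the query. One-query-at-
a-time classification makes each call independent of cohort composition.
A panel whose signature probes carry no variation is handled explicitly:
every query is ambiguous. The clade-purity rule is one pluggable choice;
a nearest-centroid rule with a relative margin (ambiguous when the two
class-centroid distances differ by less than 20% of the larger) is
provided as an alternative.

The in-package agglomerative clusterer supports euclidean, manhattan and
correlation distances with complete, average and Ward linkage
(Lance–Williams updates; Ward on squared euclidean distances with
square-root heights, matching the common convention). Ties in the minimum
inter-cluster distance break deterministically toward the smallest pair of
cluster indices, so dendrograms — and therefore classifications — are
reproducible bit-for-bit. The merge matrix is emitted in the standard
(n−1)×4 layout consumed by scipy's dendrogram utilities, and agreement of
cophenetic distances with scipy's agglomerator is part of the test suite.
The signature — probe order, reference β, labels, distance, linkage and
refinement record — serializes to JSON, making the classifier a single
portable file.

## Synthetic cohorts

The generator emulates the study design end to end, with every planted
effect recorded in a truth object.

* **Methylation.** Per-probe baseline M-values come from a two-component
  Gaussian mixture (modes ±2.5, SD 0.8, equal weights), reproducing the
  bimodal β distribution of real arrays. Per-probe residual variances are
  drawn from a scaled inverse-χ²(d₀ = 4, s₀² = 0.04) — deliberately the
  same hierarchical family the moderated test assumes, so null calibration
  is a meaningful check of the machinery rather than of a lucky
  mismatch. Samples are μ + class effect + N(0, σ²_p) on the M scale,
  mapped through the logistic to β.
* **Planted DMPs** specify a β-scale separation: for each planted probe a
  low baseline is drawn uniformly from [0.1, 0.9 − Δβ], the sensitive
  class (sensitive lines + PDXs + true-sensitive queries) sits at either
  the low or the high value with random sign, and both class means are
  converted to M via logit2. The default Δβ = 0.3 with 100 planted probes
  among 10,000.
* **Panel and cohort.** 5 sensitive / 4 resistant / 4 promoted cell lines,
  4 PDXs (one array per model), 70 queries with a true-sensitive fraction
  of 0.17 (count rounded, assignment randomized).
* **Expression.** Gene baselines N(7, 1.5²) log2 units with per-gene
  variances from scaled inverse-χ²(10, 0.09); 50 planted baseline and 50
  planted induced genes at |log2 FC| = 1.5 with random sign. Seventeen
  coupled (probe, gene) pairs tie expression to the probe's β with slope
  −4 log2 units per β unit plus N(0, 0.15) noise, enforcing the negative
  monotone methylation–expression relation; coupled genes are members of
  both DE truth sets and their probes are kept off the blacklist.
* **Growth.** Lognormal weights, control mean 1 g, σ_log = 0.2 (≈20% CV);
  treated means multiplied by 0.4 / 1.0 / 1.8 for sensitive / resistant /
  promoted groups, 8 mice per arm. The CV was set so that the planted
  multiplicative effects are detected with the intended near-certain power
  at these arm sizes while the null effect stays at nominal significance.
* **Manifest and genome.** Probes get uniform positions on a two-chromosome
  toy genome (7.5 Mb default), island relations computed from randomly
  placed islands by the same interval arithmetic the analysis uses, 0–2
  gene associations, platform membership (85% on both arrays), and a 2%
  blacklist that deliberately includes three planted DMPs so the filter is
  consequential in tests. Genes are placed on a regular grid with ≥23 kb
  spacing so neighboring genes' 10 kb motif windows cannot overlap; the
  genome background is scrubbed of chance RGKTCA half-sites before exact
  direct-repeat motifs are planted near 30% of gene starts, making the
  per-gene motif truth flags exact rather than probabilistic.

Identical configuration and seed reproduce every output byte-for-byte.

### What the generator does not emulate

Probe type I/II chemistry differences, batch and normalization artifacts,
copy-number contamination of β, cell-composition mixtures, correlated
probes (all probes are independent given their class means), replicate
arrays, IDAT-level data, and mutation/subtype covariate structure. Passing
recovery tests on these cohorts therefore demonstrates correctness of the
statistical machinery under its own assumptions — not robustness to the
technical artifacts of real array data, which normalization pipelines
upstream of this package are expected to handle.

## Problem sizes and numerical conventions

Default analyses run at 10,000 probes, 300 genes, 17 panel samples and 70
queries; the full discovery-plus-classification chain completes in roughly
a second, and the bundled verification script covers multi-seed replicate
studies (10–20 cohorts, 600 growth simulations) in well under a minute.
β values are clipped at 10⁻⁶ before the logit; the β↔M round trip is exact
to 10⁻¹² over the clipped range. BH q-values come from the standard
step-up procedure. Fisher p-values use exact hypergeometric summation
(values within a factor 1+10⁻⁷ of the observed table's probability are
included in the tail, the usual guard against floating-point exclusion of
tied tables). Zero-variance features with a nonzero mean difference report
p = 0; identical degenerate groups report p = 1. All tie-breaks (probe
ranking, cluster merges) are deterministic and documented above.

## Known limitations

The phenotype rule (significance + direction) treats borderline models as
resistant; no uncertainty is attached to a classification call beyond the
ambiguous category; the clade-purity rule depends on the chosen distance
and linkage (defaults euclidean/complete, recorded in the serialized
model); refinement ranks probes purely by the two-class test with no
penalty for inter-probe correlation; and motif scanning is exact-match
only, so degenerate response elements beyond the IUPAC consensus are not
found.
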