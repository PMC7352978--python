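# Methods

`pnenmeth` re-implements, as a tested library, a methylation-array
analysis of pancreatic neuroendocrine neoplasms (PNENs): genome-wide
differential methylation against normal pancreatic islets, subtyping of
tumors by the methylation state of the *PDX1* region, copy-number
inference from array intensities, and association/survival statistics.
Because the original cohorts (EPIC and 450K arrays of tumors, islets,
and purified alpha/beta cells) are not redistributable, every stage is
exercised against a synthetic cohort generator whose ground truth is
known exactly. This note documents the models, the defaults and why
they were chosen, what the generator does and does not emulate, and the
numerical choices that make runs reproducible.

## Data model

Probes-in-rows, samples-in-columns throughout. Coordinates are 1-based
inclusive internally; BED exports are 0-based half-open. Beta values
are methylation fractions in [0, 1]; M-values are their logit2
transform, M = log2(b/(1-b)) with clipping at 1e-6. The sample sheet
flags (rather than drops) tumors whose tumor-cell fraction is not above
60%, the inclusion requirement for the analysis. Probes with any
missing beta value are removed at preprocessing (complete-case array
practice) and the removal counts are logged.

## Synthetic cohorts

The generator is the package's study design, not a test fixture. Its
defaults are the conditions the downstream claims are evaluated under:

* **Cohort**: 62 subtype-A and 21 subtype-B tumors, 5 islets, 2 alpha
  and 3 beta references — the published study design.
* **Probe geometry**: probes are placed in clusters of 1–10 probes at
  30–200 bp spacing separated by 2–20 kb gaps, emulating the CpG-dense
  islands of real arrays; without this, a within-cluster smoother
  (maximum gap 300 bp) would have nothing to smooth. A block of 10
  probes spans the *PDX1*-like region on chr13.
* **Methylation**: per-probe baselines are drawn from three states
  (unmethylated 0.10, intermediate 0.50, methylated 0.85 with weights
  0.45/0.10/0.45 — the bimodal shape of array data). Sample noise is
  beta-distributed with concentration 100, giving sd ≈ 0.05 at
  intermediate methylation; the beta family respects the [0, 1] support
  and reproduces the mean-variance dependence of real arrays.
* **Region signal**: *PDX1*-region probes sit at 0.5 ± separation/2
  (default separation 0.7) — high in alpha references and subtype-A
  tumors, low in beta references and subtype-B tumors; islets, a
  beta-dominant cell mixture, sit at 0.35.
* **Differential signal**: a configurable fraction of probes is shifted
  by ±delta in all tumors (85% hypomethylated, matching the reported
  direction bias); shifts are only implanted on probes whose baseline
  accommodates the full effect, so ground truth equals what the matrix
  contains. DMRs shift whole probe clusters (CpG islands move as
  units), preferring clusters of exactly the configured probe count.
* **Copy number**: log2 intensities are a flat baseline (13.0) plus a
  per-sample offset (sd 0.10) and per-probe noise (sd 0.15), with
  whole-chromosome shifts of ±0.3 per subtype (chr5 gain and chr6/chr11
  losses in A; chr6/chr8 gains and chr11 loss in B) — alterations in
  these tumors are predominantly chromosome-scale. References carry no
  shifts.
* **Survival**: exponential event times with hazard ln(2)/11.9 per year
  for subtype A (median 11.9 years, the reported value) multiplied by a
  hazard ratio of 0.22 for subtype B; independent exponential censoring
  at 0.02/year yields ≈ 30–35% censoring. The exponential model
  satisfies proportional hazards exactly, making Cox recovery a clean
  test.
* **Determinism**: one global seed feeds a fixed counter-based
  sub-stream per stage (manifest / methylation / clinical / intensity),
  so adding a stage never perturbs earlier draws and identical
  configurations give byte-identical files.

What the generator does **not** emulate: probe cross-reactivity, SNP
artifacts, batch effects beyond a type II compression knob, cell-type
heterogeneity within samples, sub-chromosomal or subclonal copy-number
events, and informative censoring. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical structure,
not robustness to every artifact of real arrays.

## Normalization (type II → type I)

The two Infinium probe chemistries differ in dynamic range. Per sample,
a three-state beta mixture (unmethylated U, hemimethylated H,
methylated M) is fitted separately to type I and type II probes by EM:
responsibilities are initialized by thresholds at 0.25/0.75, the M-step
matches each component's weighted mean and variance to a beta
distribution (method of moments — stable and reproducible where
per-component likelihood maximization is fragile), and iteration stops
at a relative log-likelihood change of 1e-6 or 100 iterations. Type II
probes are assigned to states by maximum posterior; U- and M-state
probes are quantile-mapped through the fitted component CDFs onto the
type I components, and H-state probes are rescaled by the linear map
sending the type II H-range onto the type I H-range (linear dilation
avoids the instability of quantile matching when H probes are few).
Type I probes are never modified. Samples with fewer than 50 probes of
either type, or with a non-convergent fit, fall back to identity and
are flagged in the report.

## Differential methylation

**Probes (DMPs).** A two-group comparison per probe with
empirical-Bayes variance moderation: per-probe variances are modeled as
s² ~ s0²·F(d, d0) and the prior df d0 and scale s0² are estimated by
digamma/trigamma moment matching on log s². Because bounded
methylation fractions are heteroscedastic (variance depends on mean)
and skewed near 0 and 1, two choices depart from the plain textbook
recipe, both standard in the expression/methylation literature: the
prior scale follows a running-mean trend of log s² on mean methylation
(a trended prior), and the moderated statistic is computed on M-values,
the variance-stabilizing scale, while group means and delta beta are
reported on the beta scale. On raw betas the moderated test is visibly
anti-conservative (≈ 0.10 of null cohorts yield a spurious BH
discovery, versus ≈ 0.03 on M-values and the nominal 0.05); the raw
beta statistic remains available (`stat_scale="beta"`), as does
disabling moderation (`prior_df=0`, which reduces exactly to the
classical pooled t). Significance is Benjamini–Hochberg adjusted p
≤ 0.05; effects with |delta beta| > 0.3 are highlighted. Distribution
summaries normalize DMP counts by the number of analyzed probes per
CpG-island or genomic-feature category, with TSS1500+TSS200+5'UTR
rolled up as the promoter region.

**Regions (DMRs).** Bump hunting: probes are clustered at a maximum
gap of 300 bp; the per-probe group difference (beta scale) is smoothed
by a centered 3-probe running mean within clusters; candidate bumps are
maximal same-sign runs of smoothed coefficients whose magnitude exceeds
the 99th percentile of the pooled permutation null, keeping runs of
≥ 3 probes; each bump is scored by its area (sum of |smoothed
coefficient|). The null is B = 250 label permutations (B ≥ 50
enforced); the family-wise p of a bump is the add-one fraction
(1 + #{permutation max area ≥ observed}) / (1 + B) — the raw fraction
can return zero and is invalid as a p-value — followed by BH across
candidates.

## Subtyping

Probes inside chr13:28,480,000–28,510,000 (inclusive bounds) that are
present on both the 450K and EPIC platforms are selected,
position-ordered. Samples (tumors plus alpha and beta references) are
clustered on Euclidean distances with Ward's minimum-variance criterion
(the squared-distance update; heights on the distance scale). The tree
is cut at the root: the top-level cluster containing all alpha
references is subtype A, the one containing all beta references subtype
B; co-clustered or split references are hard errors, not silent calls.
An AU-threshold cut is deliberately not used — the two-group reading of
the dendrogram is the procedure being reproduced.

Cluster confidence is multiscale bootstrap over features: at each scale
r ∈ {0.5, …, 1.4}, 1000 resamples of ⌈r·P⌉ probes are drawn with
replacement and reclustered, and each original edge's bootstrap
proportion bp_r is the fraction of resampled trees containing the
identical leaf set. Probes (not samples) are resampled because the
object under assessment is the clustering of samples. The
approximately unbiased support comes from the signed-distance/curvature
model: Φ⁻¹(1 − bp_r) = v√r + c/√r fitted by weighted least squares
(binomial-variance weights), with AU = 1 − Φ(v − c). Proportions of
exactly 0 or 1 carry no gradient information; such scales are excluded
from the fit, and an edge degenerate at every scale is reported as
saturated with AU equal to its rounded proportion (fitting the clipped
constant instead would send AU toward 0.5 for maximally supported
edges, which is not a sensible support value).

## Copy number

Each query sample's per-probe log2 intensity is regressed (OLS with
intercept) on the reference panel — by default all islet samples —
and the median-centered residual is the log2 copy ratio; the intercept
plus centering make calls invariant to global intensity offsets.
Probes are grouped into bins that satisfy both ≥ 50 kb width and ≥ 15
probes (the referenced tool's documented default), built greedily per
chromosome with boundaries midway between flanking probes (terminal
probes receive an extrapolated half-gap); trailing probes merge into
the previous bin, and under-populated chromosomes become a single
flagged bin. Bin values are member-probe means (median available via
config). States are thresholded with inclusive boundaries: gain at
log2 ratio ≥ +0.150, loss at ≤ −0.150. No segmentation is applied —
per-bin calls feed per-subtype gain/loss frequency tracks directly, as
in a circos frequency plot.

## Association and survival statistics

**Fisher's exact test** uses the probability-ordering two-sided rule
("as or more extreme" = table probability ≤ observed × (1 + 1e-7)),
the convention needed to reproduce the published table p-values. 2×2
tables use the hypergeometric distribution; r×c tables are enumerated
completely over the margin-fixed lattice (guarded at 10⁷ candidate
tables). The published contingency tables reproduce to printed
precision: mutation 7.6E-06, functionality 0.011, distant metastasis
0.022, recurrence 5.9E-04, gender 0.20, WHO grade 0.66.

**Location tests**: Welch t by default (Student optional);
Mann–Whitney with exact enumeration when both groups have ≤ 8
observations, otherwise the tie-corrected normal approximation with
continuity correction.

**Cox proportional hazards**: Newton–Raphson maximization of the
partial likelihood with Efron tie handling (max 50 iterations, gradient
tolerance 1e-8, step-halving on likelihood decrease; covariates are
centered for conditioning, which leaves coefficients unchanged).
Monotone likelihood (complete separation) is detected when a
coefficient exceeds 10 log-hazard units per covariate SD and is flagged
as non-convergence rather than reported silently. Inference is Wald
(normal CI on the log scale, exponentiated). Proportionality is
checked per covariate by correlating scaled Schoenfeld residuals
(d·V·s_k + β̂) with the rank of the event time, χ² with 1 df.

**Kaplan–Meier**: product-limit estimator with Greenwood variance and
log(−log) confidence intervals; the median is the earliest time the
curve reaches 0.5 ("not reached" when it never does), and its CI
bounds are the crossings of the confidence band with 0.5.

The association report tests each clinicopathological variable against
the subtype with complete-case denominators per variable (documented in
`n_used`); variables with a single observed level are reported without
a p-value rather than erroring.

## Validation studies and problem sizes

`pnenmeth.validation` packages the recovery studies the test suite and
`scripts/acceptance.py` run; the sizes below keep the full battery
within a few minutes on one core while leaving the statistical
conditions (effect sizes, noise, per-cohort sample counts) at their
documented values:

* subtype recovery: 20 cohorts of 40 tumors + 2 alpha + 3 beta at
  separation 0.7, AU from 10 scales × 1000 replicates;
* bootstrap consistency: one 10-sample tree, multiscale bp at scale 1
  versus an independently coded plain bootstrap at 1000 replicates;
* DMP error control: 200 null cohorts of 2000 probes, 10 tumors vs 5
  islets (the *PDX1* block is excluded from the genome-wide null since
  it is differential by construction); sensitivity on 100 implanted
  delta-0.3 probes;
* DMR: 3 cohorts × 5 implanted 5-probe delta-0.4 regions (B = 250),
  a 2-probe implant checked against the 3-probe minimum, and 100 null
  cohorts (B = 100);
* CNA: one EPIC-like cohort (16 A + 10 B tumors, 5 islets, 12
  chromosomes), plus a held-out-reference self-test;
* Cox: 200 cohorts at the default design (83 tumors, HR 0.22).

## Known limitations

* The BMIQ-style fit uses moment-matching EM; component boundaries can
  differ slightly from likelihood-based fits, though the mapped values
  agree closely in practice.
* The r×c exact test is limited to tables enumerable within 10⁷
  candidates; larger tables need a Monte-Carlo approach that is out of
  scope.
* DMR detection assumes the array's clustered probe geometry; isolated
  probes can never form regions, whatever their effect size.
* The CNA caller reports per-bin states only; focal events smaller than
  a bin and allele-specific changes are invisible.
* AU support is an asymptotic quantity; at 1000 replicates per scale,
  values near the 0.95 decision region carry Monte-Carlo error of
  roughly ±0.01–0.02.
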