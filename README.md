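# pnenmeth

Methylation-array analysis of pancreatic neuroendocrine neoplasms
(PNENs), built as an importable Python library.

PNENs arise from the endocrine (islet) cells of the pancreas. Two
clinically distinct subtypes exist, tied to cell of origin: subtype A
resembles alpha cells — the *PDX1* gene region is methylated, *ATRX* /
*DAXX* / *MEN1* mutations are frequent, and prognosis is worse — while
subtype B resembles beta cells, with an unmethylated *PDX1* region and
markedly better survival (hazard ratio ≈ 0.22 for B vs A). This
package implements the full analysis around that observation for
Illumina 450K/EPIC beta-value data:

* **arrays_io** — probe manifest, beta/intensity matrices, sample sheet
  and analysis configuration, with validating TSV/CSV/YAML readers and
  writers and 450K∩EPIC platform intersection;
* **synthetic** — a cohort generator with known ground truth
  (two-subtype tumors, alpha/beta/islet references, implanted
  DMPs/DMRs, chromosome-scale copy-number shifts, subtype-dependent
  survival), so every stage is testable without external data;
* **preprocessing** — probe filtering, BMIQ-style beta-mixture quantile
  normalization of type II probes, M-values, classical MDS;
* **differential** — moderated per-CpG tests (empirical-Bayes variance
  shrinkage with a mean-variance trended prior, statistic on M-values,
  effects as delta beta, BH correction), category distribution
  summaries, and bump-hunting DMRs with a permutation null;
* **subtyping** — *PDX1*-region probe selection
  (chr13:28,480,000–28,510,000), Ward/Euclidean clustering, multiscale
  bootstrap AU/BP support per edge (1000 replicates × 10 scales), and
  reference-anchored A/B assignment;
* **cna** — copy-number log2 ratios against islet references (OLS
  baseline), ≥50 kb bins, gain/loss calls at ±0.150, per-subtype
  frequency tracks;
* **clinstats** — Fisher's exact test (2×2 and full r×c enumeration),
  Welch t / Mann–Whitney, a Table-1-style association report, Cox
  proportional hazards with Efron ties and Schoenfeld proportionality
  checks, and Kaplan–Meier estimation.

The statistical core (exact tests, moderated tests, bump hunting, AU
support, Cox, KM) is implemented in this package and cross-checked in
the test suite against independent oracles (scipy, lifelines,
brute-force enumeration and maximization).

## Worked example

Subtyping a synthetic cohort by *PDX1*-region methylation
(`examples/04_pdx1_subtyping.py`):

```python
from pnenmeth import AnalysisConfig, SimulationConfig, simulate_cohort
from pnenmeth.subtyping import subtype_pipeline

cfg = SimulationConfig(n_tumors_A=20, n_tumors_B=15, n_islets=3,
                       n_probes=1500, n_chromosomes=6,
                       pdx1_n_probes=10, pdx1_separation=0.7, rng_seed=4)
manifest, beta, _, sheet, truth = simulate_cohort(cfg)
calls, dendrogram, support = subtype_pipeline(
    beta.data, manifest, sheet, AnalysisConfig(n_bootstrap=1000, rng_seed=4))
```

prints

```
subtype calls: 20 A, 15 B (35/35 match the generating labels)
top-level cluster support: AU=1.000 / AU=1.000 (BP 1.000 / 1.000)
```

Every tumor lands in the cluster anchored by the correct cell-type
reference, and both top-level clusters have approximately-unbiased
bootstrap support of 1.0 — the split survives probe resampling at every
scale, so the subtype assignment is not an artifact of particular CpGs.

Survival and associations (`examples/06_clinical_associations.py`), on
the published contingency tables and a cohort generated at the true
hazard ratio 0.22:

```
exact tests on the published contingency tables:
  mutation             p = 7.6e-06
  functionality        p = 0.011
  distant_metastasis   p = 0.022
  recurrence           p = 0.00059

Cox PH: HR(B vs A) = 0.29 [95% CI 0.145-0.58], p = 0.001; proportionality p = 0.50
Kaplan-Meier subtype A: median OS 12.9 y (51/62 events)
Kaplan-Meier subtype B: median OS 46.9 y (12/21 events)
```

The exact-test p-values reproduce the published table at printed
precision; the fitted hazard ratio is within sampling error of the
generating value and subtype A's median overall survival lands near the
reported 11.9 years.

The other scripts in `examples/` cover cohort simulation, type II
normalization + MDS, differential methylation, and copy-number calling;
each prints a few numbers and a line on what they mean.

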