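# mirtarkey

Prognosis-related **key miRNA–target interaction** discovery from paired
tumor/normal miRNA and mRNA expression with survival outcomes.

microRNAs repress their target mRNAs post-transcriptionally, so a regulating
pair shows *opposite* dysregulation in tumors (miRNA up, target down, or vice
versa). This package screens predicted miRNA–target pairs for that reversed
pattern and then asks which of the surviving pairs carry prognostic
information, using a resampling-stabilized Cox screen on the per-patient
expression ratio of the miRNA to its target. It is aimed at computational
biologists analyzing TCGA-like cohorts (paired expression matrices plus
overall-survival follow-up) who want a reproducible, tested implementation of
the whole chain — screening, selection, network characterization, hallmark
impact scoring and signature evaluation — plus a synthetic-cohort generator
with planted ground truth for calibration.

## Method

**1. Dysregulation screen.** Counts are normalized to log2 RPKM (mRNA) / RPM
(miRNA); tumor-vs-normal differential expression uses a Welch test with
Benjamini–Hochberg correction at FDR < 0.05 and fold change > 1.2. A
candidate pair (disease-associated miRNA, predicted target) is *dysregulated*
when both members are differentially expressed in opposite directions and the
joint pattern — miRNA above its tumor median while the target is below it (or
the mirror pattern) — occurs in more than 20% of tumors.

**2. Survival selection.** Patients beyond the 95% CI of the Kaplan–Meier
median survival time form good/poor outcome-extreme groups. For each
dysregulated pair, the univariate Cox model

&nbsp;&nbsp;&nbsp;&nbsp;h(t | x) = h₀(t) · exp(β·x),&nbsp;&nbsp; x = log₂(miRNA) − log₂(target)

is refit on 1,000 resampled sets drawing 80% of each outcome group. A pair is
*key* when β keeps one sign across resamples, P < 0.05 in more than 60% of
them, and a log-rank test between the two reversed-pattern patient groups on
the full cohort gives P < 0.05. β > 0 pairs are high-risk, β < 0 low-risk.

**3. Characterization.** The key pairs form a bipartite network (degree
distribution fit by log–log least squares; hub miRNAs = top 10% of nodes by
degree with ≥ 10 targets). Hallmark impact is scored by a random walk with
restart (restart probability 0.7) on a protein-interaction network seeded at
the key targets: each hallmark's score is the median steady-state probability
over its pathway genes, with significance from 1,000 degree-preserving
edge-rewiring permutations. The combined signature is evaluated by k-means
(k = 2) patient clustering on the ratio matrix, log-rank testing, and a
multivariable Cox model adjusting for age and gender.

## Worked example

```python
from mirtarkey import SimulationConfig, RunConfig, simulate_cohort, run_pipeline

cohort = simulate_cohort(SimulationConfig(seed=11))      # 200 tumors, 40 normals
cfg = RunConfig(n_resamples=200, n_permutations=200, rng_seed=11)
result = run_pipeline(cohort, cfg)
print(result.selection.summary())
```

```
Key miRNA-target interaction selection
======================================================
screened pairs:        26
outcome groups:        good=85  poor=85
KM median [95% CI]:    57.1 [49.4, 71.9] days
passed Cox screen:     9
key interactions:      9
------------------------------------------------------
  mirna   target  sig_freq  median_beta  logrank_p risk_group
miR-019 GENE1988         1       -0.232   5.55e-08   low-risk
miR-022 GENE1328         1        0.183    4.5e-05  high-risk
...
```

Of the 9 selected pairs, 9 of the 10 planted prognostic pairs are recovered
(`cohort.truth.prognostic` carries the ground truth). Downstream:

```python
print(result.hallmark_scores)
#                        hallmark     score  p_value  significant
#                 neutral_process  0.000033    0.199        False
#  tissue_invasion_and_metastasis  0.000966    0.005         True

ev = result.signature
print(ev.logrank_p, ev.hazard_ratio)   # 2.86e-09, 2.52
```

The enriched "tissue invasion and metastasis" hallmark — whose pathways were
built around the planted targets — is the one flagged significant, and the
two k-means patient clusters separate survival (log-rank P = 2.9e-09) with an
age/gender-adjusted hazard ratio of 2.5 for the poor-prognosis cluster.

The same run is available from the shell:

```bash
mirtarkey simulate --out cohort/ --seed 11
mirtarkey all --in cohort/ --out results/ --seed 11
```

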