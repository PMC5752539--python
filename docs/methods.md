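# Methods

This note documents the statistical procedures implemented in `mirtarkey`,
the synthetic-data model used to validate them, and the design decisions
taken where the procedure admits more than one reasonable reading.

## The selection procedure

### Preprocessing and differential expression

Raw counts are filtered (a feature is kept when it has at least 10 reads —
2 for miRNAs — in strictly more than 50% of all samples, tumor and normal
pooled) and normalized to log2(RPKM + 1) for mRNAs and log2(RPM + 1) for
miRNAs. Differential expression is a per-feature Welch two-sample t-test on
the log-normalized values with Benjamini–Hochberg correction across all
tested features. A feature is called *up* when FDR < 0.05 and the linear
fold change 2^(mean_tumor − mean_normal) exceeds 1.2, *down* symmetrically
(inverse fold change > 1.2). Dedicated count-based DE callers (negative
binomial GLMs) would be the tool of choice for small cohorts; the Welch
test on log values keeps the pipeline self-contained, and downstream stages
consume only the (direction, significance) calls, so externally computed DE
results can be substituted.

Decisions: every "more than" threshold (50% filter fraction, 20% pattern
fraction, 60% significance frequency) is a strict inequality. The fold-change
threshold is applied on the linear scale. Median dichotomization assigns
ties at the median to *low*, so "high" always means strictly above the
tumor median.

### Dysregulation screen

Candidates are predicted pairs whose miRNA is in the disease-associated
list. Criteria: both members differentially expressed; directions opposite;
and the joint reversed pattern — for an up-regulated miRNA, miRNA high *and*
target low in the same tumor (mirrored for down-regulated miRNAs) — present
in > 20% of tumor samples. The pattern is evaluated on the median-dichotomized
tumor states only; normal samples never enter the pattern count. Two
independent median splits co-occur in ~25% of samples by chance, so the 20%
cutoff removes pairs whose joint pattern is *depleted* relative to chance
while anticorrelated pairs sit near 40–50%.

### Outcome-extreme groups

The Kaplan–Meier median survival time and its 95% CI are estimated with the
log-log (exponential Greenwood) pointwise band inverted at 0.5 — the
standard median-CI construction. Patients whose survival time exceeds the
upper bound are the *good* group (censored patients qualify: they are known
to have lived past the bound); patients with an observed death before the
lower bound are the *poor* group. A patient censored before the lower bound
is uninformative and is left unassigned rather than called poor. Groups
smaller than 5 subjects abort the analysis, as resampling 80% of them would
be meaningless.

### Resampled Cox screen

The covariate is the per-patient log-ratio x = log2(miRNA) − log2(target):
the log scale makes the Cox linear predictor additive in the two expression
values and invariant to shared normalization offsets. 1,000 sample sets are
drawn once (80% of each outcome group, without replacement, stratified) and
*shared across pairs*, mirroring a design where the sample sets are fixed
first and every interaction is evaluated on the same sets. Each univariate
Cox fit maximizes the Efron partial likelihood by Newton–Raphson. The
in-package solver is vectorized (score and information from reversed
cumulative sums; an explicit tie-block path when event times tie) because
the screen performs tens of thousands of fits; it matches an independently
coded brute-force likelihood optimizer to < 1e-6 relative error and
lifelines to its convergence tolerance. Fits that fail to converge within
100 iterations (or with |β| > 50) are flagged and excluded from the
significance count; the denominator of the significance frequency is always
the nominal number of resamples, so skipped resamples count against a pair.

A pair passes when its coefficient keeps one sign across **all** converged
resamples and the frequency of P < 0.05 strictly exceeds 0.6. The sign
condition could also be read as "one sign among the significant resamples
only"; the strict reading is the default and the relaxed one is available
via `RunConfig(strict_sign_consistency=False)`.

### Log-rank confirmation

Passing pairs are confirmed on the **full cohort** (not only the
outcome-extreme subset): patients split into miRNA-high/target-low versus
miRNA-low/target-high groups (patients matching neither pattern are
excluded), compared by a two-group log-rank test at α = 0.05. Pairs are
labelled high-risk (β > 0: a larger miRNA:target ratio increases hazard) or
low-risk (β < 0).

## Network topology

The key pairs form a bipartite miRNA–gene graph. The degree distribution is
summarized by ordinary least squares of log10 N(k) on log10 k over the raw
per-degree counts (no logarithmic binning or CCDF), which matches the
straight-line-on-log-log presentation this statistic is usually given; at
least three distinct degree values are required. Hub miRNAs are miRNA nodes
inside the top 10% of *all* nodes by degree (ties at the cutoff included;
ranking over miRNA nodes only is a config switch) that regulate at least 10
targets. Maximum-likelihood (Clauset-style) power-law fitting is out of
scope by design: the quantity of interest is the regression slope.

## Hallmark impact by random walk with restart

With the key targets as seeds, the walk iterates p ← (1−r)·W·p + r·p₀ with
W the column-normalized adjacency of the PPI network, p₀ uniform over the
seeds present in the network, and restart probability r = 0.7 (the restart
mass convention; exposed in config). Iteration stops when the L1 change is
below 1e-10; the fixed point matches a direct linear solve to 1e-8. Nodes
in components containing no seed receive probability 0 naturally and no
renormalization is applied; probabilities always sum to 1.

Each hallmark's score is the **median** steady-state probability over the
distinct genes in the union of its associated pathways that are present in
the network (union-of-genes, not an average of per-pathway medians — both
readings exist; the union is implemented). Significance comes from
rewiring the network 1,000 times by double-edge swaps — 10·|E| attempted
swaps per permutation, preserving every node's exact degree — and
recomputing the walk and score each time. The permutation p-value uses the
add-one estimator p = (1 + #{random ≥ observed}) / (n + 1), so p is never
exactly zero and is bounded below by 1/(n+1); the plain fraction is
available by flag. The degree-preserving null is essential: steady-state
probability correlates strongly with degree, and rewiring isolates the
*locality* signal (seed adjacency) from the degree effect.

## Signature evaluation

Patients are clustered into two groups by k-means on the interactions ×
patients ratio matrix (columns are patients), 25 seeded restarts, best
inertia kept. Rows are z-scored first so high-variance interactions do not
dominate the Euclidean metric (switchable; the unstandardized variant is a
config flag). The split is evaluated by the log-rank test and by a
multivariable Cox model with terms cluster, age (continuous) and gender
(indicator); the cluster indicator is oriented post hoc so the reported
hazard ratio is ≥ 1 (the poor-prognosis cluster is the risk group).
Patients lacking age or gender are excluded from the multivariable fit
only. Cross-cohort transfer restricts the signature to interactions whose
features are measurable in the target cohort (fewer than three is an
error) and repeats clustering and evaluation there. Baselines re-run the
same clustering with (a) all dysregulated pairs and (b) the key miRNAs'
expression alone. Literature-support and secondary-outcome contrasts use
the chi-square test with Yates continuity correction (df = 1) — the
correction reproduces the reference p-values 0.004/0.005 on the bundled
2×2 tables, whereas the uncorrected statistic gives smaller values — and
the two-sided Fisher exact test; KPS is dichotomized at < 60 with exactly
60 counting as not impaired.

## Synthetic-cohort model

The generator produces every pipeline input with planted ground truth:

* **Counts.** Negative binomial with dispersion 0.2; baseline means are
  log-normal (miRNAs: ln-mean 5, mRNAs: 4). 200 tumors, 40 normals, 100
  miRNAs, 2,000 genes by default. 5% of miRNAs are high-abundance
  (×50) invariant "housekeeping" species, emulating the handful of
  dominant miRNAs (the miR-21/let-7 class) that stabilize real library
  totals; without them, per-million normalization would imprint a
  compositional echo of the planted risk program on every unrelated
  feature.
* **Planted regulations.** 30 (miRNA, target) pairs. The regulator's
  tumor/normal fold is 2.0 (up or down, random sign); its target is shifted
  the opposite way (fold 0.6). Within tumors the target's NB mean is
  multiplied by 0.5^z, where z is the regulator's realized standardized
  log-expression — suppression acts on the NB mean so the count noise model
  stays intact, and always in the high-miRNA→low-target direction
  regardless of the tumor/normal sign.
* **Prognostic program.** 10 of the 30 regulations are prognostic: their
  regulators additionally load (1.0 log2-units per SD, oriented by the DE
  sign) on one shared latent per-patient factor, emulating a co-regulated
  risk program. This is what makes *individual* pair ratios informative
  about the hazard; with independent pairs, each ratio would carry only a
  1/√10 share of the aggregate signal and no per-pair screen could work.
* **Survival.** Exponential event times with hazard
  0.01·exp(0.8·R) per day, where R is the standardized mean of the
  sign-oriented standardized prognostic log-ratios; uniform(0, 2000 days)
  administrative censoring; age ~ U(40, 80) and gender ~ Bernoulli(0.5)
  independent of hazard; PFS shares the risk structure with a 1.5× clock;
  KPS and M-stage are independent of everything (null covariates).
* **Network and pathways.** Preferential-attachment (Barabási–Albert)
  graph, 1,000 nodes, 3 edges per node, relabelled onto the gene universe
  with every planted target included. 50 random pathways of 15–80 genes;
  the "tissue invasion and metastasis" hallmark's five pathways draw 70%
  of members from the prognostic targets plus their 1-hop neighborhood,
  the "neutral process" hallmark's five are uniform. The 70%/1-hop choice
  makes the enriched hallmark *majority* seed-adjacent, which a
  median-based score requires — at 50% neighbor-only membership the
  pathway-union median is dominated by random filler and the planted
  enrichment is undetectable for purely combinatorial reasons.
* **Candidate lists.** The disease-miRNA list is the planted regulators
  plus 30 random decoy miRNAs; the predicted-pair list contains every
  planted regulation plus 20 decoy pairs per disease miRNA, with decoy
  targets drawn outside the planted target set so decoys carry no planted
  effect. Gene lengths are fixed at 1 kb so RPKM and RPM arithmetic agree.

All generators are deterministic given the configuration and seed; every
stage derives its generator from the master seed by hashing the stage name,
so adding a stage never perturbs the others' streams.

What the generator does *not* emulate: batch effects, tumor subtype
structure, copy-number confounding of expression, realistic miRNA target
multiplicity, or non-proportional hazards. Passing the recovery tests
therefore shows the pipeline correctly inverts its own generative
assumptions — planted anticorrelation, a co-regulated prognostic program,
proportional hazards — not that those assumptions hold in any given real
cohort.

## Operating characteristics and problem sizes

The validation suite and `scripts/acceptance.py` run the full pipeline on
five simulated cohorts at the standard configuration (200 tumors, 2,000
genes, 10 planted prognostic pairs) with 200 Cox resamples and 200 network
permutations — sizes chosen so a complete validation runs in minutes on a
single core while leaving the per-seed estimates stable; the operational
defaults in `RunConfig` remain 1,000/1,000. Typical results: selection
sensitivity ≈ 0.85–0.95 with false-discovery proportion ≈ 0.0–0.15; under
the null configuration (coupling off, hazard flat) ≈ 0–1 selections per
cohort with per-pair significance frequencies near the nominal 5%; the
enriched hallmark significant in 5/5 seeds with the neutral hallmark
uniform. Because the resampled sets overlap heavily, the significance
frequency of a *single* null pair is approximately a rescaled draw of its
full-sample p-value, not an average over independent trials — null
behavior is therefore judged over many pairs, and occasional single null
pairs with high significance frequency are expected.

## Numerical choices and degenerate inputs

* Cox: covariate centered before iteration; constant covariates and < 2
  events are errors; the linear predictor is shifted by its maximum before
  exponentiation to avoid overflow.
* Log-rank with zero events in both groups is an error; a pattern split
  with an empty side drops the pair with a log entry.
* k-means on an all-identical ratio matrix is an error (degenerate
  clustering); a constant ratio row is left unstandardized with a warning.
* Rewiring on graphs admitting no valid swap (e.g. a triangle) returns the
  graph unchanged with a warning.
* A hallmark with no pathway gene in the network scores NaN and is
  flagged, never silently zero.
* All tabular output is sorted by (miRNA, target) and runs are
  byte-reproducible given (config, seed).

## Known limitations

* The Welch-test DE stage is anticonservative for very small normal-sample
  counts (< 3 normals are rejected outright); import externally computed DE
  calls for such cohorts.
* Outcome-extreme grouping discards the patients inside the median CI, so
  cohorts with a very tight median CI (strong ties, heavy rounding) can
  leave groups below the minimum size.
* The hallmark score tests seed-adjacency against a degree-preserving null;
  it does not control for community structure beyond degree.
* Power-law fitting by least squares on raw degree counts is descriptive,
  not an estimator of a power-law exponent in the maximum-likelihood sense.
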