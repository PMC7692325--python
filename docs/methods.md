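# Methods

## The network and its assumptions

The assay models transcriptional readout of Notch signaling as a three-layer
Bayesian network.  A single binary root node TC represents the state of the
NOTCH/RBPJ/MAML transcription complex.  Each of the 18 direct target genes
has a binary transcription node G_g (up/down) depending only on TC; each
probeset measuring a gene has a binary observation node O_j (high/low)
depending only on its gene.  Three conditional-independence assumptions
follow: genes are independent given TC, probesets are independent given
their gene, and a sample's score depends only on its own calls.  These are
idealizations — co-regulation by other pathways (e.g. MYC) and probe
cross-hybridization violate them on real arrays — but they buy exact,
fast, missing-data-tolerant inference: the posterior odds factorize per
gene with a two-term sum over the gene state, and any probeset without a
usable measurement simply contributes no evidence.

The score is `log2 [P(TC=active|O) / P(TC=inactive|O)]`.  With the default
prior of 0.5 the score is a pure evidence measure: 0 means the expression
pattern is equally likely under both states.  An exhaustive-enumeration
scorer (`brute_force_posterior`) exists solely as an independent oracle; it
and the analytic scorer agree to < 1e-9 on randomized networks, and it is
never used in production scoring.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `prior_active` | P(TC=active) before evidence | 0.5 | score = pure evidence; log2-odds symmetric around 0 |
| `a_g, b_g` | P(G up \| TC active / inactive) | 0.95 / 0.05 | strong literature evidence for all 18 direct targets; configurable per gene for weaker panels |
| `c_j, d_j` | P(O high \| G up / down) | calibrated | the only data-driven layer |
| `t_j` | discretization cutoff (log2 intensity) | midpoint of class-conditional medians | label-aware, robust to class imbalance and outliers; pooled median available |
| `pseudocount` | Laplace smoothing on high/low counts | 1.0 | keeps all probabilities in (0,1), hence all scores finite |

Numerical conventions: a value exactly equal to `t_j` is called **low**
(deterministic tie-break); a probeset whose calibrated `c_j ≤ d_j`
contradicts the panel's direction assumption and is excluded from scoring
(`anticorrelated`), or, with `on_anticorrelated="invert"`, kept with
flipped call polarity; a probeset constant across the calibration cohort
falls back to the default CPT (0.75, 0.25) with a warning.  After
calibration the model is frozen: scoring never mutates parameters,
refitting is refused, and serialization carries a SHA-256 content hash
verified on load.

The shipped HG-U133Plus2.0 probeset mapping is a best-effort stand-in
assembled from platform annotation; it is data (`data/notch_panel.yaml`),
not code, and should be re-derived from the platform annotation database
plus manual curation (dropping intronic, opposite-strand and
wrong-chromosome probesets) before use on real arrays.  All tests use
synthetic probeset identifiers.

## Expression input, normalization, QC

The assay consumes a probesets × samples matrix of normalized log2
intensities — the output of an upstream pipeline such as frozen RMA, which
this package deliberately does not reimplement (it requires platform frozen
reference vectors and CEL-file access).  `quantile_normalize` is a
desk-scale convenience for raw-ish log2 matrices (classical mean-quantile
algorithm, ties averaged, missing left missing, idempotent).  `qc_flag`
computes four generic per-sample surrogates (median intensity, IQR,
fraction missing, correlation to the cohort median profile) with
configurable cutoffs; it is not equivalent to a vendor QC battery and is
documented as such.

## Synthetic cohorts: what they emulate and what they do not

`simulate_calibration_cohort` emulates a two-class calibration design
(normal vs high-grade serous carcinoma, or any on/off contrast such as a
gamma-secretase-inhibitor experiment): per sample, each gene's latent log2
level is `baseline + delta·1[active] + N(0, σ_gene)` and each probeset
observes it plus a fixed offset and `N(0, σ_probeset)`.  Defaults — 50
samples/class, delta = 2.0 log2 units, σ_gene = σ_probeset = 0.5, two
probesets/gene — give cohorts where calibration is stable and active and
inactive samples separate essentially completely (AUC ≈ 1).

`simulate_tall_cohort` emulates the structure of a 117-patient pediatric
leukemia cohort.  Mutation classes (none/weak/strong, proportions
0.40/0.39/0.21 among the ~96% with known status, so strong ≈ 23/112 as in
the published cohort) shift a latent activity level on a 0–1 scale (means
0.20/0.50/0.80, SD 0.12); expression follows the same layered noise model
driven by that continuous latent level; ICN1 protein is a noisy linear
readout of latent activity (slope 5, SD 1, missing for ~47% of patients);
survival is exponential with baseline hazard 0.10/yr, multiplied by 3 for
the lowest latent-activity quartile, under uniform censoring on 0–10 yr
(≈30–40% event rate); PTEN loss is Bernoulli with probability 11/29 in the
lowest quartile and 12/84 elsewhere (the published marginal rates), missing
for 4 patients.  Subtype labels mix the four T-ALL subgroups with TLX
enriched among strong-mutation patients.

What the generators do **not** emulate: full-transcriptome backgrounds,
array-level artifacts, batch effects, probe cross-hybridization,
inter-gene correlation beyond the shared TC/latent-activity driver, and
competing-risk or non-proportional-hazard survival structure.  Passing
tests on these cohorts therefore demonstrate correctness of the inference
and analysis machinery under the model's own assumptions, not clinical
performance on real arrays.

## Downstream analysis conventions

Mutation strength: strong = juxtamembrane mutation, or HD combined with
PEST or FBXW7; weak = any single HD/PEST/FBXW7 hit otherwise; unknown
status excludes a sample from mutation-based analyses only.  Activity
groups: quartiles of the analyzed cohort's scores with linear
interpolation; low is strictly < Q1 and high strictly > Q3, scores equal to
a cut go to middle — with 117 distinct scores this yields 29 low, matching
the published low-group size, and assignment is invariant under monotone
score transforms.  The PTEN association collapses groups to {low} vs
{middle, high} and uses the Pearson chi-square **without** continuity
correction (with Yates the published table gives p ≈ 0.014 instead of the
published 0.006).  Group-comparison contrasts default to the unpaired
rank-sum test; the paired signed-rank variant is available where samples
are genuinely paired.  Missing clinical fields are deleted listwise per
analysis and each analysis reports its own n.

Hypothesis tests are delegated to scipy.stats (Kruskal–Wallis, Pearson /
Spearman, chi-square, rank tests) and lifelines (Kaplan–Meier,
multivariate log-rank); this package contributes the contracts, degenerate-
input handling (identical groups → H = 0, p = 1; all-zero paired
differences → p = 1 with a warning; zero-margin tables and zero-event
cohorts → explicit errors) and the cohort-assembly logic around them.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; there is no hidden global
RNG state.  The test suite and the acceptance script run at desk scale:
100 random networks for the oracle-equivalence check, 200 samples/class
for CPT recovery (binomial SE ≈ 0.016 at c = 0.95, comfortably inside the
±0.05 acceptance band; the recovery generator pins the gene layer to the
class so the class-conditional high rate *is* the probeset CPT being
recovered), 50 samples/class for the separation AUC, one 117-patient
simulated cohort for the downstream pipeline, and 500 replicate tables for
the chi-square power estimate.  At the chosen survival conditions the
single-cohort log-rank test has moderate power, so its p-value varies
across simulation seeds while the fixed-seed checks in the test suite are
reproducible.

## Known limitations

- Hard low/high calls discard within-class magnitude information; soft
  (continuous) evidence is a natural extension not implemented here.
- The gene-layer CPTs are configured, not learned; the defaults treat all
  18 targets as equally strong evidence.
- The shipped probeset mapping is unvalidated against current platform
  annotation.
- Scores from models calibrated on different cohorts or thresholds are not
  directly comparable; compare only within one frozen model.
- No multivariable survival modeling (e.g. Cox regression) is provided;
  the survival analysis is the descriptive Kaplan–Meier / log-rank stage.
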