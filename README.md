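# notchscore

Quantitative Notch pathway activity from gene expression, plus the
downstream clinical analyses used to interpret it in T-cell acute
lymphoblastic leukemia (T-ALL).

Whether the Notch pathway is functionally active in a tumor cannot be read
off reliably from *NOTCH1*/*FBXW7* mutation status alone: samples without
hotspot mutations can show high pathway output and vice versa.  This
package infers activity directly from the transcriptional consequence of an
active NOTCH/RBPJ/MAML transcription complex — the expression of a curated
panel of 18 direct target genes (*CD44, DTX1, EPHB3, HES1, HES4, HES5,
HES7, HEY1, HEY2, HEYL, MYC, NFKB2, NOX1, NRARP, PBX1, PIN1, PLXND1,
SOX9*) — and reports a per-sample **log2-odds activity score**.  It is
aimed at computational biologists working with normalized probeset-level
microarray matrices (Affymetrix HG-U133Plus2.0 dialect) or any
probeset-like panel measurement.

## The model

A three-layer Bayesian network:

* **TC** — latent binary transcription-complex state (active / inactive),
  prior `P(TC = active) = 0.5`;
* **G_g** — latent transcription state (up / down) of target gene *g*,
  conditionally independent given TC, with CPT
  `(a_g, b_g) = (P(up | active), P(up | inactive))` encoding
  literature-evidence strength (default 0.95 / 0.05);
* **O_j** — observed probeset call (high / low), obtained by thresholding
  the normalized log2 intensity at a calibrated cutoff `t_j`, conditionally
  independent given the gene, with CPT
  `(c_j, d_j) = (P(high | up), P(high | down))`.

Calibration on a labeled two-class cohort (e.g. normal tissue = inactive vs
high-grade serous ovarian carcinoma = active) estimates `t_j` (midpoint of
the class-conditional medians) and `(c_j, d_j)` (Laplace-smoothed high-call
frequencies per class).  The model is then **frozen**; scoring a new sample
computes, by exact marginalization over the gene layer,

```
score = log2  P(TC = active | O) / P(TC = inactive | O)
      = Σ_g  log2  [ a_g Π_j f_j(up) + (1−a_g) Π_j f_j(down) ]
                   ───────────────────────────────────────────
                   [ b_g Π_j f_j(up) + (1−b_g) Π_j f_j(down) ]
```

(with prior 0.5 the prior term vanishes; missing calls contribute no
evidence).  Positive scores mean the evidence favors an active pathway.

## Worked example

```python
from notchscore import *

panel = load_panel()                                   # shipped 18-gene Notch panel
pmap  = synthetic_probeset_map(panel, probesets_per_gene=2)

# two-class calibration cohort (50 active / 50 inactive, default conditions)
cal_expr, cal_labels = simulate_calibration_cohort(
    SyntheticCohortSpec(seed=1), panel, pmap)

est = PathwayActivityModel(cal_expr, cal_labels, panel=panel, probeset_map=pmap)
res = est.fit()                                        # calibrate + freeze
print(res.summary())

# score an independent cohort
val_expr, val_labels = simulate_calibration_cohort(
    SyntheticCohortSpec(seed=2), panel, pmap)
scores = res.score(val_expr).as_series()
```

The summary header and scores this prints:

```
Pathway activity assay: NOTCH (panel v0.1-standin, model v0)
========================================================================
genes: 18    probesets: 36 (active 36, excluded 0, inverted 0)
prior P(active): 0.500    frozen: True
content hash: 5c614f9256a191cc…

S001   41.77
S002   43.53
S003   43.68
```

The per-sample numbers are posterior log2-odds: sample S001's expression
pattern is 2^41.8 times more likely under an active than an inactive
transcription complex.  Across the validation cohort the median score is
**38.74** for the truly active samples and **−47.10** for the inactive
ones — a fully separated two-class cohort at the default effect size
(2 log2-units per gene).  Real cohorts sit much closer to 0 (the published
T-ALL range is roughly −8.6 to 7.5) because biological activity is graded,
not binary.

Downstream clinical analysis of a scored cohort
(`analyze_cohort(scores, clinical)`) classifies NOTCH1/FBXW7 mutations into
none/weak/strong, compares score distributions (Kruskal–Wallis), correlates
scores with ICN1 protein, forms low/middle/high activity groups at the
25th/75th score percentiles, compares survival (Kaplan–Meier + log-rank)
and tests the low-activity ↔ PTEN-loss association (Pearson chi-square).

The same pipeline is scriptable from a shell:

```sh
notchscore simulate  --kind calibration --seed 1 --outdir cal/
notchscore calibrate --expression cal/expression.tsv --labels cal/labels.tsv \
                     --panel cal/panel.yaml --outdir model/
notchscore simulate  --kind tall --seed 2 --outdir tall/
notchscore score     --model model/model.json --expression tall/expression.tsv \
                     --outdir scores/
notchscore analyze   --scores scores/scores.tsv --clinical tall/clinical.tsv \
                     --outdir analysis/
```

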