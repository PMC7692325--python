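"""Synthetic cohorts with the statistical structure the assay assumes.

Three generators:

* :func:`simulate_calibration_cohort` — a two-class (pathway active vs
  inactive) cohort on the log2-intensity scale, emulating the structure of
  a normal-tissue vs high-grade-serous-carcinoma calibration set, and
  equally usable as an on/off contrast (e.g. a gamma-secretase-inhibitor
  experiment) by shrinking the class sizes.
* :func:`simulate_from_model` — draws discrete network states from known
  CPTs and emits intensities around the model's thresholds; used to check
  that calibration recovers known parameters.
* :func:`simulate_tall_cohort` — a leukemia-like clinical cohort (default
  117 patients) with mutation classes, a latent activity level driving
  expression, a correlated ICN1 protein level, exponential survival with a
  hazard penalty for the lowest-activity quartile, and activity-dependent
  PTEN loss.

The noise model is additive Gaussian on the log2 scale at both the gene and
probeset layers — the standard desk-scale approximation for summarized
microarray intensities.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import ExpressionMatrix
from .genesets import (
    ProbesetEntry,
    ProbesetMap,
    TargetGenePanel,
    load_panel,
    probesets_for_gene,
)
from .model import PathwayModel


def synthetic_probeset_map(
    panel: TargetGenePanel, probesets_per_gene: int = 2
) -> ProbesetMap:
    """Deterministic synthetic probeset ids ``<GENE>_ps<k>`` for a panel."""
    entries = [
        ProbesetEntry(f"{g}_ps{k}", g, True)
        for g in panel.genes
        for k in range(1, probesets_per_gene + 1)
    ]
    return ProbesetMap(entries=tuple(entries))


@dataclass
class SyntheticCohortSpec:
    """Two-class calibration/contrast cohort parameters.

    ``delta`` is the per-gene mean log2 shift between the active and
    inactive class; ``sigma_gene`` the biological (per-sample, per-gene) SD;
    ``sigma_probeset`` the measurement SD added per probeset; ``baseline``
    the range of fixed per-probeset offsets around the global gene baseline.
    """

    n_active: int = 50
    n_inactive: int = 50
    delta: float = 2.0
    sigma_gene: float = 0.5
    sigma_probeset: float = 0.5
    probesets_per_gene: int = 2
    baseline: tuple[float, float] = (-1.0, 1.0)
    gene_baseline: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValidationError("class sizes must be >= 0")
        if self.sigma_gene <= 0 or self.sigma_probeset <= 0:
            raise ValidationError("noise SDs must be > 0")
        if self.probesets_per_gene < 1:
            raise ValidationError("need at least one probeset per gene")


def simulate_calibration_cohort(
    spec: SyntheticCohortSpec,
    panel: TargetGenePanel | None = None,
    pmap: ProbesetMap | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate (expression matrix, labels) for a two-class cohort.

    Per sample s with class indicator y_s: each gene's latent log2 level is
    ``gene_baseline + delta * y_s + N(0, sigma_gene)``; each of its probesets
    observes that level plus a fixed probeset offset (uniform in ``baseline``)
    plus ``N(0, sigma_probeset)``.
    """
    panel = panel or load_panel()
    pmap = pmap or synthetic_probeset_map(panel, spec.probesets_per_gene)
    rng = np.random.default_rng(spec.seed)

    probesets = [j for g in panel.genes for j in probesets_for_gene(pmap, g)]
    if not probesets:
        raise ValidationError("probeset map yields zero probesets for the panel")
    offsets = {
        j: rng.uniform(spec.baseline[0], spec.baseline[1]) for j in probesets
    }

    n = spec.n_active + spec.n_inactive
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    y = np.array([1] * spec.n_active + [0] * spec.n_inactive)
    labels = pd.Series(
        np.where(y == 1, "active", "inactive"), index=sample_ids, name="label"
    )

    values = np.empty((len(probesets), n))
    gene_of = {j: pmap.gene_of(j) for j in probesets}
    for s in range(n):
        gene_level = {
            g: spec.gene_baseline
            + spec.delta * panel.direction[g] * y[s]
            + rng.normal(0.0, spec.sigma_gene)
            for g in panel.genes
        }
        for r, j in enumerate(probesets):
            values[r, s] = (
                gene_level[gene_of[j]]
                + offsets[j]
                + rng.normal(0.0, spec.sigma_probeset)
            )
    expr = ExpressionMatrix(pd.DataFrame(values, index=probesets, columns=sample_ids))
    return expr, labels


def simulate_from_model(
    model: PathwayModel,
    n_active: int,
    n_inactive: int,
    seed: int = 0,
    spread: float = 1.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Sample the discrete network forward from known CPTs.

    Each sample's TC state is fixed by its class label; gene states are drawn
    from the gene CPTs and probeset calls from (c_j, d_j).  Calls are emitted
    as intensities ``t_j + spread`` (high) / ``t_j - spread`` (low) so the
    output flows through the same discretization path as real data.
    """
    rng = np.random.default_rng(seed)
    probesets = model.all_active_probesets()
    n = n_active + n_inactive
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    labels = pd.Series(
        ["active"] * n_active + ["inactive"] * n_inactive,
        index=sample_ids,
        name="label",
    )
    values = np.empty((len(probesets), n))
    for s in range(n):
        tc = labels.iloc[s] == "active"
        gene_state: dict[str, bool] = {}
        for g in model.panel.genes:
            a, b = model.gene_cpt[g]
            gene_state[g] = rng.random() < (a if tc else b)
        for r, j in enumerate(probesets):
            g = model.probeset_map.gene_of(j)
            c, d = model.probeset_cpt[j]
            high = rng.random() < (c if gene_state[g] else d)
            values[r, s] = model.thresholds[j] + (spread if high else -spread)
    expr = ExpressionMatrix(pd.DataFrame(values, index=probesets, columns=sample_ids))
    return expr, labels


@dataclass
class SyntheticTallSpec:
    """Leukemia-cohort generator parameters.

    Latent activity is on a 0–1 scale; mutation classes shift it.  Cohort
    marginals (size, PTEN loss rates, missingness) default to the printed
    clinical-table structure the downstream pipeline expects: 117 patients,
    PTEN loss probability 11/29 in the lowest-activity quartile vs 12/84
    elsewhere, ~5 patients with unknown mutation status, ICN1 measured for
    roughly half the cohort and PTEN known for all but 4 patients.
    """

    n_patients: int = 117
    #: P(none), P(weak), P(strong) among status-known patients
    mutation_proportions: tuple[float, float, float] = (0.40, 0.39, 0.21)
    prob_status_unknown: float = 5 / 117
    #: class-conditional mean latent activity (0-1 scale) and its SD
    activity_by_class: dict = field(
        default_factory=lambda: {"none": 0.20, "weak": 0.50, "strong": 0.80}
    )
    activity_sd: float = 0.12
    #: expression effect span: latent activity 0 -> baseline, 1 -> baseline+delta
    delta: float = 2.0
    sigma_gene: float = 0.5
    sigma_probeset: float = 0.5
    probesets_per_gene: int = 2
    baseline: tuple[float, float] = (-1.0, 1.0)
    gene_baseline: float = 7.0
    icn1_slope: float = 5.0
    icn1_noise: float = 1.0
    icn1_missing_frac: float = 55 / 117
    #: events per year for the non-low group; multiplier for the lowest
    #: latent-activity quartile
    baseline_hazard: float = 0.10
    hazard_multiplier_low: float = 3.0
    censor_max_years: float = 10.0
    pten_loss_prob_low: float = 11 / 29
    pten_loss_prob_rest: float = 12 / 84
    pten_missing_frac: float = 4 / 117
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mutation_proportions) - 1.0) > 1e-9:
            raise ValidationError("mutation class proportions must sum to 1")
        if self.baseline_hazard <= 0 or self.hazard_multiplier_low <= 0:
            raise ValidationError("hazards must be > 0")
        for p in (
            self.prob_status_unknown,
            self.icn1_missing_frac,
            self.pten_loss_prob_low,
            self.pten_loss_prob_rest,
            self.pten_missing_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0,1]")


_SUBTYPES = ("ETP/immature", "TLX", "Proliferative", "TALLMO")
#: subtype mixing per mutation class; TLX is enriched for strong mutations
_SUBTYPE_PROBS = {
    "none": (0.30, 0.10, 0.25, 0.35),
    "weak": (0.20, 0.20, 0.30, 0.30),
    "strong": (0.10, 0.45, 0.25, 0.20),
}


def _flags_for_class(cls: str, rng: np.random.Generator) -> dict[str, bool]:
    hd = pest = jme = fbxw7 = False
    if cls == "strong":
        if rng.random() < 0.5:
            jme = True
        else:
            hd = True
            if rng.random() < 0.5:
                pest = True
            else:
                fbxw7 = True
    elif cls == "weak":
        which = rng.integers(0, 3)
        hd, pest, fbxw7 = which == 0, which == 1, which == 2
    return {"hd": hd, "pest": pest, "jme": jme, "fbxw7": fbxw7}


def simulate_tall_cohort(
    spec: SyntheticTallSpec,
    panel: TargetGenePanel | None = None,
    pmap: ProbesetMap | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate (expression, clinical annotations) for a leukemia-like cohort.

    The clinical table carries, per patient: subtype, mutation flags
    (hd/pest/jme/fbxw7 + status_known), ICN1 level (missing for a fraction),
    PTEN loss (missing for a fraction), event-free and relapse-free survival
    (time, event), and the simulation's ground-truth ``latent_activity``.
    """
    panel = panel or load_panel()
    pmap = pmap or synthetic_probeset_map(panel, spec.probesets_per_gene)
    rng = np.random.default_rng(spec.seed)

    n = spec.n_patients
    sample_ids = [f"P{i+1:03d}" for i in range(n)]
    classes = rng.choice(
        ["none", "weak", "strong"], size=n, p=list(spec.mutation_proportions)
    )
    status_known = rng.random(n) >= spec.prob_status_unknown

    latent = np.clip(
        np.array([spec.activity_by_class[c] for c in classes])
        + rng.normal(0.0, spec.activity_sd, size=n),
        0.0,
        1.0,
    )

    # expression: same layered noise model as the calibration generator,
    # with the binary class indicator replaced by continuous latent activity
    probesets = [j for g in panel.genes for j in probesets_for_gene(pmap, g)]
    offsets = {j: rng.uniform(spec.baseline[0], spec.baseline[1]) for j in probesets}
    gene_of = {j: pmap.gene_of(j) for j in probesets}
    values = np.empty((len(probesets), n))
    for s in range(n):
        gene_level = {
            g: spec.gene_baseline
            + spec.delta * panel.direction[g] * latent[s]
            + rng.normal(0.0, spec.sigma_gene)
            for g in panel.genes
        }
        for r, j in enumerate(probesets):
            values[r, s] = (
                gene_level[gene_of[j]]
                + offsets[j]
                + rng.normal(0.0, spec.sigma_probeset)
            )
    expr = ExpressionMatrix(pd.DataFrame(values, index=probesets, columns=sample_ids))

    flags = [_flags_for_class(c, rng) for c in classes]
    subtypes = [
        _SUBTYPES[rng.choice(4, p=_SUBTYPE_PROBS[c])] for c in classes
    ]

    icn1 = np.maximum(
        spec.icn1_slope * latent + rng.normal(0.0, spec.icn1_noise, size=n), 0.0
    )
    icn1_missing = rng.random(n) < spec.icn1_missing_frac

    q1 = np.percentile(latent, 25)
    low_group = latent < q1

    def survival(hazard: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        event_time = rng.exponential(1.0 / hazard)
        censor_time = rng.uniform(0.0, spec.censor_max_years, size=n)
        observed = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        return observed, event

    hazard = spec.baseline_hazard * np.where(low_group, spec.hazard_multiplier_low, 1.0)
    efs_time, efs_event = survival(hazard)
    rfs_time, rfs_event = survival(hazard)

    pten_p = np.where(low_group, spec.pten_loss_prob_low, spec.pten_loss_prob_rest)
    pten = (rng.random(n) < pten_p).astype(float)
    pten[rng.random(n) < spec.pten_missing_frac] = np.nan

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtypes,
            "hd": [f["hd"] for f in flags],
            "pest": [f["pest"] for f in flags],
            "jme": [f["jme"] for f in flags],
            "fbxw7": [f["fbxw7"] for f in flags],
            "status_known": status_known,
            "icn1": np.where(icn1_missing, np.nan, icn1),
            "pten_loss": pten,
            "efs_time": efs_time,
            "efs_event": efs_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
            "latent_activity": latent,
        }
    )
    return expr, clinical


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.10g")
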