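"""The pathway-activity Bayesian network: calibration, freezing, inference.

The network has three layers.  A latent binary *transcription complex* node
TC (active/inactive) with prior ``P(TC=active)``; one latent binary node per
target gene G_g (transcriptionally up/down), conditionally independent given
TC with CPT ``(a_g, b_g) = (P(up|active), P(up|inactive))``; and one observed
binary node per probeset O_j (high/low after thresholding the normalized
log2 intensity at t_j), conditionally independent given their gene with CPT
``(c_j, d_j) = (P(high|up), P(high|down))``.

The activity read-out of a sample is the posterior log2-odds

    score = log2[ P(TC=active | O) / P(TC=inactive | O) ]

computed by exact marginalization over the gene layer.  Calibration
estimates the observation layer (thresholds and (c_j, d_j)) from a labeled
two-class cohort; the gene layer encodes literature-evidence strength and is
configured, not fitted.  After calibration the model is *frozen*: scoring
never mutates parameters and recalibration of a frozen model is refused.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    FrozenModelError,
    InputError,
    ScoringError,
    ValidationError,
)
from .expression import ExpressionMatrix
from .genesets import ProbesetMap, TargetGenePanel, probesets_for_gene

Call = Literal["low", "high", "missing"]

#: Gene-layer defaults: strength of the literature evidence linking the
#: transcription complex to each direct target.
DEFAULT_GENE_UP_GIVEN_ACTIVE = 0.95
DEFAULT_GENE_UP_GIVEN_INACTIVE = 0.05
#: Observation-layer fallback for probesets that cannot be calibrated
#: (constant across the calibration cohort).
DEFAULT_PROBESET_CPT = (0.75, 0.25)


@dataclass(frozen=True)
class EvidenceVector:
    """Discretized probeset calls for one sample."""

    sample_id: str
    calls: Mapping[str, Call]

    def n_informative(self) -> int:
        return sum(1 for v in self.calls.values() if v != "missing")


@dataclass
class ActivityScoreTable:
    """Per-sample log2-odds scores plus per-sample scoring failures."""

    scores: pd.DataFrame  # columns: sample_id, log2_odds, n_probesets_used
    failures: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @staticmethod
    def read(path: str | Path) -> "ActivityScoreTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return ActivityScoreTable(scores=df)

    def as_series(self) -> pd.Series:
        return self.scores.set_index("sample_id")["log2_odds"]


@dataclass(frozen=True)
class PathwayModel:
    """Frozen-able parameter set of the three-layer network."""

    panel: TargetGenePanel
    probeset_map: ProbesetMap
    prior_active: float = 0.5
    gene_cpt: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    probeset_cpt: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    thresholds: Mapping[str, float] = field(default_factory=dict)
    excluded: Mapping[str, str] = field(default_factory=dict)
    inverted: frozenset[str] = frozenset()
    #: raw (unrepaired) calibrated CPTs, kept for diagnostics
    raw_probeset_cpt: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    frozen: bool = False
    version: str = "0"

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_active < 1.0):
            raise ValidationError("prior_active must be in (0,1)")
        for g, (a, b) in self.gene_cpt.items():
            if not (0 < a < 1 and 0 < b < 1):
                raise ValidationError(f"gene CPT for {g!r} outside (0,1)")
            if self.panel.direction.get(g, 1) == 1 and not a > b:
                raise ValidationError(f"gene {g!r}: requires P(up|active) > P(up|inactive)")
        for j, (c, d) in self.probeset_cpt.items():
            if not (0 < c < 1 and 0 < d < 1):
                raise ValidationError(f"probeset CPT for {j!r} outside (0,1)")
            if j not in self.excluded and not c > d:
                raise ValidationError(
                    f"probeset {j!r}: P(high|up) <= P(high|down) but not excluded"
                )

    # -- structure ---------------------------------------------------------

    def active_probesets(self, gene: str) -> list[str]:
        """Included, non-excluded probesets with a CPT and threshold."""
        return [
            j
            for j in probesets_for_gene(self.probeset_map, gene)
            if j not in self.excluded and j in self.probeset_cpt and j in self.thresholds
        ]

    def all_active_probesets(self) -> list[str]:
        out: list[str] = []
        for g in self.panel.genes:
            out.extend(self.active_probesets(g))
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "version": self.version,
            "frozen": self.frozen,
            "prior_active": self.prior_active,
            "panel": {
                "pathway_name": self.panel.pathway_name,
                "version": self.panel.version,
                "genes": [
                    {"symbol": g, "direction": int(self.panel.direction[g])}
                    for g in self.panel.genes
                ],
            },
            "probesets": [
                {
                    "id": e.probeset_id,
                    "gene": e.gene,
                    "included": e.included,
                    "reason": e.reason,
                }
                for e in self.probeset_map.entries
            ],
            "gene_cpt": {g: list(v) for g, v in self.gene_cpt.items()},
            "probeset_cpt": {j: list(v) for j, v in self.probeset_cpt.items()},
            "raw_probeset_cpt": {j: list(v) for j, v in self.raw_probeset_cpt.items()},
            "thresholds": dict(self.thresholds),
            "excluded": dict(self.excluded),
            "inverted": sorted(self.inverted),
        }
        d["content_hash"] = _content_hash(d)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PathwayModel":
        from .genesets import ProbesetEntry, make_panel

        stored_hash = d.get("content_hash")
        if stored_hash is not None:
            body = {k: v for k, v in d.items() if k != "content_hash"}
            if _content_hash(body) != stored_hash:
                raise ValidationError("model file content hash mismatch")
        panel = make_panel(
            [g["symbol"] for g in d["panel"]["genes"]],
            pathway_name=d["panel"]["pathway_name"],
            version=d["panel"].get("version", "unversioned"),
            direction={g["symbol"]: int(g["direction"]) for g in d["panel"]["genes"]},
        )
        pmap = ProbesetMap(
            entries=tuple(
                ProbesetEntry(p["id"], p["gene"], p["included"], p.get("reason"))
                for p in d["probesets"]
            )
        )
        return PathwayModel(
            panel=panel,
            probeset_map=pmap,
            prior_active=float(d["prior_active"]),
            gene_cpt={g: tuple(v) for g, v in d["gene_cpt"].items()},
            probeset_cpt={j: tuple(v) for j, v in d["probeset_cpt"].items()},
            raw_probeset_cpt={
                j: tuple(v) for j, v in d.get("raw_probeset_cpt", {}).items()
            },
            thresholds={j: float(t) for j, t in d["thresholds"].items()},
            excluded=dict(d.get("excluded", {})),
            inverted=frozenset(d.get("inverted", [])),
            frozen=bool(d["frozen"]),
            version=str(d.get("version", "0")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "PathwayModel":
        path = Path(path)
        if not path.exists():
            raise InputError(f"model file not found: {path}")
        return PathwayModel.from_dict(json.loads(path.read_text()))

    def content_hash(self) -> str:
        return self.to_dict()["content_hash"]


def _content_hash(body: dict) -> str:
    blob = json.dumps(body, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(expr: ExpressionMatrix, model: PathwayModel) -> list[EvidenceVector]:
    """Threshold intensities into low/high/missing calls, one vector per sample.

    Convention: value > t_j -> high, value <= t_j -> low (ties are low),
    absent probeset or non-finite value -> missing.  For probesets flagged as
    inverted during calibration the comparison is flipped so that the stored
    (c_j, d_j) keep their ``c > d`` orientation.
    """
    probesets = model.all_active_probesets()
    overlap = [j for j in probesets if j in expr.data.index]
    if not overlap:
        raise InputError(
            "no overlap between expression matrix probesets and model probesets"
        )
    vectors = []
    for s in expr.sample_ids:
        calls: dict[str, Call] = {}
        for j in probesets:
            if j not in expr.data.index:
                calls[j] = "missing"
                continue
            v = expr.data.at[j, s]
            if v is None or not np.isfinite(v):
                calls[j] = "missing"
                continue
            hi = v > model.thresholds[j]
            if j in model.inverted:
                hi = not hi
            calls[j] = "high" if hi else "low"
        vectors.append(EvidenceVector(sample_id=s, calls=calls))
    return vectors


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    expr: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    panel: TargetGenePanel,
    pmap: ProbesetMap,
    pseudocount: float = 1.0,
    prior_active: float = 0.5,
    gene_cpt: Mapping[str, tuple[float, float]] | None = None,
    threshold_method: Literal["class_median_midpoint", "pooled_median"] = "class_median_midpoint",
    on_anticorrelated: Literal["exclude", "invert"] = "exclude",
    version: str = "0",
) -> PathwayModel:
    """Estimate the observation layer from a labeled two-class cohort.

    Per included probeset present in ``expr``: the threshold t_j is the
    midpoint between the class-conditional medians (or the pooled median),
    and (c_j, d_j) are Laplace-smoothed frequencies of high calls in the
    active and inactive class.  Gene-layer CPTs default to
    (0.95, 0.05) for every gene.  Probesets whose calibrated c_j <= d_j are
    excluded (``anticorrelated``) or, with ``on_anticorrelated='invert'``,
    kept with flipped call polarity.  Constant probesets fall back to the
    default CPT with a warning.  The returned model is NOT frozen.
    """
    if pseudocount <= 0:
        raise CalibrationError("pseudocount must be positive")
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.astype(str)
    known = [s for s in expr.sample_ids if s in labels.index]
    active = [s for s in known if labels[s] == "active"]
    inactive = [s for s in known if labels[s] == "inactive"]
    if not active or not inactive:
        raise CalibrationError(
            f"both classes must be non-empty (active={len(active)}, "
            f"inactive={len(inactive)})"
        )
    pmap.validate_against(panel)

    gene_cpt = dict(gene_cpt) if gene_cpt else {
        g: (DEFAULT_GENE_UP_GIVEN_ACTIVE, DEFAULT_GENE_UP_GIVEN_INACTIVE)
        for g in panel.genes
    }

    thresholds: dict[str, float] = {}
    cpt: dict[str, tuple[float, float]] = {}
    raw_cpt: dict[str, tuple[float, float]] = {}
    excluded: dict[str, str] = {}
    inverted: set[str] = set()

    act = expr.data[active]
    ina = expr.data[inactive]
    for gene in panel.genes:
        for j in probesets_for_gene(pmap, gene):
            if j not in expr.data.index:
                excluded[j] = "not_in_calibration"
                continue
            va = act.loc[j].dropna()
            vi = ina.loc[j].dropna()
            pooled = pd.concat([va, vi])
            if len(va) == 0 or len(vi) == 0:
                excluded[j] = "not_in_calibration"
                continue
            if pooled.nunique() <= 1:
                warnings.warn(
                    f"probeset {j} is constant across the calibration cohort; "
                    "using default CPT"
                )
                thresholds[j] = float(pooled.iloc[0])
                cpt[j] = DEFAULT_PROBESET_CPT
                raw_cpt[j] = DEFAULT_PROBESET_CPT
                continue
            if threshold_method == "class_median_midpoint":
                t = 0.5 * (float(va.median()) + float(vi.median()))
            elif threshold_method == "pooled_median":
                t = float(pooled.median())
            else:
                raise CalibrationError(f"unknown threshold method {threshold_method!r}")
            thresholds[j] = t
            c = (float((va > t).sum()) + pseudocount) / (len(va) + 2 * pseudocount)
            d = (float((vi > t).sum()) + pseudocount) / (len(vi) + 2 * pseudocount)
            raw_cpt[j] = (c, d)
            if c > d:
                cpt[j] = (c, d)
            elif c == d:
                excluded[j] = "anticorrelated"
                cpt[j] = (c, d)
            else:
                if on_anticorrelated == "invert":
                    # flip call polarity: high-evidence state becomes "below t"
                    inverted.add(j)
                    c_inv = (float((va <= t).sum()) + pseudocount) / (len(va) + 2 * pseudocount)
                    d_inv = (float((vi <= t).sum()) + pseudocount) / (len(vi) + 2 * pseudocount)
                    cpt[j] = (c_inv, d_inv)
                else:
                    excluded[j] = "anticorrelated"
                    cpt[j] = (c, d)

    if not cpt:
        raise CalibrationError(
            "no panel probeset found in the expression matrix; check that it "
            "uses the panel's probeset ids"
        )
    return PathwayModel(
        panel=panel,
        probeset_map=pmap,
        prior_active=prior_active,
        gene_cpt=gene_cpt,
        probeset_cpt=cpt,
        raw_probeset_cpt=raw_cpt,
        thresholds=thresholds,
        excluded=excluded,
        inverted=frozenset(inverted),
        frozen=False,
        version=version,
    )


def freeze(model: PathwayModel) -> PathwayModel:
    """Return a frozen copy; frozen models are read-only for scoring."""
    return replace(model, frozen=True)


def recalibrate(model: PathwayModel, *args, **kwargs) -> PathwayModel:
    """Refuse to recalibrate a frozen model; delegate otherwise."""
    if model.frozen:
        raise FrozenModelError(
            "model is frozen; calibrate a new model instead of mutating this one"
        )
    return calibrate(*args, **kwargs)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _gene_likelihood(
    model: PathwayModel, gene: str, ev: EvidenceVector
) -> tuple[float, float] | None:
    """(L_g(active), L_g(inactive)) marginalizing the gene state; None if no evidence."""
    probesets = [
        j for j in model.active_probesets(gene) if ev.calls.get(j, "missing") != "missing"
    ]
    if not probesets:
        return None
    lik_up = 1.0
    lik_down = 1.0
    for j in probesets:
        c, d = model.probeset_cpt[j]
        if ev.calls[j] == "high":
            lik_up *= c
            lik_down *= d
        else:
            lik_up *= 1.0 - c
            lik_down *= 1.0 - d
    a, b = model.gene_cpt[gene]
    return (a * lik_up + (1 - a) * lik_down, b * lik_up + (1 - b) * lik_down)


def infer_log2odds(model: PathwayModel, ev: EvidenceVector) -> float:
    """Posterior log2-odds of pathway activity given one sample's calls.

    Exact marginalization: genes are conditionally independent given TC and
    probesets conditionally independent given their gene, so the joint
    likelihood factorizes per gene with a two-term sum over the gene state.
    Missing calls contribute no evidence; a sample with no informative call
    raises :class:`ScoringError`.
    """
    if not model.frozen:
        raise FrozenModelError("model must be frozen before scoring")
    log_odds = math.log2(model.prior_active) - math.log2(1.0 - model.prior_active)
    informative = 0
    for gene in model.panel.genes:
        lik = _gene_likelihood(model, gene, ev)
        if lik is None:
            continue
        informative += 1
        log_odds += math.log2(lik[0]) - math.log2(lik[1])
    if informative == 0:
        raise ScoringError(f"sample {ev.sample_id!r}: all probeset calls missing")
    return log_odds


def brute_force_posterior(model: PathwayModel, ev: EvidenceVector) -> float:
    """Log2-odds by exhaustive enumeration of all (TC, G_1..G_n) completions.

    Independent oracle for :func:`infer_log2odds`; refuses state spaces
    larger than 2^20 joint assignments.
    """
    genes = [
        g
        for g in model.panel.genes
        if any(ev.calls.get(j, "missing") != "missing" for j in model.active_probesets(g))
    ]
    if not genes:
        # no evidence: the posterior is the prior
        return math.log2(model.prior_active) - math.log2(1.0 - model.prior_active)
    if 2 ** (len(genes) + 1) > 2 ** 20:
        raise ValidationError("latent state space exceeds 2^20; refusing enumeration")
    joint = {True: 0.0, False: 0.0}
    for tc in (True, False):
        p_tc = model.prior_active if tc else 1.0 - model.prior_active
        for states in itertools.product((True, False), repeat=len(genes)):
            p = p_tc
            for g, up in zip(genes, states):
                a, b = model.gene_cpt[g]
                p_up = a if tc else b
                p *= p_up if up else 1.0 - p_up
                for j in model.active_probesets(g):
                    call = ev.calls.get(j, "missing")
                    if call == "missing":
                        continue
                    c, d = model.probeset_cpt[j]
                    p_high = c if up else d
                    p *= p_high if call == "high" else 1.0 - p_high
            joint[tc] += p
    return math.log2(joint[True]) - math.log2(joint[False])


def score_samples(model: PathwayModel, expr: ExpressionMatrix) -> ActivityScoreTable:
    """Score every sample of a matrix; per-sample failures recorded, not fatal.

    Scores depend only on each sample's own calls, never on the rest of the
    batch.
    """
    if not model.frozen:
        raise FrozenModelError("model must be frozen before scoring")
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise InputError("cannot score an empty expression matrix")
    rows = []
    failures: dict[str, str] = {}
    for ev in discretize(expr, model):
        try:
            score = infer_log2odds(model, ev)
        except ScoringError as exc:
            failures[ev.sample_id] = str(exc)
            continue
        rows.append(
            {
                "sample_id": ev.sample_id,
                "log2_odds": score,
                "n_probesets_used": ev.n_informative(),
            }
        )
    frame = pd.DataFrame(rows, columns=["sample_id", "log2_odds", "n_probesets_used"])
    return ActivityScoreTable(scores=frame, failures=failures)
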