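"""Estimator-style front end: ``PathwayActivityModel(...).fit()`` -> results.

This wraps the functional core in :mod:`notchscore.model` with the familiar
model/results idiom: construct the model from a labeled calibration cohort,
``fit()`` it, and use the returned :class:`PathwayActivityResults` to
inspect parameters (``params``, ``summary()``), score new cohorts
(``score``) and persist the frozen assay (``save``/``load``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from . import model as _core
from .errors import FrozenModelError
from .expression import ExpressionMatrix
from .genesets import ProbesetMap, TargetGenePanel, load_config


class PathwayActivityModel:
    """Pathway-activity assay to be calibrated on a labeled two-class cohort.

    Parameters
    ----------
    expr
        Calibration expression matrix (probesets x samples, log2 scale).
    labels
        ``sample_id -> {"active", "inactive"}`` for the calibration samples.
    panel, probeset_map
        Gene panel and probeset mapping; default to the shipped Notch panel.
    prior_active
        Prior probability of the active transcription-complex state.  The
        default 0.5 makes the score a pure evidence measure.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        labels: Mapping[str, str] | pd.Series,
        panel: TargetGenePanel | None = None,
        probeset_map: ProbesetMap | None = None,
        prior_active: float = 0.5,
    ):
        if panel is None or probeset_map is None:
            shipped_panel, shipped_map = load_config()
            panel = panel or shipped_panel
            probeset_map = probeset_map or shipped_map
        self.expr = expr
        self.labels = labels
        self.panel = panel
        self.probeset_map = probeset_map
        self.prior_active = prior_active
        self._results: "PathwayActivityResults | None" = None

    @classmethod
    def from_files(
        cls,
        expr_path: str | Path,
        labels_path: str | Path,
        panel_path: str | Path | None = None,
        **kwargs,
    ) -> "PathwayActivityModel":
        from .expression import read_annotation_table, read_expression_table

        expr = read_expression_table(expr_path)
        ann = read_annotation_table(labels_path)
        if "label" not in ann.columns:
            from .errors import ParseError

            raise ParseError(f"{labels_path}: labels table must have a 'label' column")
        labels = ann.set_index("sample_id")["label"]
        panel, pmap = load_config(panel_path)
        return cls(expr, labels, panel=panel, probeset_map=pmap, **kwargs)

    def fit(
        self,
        pseudocount: float = 1.0,
        threshold_method: Literal[
            "class_median_midpoint", "pooled_median"
        ] = "class_median_midpoint",
        on_anticorrelated: Literal["exclude", "invert"] = "exclude",
        gene_cpt: Mapping[str, tuple[float, float]] | None = None,
        version: str = "0",
    ) -> "PathwayActivityResults":
        """Calibrate the observation layer and return frozen results.

        Refitting an already-fitted (hence frozen) assay is refused; build a
        new :class:`PathwayActivityModel` instead.
        """
        if self._results is not None:
            raise FrozenModelError(
                "this assay was already fitted and frozen; construct a new "
                "PathwayActivityModel to recalibrate"
            )
        fitted = _core.calibrate(
            self.expr,
            self.labels,
            self.panel,
            self.probeset_map,
            pseudocount=pseudocount,
            prior_active=self.prior_active,
            gene_cpt=gene_cpt,
            threshold_method=threshold_method,
            on_anticorrelated=on_anticorrelated,
            version=version,
        )
        self._results = PathwayActivityResults(_core.freeze(fitted), parent=self)
        return self._results


class PathwayActivityResults:
    """Frozen calibrated assay: parameters, diagnostics, scoring."""

    def __init__(self, pathway_model: _core.PathwayModel, parent=None):
        if not pathway_model.frozen:
            pathway_model = _core.freeze(pathway_model)
        self.pathway_model = pathway_model
        self.model = parent

    # -- parameters ---------------------------------------------------------

    @property
    def params(self) -> pd.DataFrame:
        """Per-probeset parameter table (gene, threshold, CPT, status)."""
        pm = self.pathway_model
        rows = []
        for e in pm.probeset_map.entries:
            j = e.probeset_id
            c, d = pm.probeset_cpt.get(j, (float("nan"), float("nan")))
            c_raw, d_raw = pm.raw_probeset_cpt.get(j, (float("nan"), float("nan")))
            if not e.included:
                status = f"excluded:{e.reason}"
            elif j in pm.excluded:
                status = f"excluded:{pm.excluded[j]}"
            elif j in pm.inverted:
                status = "inverted"
            else:
                status = "active"
            rows.append(
                {
                    "probeset_id": j,
                    "gene": e.gene,
                    "threshold": pm.thresholds.get(j, float("nan")),
                    "p_high_given_up": c,
                    "p_high_given_down": d,
                    "p_high_given_up_raw": c_raw,
                    "p_high_given_down_raw": d_raw,
                    "status": status,
                }
            )
        return pd.DataFrame(rows).set_index("probeset_id")

    @property
    def gene_params(self) -> pd.DataFrame:
        pm = self.pathway_model
        return pd.DataFrame(
            {
                "p_up_given_active": {g: v[0] for g, v in pm.gene_cpt.items()},
                "p_up_given_inactive": {g: v[1] for g, v in pm.gene_cpt.items()},
            }
        ).rename_axis("gene")

    def summary(self) -> str:
        pm = self.pathway_model
        p = self.params
        n_active = int((p["status"] == "active").sum())
        n_excluded = int(p["status"].str.startswith("excluded").sum())
        lines = [
            f"Pathway activity assay: {pm.panel.pathway_name} "
            f"(panel v{pm.panel.version}, model v{pm.version})",
            "=" * 72,
            f"genes: {len(pm.panel)}    probesets: {len(pm.probeset_map.entries)} "
            f"(active {n_active}, excluded {n_excluded}, inverted {len(pm.inverted)})",
            f"prior P(active): {pm.prior_active:.3f}    frozen: {pm.frozen}",
            f"content hash: {pm.content_hash()[:16]}…",
            "-" * 72,
            p.to_string(
                float_format=lambda v: f"{v:.4f}",
                columns=[
                    "gene",
                    "threshold",
                    "p_high_given_up",
                    "p_high_given_down",
                    "status",
                ],
            ),
        ]
        return "\n".join(lines)

    # -- scoring ------------------------------------------------------------

    def score(self, expr: ExpressionMatrix) -> _core.ActivityScoreTable:
        """Per-sample posterior log2-odds of pathway activity."""
        return _core.score_samples(self.pathway_model, expr)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self.pathway_model.save(path)

    @staticmethod
    def load(path: str | Path) -> "PathwayActivityResults":
        return PathwayActivityResults(_core.PathwayModel.load(path))
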