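"""Downstream clinical analysis of activity scores in a leukemia cohort.

Implements the analysis pipeline applied to T-ALL: classify NOTCH1/FBXW7
mutations into none/weak/strong activation strength, compare activity scores
across groups (Kruskal–Wallis), correlate scores with ICN1 protein levels
(Pearson + Spearman), split the cohort into low/middle/high activity groups
at the 25th/75th score percentiles, compare survival (Kaplan–Meier +
log-rank), and test the association between low activity and functional
PTEN loss (Pearson chi-square, no continuity correction).

Mutation-strength rules: *strong* = juxtamembrane-domain mutation, or a
heterodimerization-domain mutation combined with a PEST-domain or FBXW7
mutation; *weak* = any single HD / PEST / FBXW7 hit that is not strong;
*none* otherwise.  Samples with unknown mutation status are excluded from
mutation-based analyses but kept everywhere else (listwise deletion per
analysis, with the per-analysis n reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ValidationError

MUTATION_CLASSES = ("none", "weak", "strong")
ACTIVITY_GROUPS = ("low", "middle", "high")


def classify_notch_mutation(
    hd: bool, pest: bool, jme: bool, fbxw7: bool, status_known: bool = True
) -> str | None:
    """Mutation activation strength: 'strong', 'weak' or 'none'.

    Returns ``None`` when the mutation status is unknown; callers drop such
    samples from mutation-based analyses.
    """
    if not status_known:
        return None
    if jme or (hd and (pest or fbxw7)):
        return "strong"
    if hd or pest or fbxw7:
        return "weak"
    return "none"


def add_mutation_class(clinical: pd.DataFrame) -> pd.DataFrame:
    """Append a ``mutation_class`` column (None where status unknown)."""
    out = clinical.copy()
    out["mutation_class"] = [
        classify_notch_mutation(
            bool(r.hd), bool(r.pest), bool(r.jme), bool(r.fbxw7), bool(r.status_known)
        )
        for r in clinical.itertuples()
    ]
    return out


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    medians: dict[str, float]
    group_sizes: dict[str, int]


def kruskal_wallis_by_group(
    scores: pd.Series, groups: pd.Series
) -> GroupComparison:
    """Tie-corrected Kruskal–Wallis H test across ≥2 non-empty groups.

    Empty groups are dropped with a warning; missing scores/group labels are
    removed listwise.
    """
    df = pd.DataFrame({"score": scores, "group": groups}).dropna()
    arrays = {g: sub["score"].to_numpy() for g, sub in df.groupby("group", observed=True)}
    empty = [g for g, a in arrays.items() if len(a) == 0]
    for g in empty:
        warnings.warn(f"group {g!r} is empty; dropped")
        del arrays[g]
    if len(arrays) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 non-empty groups")
    values = list(arrays.values())
    if all(np.all(v == values[0][0]) for v in values):
        # degenerate: every observation identical -> no evidence of difference
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)
    return GroupComparison(
        statistic=float(h),
        p_value=float(p),
        medians={g: float(np.median(a)) for g, a in arrays.items()},
        group_sizes={g: int(len(a)) for g, a in arrays.items()},
    )


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def icn1_correlation(icn1: pd.Series, scores: pd.Series) -> CorrelationResult:
    """Pearson and Spearman correlation between protein level and score.

    Pairs with a missing value on either side are dropped listwise; a
    constant vector makes the correlation undefined and raises.
    """
    df = pd.DataFrame({"icn1": icn1, "score": scores}).dropna()
    if len(df) < 3:
        raise ValidationError("need at least 3 paired non-missing observations")
    if df["icn1"].nunique() == 1 or df["score"].nunique() == 1:
        raise ValidationError("correlation undefined for a constant vector")
    pr = stats.pearsonr(df["icn1"], df["score"])
    sr = stats.spearmanr(df["icn1"], df["score"])
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=len(df),
    )


def assign_activity_groups(scores: pd.Series) -> pd.Series:
    """Split a cohort at the 25th/75th score percentiles into low/middle/high.

    Quartiles use the linear-interpolation definition; a score exactly equal
    to Q1 or Q3 is *middle* (the outer groups are strictly < Q1 / > Q3).
    Group membership is invariant under monotone transforms of the score.
    """
    s = scores.dropna()
    if len(s) < 4:
        raise ValidationError("need at least 4 samples to form quartile groups")
    q1, q3 = np.percentile(s.to_numpy(), [25, 75])
    out = pd.Series("middle", index=s.index, dtype=object)
    out[s < q1] = "low"
    out[s > q3] = "high"
    return out.reindex(scores.index)


@dataclass
class SurvivalComparison:
    chi2: float
    p_value: float
    group_sizes: dict[str, int]
    n_events: int
    #: per-group Kaplan-Meier survival curves (index: time, column: estimate)
    curves: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)


def km_logrank(
    groups: pd.Series, time: pd.Series, event: pd.Series
) -> SurvivalComparison:
    """Kaplan–Meier curves per group plus the k-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame({"group": groups, "time": time, "event": event}).dropna()
    if (df["time"] < 0).any():
        raise ValidationError("survival times must be >= 0")
    if df["group"].nunique() < 2:
        raise ValidationError("log-rank needs at least 2 groups")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValidationError("log-rank p undefined with zero events")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    curves = {}
    for g, sub in df.groupby("group", observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[str(g)] = kmf.survival_function_
    return SurvivalComparison(
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=df.groupby("group", observed=True).size().to_dict(),
        n_events=n_events,
        curves=curves,
    )


@dataclass
class ContingencyResult:
    table: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    p_value: float
    n: int


def pten_association(
    groups: pd.Series, pten_loss: pd.Series
) -> ContingencyResult:
    """Low-activity vs rest x PTEN loss, Pearson chi-square (df=1, 2-sided).

    Activity groups are collapsed to {low} vs {middle, high}; samples with
    missing PTEN status are dropped.  The statistic is the classical Pearson
    chi-square WITHOUT Yates continuity correction.
    """
    df = pd.DataFrame({"group": groups, "pten": pten_loss}).dropna()
    df["row"] = np.where(df["group"] == "low", "low", "middle+high")
    df["col"] = np.where(df["pten"].astype(float) > 0, "pten_loss", "pten_intact")
    table = (
        df.pivot_table(index="row", columns="col", aggfunc="size", fill_value=0)
        .reindex(index=["low", "middle+high"], columns=["pten_loss", "pten_intact"])
        .fillna(0)
        .astype(int)
    )
    return chi_square_2x2(table)


def chi_square_2x2(table: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    arr = table.to_numpy(dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError(f"zero margin in contingency table:\n{table}")
    chi2, p, _, expected = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        table=table,
        expected=pd.DataFrame(expected, index=table.index, columns=table.columns),
        chi2=float(chi2),
        p_value=float(p),
        n=int(arr.sum()),
    )


def wilcoxon_two_condition(
    a, b, paired: bool = False
) -> tuple[float, float]:
    """Two-sided rank test between two conditions -> (statistic, p).

    ``paired=True`` runs the Wilcoxon signed-rank test on the differences
    (all-zero differences are degenerate: p = 1 with a warning);
    ``paired=False`` runs the Wilcoxon rank-sum / Mann-Whitney U test, exact
    for small samples without ties, normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired test requires equal-length conditions")
        if np.all(a == b):
            warnings.warn("all paired differences are zero; degenerate test, p=1")
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("unpaired test requires both conditions non-empty")
    method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # ties make the exact method unavailable
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def analyze_cohort(
    scores: pd.Series, clinical: pd.DataFrame
) -> dict:
    """Run the full downstream pipeline; per-analysis skips recorded.

    Returns a JSON-serializable summary: mutation-class score comparison,
    subtype comparison (when present), ICN1 correlation, activity-group
    sizes, EFS/RFS log-rank, and the PTEN association.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    common = scores.index.intersection(clin.index)
    if len(common) == 0:
        raise InputError("no overlap between scored samples and clinical table")
    scores = scores.loc[common]
    clin = clin.loc[common]
    summary: dict = {"n_samples": int(len(common)), "skipped": {}}

    flag_cols = {"hd", "pest", "jme", "fbxw7", "status_known"}
    if flag_cols.issubset(clin.columns):
        mut = add_mutation_class(clin.reset_index()).set_index("sample_id")[
            "mutation_class"
        ]
        known = mut.dropna()
        try:
            cmp_ = kruskal_wallis_by_group(scores.loc[known.index], known)
            summary["mutation_class"] = {
                "H": cmp_.statistic,
                "p": cmp_.p_value,
                "medians": cmp_.medians,
                "n": cmp_.group_sizes,
            }
        except ValidationError as exc:
            summary["skipped"]["mutation_class"] = str(exc)
    else:
        summary["skipped"]["mutation_class"] = "mutation flag columns missing"

    if "subtype" in clin.columns:
        try:
            cmp_ = kruskal_wallis_by_group(scores, clin["subtype"])
            summary["subtype"] = {
                "H": cmp_.statistic,
                "p": cmp_.p_value,
                "medians": cmp_.medians,
                "n": cmp_.group_sizes,
            }
        except ValidationError as exc:
            summary["skipped"]["subtype"] = str(exc)
    else:
        summary["skipped"]["subtype"] = "subtype column missing"

    if "icn1" in clin.columns:
        try:
            corr = icn1_correlation(clin["icn1"], scores)
            summary["icn1"] = {
                "pearson_r": corr.pearson_r,
                "pearson_p": corr.pearson_p,
                "spearman_rho": corr.spearman_rho,
                "spearman_p": corr.spearman_p,
                "n": corr.n,
            }
        except ValidationError as exc:
            summary["skipped"]["icn1"] = str(exc)
    else:
        summary["skipped"]["icn1"] = "icn1 column missing"

    groups = assign_activity_groups(scores)
    summary["activity_groups"] = groups.value_counts().to_dict()

    for endpoint in ("efs", "rfs"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if {tcol, ecol}.issubset(clin.columns):
            try:
                surv = km_logrank(groups, clin[tcol], clin[ecol])
                summary[f"{endpoint}_logrank"] = {
                    "chi2": surv.chi2,
                    "p": surv.p_value,
                    "n": surv.group_sizes,
                    "events": surv.n_events,
                }
            except ValidationError as exc:
                summary["skipped"][f"{endpoint}_logrank"] = str(exc)
        else:
            summary["skipped"][f"{endpoint}_logrank"] = "survival columns missing"

    if "pten_loss" in clin.columns:
        try:
            pten = pten_association(groups, clin["pten_loss"])
            summary["pten"] = {
                "chi2": pten.chi2,
                "p": pten.p_value,
                "n": pten.n,
                "table": {
                    str(r): {str(c): int(v) for c, v in row.items()}
                    for r, row in pten.table.to_dict(orient="index").items()
                },
            }
        except ValidationError as exc:
            summary["skipped"]["pten"] = str(exc)
    else:
        summary["skipped"]["pten"] = "pten_loss column missing"

    return summary
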