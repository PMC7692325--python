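import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notchscore import (
    EvidenceVector,
    ExpressionMatrix,
    PathwayActivityModel,
    PathwayModel,
    brute_force_posterior,
    calibrate,
    discretize,
    freeze,
    infer_log2odds,
    make_panel,
    recalibrate,
    score_samples,
    simulate_calibration_cohort,
    synthetic_probeset_map,
    SyntheticCohortSpec,
)
from notchscore.errors import (
    CalibrationError,
    FrozenModelError,
    InputError,
    ScoringError,
    ValidationError,
)
from conftest import auc, build_model, random_evidence, random_model


def two_class_cohort(**kw):
    spec = SyntheticCohortSpec(**kw)
    panel = make_panel([f"G{i+1}" for i in range(5)])
    pmap = synthetic_probeset_map(panel, spec.probesets_per_gene)
    expr, labels = simulate_calibration_cohort(spec, panel, pmap)
    return expr, labels, panel, pmap


class TestDiscretize:
    def test_threshold_convention(self):
        model = build_model(["G1"], thresholds=7.0)
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [8.2], "s2": [7.0], "s3": [6.9]}, index=["G1_ps1"])
        )
        calls = {ev.sample_id: ev.calls["G1_ps1"] for ev in discretize(expr, model)}
        assert calls == {"s1": "high", "s2": "low", "s3": "low"}

    def test_absent_or_nonfinite_is_missing(self):
        model = build_model(["G1", "G2"], thresholds=7.0)
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [8.0, np.nan]}, index=["G1_ps1", "G2_ps1"])
        )
        ev = discretize(expr, model)[0]
        assert ev.calls["G2_ps1"] == "missing"

    def test_no_overlap_is_an_input_error(self):
        model = build_model(["G1"])
        expr = ExpressionMatrix(pd.DataFrame({"s1": [8.0]}, index=["other_ps"]))
        with pytest.raises(InputError):
            discretize(expr, model)


class TestCalibrate:
    def test_recovers_class_direction_and_matches_direct_counting(self):
        expr, labels, panel, pmap = two_class_cohort(
            n_active=20, n_inactive=20, delta=2.0, sigma_probeset=0.5, seed=1
        )
        model = calibrate(expr, labels, panel, pmap, pseudocount=1.0)
        active = [s for s in labels.index if labels[s] == "active"]
        inactive = [s for s in labels.index if labels[s] == "inactive"]
        for j in model.all_active_probesets():
            c, d = model.probeset_cpt[j]
            assert c > d
            # independent oracle: recount high calls directly from the matrix
            t = model.thresholds[j]
            c_ref = ((expr.data.loc[j, active] > t).sum() + 1) / (len(active) + 2)
            d_ref = ((expr.data.loc[j, inactive] > t).sum() + 1) / (len(inactive) + 2)
            assert c == pytest.approx(c_ref, abs=1e-12)
            assert d == pytest.approx(d_ref, abs=1e-12)

    def test_large_pseudocount_shrinks_cpts_to_half(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=10, n_inactive=10, seed=2)
        model = calibrate(expr, labels, panel, pmap, pseudocount=1e9)
        for j, (c, d) in model.raw_probeset_cpt.items():
            assert c == pytest.approx(0.5, abs=1e-6)
            assert d == pytest.approx(0.5, abs=1e-6)

    def test_identical_classes_give_symmetric_raw_cpts(self):
        rng = np.random.default_rng(3)
        panel = make_panel(["G1", "G2"])
        pmap = synthetic_probeset_map(panel, 2)
        block = rng.normal(7, 1, size=(4, 6))
        expr = ExpressionMatrix(
            pd.DataFrame(
                np.hstack([block, block]),
                index=pmap.probeset_ids,
                columns=[f"a{i}" for i in range(6)] + [f"i{i}" for i in range(6)],
            )
        )
        labels = pd.Series(["active"] * 6 + ["inactive"] * 6, index=expr.sample_ids)
        model = calibrate(expr, labels, panel, pmap)
        for c, d in model.raw_probeset_cpt.values():
            assert c == pytest.approx(d)
        # symmetric probesets carry no direction and are excluded from scoring
        assert set(model.excluded.values()) == {"anticorrelated"}

    def test_empty_class_is_a_calibration_error(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=5, n_inactive=5, seed=4)
        with pytest.raises(CalibrationError):
            calibrate(expr, labels.replace("inactive", "active"), panel, pmap)

    def test_constant_probeset_falls_back_to_default_cpt(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=5, n_inactive=5, seed=5)
        expr.data.iloc[0, :] = 7.0
        j = expr.probeset_ids[0]
        with pytest.warns(UserWarning, match="constant"):
            model = calibrate(expr, labels, panel, pmap)
        assert model.probeset_cpt[j] == (0.75, 0.25)

    def test_inversion_keeps_anticorrelated_probesets_usable(self):
        expr, labels, panel, pmap = two_class_cohort(
            n_active=20, n_inactive=20, delta=2.0, seed=6
        )
        j = expr.probeset_ids[0]
        expr.data.loc[j] = -expr.data.loc[j]  # flip one probeset's direction
        excl = calibrate(expr, labels, panel, pmap, on_anticorrelated="exclude")
        assert excl.excluded.get(j) == "anticorrelated"
        inv = calibrate(expr, labels, panel, pmap, on_anticorrelated="invert")
        assert j in inv.inverted
        c, d = inv.probeset_cpt[j]
        assert c > d


class TestFreezeContract:
    def test_frozen_scoring_is_deterministic_and_read_only(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=8, n_inactive=8, seed=7)
        model = freeze(calibrate(expr, labels, panel, pmap))
        before = model.to_dict()
        s1 = score_samples(model, expr).scores
        s2 = score_samples(model, expr).scores
        pd.testing.assert_frame_equal(s1, s2)
        assert model.to_dict() == before

    def test_recalibration_of_frozen_model_refused(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=5, n_inactive=5, seed=8)
        model = freeze(calibrate(expr, labels, panel, pmap))
        with pytest.raises(FrozenModelError):
            recalibrate(model, expr, labels, panel, pmap)

    def test_estimator_refuses_refit(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=5, n_inactive=5, seed=8)
        est = PathwayActivityModel(expr, labels, panel=panel, probeset_map=pmap)
        est.fit()
        with pytest.raises(FrozenModelError):
            est.fit()

    def test_serialization_round_trip_preserves_scores(self, tmp_path):
        expr, labels, panel, pmap = two_class_cohort(n_active=8, n_inactive=8, seed=9)
        model = freeze(calibrate(expr, labels, panel, pmap))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PathwayModel.load(path)
        pd.testing.assert_frame_equal(
            score_samples(model, expr).scores, score_samples(loaded, expr).scores
        )
        assert loaded.content_hash() == model.content_hash()

    def test_tampered_model_file_rejected(self, tmp_path):
        expr, labels, panel, pmap = two_class_cohort(n_active=5, n_inactive=5, seed=10)
        model = freeze(calibrate(expr, labels, panel, pmap))
        path = tmp_path / "model.json"
        model.save(path)
        path.write_text(path.read_text().replace("0.5", "0.6", 1))
        with pytest.raises(ValidationError):
            PathwayModel.load(path)

    def test_unfrozen_model_cannot_score(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=5, n_inactive=5, seed=11)
        model = calibrate(expr, labels, panel, pmap)
        with pytest.raises(FrozenModelError):
            score_samples(model, expr)


class TestInference:
    def test_two_gene_model_matches_enumeration_and_closed_form(self):
        model = build_model(["G1", "G2"], a=0.9, b=0.1, c=0.8, d=0.2)
        ev = EvidenceVector("s", {"G1_ps1": "high", "G2_ps1": "high"})
        score = infer_log2odds(model, ev)
        assert score == pytest.approx(brute_force_posterior(model, ev), abs=1e-12)
        # closed form: per gene (0.9*0.8 + 0.1*0.2) / (0.1*0.8 + 0.9*0.2)
        expected = 2 * math.log2((0.9 * 0.8 + 0.1 * 0.2) / (0.1 * 0.8 + 0.9 * 0.2))
        assert score == pytest.approx(expected, abs=1e-12)

    def test_complementary_cpts_make_all_low_the_negation(self):
        model = build_model(["G1", "G2"], a=0.9, b=0.1, c=0.8, d=0.2)
        hi = EvidenceVector("s", {"G1_ps1": "high", "G2_ps1": "high"})
        lo = EvidenceVector("s", {"G1_ps1": "low", "G2_ps1": "low"})
        assert infer_log2odds(model, lo) == pytest.approx(
            -infer_log2odds(model, hi), abs=1e-12
        )

    def test_symmetric_evidence_scores_zero(self):
        # one high and one low call on probesets with complementary CPTs
        model = build_model(["G1"], probesets_per_gene=2, a=0.9, b=0.1, c=0.8, d=0.2)
        ev = EvidenceVector("s", {"G1_ps1": "high", "G1_ps2": "low"})
        assert infer_log2odds(model, ev) == pytest.approx(0.0, abs=1e-12)

    def test_prior_only_enumeration(self):
        model = build_model(["G1"], prior=0.8)
        ev = EvidenceVector("s", {"G1_ps1": "missing"})
        assert brute_force_posterior(model, ev) == pytest.approx(2.0, abs=1e-12)

    def test_all_missing_is_a_scoring_error(self):
        model = build_model(["G1"])
        with pytest.raises(ScoringError):
            infer_log2odds(model, EvidenceVector("s", {"G1_ps1": "missing"}))

    def test_one_gene_one_probeset_closed_form(self):
        model = build_model(["G1"], a=0.9, b=0.1, c=0.8, d=0.2)
        ev = EvidenceVector("s", {"G1_ps1": "high"})
        expected = math.log2((0.9 * 0.8 + 0.1 * 0.2) / (0.1 * 0.8 + 0.9 * 0.2))
        assert brute_force_posterior(model, ev) == pytest.approx(expected, abs=1e-12)

    def test_missing_call_equals_model_without_that_probeset(self):
        rng = np.random.default_rng(12)
        model = build_model(["G1", "G2"], probesets_per_gene=2)
        ev_full = random_evidence(model, rng, p_missing=0.0)
        calls = dict(ev_full.calls)
        calls["G1_ps2"] = "missing"
        # same model with the probeset physically removed
        entries = tuple(e for e in model.probeset_map.entries if e.probeset_id != "G1_ps2")
        reduced = freeze(
            dataclasses.replace(
                model,
                frozen=False,
                probeset_map=dataclasses.replace(model.probeset_map, entries=entries),
                probeset_cpt={j: v for j, v in model.probeset_cpt.items() if j != "G1_ps2"},
                thresholds={j: v for j, v in model.thresholds.items() if j != "G1_ps2"},
            )
        )
        assert infer_log2odds(model, EvidenceVector("s", calls)) == pytest.approx(
            infer_log2odds(reduced, EvidenceVector("s", calls)), abs=1e-12
        )

    def test_state_space_guard(self):
        model = build_model([f"G{i}" for i in range(25)])
        ev = EvidenceVector("s", {f"G{i}_ps1": "high" for i in range(25)})
        with pytest.raises(ValidationError):
            brute_force_posterior(model, ev)


class TestInferenceProperties:
    def test_equals_enumeration_on_100_random_models(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            model = random_model(rng)
            ev = random_evidence(model, rng)
            delta = abs(infer_log2odds(model, ev) - brute_force_posterior(model, ev))
            worst = max(worst, delta)
        assert worst < 1e-9

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_single_low_to_high_flip_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        ev = random_evidence(model, rng)
        base = infer_log2odds(model, ev)
        low_calls = [j for j, v in ev.calls.items() if v == "low"]
        for j in low_calls:
            flipped = dict(ev.calls)
            flipped[j] = "high"
            assert infer_log2odds(model, EvidenceVector("s", flipped)) >= base - 1e-12

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_complementary_model_negates_score_under_call_inversion(self, seed):
        rng = np.random.default_rng(seed)
        a = float(rng.uniform(0.55, 0.95))
        c = float(rng.uniform(0.55, 0.95))
        model = build_model(["G1", "G2"], probesets_per_gene=2, a=a, b=1 - a, c=c, d=1 - c)
        ev = random_evidence(model, rng, p_missing=0.0)
        inverted = {
            j: ("high" if v == "low" else "low") for j, v in ev.calls.items()
        }
        assert infer_log2odds(model, EvidenceVector("s", inverted)) == pytest.approx(
            -infer_log2odds(model, ev), abs=1e-9
        )


class TestScoreSamples:
    def test_scores_are_independent_of_batch_composition(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=6, n_inactive=6, seed=13)
        model = freeze(calibrate(expr, labels, panel, pmap))
        full = score_samples(model, expr).as_series()
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.sample_ids).tolist()
        permuted = score_samples(model, expr.subset_samples(perm)).as_series()
        pd.testing.assert_series_equal(full.sort_index(), permuted.sort_index())
        # scoring a subset yields identical per-sample values
        sub = score_samples(model, expr.subset_samples(perm[:3])).as_series()
        pd.testing.assert_series_equal(sub, full.loc[sub.index], check_names=False)

    def test_duplicated_sample_gets_equal_score(self):
        expr, labels, panel, pmap = two_class_cohort(n_active=4, n_inactive=4, seed=14)
        model = freeze(calibrate(expr, labels, panel, pmap))
        dup = expr.data.copy()
        dup["copy"] = dup[expr.sample_ids[0]]
        scores = score_samples(model, ExpressionMatrix(dup)).as_series()
        assert scores["copy"] == scores[expr.sample_ids[0]]

    def test_two_class_cohort_separates_by_median(self):
        expr, labels, panel, pmap = two_class_cohort(
            n_active=20, n_inactive=20, delta=2.0, sigma_probeset=0.5, seed=2
        )
        model = freeze(calibrate(expr, labels, panel, pmap))
        s = score_samples(model, expr).as_series()
        assert s[labels == "active"].median() > s[labels == "inactive"].median()

    def test_empty_matrix_rejected(self):
        model = build_model(["G1"])
        with pytest.raises(InputError):
            score_samples(model, ExpressionMatrix(pd.DataFrame()))

    def test_per_sample_failures_do_not_abort_the_batch(self):
        model = build_model(["G1"])
        expr = ExpressionMatrix(
            pd.DataFrame({"ok": [8.0], "bad": [np.nan]}, index=["G1_ps1"])
        )
        table = score_samples(model, expr)
        assert list(table.scores["sample_id"]) == ["ok"]
        assert "bad" in table.failures
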