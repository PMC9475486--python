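import numpy as np
import pytest

import cdrstraj as ct
from cdrstraj.model import (
    FrozenModel,
    PipelineConfig,
    PipelineError,
    TreatmentCourseModel,
    replication_report,
)
from cdrstraj.rules import PrognosisRule


class TestFit:
    def test_full_pipeline_artifacts(self, fitted):
        assert len(fitted.paths) == 7
        assert fitted.prognostic_symptoms.item_ids == [2, 3, 6, 8, 10, 11]
        assert len(fitted.rules) == 6
        assert 0.4 < fitted.nir < 0.65
        text = fitted.summary()
        assert "stratum boundary" in text and "prognostic symptoms (6)" in text

    def test_placebo_training_aborts(self):
        cohort = ct.generate_cohort(ct.default_configs()["testing_placebo"], seed=23)
        model = TreatmentCourseModel(cohort, PipelineConfig(seed=0))
        with pytest.raises(PipelineError, match="no prognostic symptoms"):
            model.fit()

    def test_from_dataframe(self, training_cohort):
        model = TreatmentCourseModel.from_dataframe(
            training_cohort.frame, PipelineConfig(seed=17)
        )
        assert len(model.cohort) == 271


class TestFrozenModel:
    def test_round_trip_preserves_digest(self, tmp_path, fitted):
        frozen = fitted.to_frozen()
        path = tmp_path / "frozen.json"
        frozen.save(path)
        assert FrozenModel.load(path).digest() == frozen.digest()

    def _toy_frozen(self):
        """Frozen model with the published training rules."""
        items = (2, 3, 6, 8, 10, 11)
        rules = [
            PrognosisRule("A2", "B2", "response", "at_least", 2, 3, items),
            PrognosisRule("A2", "B1", "remission", "at_least", 2, 4, items),
            PrognosisRule("A1", "B3", "nonresponse", "at_most", 1, 5, items),
        ]
        import cdrstraj.pgm as pgm

        u3 = np.full((3, 3), 1 / 3)
        model = pgm.PGModel(
            pi=np.array([0.42, 0.58]), T1=np.full((2, 3), 1 / 3),
            T2=u3, E_mid=u3, E_end=u3, counts={},
        )
        return FrozenModel(
            boundary=55, pgm=model, paths=[], item_ids=items, rules=rules,
            rule_accuracies={"A2-B2": 0.86, "A2-B1": 0.67, "A1-B3": 0.66},
            nir=0.52,
        )

    def test_predict_patient_examples(self):
        frozen = self._toy_frozen()
        base = np.full(17, 4); base[[1, 2, 5]] = 5
        base[3] = base[4] = base[15] = 3
        b0 = int(base.sum())
        assert b0 >= 56  # A2 patient

        # A2 -> B2 with three prognostic items improved by >= 2 -> response
        mid = base.copy()
        for idx in (1, 2, 5):
            mid[idx] -= 2
        mid = _force_total(mid, 35)
        pred, rule = frozen.predict_patient(base, mid)
        assert pred == "response" and rule.mid == "B2"

        # same transition with no early change -> uncovered (total 38 keeps
        # the visit in the 29-39 band with the prognostic items untouched)
        mid2 = _force_total(base.copy(), 38, protect=(1, 2, 5, 7, 9, 10))
        pred, rule = frozen.predict_patient(base, mid2)
        assert pred == "uncovered" and rule is None
        pred_fb, _ = frozen.predict_patient(base, mid2, fallback_nonresponse=True)
        assert pred_fb == "nonresponse"

    def test_a1_nonresponse_rule(self):
        frozen = self._toy_frozen()
        base = np.full(17, 2); base[[1, 2, 5, 7, 9, 10]] = 4
        assert base.sum() == 46  # A1 patient
        mid = base.copy()
        mid[0] = 1  # improvement outside the prognostic set only
        assert mid.sum() == 45  # lands in B3 with all six items unchanged
        pred, rule = frozen.predict_patient(base, mid)
        assert pred == "nonresponse" and rule.direction == "at_most"

    def test_no_rule_for_transition(self):
        frozen = self._toy_frozen()
        base = np.full(17, 2); base[[1, 2, 5, 7, 9, 10]] = 4  # A1
        mid = _force_total(base.copy(), 35)
        pred, rule = frozen.predict_patient(base, mid)  # no A1-B2 rule on file
        assert pred == "uncovered" and rule is None


class TestReplication:
    def test_training_cohort_replicates_itself(self, fitted, training_cohort):
        rep = fitted.replicate(training_cohort)
        train = fitted.rule_frame
        merged = rep.table.merge(train, on=["baseline", "mid"], suffixes=("_rep", "_tr"))
        assert np.allclose(merged["accuracy_rep"], merged["accuracy_tr"])
        assert np.allclose(merged["coverage_rep"], merged["coverage_tr"])

    def test_replication_does_not_mutate_frozen_model(self, fitted):
        frozen = fitted.to_frozen()
        before = frozen.digest()
        cohort = ct.generate_cohort(ct.default_configs()["testing_duloxetine"], seed=5)
        replication_report(frozen, cohort)
        assert frozen.digest() == before

    def test_duloxetine_accuracy_near_printed(self, fitted):
        accs = []
        for seed in (41, 42, 43):
            cohort = ct.generate_cohort(
                ct.default_configs()["testing_duloxetine"], seed=seed
            )
            accs.append(fitted.replicate(cohort).mean_accuracy)
        assert np.mean(accs) == pytest.approx(0.75, abs=0.06)

    def test_placebo_nonresponse_rules_weakest(self, fitted):
        cohort = ct.generate_cohort(ct.default_configs()["testing_placebo"], seed=7)
        rep = fitted.replicate(cohort)
        assert rep.mean_accuracy == pytest.approx(0.67, abs=0.12)
        tab = rep.table
        nr = tab.loc[tab.predicted_outcome == "nonresponse", "accuracy"].mean()
        other = tab.loc[tab.predicted_outcome != "nonresponse", "accuracy"].mean()
        assert nr < other

    def test_predictions_ignore_end_visit(self, fitted, training_cohort):
        preds = fitted.predict(training_cohort)
        corrupted = training_cohort.frame.copy()
        from cdrstraj.cohort import ITEM_COLS, Cohort

        corrupted[ITEM_COLS["end"]] = 1
        preds2 = fitted.predict(Cohort(corrupted))
        assert (preds["predicted"] == preds2["predicted"]).all()


def _force_total(items, total, protect=()):
    """Adjust non-protected items until the vector sums to ``total``."""
    from cdrstraj.scale import ITEM_MAXES

    items = items.copy()
    free = [i for i in range(17) if i not in protect]
    j = 0
    guard = 0
    while items.sum() != total:
        i = free[j % len(free)]
        if items.sum() < total and items[i] < ITEM_MAXES[i]:
            items[i] += 1
        elif items.sum() > total and items[i] > 1:
            items[i] -= 1
        j += 1
        guard += 1
        if guard > 500:
            raise RuntimeError("could not hit target total")
    return items


def test_symptom_trajectory_plot(fitted, training_cohort):
    import matplotlib

    matplotlib.use("Agg")
    from cdrstraj.plotting import plot_symptom_trajectories

    ax = plot_symptom_trajectories(
        training_cohort, 8, paths=fitted.paths, mixture=fitted.mixture
    )
    assert ax.get_title() == "irritability"
    assert len(ax.lines) >= 3
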