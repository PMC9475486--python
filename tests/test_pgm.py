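import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdrstraj.pgm import (
    PGModel,
    count_possible_paths,
    enumerate_labelled_paths,
    estimate_pgm,
    forward_predict,
    most_likely_end_stratum,
    path_likelihood,
    select_symptom_dynamic_paths,
)
from conftest import fixed_mixture, make_cohort


def _model(pi, T1, T2, E_mid, E_end):
    m = PGModel(
        pi=np.asarray(pi, float), T1=np.asarray(T1, float),
        T2=np.asarray(T2, float), E_mid=np.asarray(E_mid, float),
        E_end=np.asarray(E_end, float), counts={},
    )
    m.validate()
    return m


def uniform_model():
    u3 = np.full((3, 3), 1 / 3)
    return _model([0.5, 0.5], np.full((2, 3), 1 / 3), u3, u3, u3)


def chain_model():
    """All probability mass on A1 -> B1 -> C1 with remission observations."""
    e = np.zeros((3, 3)); e[:, 0] = 1.0
    t1 = np.zeros((2, 3)); t1[:, 0] = 1.0
    t2 = np.zeros((3, 3)); t2[:, 0] = 1.0
    return _model([1.0, 0.0], t1, t2, e, e)


@st.composite
def random_models(draw):
    def rows(n, k):
        mat = np.array([[draw(st.floats(0.05, 1.0)) for _ in range(k)] for _ in range(n)])
        return mat / mat.sum(axis=1, keepdims=True)

    pi = rows(1, 2)[0]
    return _model(pi, rows(2, 3), rows(3, 3), rows(3, 3), rows(3, 3))


class TestPathLikelihood:
    def test_uniform_model_every_path_1_over_162(self):
        m = uniform_model()
        for path in enumerate_labelled_paths()[:10]:
            assert path_likelihood(m, path) == pytest.approx(1 / 162)

    def test_deterministic_chain(self):
        m = chain_model()
        assert path_likelihood(m, ("A1", "B1", "C1", "remission", "remission")) == 1.0
        assert path_likelihood(m, ("A1", "B2", "C1", "remission", "remission")) == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            path_likelihood(uniform_model(), ("A1", "B9", "C1", "remission", "remission"))

    @given(random_models())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_total_mass_is_one(self, model):
        """Brute-force enumeration of all 162 labelled paths sums to 1."""
        total = sum(path_likelihood(model, p) for p in enumerate_labelled_paths())
        assert total == pytest.approx(1.0, abs=1e-9)

    @given(random_models())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_forward_predict_matches_exhaustive_conditioning(self, model):
        for a, b, o in itertools.product(("A1", "A2"), ("B1", "B2", "B3"),
                                         ("remission", "response", "nonresponse")):
            pred = forward_predict(model, a, b, o)
            joint = np.zeros(3)
            for path in enumerate_labelled_paths():
                if path[0] == a and path[1] == b and path[3] == o:
                    joint[("C1", "C2", "C3").index(path[2])] += path_likelihood(model, path)
            assert np.allclose(pred, joint / joint.sum(), atol=1e-12)

    def test_forward_predict_tie_break_and_errors(self):
        assert most_likely_end_stratum(uniform_model(), "A1", "B2", "response") == "C1"
        m = chain_model()
        assert most_likely_end_stratum(m, "A1", "B1", "remission") == "C1"
        with pytest.raises(ValueError, match="zero probability"):
            forward_predict(m, "A2", "B1", "remission")


class TestCountPossiblePaths:
    @pytest.mark.parametrize("args,expected", [((2, 3, 2), 18), ((1, 1, 5), 1), ((2, 4, 2), 32)])
    def test_values(self, args, expected):
        assert count_possible_paths(*args) == expected

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            count_possible_paths(0, 3, 2)


class TestEstimatePGM:
    def test_count_fractions_by_hand(self):
        # 3 A1 patients all to B1/C1; 2 A2 patients split B2/B3
        cohort = make_cohort(
            [(50, 22, 22), (50, 25, 24), (50, 28, 26), (60, 30, 30), (60, 45, 50)]
        )
        model = estimate_pgm(cohort, fixed_mixture(55))
        assert np.allclose(model.pi, [3 / 5, 2 / 5])
        assert np.allclose(model.T1[0], [1, 0, 0])
        assert np.allclose(model.T1[1], [0, 0.5, 0.5])
        # probability x denominator reproduces the integer numerator
        for name in ("T1", "T2", "E_mid", "E_end"):
            counts = model.counts[name]
            denom = counts.sum(axis=1, keepdims=True)
            frac = getattr(model, name)
            np.testing.assert_array_equal(
                np.rint(frac * np.where(denom == 0, 1, denom)).astype(int),
                np.where(denom == 0, np.rint(frac).astype(int) * 0 + counts, counts),
            )

    def test_zero_count_rows_uniform_and_flagged(self):
        cohort = make_cohort([(50, 22, 22)] * 4)  # nobody ever reaches B2/B3
        model = estimate_pgm(cohort, fixed_mixture(55))
        assert np.allclose(model.T2[1], 1 / 3)
        assert 1 in model.uniform_rows["T2"]

    def test_permutation_invariance(self, training_cohort):
        mix = fixed_mixture(55)
        base = estimate_pgm(training_cohort, mix)
        rng = np.random.default_rng(0)
        shuffled = training_cohort.subset(rng.permutation(len(training_cohort)))
        other = estimate_pgm(shuffled, mix)
        assert np.allclose(base.T1, other.T1) and np.allclose(base.E_end, other.E_end)

    def test_row_stochastic(self, fitted):
        for name in ("T1", "T2", "E_mid", "E_end"):
            assert np.allclose(getattr(fitted.pgm, name).sum(axis=1), 1.0, atol=1e-9)

    def test_serialisation_round_trip(self, tmp_path, fitted):
        path = tmp_path / "model.json"
        fitted.pgm.save(path)
        back = PGModel.load(path)
        np.testing.assert_array_equal(back.counts["T1"], fitted.pgm.counts["T1"])
        assert np.allclose(back.T2, fitted.pgm.T2)


class TestPathSelection:
    def test_single_path_cohort(self):
        cohort = make_cohort([(50, 22, 22)] * 12)
        mix = fixed_mixture(55)
        model = estimate_pgm(cohort, mix)
        paths = select_symptom_dynamic_paths(model, cohort, mix)
        assert len(paths) == 1
        p = paths[0]
        assert (p.baseline, p.mid, p.end) == ("A1", "B1", "C1")
        assert p.coverage == 1.0 and p.n_on_path == 12

    def test_low_coverage_path_excluded(self):
        triples = [(50, 22, 22)] * 19 + [(50, 45, 25)]  # 1 of 20 via B3 -> C1
        cohort = make_cohort(triples)
        mix = fixed_mixture(55)
        model = estimate_pgm(cohort, mix)
        paths = select_symptom_dynamic_paths(model, cohort, mix, min_coverage=0.10)
        assert {(p.baseline, p.mid, p.end) for p in paths} == {("A1", "B1", "C1")}

    def test_raising_threshold_never_adds_paths(self, training_cohort, fitted):
        mix = fitted.mixture
        model = fitted.pgm
        prev = None
        for cov in (0.05, 0.10, 0.20, 0.4):
            got = {
                (p.baseline, p.mid, p.end)
                for p in select_symptom_dynamic_paths(model, training_cohort, mix, cov)
            }
            if prev is not None:
                assert got <= prev
            prev = got

    def test_selection_invariant_to_patient_order(self, training_cohort, fitted):
        rng = np.random.default_rng(1)
        shuffled = training_cohort.subset(rng.permutation(len(training_cohort)))
        a = select_symptom_dynamic_paths(fitted.pgm, training_cohort, fitted.mixture)
        b = select_symptom_dynamic_paths(fitted.pgm, shuffled, fitted.mixture)
        assert [(p.baseline, p.mid, p.end, p.n_on_path) for p in a] == [
            (p.baseline, p.mid, p.end, p.n_on_path) for p in b
        ]

    def test_unpopulated_stratum_contributes_no_paths(self):
        cohort = make_cohort([(50, 22, 22)] * 6)  # nobody in A2
        model = estimate_pgm(cohort, fixed_mixture(55))
        paths = select_symptom_dynamic_paths(model, cohort, fixed_mixture(55))
        assert all(p.baseline == "A1" for p in paths)

    def test_sorted_by_likelihood(self, fitted):
        liks = [p.likelihood for p in fitted.paths]
        assert liks == sorted(liks, reverse=True)
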