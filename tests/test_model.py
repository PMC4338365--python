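"""The classifier proper: standardisation, BOE assembly routes, prediction,
objective, evaluation metrics, fitting and contribution curves."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import ncarbs.model as M
from ncarbs import _engine
from ncarbs.construction import ControlParameterSet
from ncarbs.evidence import FrameOfDiscernment, pignistic, vacuous
from ncarbs.synthetic import generate, separated_cohort_spec, worked_fixture
from ncarbs.tde import TDEConfig

from .conftest import random_parameter_set


def make_dataset(values, frame, associations=None, characteristics=None):
    values = np.asarray(values, dtype=float)
    return M.SubjectDataset(
        ids=[f"s{i}" for i in range(values.shape[0])],
        values=values,
        frame=frame,
        characteristics=characteristics
        or tuple(f"c{j + 1}" for j in range(values.shape[1])),
        associations=associations,
    )


class TestStandardise:
    def test_symmetric_triple(self, ab_frame):
        ds = make_dataset([[1.0], [2.0], [3.0]], ab_frame)
        out = M.standardise(ds)
        assert np.allclose(out.values[:, 0], [-1.0, 0.0, 1.0])
        assert out.standardisation.mean[0] == pytest.approx(2.0)
        assert out.standardisation.sd[0] == pytest.approx(1.0)

    def test_idempotent_on_standardised_column(self, ab_frame, rng):
        ds = M.standardise(make_dataset(rng.normal(size=(10, 2)), ab_frame))
        again = M.standardise(ds)
        assert np.allclose(again.values, ds.values, atol=1e-12)

    def test_missing_preserved_and_stats_from_observed(self, ab_frame):
        column = [1.0, 4.0, np.nan, 7.0, np.nan]
        ds = make_dataset(np.array(column)[:, None], ab_frame)
        out = M.standardise(ds)
        assert np.isnan(out.values[2, 0]) and np.isnan(out.values[4, 0])
        assert out.standardisation.mean[0] == pytest.approx(4.0)
        assert out.standardisation.sd[0] == pytest.approx(3.0)
        assert np.allclose(out.values[[0, 1, 3], 0], [-1.0, 0.0, 1.0])

    def test_degenerate_column_raises(self, ab_frame):
        with pytest.raises(ValueError, match="degenerate"):
            M.standardise(make_dataset([[5.0], [5.0], [5.0]], ab_frame))

    def test_apply_reuses_training_statistics(self, ab_frame):
        train = M.standardise(make_dataset([[1.0], [2.0], [3.0]], ab_frame))
        new = make_dataset([[4.0]], ab_frame)
        out = M.apply_standardisation(new, train.standardisation)
        assert out.values[0, 0] == pytest.approx(2.0)  # (4 - 2) / 1


class TestBoeAssembly:
    @pytest.fixture
    def instance(self, rng, abc_frame):
        params = random_parameter_set(rng, abc_frame, ("c1", "c2"))
        ds = make_dataset(rng.normal(size=(4, 2)), abc_frame)
        return ds, params

    def test_all_missing_subject_is_vacuous(self, abc_frame, rng):
        params = random_parameter_set(rng, abc_frame, ("c1", "c2"))
        ds = make_dataset([[np.nan, np.nan]], abc_frame)
        assert M.state_boe(ds, 0, 0, params) == vacuous(abc_frame)
        assert M.characteristic_boe(ds, 0, 1, params) == vacuous(abc_frame)
        assert M.object_boe(ds, 0, params) == vacuous(abc_frame)

    def test_single_characteristic_state_boe_is_the_constituent(self, abc_frame, rng):
        from ncarbs.construction import constituent_for_value

        params = random_parameter_set(rng, abc_frame, ("c1",))
        ds = make_dataset([[0.7]], abc_frame, characteristics=("c1",))
        assert M.state_boe(ds, 0, 2, params) == constituent_for_value(0.7, 0, 2, params).boe

    def test_route_equivalence(self, rng):
        """State-wise, characteristic-wise and flat folds of the same
        constituents agree (associativity of Dempster's rule)."""
        for _ in range(30):
            size = int(rng.integers(2, 5))
            frame = FrameOfDiscernment([f"d{i}" for i in range(size)])
            n_char = int(rng.integers(1, 4))
            chars = tuple(f"c{j}" for j in range(n_char))
            params = random_parameter_set(rng, frame, chars)
            ds = make_dataset(rng.normal(size=(1, n_char)), frame, characteristics=chars)
            by_state = M.object_boe(ds, 0, params, route="state")
            by_char = M.object_boe(ds, 0, params, route="characteristic")
            by_flat = M.object_boe(ds, 0, params, route="flat")
            for focal in by_state.focal_elements:
                assert by_char.mass(focal) == pytest.approx(by_state.mass(focal), abs=1e-10)
                assert by_flat.mass(focal) == pytest.approx(by_state.mass(focal), abs=1e-10)

    def test_engine_matches_object_level_algebra(self, instance):
        """The dense vectorised pipeline agrees with the per-subject
        mass-function fold."""
        ds, params = instance
        dense, bad = _engine.object_dense(ds.values, params)
        assert not bad.any()
        for i in range(ds.n_subjects):
            reference = M.object_boe(ds, i, params).to_dense()
            assert np.allclose(dense[i], reference, atol=1e-10)


class TestPredict:
    def test_vacuous_subject_uniform_and_centroid(self, abc_frame, rng):
        params = random_parameter_set(rng, abc_frame, ("c1",))
        ds = make_dataset([[np.nan]], abc_frame, characteristics=("c1",))
        (rec,) = M.predict(ds, params)
        assert np.allclose(rec.betp.probs, 1 / 3, atol=1e-12)
        assert rec.simplex == pytest.approx((0.5, math.sqrt(3) / 6), abs=1e-12)
        assert rec.ambiguous

    def test_worked_fixture_end_to_end(self):
        fx = worked_fixture()
        records = M.predict(fx.dataset, fx.params)
        expected_betp = fx.expected["betp"]
        for i, rec in enumerate(records):
            assert np.allclose(rec.betp.probs, expected_betp[i], atol=1e-12)
            for focal, value in fx.expected["object_boes"][i].items():
                assert rec.boe.mass(focal) == pytest.approx(value, abs=1e-12)

    def test_betp_rows_sum_to_one(self, rng, abc_frame):
        params = random_parameter_set(rng, abc_frame, ("c1", "c2", "c3"))
        ds = make_dataset(rng.normal(size=(20, 3)), abc_frame)
        for rec in M.predict(ds, params):
            assert rec.betp.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_frame_mismatch_rejected(self, rng, ab_frame, abc_frame):
        params = random_parameter_set(rng, ab_frame, ("c1",))
        ds = make_dataset([[0.0]], abc_frame, characteristics=("c1",))
        with pytest.raises(ValueError, match="frame"):
            M.predict(ds, params)


class TestObjective:
    def test_perfect_prediction_is_zero(self):
        fx = worked_fixture()
        betp = fx.dataset.associations
        assert _engine.objective_from_betp(betp, fx.dataset.associations) == 0.0

    def test_uniform_vs_crisp_three_state(self):
        betp = np.full((43, 3), 1 / 3)
        assoc = np.zeros((43, 3))
        assoc[:, 0] = 1.0
        ob = _engine.objective_from_betp(betp, assoc)
        assert ob == pytest.approx(math.sqrt(6) / 9, abs=1e-12)

    def test_vertex_to_wrong_vertex(self):
        betp = np.array([[1.0, 0.0, 0.0]])
        assoc = np.array([[0.0, 1.0, 0.0]])
        ob = _engine.objective_from_betp(betp, assoc)
        assert ob == pytest.approx(math.sqrt(2) / 3, abs=1e-12)

    def test_normaliser_variants(self):
        fx = worked_fixture()
        standard = M.objective(fx.dataset, fx.params, normaliser="standard")
        per_object = M.objective(fx.dataset, fx.params, normaliser="per-object")
        assert standard == pytest.approx(fx.expected["objective_standard"], abs=1e-12)
        assert per_object == pytest.approx(standard * fx.dataset.frame.size, abs=1e-12)

    def test_requires_associations(self, rng, abc_frame):
        params = random_parameter_set(rng, abc_frame, ("c1",))
        ds = make_dataset([[0.0]], abc_frame, characteristics=("c1",))
        with pytest.raises(ValueError, match="association"):
            M.objective(ds, params)

    def test_bounded_on_random_inputs(self, rng, abc_frame):
        params = random_parameter_set(rng, abc_frame, ("c1", "c2"))
        assoc = np.eye(3)[rng.integers(3, size=15)]
        ds = make_dataset(rng.normal(size=(15, 2)), abc_frame, associations=assoc)
        ob = M.objective(ds, params)
        assert 0.0 <= ob <= math.sqrt(2) / 3 + 1e-12


class TestClassify:
    def test_dominant_label(self, abc_frame):
        assert M.classify((0.6, 0.3, 0.1), abc_frame) == ("a", False)
        assert M.classify((0.2, 0.2, 0.6), abc_frame) == ("c", False)

    def test_tie_breaks_to_first_label_and_flags(self, abc_frame):
        label, ambiguous = M.classify((1 / 3, 1 / 3, 1 / 3), abc_frame)
        assert label == "a" and ambiguous


class TestEvaluate:
    @pytest.fixture
    def lda_confusion(self):
        # rows = actual, columns = predicted
        frame = ["LA", "PA", "NP"]
        counts = [[8, 4, 2], [5, 3, 5], [1, 5, 10]]
        return pd.DataFrame(counts, index=frame, columns=frame)

    def test_all_correct(self, abc_frame):
        result = M.evaluate(["a", "b", "c"], ["a", "b", "c"], abc_frame)
        assert result.overall_accuracy == 1.0
        assert np.array_equal(np.diag(result.confusion.to_numpy()), [1, 1, 1])

    def test_confusion_arithmetic(self, lda_confusion):
        result = M.EvaluationResult.from_confusion(lda_confusion)
        assert result.overall_accuracy == pytest.approx(21 / 43)
        assert result.per_class_accuracy == pytest.approx(
            {"LA": 8 / 14, "PA": 3 / 13, "NP": 10 / 16}
        )
        assert result.precision == pytest.approx(
            {"LA": 8 / 14, "PA": 3 / 12, "NP": 10 / 17}
        )
        assert result.n == 43

    def test_matrix_from_labels_matches_counts(self, lda_confusion):
        frame = FrameOfDiscernment(("LA", "PA", "NP"))
        truths, preds = [], []
        for actual in frame.labels:
            for predicted in frame.labels:
                count = int(lda_confusion.loc[actual, predicted])
                truths += [actual] * count
                preds += [predicted] * count
        result = M.evaluate(truths, preds, frame)
        assert np.array_equal(result.confusion.to_numpy(), lda_confusion.to_numpy())
        assert list(result.confusion.index) == list(lda_confusion.index)

    def test_empty_predicted_class_flagged(self, abc_frame):
        result = M.evaluate(["a", "b", "c"], ["a", "a", "a"], abc_frame)
        assert math.isnan(result.precision["b"])
        assert set(result.undefined_precision) == {"b", "c"}
        assert result.precision["a"] == pytest.approx(1 / 3)


class TestFit:
    SMALL = dict(NP=24, max_generations=40)

    def small_config(self):
        return TDEConfig(bounds=[(0.0, 1.0)], **self.SMALL)

    def test_seeded_determinism(self):
        ds = generate(separated_cohort_spec(2.5, sizes=(5, 5, 5)), seed=3)
        r1 = M.fit(ds, config=self.small_config(), n_runs=2, seed=9)
        r2 = M.fit(ds, config=self.small_config(), n_runs=2, seed=9)
        assert r1.objective == r2.objective
        assert np.array_equal(r1.params.values, r2.params.values)
        assert [run.seed for run in r1.runs] == [run.seed for run in r2.runs]

    def test_beats_random_parameters(self, rng):
        ds = generate(separated_cohort_spec(2.0, sizes=(4, 4, 4)), seed=5)
        std = M.standardise(ds)
        baseline = min(
            M.objective(std, random_parameter_set(rng, ds.frame, ds.characteristics))
            for _ in range(10)
        )
        result = M.fit(ds, config=self.small_config(), n_runs=1, seed=2)
        assert result.objective < baseline

    def test_refuses_unlabelled_data(self, abc_frame):
        ds = make_dataset(np.random.default_rng(0).normal(size=(6, 2)), abc_frame)
        with pytest.raises(ValueError, match="association"):
            M.fit(ds)

    def test_recomputed_objective_matches(self):
        ds = generate(separated_cohort_spec(2.0, sizes=(4, 4, 4)), seed=5)
        result = M.fit(ds, config=self.small_config(), n_runs=1, seed=2)
        std = M.standardise(ds)
        assert M.objective(std, result.params, normaliser=result.normaliser) == pytest.approx(
            result.objective, abs=1e-9
        )


class TestContributionCurves:
    @pytest.fixture
    def params(self, rng, abc_frame):
        return random_parameter_set(rng, abc_frame, ("c1", "c2"))

    def test_mass_curves_sum_to_one_and_match_pointwise(self, params):
        grid = np.linspace(-3, 3, 64)
        curves = M.mass_contribution_curves(params, 1, 2, grid)
        total = curves.m_state + curves.m_complement + curves.m_ignorance
        assert np.allclose(total, 1.0, atol=1e-12)
        from ncarbs.construction import confidence, mass_triplet

        q = params.quadruple(1, 2)
        for idx in (0, 31, 63):
            m_d, m_n, m_i = mass_triplet(confidence(grid[idx], q), q.A, q.B)
            assert curves.m_state[idx] == pytest.approx(float(m_d), abs=1e-12)
            assert curves.m_ignorance[idx] == pytest.approx(float(m_i), abs=1e-12)

    def test_plateau_regimes_in_curves(self, abc_frame):
        low_A = ControlParameterSet(
            np.array([[[2.0, 0.0, 0.2, 0.5]] * 3]), abc_frame, ("c1",)
        )
        curves = M.mass_contribution_curves(low_A, 0, 0, np.linspace(-4, 4, 512))
        plateau = 1.0 - 0.5 * (1 - 0.4) / 0.8
        assert np.isclose(curves.m_ignorance, plateau, atol=1e-9).any()
        high_A = ControlParameterSet(
            np.array([[[2.0, 0.0, 0.8, 0.5]] * 3]), abc_frame, ("c1",)
        )
        curves = M.mass_contribution_curves(high_A, 0, 0, np.linspace(-4, 4, 512))
        assert np.isclose(curves.m_ignorance, 1.0, atol=0).any()

    def test_betp_curves_sum_to_one(self, params):
        curves = M.betp_contribution_curves(params, 0, np.linspace(-3, 3, 128))
        assert np.allclose(curves.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_no_evidence_gives_uniform_curves(self, abc_frame):
        values = np.zeros((2, 3, 4))
        values[..., 3] = 0.0  # B = 0 everywhere: no directed mass at all
        params = ControlParameterSet(values, abc_frame, ("c1", "c2"))
        curves = M.betp_contribution_curves(params, 0, np.linspace(-2, 2, 16))
        assert np.allclose(curves.probs, 1 / 3, atol=1e-12)

    def test_single_point_matches_pipeline(self, params, abc_frame):
        grid = np.array([0.37])
        curves = M.betp_contribution_curves(params, 1, grid)
        ds = make_dataset([[np.nan, 0.37]], abc_frame)
        boe = M.characteristic_boe(ds, 0, 1, params)
        assert np.allclose(curves.probs[0], pignistic(boe).probs, atol=1e-10)
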