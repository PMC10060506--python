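import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gmfa.network import FluxSpec, GeneralizedStoichiometry, NodeSpec
from gmfa.twin import (
    FitConfig,
    PatientRecord,
    denormalize_state,
    fit_cohort,
    fit_twin,
    impute_missing,
    normalize_readings,
    reference_state,
)

from .helpers import grid_search_objective, make_model, random_qp_instance


class TestImputeMissing:
    def test_missing_value_becomes_cohort_mean(self):
        cohort = [
            PatientRecord("a", {"Glucose": 8.0}),
            PatientRecord("b", {"Glucose": 10.0}),
            PatientRecord("c", {}),
        ]
        out = impute_missing(cohort)
        assert out[2].readings["Glucose"] == pytest.approx(9.0)
        assert out[2].imputed == {"Glucose"}

    def test_fully_observed_node_untouched(self):
        cohort = [PatientRecord("a", {"x": 1.0}), PatientRecord("b", {"x": 3.0})]
        out = impute_missing(cohort)
        assert [r.readings["x"] for r in out] == [1.0, 3.0]
        assert all(not r.imputed for r in out)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            impute_missing([])


class TestNormalizeReadings:
    def test_reference_mean_maps_to_zero(self, diabetes_map):
        rec = PatientRecord("p", {"Glucose": 8.89})
        assert normalize_readings(rec, diabetes_map)["Glucose"] == pytest.approx(0.0)

    def test_one_sd_above_reference_maps_to_one(self, diabetes_map):
        rec = PatientRecord("p", {"Pulse-wave-velocity": 10.09})
        sv = normalize_readings(rec, diabetes_map)
        assert sv["Pulse-wave-velocity"] == pytest.approx(1.0)

    @given(st.floats(min_value=-50, max_value=500, allow_nan=False))
    def test_round_trip_exact(self, raw):
        model = make_model([[1.0]], means=[7.0], sds=[2.5])
        rec = PatientRecord("p", {"n0": raw})
        sv = normalize_readings(rec, model)
        back = denormalize_state(sv, model)[0]
        assert back == pytest.approx(raw, abs=1e-12 * max(1.0, abs(raw)))

    def test_zero_reference_sd_raises(self):
        model = GeneralizedStoichiometry(
            (NodeSpec("n0", node_class="metabolite", reference_mean=0.0, reference_sd=1.0),),
            (FluxSpec("f", substrates=(("n0", 1.0),)),),
        )
        bad = GeneralizedStoichiometry(
            (NodeSpec("n0", node_class="metabolite", reference_mean=0.0, reference_sd=0.0),),
            model.fluxes,
        )
        with pytest.raises(ValueError, match="n0"):
            normalize_readings(PatientRecord("p", {"n0": 1.0}), bad)


class TestFitTwin:
    def test_reference_patient_gives_zero_flux(self, diabetes_map):
        mean, _ = diabetes_map.reference_stats()
        readings = {
            n.id: float(mean[i])
            for i, n in enumerate(diabetes_map.nodes)
            if n.node_class != "source_sink"
        }
        twin = fit_twin(
            diabetes_map, PatientRecord("ref", readings), reference_state(diabetes_map)
        )
        assert twin.solver_status == "optimal"
        np.testing.assert_allclose(twin.v, 0.0, atol=1e-6)
        assert twin.objective_value == pytest.approx(0.0, abs=1e-10)

    def test_two_node_conversion_forced_analytically(self, two_node_model):
        rec = PatientRecord("p", {"n0": -0.5, "n1": 0.5})
        twin = fit_twin(two_node_model, rec, reference_state(two_node_model))
        assert twin.solver_status == "optimal"
        assert twin.v[0] == pytest.approx(0.5, abs=1e-5)
        assert max(abs(r) for r in twin.residuals.values()) < 1e-5

    def test_band_constraint_binds_at_analytic_edge(self):
        # one flux feeding two nodes; weights pull the fit below the second
        # node's 20% band, so the optimum pins at the band edge x = 0.84
        model = make_model([[1.0], [1.0]])
        rec = PatientRecord("p", {"n0": 0.75, "n1": 1.05})
        cfg = FitConfig(objective_weights={"n0": 10.0, "n1": 1.0})
        twin = fit_twin(model, rec, reference_state(model), cfg)
        assert twin.solver_status == "optimal"
        assert twin.v[0] == pytest.approx(0.84, abs=1e-8)

    def test_infeasible_band_relaxes_to_bound(self):
        model = make_model([[1.0]], lb=[0.0], ub=[0.5])
        twin = fit_twin(
            model, PatientRecord("p", {"n0": 1.0}), reference_state(model)
        )
        assert twin.solver_status == "relaxed_optimal"
        assert twin.relaxed
        assert twin.v[0] == pytest.approx(0.5, abs=1e-6)

    def test_infeasible_band_fails_without_relaxation(self):
        model = make_model([[1.0]], lb=[0.0], ub=[0.5])
        cfg = FitConfig(relax_on_infeasible=False)
        twin = fit_twin(model, PatientRecord("p", {"n0": 1.0}), reference_state(model), cfg)
        assert twin.solver_status == "failed"
        assert twin.v is None

    def test_window_property_for_optimal_twins(self):
        rng = np.random.default_rng(5)
        cfg = FitConfig()
        for _ in range(20):
            model, rec = random_qp_instance(rng)
            twin = fit_twin(model, rec, reference_state(model), cfg)
            if twin.solver_status != "optimal":
                continue
            for node_id, y in rec.readings.items():
                fitted = y + twin.residuals[node_id]
                assert abs(fitted - y) / abs(y) <= cfg.window_fraction + 1e-9

    def test_objective_beats_grid_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            model, rec = random_qp_instance(rng)
            twin = fit_twin(model, rec, reference_state(model))
            oracle = grid_search_objective(model, rec)
            assert oracle is not None
            assert twin.objective_value <= oracle + 1e-6

    def test_unit_rescaling_leaves_solution_invariant(self, diabetes_map):
        rec = PatientRecord(
            "p", {"Glucose": 12.0, "HbA1c": 10.0, "LDL": 3.4, "Pulse-wave-velocity": 9.5}
        )
        base = fit_twin(diabetes_map, rec, reference_state(diabetes_map))
        # express glucose in mg/dL instead of mmol/L (x18 everywhere)
        scaled_nodes = tuple(
            NodeSpec(n.id, n.label, n.node_class, "mg/dL",
                     n.reference_mean * 18.0, n.reference_sd * 18.0)
            if n.id == "Glucose" else n
            for n in diabetes_map.nodes
        )
        scaled_model = GeneralizedStoichiometry(scaled_nodes, diabetes_map.fluxes)
        scaled_rec = PatientRecord("p", {**rec.readings, "Glucose": 12.0 * 18.0})
        scaled = fit_twin(scaled_model, scaled_rec, reference_state(scaled_model))
        np.testing.assert_allclose(scaled.v, base.v, atol=1e-8)

    def test_repeated_solves_agree(self, diabetes_map):
        rec = PatientRecord("p", {"Glucose": 14.0, "Ferritin": 300.0, "RHI": 0.4})
        x_a = reference_state(diabetes_map)
        first = fit_twin(diabetes_map, rec, x_a)
        second = fit_twin(diabetes_map, rec, x_a)
        np.testing.assert_allclose(first.v, second.v, atol=1e-8)


class TestFitCohort:
    def test_identical_records_give_identical_twins(self, two_node_model):
        recs = [PatientRecord(f"p{i}", {"n0": -0.3, "n1": 0.3}) for i in range(3)]
        twins = fit_cohort(two_node_model, recs, reference_state(two_node_model))
        assert len(twins) == 3
        for t in twins[1:]:
            np.testing.assert_array_equal(t.v, twins[0].v)

    def test_empty_cohort_warns_and_returns_empty(self, two_node_model):
        with pytest.warns(UserWarning, match="empty"):
            twins = fit_cohort(two_node_model, [], reference_state(two_node_model))
        assert twins == []
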