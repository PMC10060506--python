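import numpy as np
import pytest

from gmfa.risk import (
    TWILIGHT_PRESETS,
    ResampleConfig,
    fisher_association,
    fit_logistic_resampled,
    median_flux_profile,
    quadrant_risk_groups,
    roc_auc,
    twilight_exclusion,
)
from gmfa.twin import DigitalTwin


def _twin(pid, v):
    return DigitalTwin(pid, np.asarray(v, dtype=float), None, 0.0, {}, False, "optimal")


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.9], [0, 1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_rank_formula_equals_trapezoid_of_step_curve(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = rng.integers(6, 60)
            scores = np.round(rng.uniform(size=n), 2)  # ties likely
            labels = (rng.uniform(size=n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            auc, pts = roc_auc(scores, labels)
            # independent oracle: trapezoidal area under the tie-aware curve
            trapezoid = float(np.trapezoid(pts[:, 1], pts[:, 0]))
            assert auc == pytest.approx(trapezoid, abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(3)
        scores = np.round(rng.uniform(size=40), 1)
        labels = (rng.uniform(size=40) < 0.4).astype(int)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-15)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestLogisticResampled:
    def test_perfectly_separated_feature_gives_auc_one(self):
        x = np.r_[np.zeros(20), np.ones(20)].reshape(-1, 1)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = fit_logistic_resampled(x, y, ResampleConfig(seed=0))
        assert model.median_auc == 1.0

    def test_null_features_give_central_auc(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(200, 3))
        y = (rng.uniform(size=200) < 0.5).astype(int)
        model = fit_logistic_resampled(x, y, ResampleConfig(n_iterations=50, seed=7))
        assert 0.4 <= model.median_auc <= 0.6

    def test_same_seed_reproduces_model_exactly(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 2))
        y = (rng.uniform(size=60) < 0.4).astype(int)
        cfg = ResampleConfig(seed=11)
        m1 = fit_logistic_resampled(x, y, cfg)
        m2 = fit_logistic_resampled(x, y, cfg)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        np.testing.assert_array_equal(m1.iteration_aucs, m2.iteration_aucs)
        assert m1.scores == m2.scores

    def test_scores_bounded(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(50, 2))
        y = (rng.uniform(size=50) < 0.5).astype(int)
        model = fit_logistic_resampled(x, y, ResampleConfig(seed=1))
        vals = np.array(list(model.scores.values()))
        assert np.all((vals >= 0) & (vals <= 1))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_logistic_resampled(np.zeros((4, 1)), [1, 1, 1, 1])


class TestTwilightExclusion:
    def test_hundred_distinct_scores_band_40_60_retains_80(self):
        scores = np.arange(1, 101, dtype=float)
        retained = twilight_exclusion(scores, (40.0, 60.0))
        assert retained.size == 80
        assert set(scores[retained]) == set(range(1, 41)) | set(range(61, 101))

    def test_degenerate_band_retains_everyone(self):
        scores = np.random.default_rng(0).uniform(size=57)
        assert twilight_exclusion(scores, "quantile_50").size == 57

    def test_presets_nest_monotonically(self):
        scores = np.random.default_rng(12).uniform(size=200)
        widths = ["quantile_50", "quantile_45", "quantile_40", "quantile_35",
                  "quantile_33", "quantile_25"]
        sizes = [twilight_exclusion(scores, b).size for b in widths]
        assert sizes == sorted(sizes, reverse=True)
        # nested: each wider band's retained set is a subset
        prev = set(twilight_exclusion(scores, widths[0]))
        for b in widths[1:]:
            cur = set(twilight_exclusion(scores, b))
            assert cur <= prev
            prev = cur

    def test_extreme_deciles_never_removed(self):
        scores = np.random.default_rng(5).normal(size=300)
        lo, hi = np.percentile(scores, [10, 90])
        for band in TWILIGHT_PRESETS.values():
            kept = scores[twilight_exclusion(scores, band)]
            assert np.all(np.isin(scores[scores <= lo], kept))
            assert np.all(np.isin(scores[scores >= hi], kept))

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            twilight_exclusion([0.1, 0.9], (60.0, 40.0))


class TestQuadrantRiskGroups:
    def test_hand_worked_eight_patients(self):
        vals = {f"p{i}": float(i) for i in range(1, 9)}
        groups = quadrant_risk_groups(vals, dict(vals))
        assert set(groups.members("low")) == {"p1", "p2"}
        assert set(groups.members("high")) == {"p7", "p8"}
        assert set(groups.members("intermediate")) == {f"p{i}" for i in range(3, 7)}

    def test_anticorrelated_inputs_give_empty_high_group(self):
        scores = {f"p{i}": float(i) for i in range(8)}
        distances = {f"p{i}": float(-i) for i in range(8)}
        groups = quadrant_risk_groups(scores, distances)
        assert groups.members("high") == []

    def test_patient_order_irrelevant(self):
        rng = np.random.default_rng(2)
        ids = [f"p{i}" for i in range(20)]
        s = dict(zip(ids, rng.uniform(size=20)))
        d = dict(zip(ids, rng.uniform(size=20)))
        shuffled = list(ids)
        rng.shuffle(shuffled)
        g1 = quadrant_risk_groups(s, d)
        g2 = quadrant_risk_groups({p: s[p] for p in shuffled}, {p: d[p] for p in shuffled})
        assert g1.assignments == g2.assignments

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            quadrant_risk_groups({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestFisherAssociation:
    def test_balanced_table_gives_p_one(self):
        _, p = fisher_association([[1, 1], [1, 1]])
        assert p == 1.0

    def test_row_and_column_swap_invariance(self):
        table = np.array([[20, 5], [7, 18]])
        _, p0 = fisher_association(table)
        _, p1 = fisher_association(table[::-1, ::-1])
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_risk_group_table_construction(self):
        vals = {f"p{i}": float(i) for i in range(1, 9)}
        groups = quadrant_risk_groups(vals, dict(vals))
        diagnosis = {f"p{i}": int(i >= 7) for i in range(1, 9)}
        table, p = fisher_association(groups, diagnosis)
        np.testing.assert_array_equal(table, [[2, 0], [0, 2]])
        assert 0 < p <= 1


class TestMedianFluxProfile:
    def test_whole_population_group_has_zero_deviation(self):
        rng = np.random.default_rng(1)
        twins = [_twin(f"p{i}", rng.normal(size=4)) for i in range(30)]
        profile = median_flux_profile(twins, [t.patient_id for t in twins])
        assert all(v == 0.0 for v in profile.values())

    def test_planted_shift_recovered_in_iqr_units(self):
        rng = np.random.default_rng(42)
        n = 500
        twins = []
        pop = rng.normal(size=(n, 2))
        iqr0 = np.percentile(pop[:, 0], 75) - np.percentile(pop[:, 0], 25)
        # small group (5%) so the shift barely moves the population statistics
        group = []
        for i in range(n):
            v = pop[i].copy()
            if i < n // 20:
                v[0] += 2.0 * iqr0
                group.append(f"p{i}")
            twins.append(_twin(f"p{i}", v))
        profile = median_flux_profile(twins, group, flux_ids=["fa", "fb"])
        assert profile["fa"] == pytest.approx(2.0, abs=0.5)
        assert abs(profile["fb"]) < 0.3

    def test_covers_exactly_the_model_flux_ids(self):
        twins = [_twin(f"p{i}", [float(i), -float(i)]) for i in range(8)]
        profile = median_flux_profile(twins, ["p1"], flux_ids=["fa", "fb"])
        assert set(profile) == {"fa", "fb"}

    def test_zero_iqr_flux_flagged_as_zero(self):
        twins = [_twin(f"p{i}", [1.0, float(i)]) for i in range(8)]
        with pytest.warns(UserWarning, match="zero population IQR"):
            profile = median_flux_profile(twins, ["p7"], flux_ids=["fa", "fb"])
        assert profile["fa"] == 0.0
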