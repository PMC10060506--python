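import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kendalltau as scipy_kendalltau

from gmfa.stats import association_screen, by_fdr, kendall_tau, wmw_test
from gmfa.twin import DigitalTwin, PatientRecord

from .helpers import closed_form_by, permutation_wmw_p


class TestWMW:
    def test_separated_small_groups_exact_p(self):
        # {1,2,3} vs {4,5,6}: 2/20 assignments are at least as extreme
        res = wmw_test([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 9.0  # U of the larger group

    def test_identical_multisets_give_p_one(self):
        res = wmw_test([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert res.p_value == 1.0

    def test_exact_matches_independent_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n1, n2 = rng.integers(3, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            labels = np.r_[np.ones(n1), np.zeros(n2)].astype(int)
            ours = wmw_test(np.r_[x, y], labels).p_value
            oracle = permutation_wmw_p(x, y)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            labels = np.r_[np.ones(8), np.zeros(8)].astype(int)
            exact = wmw_test(np.r_[x, y], labels).p_value
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(exact - approx) <= 0.02

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=14)
        labels = (rng.uniform(size=14) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = wmw_test(v, labels)
        b = wmw_test(v, 1 - labels)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        n1, n2 = a.n_per_group
        assert b.statistic == pytest.approx(n1 * n2 - a.statistic)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wmw_test([1.0, 2.0], [1, 1])


class TestBY:
    def test_hand_computed_example(self):
        # c(3) = 11/6; all three adjust to 0.01 * 3 * 11/6 = 0.055
        np.testing.assert_allclose(by_fdr([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055])

    def test_single_p_unchanged(self):
        assert by_fdr([0.2])[0] == pytest.approx(0.2)

    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=30)
    )
    def test_dominates_input_and_capped(self, ps):
        adjusted = by_fdr(ps)
        assert np.all(adjusted >= np.asarray(ps) - 1e-15)
        assert np.all(adjusted <= 1.0)

    def test_matches_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(by_fdr(p), closed_form_by(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(by_fdr(p)[perm], by_fdr(p[perm]), atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.5])


def _twin(pid, v):
    return DigitalTwin(pid, np.asarray(v, dtype=float), None, 0.0, {}, False, "optimal")


class TestAssociationScreen:
    def _cohort(self, rng, n_per_group=40, shift=0.0):
        twins, records, labels = [], [], {}
        for i in range(2 * n_per_group):
            lab = int(i < n_per_group)
            v = rng.normal(size=3)
            v[0] += shift * lab
            pid = f"p{i}"
            twins.append(_twin(pid, v))
            records.append(PatientRecord(pid, {"marker": float(rng.normal())}))
            labels[pid] = lab
        return twins, records, labels

    def test_shifted_flux_detected(self):
        rng = np.random.default_rng(42)
        twins, records, labels = self._cohort(rng, shift=2.0)
        screen = association_screen(twins, records, labels, flux_ids=["fa", "fb", "fc"])
        assert [r.variable_id for r in screen["fluxes"]] == ["fa"]
        assert screen["fluxes"][0].fdr <= 0.15

    def test_null_labels_yield_no_hits(self):
        rng = np.random.default_rng(7)
        twins, records, labels = self._cohort(rng, shift=0.0)
        screen = association_screen(twins, records, labels)
        assert screen["fluxes"] == []

    def test_constant_variable_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        twins, records, labels = self._cohort(rng, n_per_group=5)
        for r in records:
            r.readings["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            screen = association_screen(twins, records, labels)
        assert all(r.variable_id != "flat" for r in screen["readings"])

    def test_results_sorted_by_p_and_fdr_dominates_p(self):
        rng = np.random.default_rng(9)
        twins, records, labels = self._cohort(rng, shift=1.0)
        # add a second, stronger flux shift
        for t, lab in zip(twins, (labels[t.patient_id] for t in twins)):
            t.v = t.v.copy()
            t.v[1] += 3.0 * lab
        screen = association_screen(twins, records, labels, fdr_cap=1.0)
        ps = [r.p_value for r in screen["fluxes"]]
        assert ps == sorted(ps)
        assert all(r.fdr >= r.p_value for r in screen["fluxes"])


class TestKendallTau:
    def test_perfect_concordance(self):
        tau, _ = kendall_tau([1, 2, 3], [1, 2, 3])
        assert tau == 1.0

    def test_perfect_discordance(self):
        tau, _ = kendall_tau([1, 2, 3], [3, 2, 1])
        assert tau == -1.0

    def test_exact_p_matches_pair_count_enumeration(self):
        # independent oracle: tau from explicit concordant/discordant pair
        # counts over all 5! permutations
        from itertools import combinations, permutations

        def pair_tau(x, y):
            conc = disc = 0
            for i, j in combinations(range(len(x)), 2):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                conc += s > 0
                disc += s < 0
            n = len(x)
            return (conc - disc) / (n * (n - 1) / 2)

        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            tau, p_exact = kendall_tau(x, y)
            assert tau == pytest.approx(pair_tau(x, y), abs=1e-12)
            taus = np.array([pair_tau(x, np.asarray(p)) for p in permutations(y)])
            oracle = np.mean(np.abs(taus) >= abs(tau) - 1e-12)
            assert p_exact == pytest.approx(oracle, abs=1e-12)

    def test_exact_vs_asymptotic_p_at_n5(self):
        # the normal approximation is coarse at n=5; agreement holds only to
        # ~0.2 in the far tail (|tau| = 1), tighter elsewhere
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p_exact = kendall_tau(x, y)
            p_asym = float(scipy_kendalltau(x, y, method="asymptotic").pvalue)
            assert abs(p_exact - p_asym) <= 0.2

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])
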