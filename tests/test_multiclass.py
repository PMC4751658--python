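import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from snpclass.multiclass import (OneVsAllThresholdClassifier,
                                 OneVsOneThresholdClassifier,
                                 PairwiseProbTable, breeding_values, classify,
                                 couple_ovo, normalize_ova, train_ova,
                                 train_ovo, vote_ovo)
from snpclass.simpop import SimSpec, simulate
from snpclass.threshold import ProbitGibbsClassifier

FAST = ProbitGibbsClassifier(n_iter=1500, burn_in=500)


def coupling_oracle(P):
    """Independent constrained least-squares solve of the determining system
    p_kk' (p_k + p_k') = p_k over the simplex (SLSQP)."""
    K = P.shape[0]

    def objective(p):
        r = 0.0
        for k in range(K):
            for l in range(K):
                if k != l:
                    r += (P[k, l] * (p[k] + p[l]) - p[k]) ** 2
        return r

    res = minimize(objective, np.full(K, 1.0 / K), method="SLSQP",
                   bounds=[(1e-9, 1)] * K,
                   constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1}],
                   options={"ftol": 1e-14, "maxiter": 500})
    return res.x


class TestNormalizeOva:
    @pytest.mark.parametrize("v,expected", [
        ([0.5, 0.5, 0.5, 0.5], [0.25, 0.25, 0.25, 0.25]),
        ([0.9, 0.3, 0.3, 0.3], [0.5, 1 / 6, 1 / 6, 1 / 6]),
        ([0.8, 0.2], [0.8, 0.2]),
    ])
    def test_examples(self, v, expected):
        np.testing.assert_allclose(normalize_ova(v).p, expected, atol=1e-9)

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
           st.floats(0.1, 0.9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, v, c):
        a = normalize_ova(np.asarray(v)).p
        b = normalize_ova(c * np.asarray(v)).p
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestVote:
    def test_dominant_class_k4(self):
        # class 2 (index 1) wins its 3 pairings -> p = 3 * 2/12 = 0.5
        p = np.full((4, 4), 0.4)
        p[1, :] = 0.9
        p[:, 1] = 0.1
        iu = np.triu_indices(4, 1)
        p[iu] = 1 - p.T[iu]
        np.fill_diagonal(p, 0)
        tab = PairwiseProbTable(p)
        cpv, winner = vote_ovo(tab)
        assert cpv.p[1] == pytest.approx(0.5)
        assert winner == 1

    def test_cyclic_tie_k3(self, caplog):
        P = np.array([[0.0, 0.6, 0.4],
                      [0.4, 0.0, 0.6],
                      [0.6, 0.4, 0.0]])
        tab = PairwiseProbTable(P)
        with caplog.at_level("WARNING"):
            cpv, winner = vote_ovo(tab)
        np.testing.assert_allclose(cpv.p, [1 / 3, 1 / 3, 1 / 3])
        assert winner == 0
        assert any("tie" in r.message for r in caplog.records)

    def test_k2(self):
        tab = PairwiseProbTable(np.array([[0.0, 0.7], [0.3, 0.0]]))
        cpv, winner = vote_ovo(tab)
        np.testing.assert_allclose(cpv.p, [1.0, 0.0])
        assert winner == 0


class TestCoupling:
    def test_k2_inverts_directly(self):
        tab = PairwiseProbTable(np.array([[0.0, 0.8], [0.2, 0.0]]))
        np.testing.assert_allclose(couple_ovo(tab).p, [0.8, 0.2], atol=1e-10)

    def test_k3_symmetric(self):
        tab = PairwiseProbTable(np.full((3, 3), 0.5) - 0.5 * np.eye(3))
        np.testing.assert_allclose(couple_ovo(tab).p, [1 / 3] * 3, atol=1e-10)

    def test_k3_hand_example(self):
        tab = PairwiseProbTable.from_true_p([0.5, 0.3, 0.2])
        np.testing.assert_allclose(tab.values[0, 1], 0.625)
        np.testing.assert_allclose(tab.values[0, 2], 5 / 7)
        np.testing.assert_allclose(tab.values[1, 2], 0.6)
        np.testing.assert_allclose(couple_ovo(tab).p, [0.5, 0.3, 0.2], atol=1e-8)

    @given(st.integers(2, 6), st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_inversion_property(self, K, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(K))
        p = np.clip(p, 1e-4, None)
        p /= p.sum()
        rec = couple_ovo(PairwiseProbTable.from_true_p(p)).p
        np.testing.assert_allclose(rec, p, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_slsqp_oracle_on_consistent_tables(self, seed):
        # the least-squares projection and the Markov fixed point are distinct
        # estimators for inconsistent tables; on a consistent table both must
        # return the generating simplex vector
        rng = np.random.default_rng(seed)
        K = int(rng.integers(3, 7))
        p = rng.dirichlet(np.ones(K))
        p = np.clip(p, 1e-3, None)
        p /= p.sum()
        tab = PairwiseProbTable.from_true_p(p)
        ours = couple_ovo(tab).p
        oracle = coupling_oracle(tab.values)
        np.testing.assert_allclose(ours, oracle, atol=1e-5)
        np.testing.assert_allclose(ours, p, atol=1e-8)

    def test_vote_and_couple_agree_on_dominant_argmax(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            K = rng.integers(2, 6)
            P = np.zeros((K, K))
            iu = np.triu_indices(K, 1)
            P[iu] = rng.uniform(0.05, 0.45, len(iu[0]))  # row 0 loses by default
            winner = rng.integers(0, K)
            P[winner, :] = rng.uniform(0.55, 0.95, K)
            P.T[iu] = 1 - P[iu]
            for j in range(K):  # re-impose winner's row after symmetrization
                if j != winner:
                    w = rng.uniform(0.55, 0.95)
                    P[winner, j] = w
                    P[j, winner] = 1 - w
            tab = PairwiseProbTable(P.copy())
            _, vwin = vote_ovo(tab)
            assert classify(couple_ovo(tab)) == vwin == winner


class TestClassify:
    def test_argmax(self):
        from snpclass.multiclass import ClassProbVector
        assert classify(ClassProbVector(np.array([0.1, 0.7, 0.2]))) == 1

    def test_tie_breaks_low_with_warning(self, caplog):
        from snpclass.multiclass import ClassProbVector
        with caplog.at_level("WARNING"):
            assert classify(ClassProbVector(np.array([0.5, 0.5]))) == 0
        assert any("tie" in r.message for r in caplog.records)


class TestSchemes:
    def test_ova_fit_counts(self, three_class_sim, stub_classifier):
        X = three_class_sim.genotypes.dosage
        y = three_class_sim.labels.labels
        model = train_ova(X, y, estimator=stub_classifier)
        assert len(model.estimators_) == 3

    def test_ovo_fit_counts(self, three_class_sim, stub_classifier):
        X = three_class_sim.genotypes.dosage
        y = three_class_sim.labels.labels
        model = train_ovo(X, y, estimator=stub_classifier)
        assert len(model.pair_estimators_) == 3  # 3*2/2

    def test_k2_complement(self, two_pop_sim, stub_classifier):
        X = two_pop_sim.genotypes.dosage
        y = two_pop_sim.labels.labels
        ova = train_ova(X, y, estimator=stub_classifier)
        p = ova.binary_proba(X[:5])
        np.testing.assert_allclose(p[:, 0], 1 - p[:, 1], atol=1e-9)

    def test_exclude_class_trains_fewer(self, three_class_sim, stub_classifier):
        X = three_class_sim.genotypes.dosage
        y = three_class_sim.labels.labels
        mask = y != "C3"
        model = train_ova(X[mask], y[mask], estimator=stub_classifier)
        assert len(model.estimators_) == 2

    def test_training_point_classified_correctly(self, three_class_sim):
        X = three_class_sim.genotypes.dosage
        y = three_class_sim.labels.labels
        model = OneVsAllThresholdClassifier(estimator=FAST, seed=1).fit(X, y)
        preds = model.predict(X[:10])
        assert (preds == y[:10]).mean() >= 0.9

    def test_untrained_class_still_scored_by_ovo(self, three_class_sim,
                                                 stub_classifier):
        X = three_class_sim.genotypes.dosage
        y = three_class_sim.labels.labels
        mask = y != "C3"
        model = OneVsOneThresholdClassifier(estimator=stub_classifier).fit(
            X[mask], y[mask])
        p = model.predict_proba(X[~mask][:3])
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def ova_fit(three_class_sim):
    X = three_class_sim.genotypes.dosage
    y = three_class_sim.labels.labels
    return (three_class_sim,
            OneVsAllThresholdClassifier(estimator=FAST, seed=3).fit(X, y))


class TestBreedingValues:
    def test_candidate_at_base_frequencies_uniform_when_effects_zero(self,
                                                                     ova_fit):
        sim, model = ova_fit
        f = np.clip(sim.genotypes.freq, 0.01, 0.99)
        # zero out posterior effect chains -> Phi(0) numerators
        import copy
        model0 = copy.deepcopy(model)
        for est in model0.estimators_:
            est.u_samples_ = np.zeros_like(est.u_samples_)
            est.b_samples_ = np.zeros_like(est.b_samples_)
        bv = breeding_values(2 * f, f, model0)
        np.testing.assert_allclose(bv.p_n, 1 / 3, atol=1e-12)

    def test_deviations_sum_to_zero(self, ova_fit):
        sim, model = ova_fit
        f = np.clip(sim.genotypes.freq, 0.01, 0.99)
        z = sim.genotypes.dosage[0]
        bv = breeding_values(z, f, model, p_0=np.array([0.2, 0.5, 0.3]))
        assert bv.g_n.sum() == pytest.approx(0.0, abs=1e-12)

    def test_strong_candidate_points_to_own_class(self, ova_fit):
        sim, model = ova_fit
        f = np.clip(sim.genotypes.freq, 0.01, 0.99)
        # a real class-1 member as candidate
        z = sim.genotypes.dosage[0]
        bv = breeding_values(z, f, model)
        assert bv.classes[int(np.argmax(bv.p_n))] == sim.labels.labels[0]

    def test_marker_mismatch_raises(self, ova_fit):
        sim, model = ova_fit
        f = np.clip(sim.genotypes.freq, 0.01, 0.99)
        with pytest.raises(ValueError):
            breeding_values(np.zeros(3), f[:3], model)


class TestPairwiseTableInvariants:
    def test_complement_enforced(self):
        with pytest.raises(ValueError):
            PairwiseProbTable(np.array([[0.0, 0.7], [0.6, 0.0]]))

    def test_clipping_keeps_interior(self):
        tab = PairwiseProbTable(np.array([[0.0, 1.0], [0.0, 0.0]]))
        assert 0 < tab.values[0, 1] < 1
        assert tab.values[0, 1] + tab.values[1, 0] == pytest.approx(1.0)
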