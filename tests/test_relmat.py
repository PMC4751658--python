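import itertools

import numpy as np
import pytest

from snpclass.geno_io import GenotypeMatrix, LabelVector, PedigreeTable
from snpclass.relmat import (RelationshipMatrix, center_markers, chol_lower,
                             eigen, eigen_features, grm, nrm,
                             relationship_summary)
from snpclass.simpop import SimSpec, simulate


def kinship_recursive(ped: PedigreeTable):
    """Independent oracle: textbook recursive kinship, A = 2 * kinship."""
    parents = ped.parents()
    order = ped.topological_order()
    memo = {}

    def phi(a, b):
        if a is None or b is None:
            return 0.0
        key = (a, b) if order.index(a) <= order.index(b) else (b, a)
        if key in memo:
            return memo[key]
        # ensure b is not an ancestor of a: recurse on the later-born one
        ia, ib = order.index(a), order.index(b)
        if ia > ib:
            a, b = b, a
        if a == b:
            s, d = parents[a]
            val = 0.5 * (1.0 + phi(s, d))
        else:
            s, d = parents[b]
            val = 0.5 * (phi(a, s) + phi(a, d))
        memo[key] = val
        return val

    n = len(ped.ids)
    A = np.zeros((n, n))
    for i, a in enumerate(ped.ids):
        for j, b in enumerate(ped.ids):
            A[i, j] = 2.0 * phi(a, b)
    return A


class TestCenterMarkers:
    def test_hand_example(self):
        g = GenotypeMatrix(["a", "b", "c"], ["m"], np.array([[0.], [1.], [2.]]))
        cm = center_markers(g, f=np.array([0.5]))
        np.testing.assert_allclose(cm.M, [[-1.], [0.], [1.]])
        assert cm.denom == pytest.approx(0.5)

    def test_external_training_frequencies(self):
        g = GenotypeMatrix(["x"], ["m"], np.array([[2.0]]))
        cm = center_markers(g, f=np.array([0.5]))
        assert cm.M[0, 0] == pytest.approx(1.0)

    def test_monomorphic_marker_contributes_nothing(self):
        g = GenotypeMatrix(["a", "b"], ["m1", "m2"],
                           np.array([[0.0, 1.0], [0.0, 1.0]]))
        cm = center_markers(g)
        np.testing.assert_allclose(cm.M[:, 0], 0.0)
        assert cm.denom == pytest.approx(0.5)  # only m2 (f=0.5)

    def test_degenerate_external_frequency_rejected(self):
        g = GenotypeMatrix(["a"], ["m1", "m2"], np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError):
            center_markers(g, f=np.array([0.0, 0.5]))


class TestGrm:
    def test_hand_example(self, toy_genotypes):
        cm = center_markers(toy_genotypes, f=np.array([0.5, 0.5]))
        G = grm(cm)
        np.testing.assert_allclose(
            G.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12)

    def test_duplicated_individuals_equal_rows(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, (4, 50)).astype(float)
        dos[3] = dos[0]
        g = GenotypeMatrix(list("abcd"), [f"m{j}" for j in range(50)], dos)
        G = grm(center_markers(g))
        np.testing.assert_allclose(G.values[0], G.values[3])

    def test_offdiagonal_mean_negative_under_own_centering(self, two_pop_sim):
        G = grm(center_markers(two_pop_sim.genotypes))
        n = G.n
        off = G.values[np.triu_indices(n, k=1)]
        # centering on the sample's own frequencies makes the average
        # relationship negative: below-average relationships in this sample
        assert off.mean() < 0

    def test_converges_to_balding_nichols_block_structure(self):
        sim = simulate(SimSpec(K=2, n_per_class=(30, 30), m=4000, F=0.3, seed=3))
        G = grm(center_markers(sim.genotypes))
        lab = sim.labels.codes()
        within = G.values[np.ix_(lab == 0, lab == 0)]
        within = within[np.triu_indices_from(within, k=1)].mean()
        between = G.values[np.ix_(lab == 0, lab == 1)].mean()
        assert within > between + 0.1


class TestNrm:
    def test_parent_offspring(self):
        ped = PedigreeTable([("S", None, None), ("O", "S", None)])
        A = nrm(ped)
        a = A.to_frame()
        assert a.loc["S", "O"] == pytest.approx(0.5)
        assert a.loc["O", "O"] == pytest.approx(1.0)

    def test_full_sibs(self):
        ped = PedigreeTable([("S", None, None), ("D", None, None),
                             ("x", "S", "D"), ("y", "S", "D")])
        a = nrm(ped).to_frame()
        assert a.loc["x", "y"] == pytest.approx(0.5)

    def test_offspring_of_half_sibs_inbred(self):
        ped = PedigreeTable([("S", None, None), ("D1", None, None),
                             ("D2", None, None), ("h1", "S", "D1"),
                             ("h2", "S", "D2"), ("o", "h1", "h2")])
        a = nrm(ped).to_frame()
        assert a.loc["o", "o"] == pytest.approx(1.125)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_recursive_kinship_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = [(f"F{i}", None, None) for i in range(5)]
        ids = [r[0] for r in records]
        for i in range(15):
            s, d = rng.choice(len(ids), size=2, replace=False)
            records.append((f"I{i}", ids[s], ids[d]))
            ids.append(f"I{i}")
        ped = PedigreeTable(records)
        A = nrm(ped).values
        np.testing.assert_allclose(A, kinship_recursive(ped), atol=1e-12)


class TestEigen:
    def test_identity(self):
        R = RelationshipMatrix(np.eye(3), "genomic", list("abc"))
        eb = eigen(R)
        np.testing.assert_allclose(eb.d, 1.0)
        np.testing.assert_allclose(eb.cumvar, [1 / 3, 2 / 3, 1.0])

    def test_rank_one(self):
        v = np.array([[1.0], [1.0]])
        R = RelationshipMatrix(v @ v.T, "genomic", ["a", "b"])
        eb = eigen(R)
        np.testing.assert_allclose(eb.cumvar, [1.0, 1.0])

    def test_reconstruction(self, two_pop_sim):
        G = grm(center_markers(two_pop_sim.genotypes))
        eb = eigen(G)
        recon = eb.U @ np.diag(eb.d) @ eb.U.T
        assert np.linalg.norm(recon - G.values) < 1e-8

    def test_first_eigenvector_separates_diverged_populations(self):
        sim = simulate(SimSpec(K=2, n_per_class=(25, 25), m=2000, F=0.5, seed=7))
        G = grm(center_markers(sim.genotypes))
        eb = eigen(G)
        codes = sim.labels.codes()
        u1 = eb.U[:, 0]
        signs = np.sign(u1)
        agree = max((signs[codes == 0] > 0).mean() + (signs[codes == 1] < 0).mean(),
                    (signs[codes == 0] < 0).mean() + (signs[codes == 1] > 0).mean())
        assert agree == pytest.approx(2.0)  # perfect separation by sign


class TestChol:
    def test_identity(self):
        R = RelationshipMatrix(np.eye(4), "pedigree", list("abcd"))
        np.testing.assert_allclose(chol_lower(R), np.eye(4))

    def test_2x2_closed_form(self):
        R = RelationshipMatrix(np.array([[1, 0.5], [0.5, 1]]), "pedigree", ["a", "b"])
        L = chol_lower(R)
        np.testing.assert_allclose(L, [[1, 0], [0.5, np.sqrt(0.75)]])

    def test_parent_offspring_defining_property(self):
        ped = PedigreeTable([("S", None, None), ("D", None, None),
                             ("O", "S", "D")])
        A = nrm(ped)
        L = chol_lower(A)
        assert np.abs(L @ L.T - A.values).max() < 1e-10

    def test_psd_with_jitter(self, two_pop_sim):
        G = grm(center_markers(two_pop_sim.genotypes))  # singular: G 1 = 0
        L = chol_lower(G)
        assert np.abs(L @ L.T - G.values).max() < 1e-6


class TestSummary:
    def test_block_constant_recovered(self):
        n = 6
        vals = np.full((n, n), 0.0)
        vals[:3, :3] = 0.1
        vals[3:, 3:] = 0.1
        np.fill_diagonal(vals, 1.0)
        R = RelationshipMatrix(vals, "genomic", [f"s{i}" for i in range(n)])
        lab = LabelVector([f"s{i}" for i in range(n)], np.array(["A"] * 3 + ["B"] * 3))
        df = relationship_summary(R, lab)
        within = df[(df.class_a == "A") & (df.class_b == "A")].iloc[0]
        between = df[(df.class_a == "A") & (df.class_b == "B")].iloc[0]
        assert within["mean"] == pytest.approx(0.1)
        assert between["mean"] == pytest.approx(0.0)

    def test_singleton_class_within_missing(self):
        R = RelationshipMatrix(np.eye(3), "genomic", ["a", "b", "c"])
        lab = LabelVector(["a", "b", "c"], np.array(["A", "B", "B"]))
        df = relationship_summary(R, lab)
        within_a = df[(df.class_a == "A") & (df.class_b == "A")].iloc[0]
        assert np.isnan(within_a["mean"])
        between = df[(df.class_a == "A") & (df.class_b == "B")].iloc[0]
        assert np.isfinite(between["mean"])

    def test_two_population_within_exceeds_between(self, two_pop_sim):
        G = grm(center_markers(two_pop_sim.genotypes))
        df = relationship_summary(G, two_pop_sim.labels)
        w = df[(df.class_a == "C1") & (df.class_b == "C1")]["mean"].iloc[0]
        b = df[(df.class_a == "C1") & (df.class_b == "C2")]["mean"].iloc[0]
        assert w > b


def test_eigen_features_shapes(two_pop_sim):
    G = grm(center_markers(two_pop_sim.genotypes))
    Z, eb = eigen_features(G)
    assert Z.shape[1] <= G.n - 1
    # standardized columns: eigenvectors of centered G are mean-zero, so the
    # sqrt(n) rescaling gives exactly unit (population) variance
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(Z.var(axis=0), 1.0, atol=1e-8)
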