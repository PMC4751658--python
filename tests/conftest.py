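import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from snpclass.geno_io import GenotypeMatrix, LabelVector
from snpclass.simpop import SimSpec, simulate


class CentroidStub(ClassifierMixin, BaseEstimator):
    """Cheap deterministic probabilistic binary classifier for scheme tests.

    Scores by distance to the two class centroids mapped through a logistic;
    no randomness, so two instances always agree.
    """

    def __init__(self, seed=0, sharpness=2.0):
        self.seed = seed
        self.sharpness = sharpness

    def fit(self, X, y, W=None):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.mu0_ = X[y == self.classes_[0]].mean(axis=0)
        self.mu1_ = X[y == self.classes_[1]].mean(axis=0)
        return self

    def predict_proba(self, X, W=None):
        X = np.asarray(X, float)
        d0 = np.linalg.norm(X - self.mu0_, axis=1)
        d1 = np.linalg.norm(X - self.mu1_, axis=1)
        p1 = 1.0 / (1.0 + np.exp(self.sharpness * (d1 - d0)))
        p1 = np.clip(p1, 1e-6, 1 - 1e-6)
        return np.column_stack([1 - p1, p1])

    def predict(self, X, W=None):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


@pytest.fixture
def stub_classifier():
    return CentroidStub()


@pytest.fixture
def toy_genotypes():
    """3 samples x 2 markers, the hand-worked example used across modules."""
    return GenotypeMatrix(["s1", "s2", "s3"], ["m1", "m2"],
                          np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two well-diverged populations (F=0.2), moderate size."""
    return simulate(SimSpec(K=2, n_per_class=(60, 60), m=600, F=0.2, seed=42))


@pytest.fixture(scope="session")
def three_class_sim():
    """The K=3 classification-power world: F=0.2, 20 per class, 500 markers."""
    return simulate(SimSpec(K=3, n_per_class=(20, 20, 20), m=500, F=0.2, seed=11))


def permuted_labels(labels: LabelVector, seed: int) -> LabelVector:
    rng = np.random.default_rng(seed)
    perm = labels.labels.copy()
    rng.shuffle(perm)
    return LabelVector(list(labels.sample_ids), perm, list(labels.classes))
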