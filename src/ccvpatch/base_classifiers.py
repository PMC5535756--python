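"""Probability-emitting base classifiers under a uniform contract.

The extreme learning machine (ELM) is implemented here: a single-hidden-
layer feedforward network whose input weights W and biases b are drawn
randomly once and frozen, and whose output weights are the minimum-norm
least-squares solution β̂ = H⁺T of Hβ = T, with H the hidden-layer
activation matrix and H⁺ its Moore–Penrose pseudoinverse.  Class
probabilities are a softmax over the raw network outputs.

SVM (linear kernel, Platt-calibrated probabilities) and random forest
(per-class tree-vote fractions) are delegated to scikit-learn; all three
expose ``predict_proba`` with columns ordered [normal, abnormal].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

NORMAL, ABNORMAL = "normal", "abnormal"
CLASS_ORDER = (NORMAL, ABNORMAL)


def _activation(name: str):
    if name == "sigmoid":
        return lambda z: 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class ELMModel:
    """Fitted ELM state: random input layer (W, b) and solved output
    weights beta."""

    W: np.ndarray  # (L, d)
    b: np.ndarray  # (L,)
    beta: np.ndarray  # (L, m)
    activation: str
    L: int
    seed: int


def elm_fit(
    X: np.ndarray,
    T: np.ndarray,
    L: int = 100,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ELMModel:
    """Fit an ELM on samples-by-features X and one-hot targets T.

    W and b are drawn uniform(−1, 1) from ``seed`` and never trained;
    beta = pinv(H) @ T.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-d with at least one feature column")
    if L < 1:
        raise ValueError("L must be >= 1")
    if len(X) != len(T):
        raise ValueError("X and T row counts differ")
    g = _activation(activation)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=L)
    H = g(X @ W.T + b)
    beta = np.linalg.pinv(H) @ T
    return ELMModel(W=W, b=b, beta=beta, activation=activation, L=L, seed=seed)


def elm_raw_output(model: ELMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.W.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} features; model expects {model.W.shape[1]}")
    g = _activation(model.activation)
    return g(X @ model.W.T + model.b) @ model.beta


def elm_predict_proba(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Softmax over the raw class outputs; rows sum to 1 and the argmax
    equals the argmax of the raw outputs."""
    raw = elm_raw_output(model, X)
    z = raw - raw.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ELMClassifier:
    """sklearn-style wrapper around the functional ELM interface."""

    def __init__(self, L: int = 100, activation: str = "sigmoid", seed: int = 0):
        self.L = L
        self.activation = activation
        self.seed = seed
        self.model: ELMModel | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "ELMClassifier":
        y = np.asarray(y)
        self.classes_ = np.asarray(CLASS_ORDER)
        T = np.column_stack([(y == c).astype(float) for c in self.classes_])
        if T.sum() != len(y):
            raise ValueError(f"labels must be in {CLASS_ORDER}")
        self.model = elm_fit(X, T, L=self.L, activation=self.activation, seed=self.seed)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return elm_predict_proba(self.model, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _BackendWrapper:
    """Normalizes an sklearn classifier to the [normal, abnormal] column
    order of this package."""

    def __init__(self, est):
        self.est = est
        self.classes_ = np.asarray(CLASS_ORDER)

    def fit(self, X, y):
        self.est.fit(X, np.asarray(y))
        self._order = [list(self.est.classes_).index(c) for c in CLASS_ORDER]
        return self

    def predict_proba(self, X):
        return self.est.predict_proba(X)[:, self._order]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_backend(
    name: str,
    X: np.ndarray,
    y: Sequence[str],
    params: dict | None = None,
    seed: int = 0,
):
    """Train a standard backend classifier (``"svm"`` or ``"rf"``).

    SVM: linear kernel, C=1, Platt-calibrated probabilities.  RF: 100
    trees; class probability is the fraction of trees voting each class.
    """
    params = dict(params or {})
    if name == "svm":
        svc = SVC(kernel=params.pop("kernel", "linear"), C=params.pop("C", 1.0),
                  random_state=seed, **params)
        # Platt-style sigmoid calibration on the decision values
        est = CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
    elif name == "rf":
        est = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 100), random_state=seed, **params)
    else:
        raise ValueError(f"unknown backend {name!r}; expected 'svm' or 'rf'")
    return _BackendWrapper(est).fit(X, y)


def make_classifier(name: str, params: dict | None = None, seed: int = 0):
    """Unfitted classifier factory over all three names (elm/svm/rf)."""
    if name == "elm":
        p = dict(params or {})
        return ELMClassifier(L=p.pop("L", 100), activation=p.pop("activation", "sigmoid"),
                             seed=seed)

    class _Deferred:
        def __init__(self):
            self.clf = None
            self.classes_ = np.asarray(CLASS_ORDER)

        def fit(self, X, y):
            self.clf = train_backend(name, X, y, params=params, seed=seed)
            return self

        def predict_proba(self, X):
            return self.clf.predict_proba(X)

        def predict(self, X):
            return self.clf.predict(X)

    if name in ("svm", "rf"):
        return _Deferred()
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ProbPrediction:
    """Initial (pre-CCV) prediction of one sample."""

    sample_id: str
    initial_label: str
    p_initial: float  # probability of the assigned class, >= 0.5 under argmax


def predict_initial(clf, X: np.ndarray, sample_ids: Sequence[str]) -> list[ProbPrediction]:
    """Argmax predictions with the winning-class probability."""
    proba = clf.predict_proba(X)
    labels = np.asarray(clf.classes_)[np.argmax(proba, axis=1)]
    p = proba.max(axis=1)
    return [ProbPrediction(sample_id=str(sid), initial_label=str(lab), p_initial=float(pi))
            for sid, lab, pi in zip(sample_ids, labels, p)]
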