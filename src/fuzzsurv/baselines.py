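"""Comparison classifiers: a plain dense deep network, an RBF-kernel SVM
tuned by grid-search cross-validation, and a 10-tree entropy random forest.

All models share one contract with the FDL network: ``fit``/``train`` on
encoded data, ``predict`` emitting labels in 0..5, and ``predict_scores``
emitting an (n, 6) score matrix (probabilities, decision values, or vote
fractions) usable for one-vs-rest ROC analysis.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .network import N_CLASSES, TrainConfig, TrainHistory, _DenseStack, _flatten, \
    _softmax, _unflatten, train


class DenseBaseline:
    """The FDL architecture minus its fuzzy front end: inputs go straight
    into the same dense rectifier stack and 6-way softmax head, trained by
    the identical SGD protocol."""

    kind = "dl"

    def __init__(self, input_dim: int, n_classes: int = N_CLASSES,
                 hidden: tuple[int, ...] = (64, 32), seed: int = 0):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.hidden = hidden
        self.seed = seed
        self.stack = _DenseStack(input_dim, hidden, n_classes,
                                 np.random.default_rng(seed))

    def forward(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.stack.forward(np.asarray(X, dtype=float))
        return _softmax(logits)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = len(X)
        logits, acts = self.stack.forward(X)
        probs = _softmax(logits)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dW, db, _ = self.stack.backward(dlogits, acts)
        return loss, _flatten([*dW, *db])

    def params(self) -> list[np.ndarray]:
        return self.stack.params()

    def get_flat_params(self) -> np.ndarray:
        return _flatten(self.params())

    def set_flat_params(self, flat: np.ndarray) -> None:
        _unflatten(np.asarray(flat, dtype=float), self.params())

    def post_step(self) -> None:
        pass

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_scores(X).argmax(axis=1)

    def to_checkpoint(self) -> dict:
        return {
            "kind": self.kind,
            "input_dim": self.input_dim,
            "n_classes": self.n_classes,
            "config": {"hidden": list(self.hidden), "seed": self.seed},
            "params": self.get_flat_params().tolist(),
        }

    @classmethod
    def from_checkpoint(cls, d: dict) -> "DenseBaseline":
        m = cls(d["input_dim"], d["n_classes"], tuple(d["config"]["hidden"]),
                d["config"]["seed"])
        m.set_flat_params(np.asarray(d["params"], dtype=float))
        return m


def train_dl_baseline(X_train, y_train, X_val, y_val,
                      config: TrainConfig = TrainConfig(),
                      hidden: tuple[int, ...] = (64, 32)
                      ) -> tuple[DenseBaseline, TrainHistory]:
    model = DenseBaseline(np.asarray(X_train).shape[1], hidden=hidden,
                          seed=config.seed)
    hist = train(model, X_train, y_train, X_val, y_val, config)
    return model, hist


# ---------------------------------------------------------------------------
# SVM

DEFAULT_SVM_GRID = {"C": (0.1, 1.0, 10.0, 100.0),
                    "gamma": (1e-3, 1e-2, 1e-1, 1.0)}


class SVMModel:
    """One-vs-rest RBF support vector machine; C and the kernel width gamma
    are chosen by k-fold cross-validated grid search on mean accuracy, with
    ties broken toward the smaller C, then the smaller gamma. ROC scores are
    per-class decision-function values."""

    kind = "svm"

    def __init__(self, grid: dict | None = None, cv_folds: int = 5, seed: int = 0,
                 n_classes: int = N_CLASSES):
        self.grid = grid or DEFAULT_SVM_GRID
        if not self.grid["C"] or not self.grid["gamma"]:
            raise ValueError("SVM grid must be non-empty")
        self.cv_folds = cv_folds
        self.seed = seed
        self.n_classes = n_classes
        self.best_params_: dict | None = None
        self.cv_accuracy_: float | None = None
        self._svc: SVC | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("SVM needs at least two classes in the training data")
        n_splits = min(self.cv_folds, int(counts.min()))
        best = None
        for C in sorted(self.grid["C"]):
            for gamma in sorted(self.grid["gamma"]):
                if n_splits >= 2:
                    accs = []
                    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                          random_state=self.seed)
                    for tr, te in skf.split(X, y):
                        m = SVC(C=C, gamma=gamma, kernel="rbf",
                                decision_function_shape="ovr")
                        m.fit(X[tr], y[tr])
                        accs.append(float((m.predict(X[te]) == y[te]).mean()))
                    score = float(np.mean(accs))
                else:  # too few per-class records to cross-validate
                    m = SVC(C=C, gamma=gamma, kernel="rbf",
                            decision_function_shape="ovr")
                    m.fit(X, y)
                    score = float((m.predict(X) == y).mean())
                if best is None or score > best[0]:
                    best = (score, C, gamma)
        self.cv_accuracy_, C, gamma = best
        self.best_params_ = {"C": C, "gamma": gamma}
        self._svc = SVC(C=C, gamma=gamma, kernel="rbf",
                        decision_function_shape="ovr")
        self._svc.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float)).astype(int)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        df = self._svc.decision_function(X)
        if df.ndim == 1:  # binary problem: signed distance for class_[1]
            df = np.column_stack([-df, df])
        out = np.full((len(X), self.n_classes), -1e9)
        for j, cls in enumerate(self._svc.classes_):
            out[:, int(cls)] = df[:, j]
        return out


def train_svm(X, y, grid: dict | None = None, cv_folds: int = 5, seed: int = 0
              ) -> SVMModel:
    return SVMModel(grid=grid, cv_folds=cv_folds, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# random forest

class RFModel:
    """Random forest with 10 trees by default and the entropy (information
    gain) split criterion; unlimited depth, sqrt(d) features per split,
    bootstrap resampling. Scores are per-class vote fractions."""

    kind = "rf"

    def __init__(self, n_trees: int = 10, max_depth: int | None = None,
                 seed: int = 0, n_classes: int = N_CLASSES):
        if n_trees < 1:
            raise ValueError("need at least one tree")
        self.n_classes = n_classes
        self._rf = RandomForestClassifier(
            n_estimators=n_trees, criterion="entropy", max_depth=max_depth,
            max_features="sqrt", bootstrap=True, random_state=seed,
        )

    @property
    def n_trees(self) -> int:
        return self._rf.n_estimators

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("cannot fit a forest on empty data")
        self._rf.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._rf.predict(np.asarray(X, dtype=float)).astype(int)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        proba = self._rf.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((len(proba), self.n_classes))
        for j, cls in enumerate(self._rf.classes_):
            out[:, int(cls)] = proba[:, j]
        return out


def train_rf(X, y, n_trees: int = 10, max_depth: int | None = None, seed: int = 0
             ) -> RFModel:
    return RFModel(n_trees=n_trees, max_depth=max_depth, seed=seed).fit(X, y)
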