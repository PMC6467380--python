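"""Comparison classifiers: extreme learning machine and RBF-kernel SVM.

Both consume the same [0,1]-normalised feature tables as the SSAE and expose
``predict`` / ``decision_scores`` so the evaluation code treats all three
models uniformly.  The ELM is a single hidden layer of sigmoid units with
random fixed input weights and a closed-form (ridge-regularised
least-squares) output layer — 20 hidden neurons by default.  The SVM
delegates to scikit-learn, with (C, gamma) chosen by stratified k-fold
cross-validation on the training split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .autoencoder import sigmoid

__all__ = ["ELMModel", "train_elm", "SVMModel", "train_svm_rbf", "DEFAULT_SVM_GRID"]

DEFAULT_SVM_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.01, 0.1, 1.0, 10.0]}


@dataclass
class ELMModel:
    """Random-hidden-layer network with least-squares output weights."""

    W_in: np.ndarray  # n_hidden x n_features, drawn uniform on [-1, 1]
    b_in: np.ndarray  # n_hidden
    W_out: np.ndarray  # n_hidden x n_classes
    seed: int = 0

    def _hidden(self, X_rows: np.ndarray) -> np.ndarray:
        X = np.asarray(X_rows, dtype=np.float64)
        return sigmoid(self.W_in @ X.T + self.b_in[:, None])  # hidden x samples

    def scores(self, X_rows: np.ndarray) -> np.ndarray:
        """Per-class linear outputs, rows-are-samples (n x 2)."""
        return (self.W_out.T @ self._hidden(X_rows)).T

    def predict(self, X_rows: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(X_rows), axis=1)

    def decision_scores(self, X_rows: np.ndarray) -> np.ndarray:
        """Positive-class score margin for ROC analysis."""
        s = self.scores(X_rows)
        return s[:, 1] - s[:, 0]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "ehgkit-elm",
                    "version": 1,
                    "seed": self.seed,
                    "W_in": self.W_in.tolist(),
                    "b_in": self.b_in.tolist(),
                    "W_out": self.W_out.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "ELMModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "ehgkit-elm":
            raise ValueError(f"{path} is not an ELM model bundle")
        return cls(
            W_in=np.array(d["W_in"]),
            b_in=np.array(d["b_in"]),
            W_out=np.array(d["W_out"]),
            seed=d["seed"],
        )


def train_elm(
    X_rows: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 20,
    seed: int = 0,
    ridge: float = 1e-8,
) -> ELMModel:
    """Closed-form ELM fit: random input weights, ridge least-squares output.

    Deterministic given ``seed``; the tiny ridge term keeps the normal
    equations well-posed when the hidden activation matrix is rank-deficient.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    X = np.asarray(X_rows, dtype=np.float64)
    y = np.asarray(y)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    rng = np.random.default_rng(seed)
    W_in = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b_in = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = sigmoid(W_in @ X.T + b_in[:, None])  # hidden x samples
    T = np.zeros((y.size, 2))
    T[np.arange(y.size), y] = 1.0
    gram = H @ H.T + ridge * np.eye(n_hidden)
    W_out = np.linalg.solve(gram, H @ T)
    return ELMModel(W_in=W_in, b_in=b_in, W_out=W_out, seed=seed)


@dataclass
class SVMModel:
    """Fitted RBF-SVM with the cross-validated (C, gamma) choice."""

    clf: SVC
    best_params: Dict[str, float] = field(default_factory=dict)

    def predict(self, X_rows: np.ndarray) -> np.ndarray:
        return self.clf.predict(np.asarray(X_rows, dtype=np.float64))

    def decision_scores(self, X_rows: np.ndarray) -> np.ndarray:
        """Signed distance to the separating surface (monotone in P(labor))."""
        return self.clf.decision_function(np.asarray(X_rows, dtype=np.float64))


def train_svm_rbf(
    X_rows: np.ndarray,
    y: np.ndarray,
    grid: Dict[str, Sequence[float]] | None = None,
    n_folds: int = 5,
) -> SVMModel:
    """RBF-kernel SVM with (C, gamma) selected by stratified k-fold CV."""
    X = np.asarray(X_rows, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("SVM training needs both classes present")
    grid = dict(grid) if grid else dict(DEFAULT_SVM_GRID)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds >= 2:
        search = GridSearchCV(
            SVC(kernel="rbf"),
            param_grid=grid,
            cv=StratifiedKFold(n_splits=n_folds, shuffle=False),
            scoring="accuracy",
        )
        search.fit(X, y)
        return SVMModel(clf=search.best_estimator_, best_params=search.best_params_)
    # too few samples to cross-validate: fall back to the first grid point
    clf = SVC(kernel="rbf", C=grid["C"][0], gamma=grid["gamma"][0]).fit(X, y)
    return SVMModel(clf=clf, best_params={"C": grid["C"][0], "gamma": grid["gamma"][0]})
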