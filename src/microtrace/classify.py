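"""Active-learning cell-type classification.

A logistic-regression classifier trained by uncertainty sampling: starting
from one labeled example per class, each iteration queries the pool cell
whose predicted probability is closest to 0.5, obtains its label from an
oracle (ground truth in tests, a file or a human in practice), and refits.
This concentrates annotation effort on the most informative examples, so a
budget of a few tens of queries suffices for well-separated cell classes.

Features are z-scored with pool statistics frozen at loop start so the
standardization does not drift as cells are labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["LogisticModel", "ActiveLearner", "fit_logistic", "query_next",
           "active_learn_loop", "PoolExhausted"]


class PoolExhausted(Exception):
    """Signals that no unlabeled cells remain to query."""


@dataclass
class LogisticModel:
    weights: np.ndarray
    bias: float
    mean: np.ndarray        # pool standardization
    scale: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.mean) / self.scale
        return Xs @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def fit_logistic(X: np.ndarray, y: np.ndarray, lam_reg: float = 1.0,
                 mean: np.ndarray | None = None,
                 scale: np.ndarray | None = None) -> LogisticModel:
    """L2-regularized maximum-likelihood logistic fit (convex, deterministic).

    Minimizes ``sum_i log(1 + exp(-y_i f(x_i))) + lam_reg/2 ||w||^2`` with an
    unpenalized intercept. Features are standardized with the provided pool
    statistics (or the training set's own if omitted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least one labeled example per class "
                         f"(got classes {classes.tolist()})")
    if mean is None:
        mean = X.mean(axis=0)
    if scale is None:
        scale = X.std(axis=0)
    scale = np.where(np.asarray(scale) > 0, scale, 1.0)
    Xs = (X - mean) / scale
    clf = LogisticRegression(C=1.0 / lam_reg, solver="lbfgs", tol=1e-10, max_iter=10_000)
    clf.fit(Xs, y)
    return LogisticModel(weights=clf.coef_[0].copy(), bias=float(clf.intercept_[0]),
                         mean=np.asarray(mean, float), scale=np.asarray(scale, float))


@dataclass
class ActiveLearner:
    X: np.ndarray
    lam_reg: float = 1.0
    labeled: dict = field(default_factory=dict)     # cell id -> label
    pool: list = field(default_factory=list)        # unlabeled cell ids
    history: list = field(default_factory=list)     # queried ids, in order
    model: LogisticModel | None = None
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if not self.pool and not self.labeled:
            self.pool = list(range(len(self.X)))
        # pool statistics frozen at loop start
        if self.mean is None:
            self.mean = self.X.mean(axis=0)
            self.scale = np.where(self.X.std(axis=0) > 0, self.X.std(axis=0), 1.0)

    def add_label(self, cell_id: int, label: int) -> None:
        self.labeled[int(cell_id)] = int(label)
        if cell_id in self.pool:
            self.pool.remove(cell_id)

    def refit(self) -> LogisticModel:
        ids = sorted(self.labeled)
        self.model = fit_logistic(self.X[ids], np.array([self.labeled[i] for i in ids]),
                                  self.lam_reg, self.mean, self.scale)
        return self.model


def query_next(learner: ActiveLearner) -> int:
    """Most-uncertain pool cell: predicted probability closest to 0.5.

    Ties break to the lowest cell id; repeats are impossible because queried
    cells leave the pool.
    """
    if not learner.pool:
        raise PoolExhausted("unlabeled pool is empty")
    pool = np.array(sorted(learner.pool))
    if learner.model is None:
        return int(pool[0])
    p = learner.model.predict_proba(learner.X[pool])
    k = int(np.argmin(np.abs(p - 0.5)))   # argmin takes the first = lowest id
    return int(pool[k])


def active_learn_loop(X: np.ndarray, oracle, budget: int, seed: int,
                      lam_reg: float = 1.0, holdout=None):
    """Uncertainty-sampling loop: query -> label -> refit for ``budget`` rounds.

    ``oracle(cell_id) -> label`` supplies ground truth. ``holdout`` is an
    optional ``(X_test, y_test)`` pair; when given, the returned curve holds
    held-out accuracy after each refit. Initialization labels one random
    example per class (seeded).
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    rng = np.random.default_rng(seed)
    learner = ActiveLearner(X=X, lam_reg=lam_reg)
    # seed the labeled set with one random example of each class
    all_ids = rng.permutation(len(X))
    seen_classes = set()
    for i in all_ids:
        lab = int(oracle(int(i)))
        if lab not in seen_classes:
            seen_classes.add(lab)
            learner.add_label(int(i), lab)
            learner.history.append(int(i))
        if len(seen_classes) == 2:
            break
    learner.refit()
    curve = []
    for _ in range(budget):
        try:
            q = query_next(learner)
        except PoolExhausted:
            break
        learner.add_label(q, int(oracle(q)))
        learner.history.append(q)
        learner.refit()
        if holdout is not None:
            Xt, yt = holdout
            curve.append(float((learner.model.predict(Xt) == yt).mean()))
    return learner.model, np.array(curve), learner
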