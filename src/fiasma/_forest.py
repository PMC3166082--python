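"""Compact random-forest classifier with the study's fixed hyperparameters.

The learner is a classical Breiman forest: ``ntree`` CART trees, each grown
on a bootstrap resample of the rows (multinomial sample weights), Gini
split criterion, ``mtry`` features considered per split, depth capped at
``maxdepth``, terminal nodes down to ``nodesize`` samples, prediction by
majority vote. Determinism is guaranteed given the seed.

Two interchangeable backends grow the individual trees:

* ``"cython"`` drives scikit-learn's internal tree builder directly
  (``sklearn.tree._tree``), the same compiled code path
  ``RandomForestClassifier`` uses, without the per-fit Python overhead --
  important here because the validation protocol refits the forest tens of
  thousands of times;
* ``"sklearn"`` loops over public :class:`~sklearn.tree.DecisionTreeClassifier`
  objects.

Both implement identical semantics; a test asserts their agreement. The
cython backend is selected automatically when the internal symbols are
importable.
"""

from __future__ import annotations

import numpy as np

try:  # fast path: sklearn's compiled tree machinery
    from sklearn.tree._criterion import Gini as _Gini
    from sklearn.tree._splitter import BestSplitter as _BestSplitter
    from sklearn.tree._tree import DepthFirstTreeBuilder as _Builder, Tree as _Tree

    _HAVE_CYTHON = True
except Exception:  # pragma: no cover - depends on sklearn internals
    _HAVE_CYTHON = False

from sklearn.tree import DecisionTreeClassifier

DEFAULT_BACKEND = "cython" if _HAVE_CYTHON else "sklearn"


class RandomForest:
    """Breiman random forest for binary labels {0, 1}.

    Parameters mirror the classical R/randomForest vocabulary: ``ntree``,
    ``nodesize`` (minimum terminal-node size), ``mtry`` (features sampled
    per split) and ``maxdepth``.
    """

    def __init__(
        self,
        ntree: int = 51,
        nodesize: int = 1,
        mtry: int | None = None,
        maxdepth: int = 8,
        seed: int = 0,
        backend: str | None = None,
    ):
        self.ntree = int(ntree)
        self.nodesize = int(nodesize)
        self.mtry = mtry
        self.maxdepth = int(maxdepth)
        self.seed = int(seed)
        self.backend = backend or DEFAULT_BACKEND
        self._trees: list = []
        self.n_features_ = 0

    # -- fitting ----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "RandomForest":
        x = np.ascontiguousarray(np.asarray(x, dtype=np.float32))
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("forest requires both classes in the training data")
        if not set(classes.tolist()) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        n, m = x.shape
        self.n_features_ = m
        mtry = self.mtry if self.mtry is not None else int(np.log2(m)) + 1
        mtry = max(1, min(mtry, m))
        rng = np.random.default_rng(self.seed)
        self._trees = []
        if self.backend == "cython":
            y2 = np.ascontiguousarray(y.astype(np.float64).reshape(-1, 1))
            n_classes = np.array([2], dtype=np.intp)
            for _ in range(self.ntree):
                w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(np.float64)
                tree_seed = int(rng.integers(0, 2**31 - 1))
                crit = _Gini(1, n_classes)
                splitter = _BestSplitter(
                    crit, mtry, self.nodesize, 0.0, np.random.RandomState(tree_seed), None
                )
                tree = _Tree(m, n_classes, 1)
                builder = _Builder(splitter, 2, self.nodesize, 0.0, self.maxdepth, 0.0)
                builder.build(tree, x, y2, w, None)
                self._trees.append(tree)
        elif self.backend == "sklearn":
            for _ in range(self.ntree):
                w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(np.float64)
                tree_seed = int(rng.integers(0, 2**31 - 1))
                dt = DecisionTreeClassifier(
                    criterion="gini",
                    max_depth=self.maxdepth,
                    min_samples_leaf=self.nodesize,
                    max_features=mtry,
                    random_state=tree_seed,
                )
                dt.fit(x, y, sample_weight=w, check_input=False)
                self._trees.append(dt)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        return self

    # -- prediction -------------------------------------------------------
    def _votes(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(np.asarray(x, dtype=np.float32))
        votes = np.zeros(x.shape[0])
        if self.backend == "cython":
            for tree in self._trees:
                value = tree.predict(x)  # per-leaf weighted class counts
                counts = value.reshape(x.shape[0], -1)
                votes += np.argmax(counts, axis=1)
        else:
            for dt in self._trees:
                votes += dt.predict(x, check_input=False)
        return votes

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Majority vote over trees (even splits fall to class 0)."""
        if not self._trees:
            raise ValueError("forest is not fitted")
        return (self._votes(x) > self.ntree / 2.0).astype(np.int64)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for each class."""
        frac1 = self._votes(x) / self.ntree
        return np.column_stack([1.0 - frac1, frac1])
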