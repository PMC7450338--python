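"""Binary front-end for wrapper feature selection.

The optimizer searches the continuous cube [0, 1]^N; every fitness
evaluation squashes each coordinate through a steep sigmoid transfer
function, thresholds it stochastically into a bit (1 = feature selected),
trains the wrapped classifier on the selected columns under a fixed
stratified k-fold partition, and scores the subset with

    Fit = alpha_w * |R|/|N| - beta_w * Avg_cross_Acc

(lower is better): a small weight on subset length traded against the
cross-validated accuracy, both normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import ConfigurationError, ObjectiveSpec

CONVENTIONS = ("as_printed", "standard")


@dataclass
class FitnessWeights:
    """Subset-length weight ``alpha_w`` (0.2) and quality weight ``beta_w`` (0.8)."""

    alpha_w: float = 0.2
    beta_w: float = 0.8

    def __post_init__(self) -> None:
        if self.alpha_w < 0 or self.beta_w < 0:
            raise ConfigurationError("fitness weights must be non-negative")


def sigmoid_transfer(x):
    """Steep sigmoid centred at 0.5: ``1 / (1 + exp(-10 (x - 0.5)))``."""
    return expit(10.0 * (np.asarray(x, dtype=float) - 0.5))


def binarize(
    position: np.ndarray,
    rng: np.random.Generator,
    convention: str = "as_printed",
) -> np.ndarray:
    """Stochastically threshold a continuous position into a feature mask.

    ``as_printed`` sets bit = 0 if rand < S else 1, so P(bit=1) = 1 - S and
    *low* continuous coordinates select features; ``standard`` is the usual
    binary-swarm rule bit = 1 if rand < S.  An all-zero mask is repaired by switching one uniformly
    chosen bit on, so every evaluated subset has at least one feature.
    """
    if convention not in CONVENTIONS:
        raise ConfigurationError(f"convention must be one of {CONVENTIONS}; got {convention!r}")
    s = sigmoid_transfer(position)
    r = rng.uniform(size=s.shape)
    bits = (r >= s) if convention == "as_printed" else (r < s)
    bits = bits.astype(np.int8)
    if not bits.any():
        bits[rng.integers(bits.size)] = 1
    return bits


def subset_fitness(
    n_selected: int,
    cv_accuracy: float,
    weights: FitnessWeights,
    total_features: int,
) -> float:
    """``alpha_w * |R|/|N| - beta_w * accuracy``; range [-beta_w, alpha_w]."""
    if not 1 <= n_selected <= total_features:
        raise ConfigurationError(
            f"selected-subset size must lie in [1, {total_features}]; got {n_selected}"
        )
    if not 0.0 <= cv_accuracy <= 1.0:
        raise ConfigurationError(f"accuracy must lie in [0, 1]; got {cv_accuracy}")
    return weights.alpha_w * (n_selected / total_features) - weights.beta_w * cv_accuracy


@dataclass
class SubsetRecord:
    """Best subset seen so far during a feature-selection run."""

    fitness: float = np.inf
    mask: Optional[np.ndarray] = None
    accuracy: float = 0.0
    n_selected: int = 0


class FeatureSelectionProblem:
    """A dataset + classifier + fixed CV plan wrapped as a minimization
    objective over [0, 1]^n_features.

    The fold partition is stratified and frozen at construction so the
    fitness of a given mask is deterministic; each objective call still
    counts one fitness evaluation even for repeated masks.  The classifier
    is a pluggable scikit-learn estimator (cloned per fold), defaulting to a
    linear-kernel SVM.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        estimator=None,
        k: int = 10,
        cv_seed: int = 0,
        weights: FitnessWeights = None,
        convention: str = "as_printed",
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ConfigurationError("X must be 2-d with one label per row")
        if not np.isfinite(X).all():
            raise ConfigurationError("dataset contains missing or non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ConfigurationError(f"need exactly two classes; got {classes.tolist()}")
        if k > counts.min():
            raise ConfigurationError(
                f"k={k} folds exceed the smallest class count ({counts.min()})"
            )
        if convention not in CONVENTIONS:
            raise ConfigurationError(f"unknown binarization convention {convention!r}")
        self.X = X
        self.y = (y == classes[1]).astype(int)
        self.estimator = estimator if estimator is not None else SVC(kernel="linear")
        self.k = k
        self.weights = weights if weights is not None else FitnessWeights()
        self.convention = convention
        self.n_features = X.shape[1]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv_seed)
        self.folds = list(skf.split(X, self.y))
        self.best = SubsetRecord()

    def cv_accuracy(self, mask: np.ndarray) -> float:
        """Mean fold accuracy of the classifier trained on the masked columns."""
        cols = np.flatnonzero(mask)
        accs = []
        for train, test in self.folds:
            clf = clone(self.estimator)
            clf.fit(self.X[np.ix_(train, cols)], self.y[train])
            pred = clf.predict(self.X[np.ix_(test, cols)])
            accs.append(float(np.mean(pred == self.y[test])))
        return float(np.mean(accs))

    def evaluate_mask(self, mask: np.ndarray) -> float:
        acc = self.cv_accuracy(mask)
        n_sel = int(mask.sum())
        fit = subset_fitness(n_sel, acc, self.weights, self.n_features)
        if fit < self.best.fitness:
            self.best = SubsetRecord(fit, mask.copy(), acc, n_sel)
        return fit

    def _objective(self, x: np.ndarray, rng: Optional[np.random.Generator]) -> float:
        if rng is None:
            rng = np.random.default_rng(0)
        mask = binarize(x, rng, self.convention)
        return self.evaluate_mask(mask)

    def as_objective(self) -> ObjectiveSpec:
        return ObjectiveSpec(
            d=self.n_features,
            lower=np.zeros(self.n_features),
            upper=np.ones(self.n_features),
            func=self._objective,
            name="feature-selection",
        )


@dataclass
class FeatureSelectionReport:
    """Outcome of one feature-selection run."""

    mask: np.ndarray
    n_selected: int
    cv_accuracy: float
    fitness: float
    selected: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.selected is None:
            self.selected = np.flatnonzero(self.mask)


def run_feature_selection(problem: FeatureSelectionProblem, config, rng=None):
    """Run the hybrid over the continuous cube and report the best subset.

    Returns ``(RunResult, FeatureSelectionReport)``; the report carries the
    best mask ever evaluated, its size |R| and its average cross-validation
    accuracy.
    """
    from .hybrid import run_continuous  # local import to avoid a cycle

    problem.best = SubsetRecord()
    result = run_continuous(problem.as_objective(), config, rng)
    rec = problem.best
    report = FeatureSelectionReport(
        mask=rec.mask, n_selected=rec.n_selected, cv_accuracy=rec.accuracy, fitness=rec.fitness
    )
    return result, report
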