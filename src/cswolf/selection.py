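"""scikit-learn estimator facade for the wrapper feature selector."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .binary import FeatureSelectionProblem, FitnessWeights, run_feature_selection
from .hybrid import HybridConfig


class CuckooWolfSelector(SelectorMixin, BaseEstimator):
    """Wrapper feature selection by the adaptive cuckoo/grey-wolf hybrid.

    Searches the continuous cube [0, 1]^n_features with the hybrid
    metaheuristic; every fitness evaluation binarizes the candidate into a
    feature mask, cross-validates the wrapped classifier on the selected
    columns, and scores the subset with
    ``alpha_w * |R|/|N| - beta_w * accuracy`` (minimized).

    Parameters
    ----------
    estimator : sklearn classifier, default ``SVC(kernel="linear")``
        Cloned and refit on every CV fold of every candidate subset.
    n_agents : int, default 30
        Population size (host nests / wolves).
    fe_budget : int, default 10000
        Total number of subset fitness evaluations (the stopping rule).
    cv : int, default 10
        Stratified folds; the partition is frozen per fit so the fitness of
        a mask is deterministic.
    alpha_w, beta_w : float, defaults 0.2 / 0.8
        Subset-length and classification-quality weights.
    convention : {"as_printed", "standard"}
        Stochastic-threshold convention of the binarization layer.
    random_state : int or None
        Seed for the whole run (search moves, binarization and CV split).

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Best feature mask found.
    n_selected_ : int
        Number of selected features, |R|.
    cv_accuracy_ : float
        Average cross-validation accuracy of the best subset.
    best_fitness_ : float
        Fitness value of the best subset.
    run_result_ : RunResult
        Full convergence log of the underlying continuous run.

    Examples
    --------
    >>> sel = CuckooWolfSelector(fe_budget=600, cv=5, random_state=0)
    >>> Xt = sel.fit_transform(X, y)   # doctest: +SKIP
    """

    def __init__(
        self,
        estimator=None,
        n_agents: int = 30,
        fe_budget: int = 10000,
        cv: int = 10,
        alpha_w: float = 0.2,
        beta_w: float = 0.8,
        step_max: float = 1.0,
        a_o: float = 1.0,
        p_a: float = 0.25,
        convention: str = "as_printed",
        elitist_idgwo: bool = False,
        random_state=None,
    ):
        self.estimator = estimator
        self.n_agents = n_agents
        self.fe_budget = fe_budget
        self.cv = cv
        self.alpha_w = alpha_w
        self.beta_w = beta_w
        self.step_max = step_max
        self.a_o = a_o
        self.p_a = p_a
        self.convention = convention
        self.elitist_idgwo = elitist_idgwo
        self.random_state = random_state

    def _seed(self) -> int:
        if self.random_state is None:
            return int(np.random.default_rng().integers(2**31 - 1))
        if isinstance(self.random_state, numbers.Integral):
            return int(self.random_state)
        raise TypeError("random_state must be an int or None")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        seed = self._seed()
        problem = FeatureSelectionProblem(
            X,
            y,
            estimator=self.estimator,
            k=self.cv,
            cv_seed=seed,
            weights=FitnessWeights(self.alpha_w, self.beta_w),
            convention=self.convention,
        )
        config = HybridConfig(
            n=self.n_agents,
            fe_budget=self.fe_budget,
            seed=seed,
            elitist_idgwo=self.elitist_idgwo,
            step_max=self.step_max,
            a_o=self.a_o,
        )
        config.cuckoo.p_a = self.p_a
        result, report = run_feature_selection(problem, config)
        self.n_features_in_ = X.shape[1]
        self.support_ = report.mask.astype(bool)
        self.n_selected_ = report.n_selected
        self.cv_accuracy_ = report.cv_accuracy
        self.best_fitness_ = report.fitness
        self.run_result_ = result
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
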