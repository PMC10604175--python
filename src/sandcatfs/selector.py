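"""scikit-learn feature-selector estimators over the swarm engine.

`PilcBscsoSelector` and `BscsoSelector` follow the `SelectorMixin`
contract (fit on ``X, y``; ``transform`` keeps the selected columns;
``support_`` / ``get_support()`` expose the mask), so they drop into
Pipelines and model-selection utilities like any other sklearn
selector.  `DifferentialExpressionFilter` (in
:mod:`sandcatfs.prefilter`) is the matching univariate prefilter; the
canonical pipeline is

    make_pipeline(StandardScaler(), DifferentialExpressionFilter(),
                  PilcBscsoSelector(), SVC(kernel="linear"))
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .optimizer import OptimizerConfig, _optimize

__all__ = ["BscsoSelector", "PilcBscsoSelector"]


class _BaseSandCatSelector(SelectorMixin, BaseEstimator):
    """Shared fit machinery; subclasses fix the enhancement switch."""

    _enhance: bool = False

    def __init__(
        self,
        n_population: int = 100,
        n_iterations: int = 50,
        sm: float = 2.0,
        phase_test: str = "abs_unit",
        abs_distance: bool = True,
        pinhole_K: float = 0.05,
        enhance_prob: float = 0.5,
        n_folds: int = 10,
        n_repeats: int = 3,
        svm_cost: float = 1.0,
        random_state: int | None = None,
    ):
        self.n_population = n_population
        self.n_iterations = n_iterations
        self.sm = sm
        self.phase_test = phase_test
        self.abs_distance = abs_distance
        self.pinhole_K = pinhole_K
        self.enhance_prob = enhance_prob
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.svm_cost = svm_cost
        self.random_state = random_state

    def _config(self) -> OptimizerConfig:
        return OptimizerConfig(
            n_population=self.n_population,
            n_iterations=self.n_iterations,
            sm=self.sm,
            phase_test=self.phase_test,
            abs_distance=self.abs_distance,
            pinhole_K=self.pinhole_K,
            enhance_prob=self.enhance_prob,
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            svm_cost=self.svm_cost,
        )

    def fit(self, X, y):
        """Run the swarm search over the columns of ``X``.

        Sets ``support_`` (the selected-gene mask), ``run_record_``
        (full trace/bookkeeping), ``best_fitness_`` and ``trace_``.
        """
        X, y = check_X_y(X, y)
        if isinstance(self.random_state, numbers.Integral):
            seed = int(self.random_state)
        elif self.random_state is None:
            seed = int(np.random.default_rng().integers(2**31))
        else:
            raise ValueError("random_state must be an int or None")
        record = _optimize(X, y, self._config(), seed, enhance=self._enhance)
        self.run_record_ = record
        self.support_ = record.best_bits.astype(bool)
        self.best_fitness_ = record.best_fitness
        self.trace_ = record.kappa_trace
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class BscsoSelector(_BaseSandCatSelector):
    """Plain binary sand cat swarm wrapper feature selection.

    Candidate subsets are scored by mean Cohen's kappa of a
    linear-kernel SVM under repeated stratified k-fold CV; the swarm
    starts from the full feature set and searches by tansig-binarized
    exploitation/exploration moves.
    """

    _enhance = False


class PilcBscsoSelector(_BaseSandCatSelector):
    """Enhanced swarm selector with crossover and pinhole opposition.

    Adds per-individual archive-improvement attempts each iteration: a
    fair coin picks single-point crossover of the global best with the
    individual (offspring adopted only on strict improvement) or a
    pinhole-imaging opposition candidate, ``(NOT individual) AND best``
    (adopted into both the archive and the individual on strict
    improvement).  The opposition move can only shrink the best subset,
    pushing toward parsimonious gene panels.
    """

    _enhance = True
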