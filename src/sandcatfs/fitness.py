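"""Cross-validated SVM fitness for candidate gene subsets.

A candidate bit-vector is scored by training a linear-kernel SVM (cost
C = 1) on the selected genes under repeated stratified k-fold
cross-validation (default 10 folds x 3 repeats) and averaging Cohen's
kappa over all folds.  Kappa — chance-corrected agreement — is the
optimized objective because the benchmark class ratios are unbalanced;
plain fold accuracy is recorded alongside for reporting.

Fold assignment is frozen per evaluator instance, so every candidate in
one optimization run is scored on identical splits: fitness values are
comparable across the population and the whole run is deterministic
given the seed.  Results are memoized on the exact bit pattern, since a
converging swarm re-proposes the same subsets many times over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold
from sklearn.svm import SVC

__all__ = ["FitnessResult", "CVConfig", "FitnessEvaluator", "cohens_kappa"]


@dataclass(frozen=True)
class FitnessResult:
    """Mean CV kappa and accuracy plus selected-gene count for one subset."""

    kappa: float
    accuracy: float
    n_selected: int

    def better_than(self, other: "FitnessResult") -> bool:
        """Strict fitness order: higher kappa wins; exact kappa ties are
        broken in favour of fewer selected genes (parsimony)."""
        if self.kappa != other.kappa:
            return self.kappa > other.kappa
        return self.n_selected < other.n_selected


# all-zero subsets cannot train a classifier; they get the worst possible kappa
EMPTY_SUBSET_SENTINEL_KAPPA = -1.0


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and classifier settings for subset scoring."""

    n_folds: int = 10
    n_repeats: int = 3
    svm_cost: float = 1.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")


def cohens_kappa(y_true, y_pred) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement rate; ``p_e`` the agreement
    expected by chance from the row/column marginals.  When ``p_e`` is 1
    (both raters constant) kappa is 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    n = y_true.shape[0]
    if n == 0:
        raise ValueError("empty label sequences")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    p_o = float(np.mean(y_true == y_pred))
    p_e = 0.0
    for lab in labels:
        p_e += np.mean(y_true == lab) * np.mean(y_pred == lab)
    if p_e >= 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


class FitnessEvaluator:
    """Scores bit-vectors against one fixed (X, y, CV-split) context.

    Parameters
    ----------
    X : ndarray, samples x genes
        Expression values (assumed already on a comparable scale).
    y : ndarray
        Binary class labels.
    cfg : CVConfig
        Folds, repeats, SVM cost and the seed that freezes the splits.
    trainer : callable, optional
        ``trainer(X_train, y_train) -> fitted`` with a ``predict``
        method; lets unit tests stub out the SVM.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: CVConfig = CVConfig(),
                 trainer=None) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"two classes required, found {len(classes)}")
        if cfg.stratified and counts.min() < cfg.n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples; "
                f"stratified {cfg.n_folds}-fold CV needs at least {cfg.n_folds}"
            )
        self.X = X
        self.y = y
        self.cfg = cfg
        self._trainer = trainer or self._svm_trainer
        splitter_cls = RepeatedStratifiedKFold if cfg.stratified else RepeatedKFold
        splitter = splitter_cls(
            n_splits=cfg.n_folds, n_repeats=cfg.n_repeats, random_state=cfg.seed
        )
        # splits frozen once: every candidate scored on identical folds
        self._splits = [(tr.copy(), te.copy()) for tr, te in splitter.split(X, y)]
        self._cache: dict[bytes, FitnessResult] = {}
        self.n_trainings = 0
        self.n_queries = 0

    def _svm_trainer(self, X_train: np.ndarray, y_train: np.ndarray):
        clf = SVC(kernel="linear", C=self.cfg.svm_cost)
        clf.fit(X_train, y_train)
        return clf

    def lookup(self, bits: np.ndarray) -> FitnessResult | None:
        """Memoized result for an identical bit pattern, or None on miss."""
        return self._cache.get(np.asarray(bits, dtype=np.int8).tobytes())

    def evaluate(self, bits: np.ndarray) -> FitnessResult:
        """Mean CV kappa/accuracy for the genes selected by ``bits``."""
        bits = np.asarray(bits, dtype=np.int8)
        if bits.shape[0] != self.X.shape[1]:
            raise ValueError(
                f"bit-vector length {bits.shape[0]} != gene count {self.X.shape[1]}"
            )
        self.n_queries += 1
        key = bits.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n_selected = int(bits.sum())
        if n_selected == 0:
            result = FitnessResult(EMPTY_SUBSET_SENTINEL_KAPPA, 0.0, 0)
        else:
            cols = np.flatnonzero(bits)
            Xs = self.X[:, cols]
            kappas, accs = [], []
            for tr, te in self._splits:
                clf = self._trainer(Xs[tr], self.y[tr])
                pred = clf.predict(Xs[te])
                kappas.append(cohens_kappa(self.y[te], pred))
                accs.append(float(np.mean(pred == self.y[te])))
            self.n_trainings += len(self._splits)
            result = FitnessResult(float(np.mean(kappas)), float(np.mean(accs)), n_selected)
        self._cache[key] = result
        return result
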