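"""Synthetic two-class expression matrices with a planted signal.

Emulates the structure of the small two-class microarray benchmarks this
kind of gene selector is evaluated on: a few dozen samples, hundreds to
thousands of genes, unbalanced classes, and a small set of truly
differential genes carrying an additive mean-shift on top of Gaussian
noise.  The signal is additive (not multiplicative) because downstream
stages assume roughly log-scale intensities, where group differences are
shifts.  Correlation structure, batch effects and count noise are
deliberately absent — recovery here demonstrates the optimizer, not
robustness to real-data pathologies.

The default spec (60 samples, 500 genes, 10 informative, effect size 2
standard deviations, 65/35 class balance) echoes the ~62-sample, 40/22
colon-cancer benchmark shape at a desk-scale gene count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabeledExpression

__all__ = ["SyntheticSpec", "SyntheticTruth", "make_synthetic_expression", "recovery_metrics"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for a planted-signal expression matrix."""

    n_samples: int = 60
    n_genes: int = 500
    n_informative: int = 10
    effect_size: float = 2.0  # between-class mean shift, in noise-sd units
    class_balance: float = 0.65  # proportion of samples in the positive class
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_pos = round(self.n_samples * self.class_balance)
        if min(n_pos, self.n_samples - n_pos) < 2:
            raise ValueError(
                f"infeasible spec: a class would have fewer than 2 samples "
                f"({n_pos} vs {self.n_samples - n_pos})"
            )


@dataclass
class SyntheticTruth:
    """Generated matrix plus the ground-truth planted gene positions."""

    planted_indices: np.ndarray
    matrix: LabeledExpression
    spec: SyntheticSpec = field(repr=False, default=None)


def make_synthetic_expression(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticTruth:
    """Generate a labeled matrix with ``n_informative`` shifted genes.

    All genes are Gaussian with standard deviation ``noise_sd``; planted
    genes additionally carry a ``effect_size * noise_sd`` mean shift in
    the positive class.  Class counts follow ``class_balance`` rounding
    exactly; planted positions are drawn uniformly without replacement.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = round(spec.n_samples * spec.class_balance)
    labels = np.array(["neg"] * (spec.n_samples - n_pos) + ["pos"] * n_pos)
    rng.shuffle(labels)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    planted = np.sort(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    shift = spec.effect_size * spec.noise_sd
    X[np.ix_(labels == "pos", planted)] += shift
    matrix = LabeledExpression(
        values=X,
        sample_ids=[f"s{i}" for i in range(spec.n_samples)],
        gene_ids=[f"g{j}" for j in range(spec.n_genes)],
        labels=labels.tolist(),
    )
    return SyntheticTruth(planted_indices=planted, matrix=matrix, spec=spec)


def recovery_metrics(selected, truth: SyntheticTruth) -> tuple[float, float]:
    """Recall and precision of a selected gene set against the planted set.

    Empty selections have precision 0 by convention.
    """
    selected = {int(i) for i in selected}
    planted = set(truth.planted_indices.tolist())
    hit = len(selected & planted)
    recall = hit / len(planted) if planted else 0.0
    precision = hit / len(selected) if selected else 0.0
    return recall, precision
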