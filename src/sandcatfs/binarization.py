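"""Transfer-function binarization of continuous position updates.

A continuous sand cat update is mapped to a feature-inclusion bit through
the hyperbolic tangent sigmoid ("tansig") transfer function

    Tf(v) = 2 / (1 + exp(-2 v)) - 1  ==  tanh(v)

followed by a stochastic threshold against a fresh uniform draw: the bit
is 1 iff ``Tf(v) > u``.  Because Tf is negative for negative v and a
uniform draw is never negative, non-positive positions always binarize to
0 — the scheme is deliberately asymmetric (an S-shaped family member, not
a V-shaped one).

Bits are the persistent state: the continuous value is transient within a
single position update and is never carried across iterations.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["transfer_tansig", "binarize"]


def transfer_tansig(v: float) -> float:
    """Tansig transfer value ``2 / (1 + e^(-2v)) - 1``, in (-1, 1).

    Algebraically identical to ``tanh(v)``; computed through ``tanh`` for
    numerical stability at large ``|v|`` (the rational form overflows
    ``exp`` near v = -355 while tanh saturates cleanly).
    """
    if not math.isfinite(v):
        raise ValueError(f"transfer input must be finite, got {v}")
    return math.tanh(v)


def binarize(tf: float, u: float) -> int:
    """Stochastic threshold: 1 iff ``tf > u`` (strict), else 0."""
    return 1 if tf > u else 0


def binarize_positions(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized tansig + threshold over a 1-D array of positions.

    One fresh uniform draw per dimension.  Returns an int8 bit array.
    """
    tf = np.tanh(values)
    u = rng.uniform(0.0, 1.0, size=values.shape)
    return (tf > u).astype(np.int8)
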