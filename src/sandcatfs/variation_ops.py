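"""Variation operators fused into the binary sand cat swarm.

Two enhancement operators act on the elitist archive each iteration:

* **Single-point crossover** between the global best and a population
  row: bits after a uniformly drawn cut point are swapped between the two
  parents, producing two offspring that conserve the per-position
  multiset of parental bits.

* **Pinhole-imaging opposition-based learning (PIOBL)**: the pinhole
  camera construction places the "inverse image" of a solution ``x`` at

      x* = (a + b)/2 + (a + b)/(2K) - x/K

  with per-dimension bounds ``a, b`` and scale factor ``K`` (default
  0.05, the ratio of object to image height).  In binary space
  (``a=0, b=1, K=0.05``) the reverse of a bit is 10.5 or -9.5, so after
  thresholding at 0.5 the reverse is exactly the bitwise complement; the
  PIOBL candidate is that complement ANDed with the current best, and is
  therefore always a subset of the best — opposition can only shrink or
  preserve the selected-gene count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PinholeParams",
    "single_point_crossover",
    "pinhole_reverse",
    "piobl_candidate",
]


@dataclass(frozen=True)
class PinholeParams:
    """Pinhole-imaging geometry: scale factor and per-dimension bounds.

    ``binarize_threshold`` converts the continuous reverse value back to
    a bit (value >= threshold -> 1); at the binary defaults this makes
    the reverse the logical complement.
    """

    K: float = 0.05
    a: float = 0.0
    b: float = 1.0
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.K == 0:
            raise ValueError("scale factor K must be non-zero")
        if self.K < 0:
            raise ValueError("scale factor K must be positive")
        if not self.a < self.b:
            raise ValueError(f"bounds require a < b, got a={self.a}, b={self.b}")


def single_point_crossover(
    p1: np.ndarray, p2: np.ndarray, cut: int
) -> tuple[np.ndarray, np.ndarray]:
    """Swap all bits strictly after ``cut`` between two parents.

    ``cut`` is 1-based from the left: offspring ``q1`` takes the first
    ``cut`` bits of ``p1`` and the remainder of ``p2``; ``q2`` is the
    mirror.  Valid cuts are ``1 .. D-1`` so both segments are non-empty.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError(f"parents must be 1-D of equal length, got {p1.shape} and {p2.shape}")
    d = p1.shape[0]
    if d < 2:
        raise ValueError("crossover needs at least 2 positions")
    if not 1 <= cut <= d - 1:
        raise ValueError(f"cut point {cut} outside valid range [1, {d - 1}]")
    q1 = np.concatenate([p1[:cut], p2[cut:]])
    q2 = np.concatenate([p2[:cut], p1[cut:]])
    return q1, q2


def pinhole_reverse(x: float, params: PinholeParams = PinholeParams()) -> float:
    """Continuous pinhole-imaging inverse: ``(a+b)/2 + (a+b)/(2K) - x/K``."""
    mid = (params.a + params.b) / 2.0
    return mid + mid / params.K - x / params.K


def piobl_candidate(
    x: np.ndarray,
    xbest: np.ndarray,
    params: PinholeParams = PinholeParams(),
) -> np.ndarray:
    """PIOBL candidate: binarized pinhole reverse of ``x``, ANDed with ``xbest``.

    With binary bounds and K = 0.05 this equals ``(NOT x) AND xbest``.
    The output is always a subset of ``xbest``.
    """
    x = np.asarray(x)
    xbest = np.asarray(xbest)
    if x.shape != xbest.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xbest.shape}")
    rev = (params.a + params.b) / 2.0 * (1.0 + 1.0 / params.K) - x / params.K
    rev_bits = (rev >= params.binarize_threshold).astype(np.int8)
    return (rev_bits & xbest.astype(np.int8)).astype(np.int8)
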