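"""Gaussian kernels and Gram matrices.

The estimator uses two scalar kernels: a time kernel ``l`` on the positive
half-line and a covariate kernel ``k`` on the covariate space.  Both are
Gaussian, ``k(u, v) = exp(-||u - v||^2 / (2 sigma^2))``, which is bounded,
has unit diagonal, and generates a dense RKHS.  The operator-valued kernel
``Gamma(x, x') = k(x, x') Id`` used by the vector-valued regression never
materializes beyond the scalar Gram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel with length-scale ``bandwidth`` (sigma)."""

    bandwidth: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported kernel family: {self.family!r}")
        if not (np.isfinite(self.bandwidth) and self.bandwidth > 0):
            raise ValueError("kernel bandwidth must be a positive real")


def _as_points(points) -> np.ndarray:
    a = np.asarray(points, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("points must be a vector or an (n, p) matrix")
    return a


def gram(points_a, points_b, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``G[i, j] = k(a_i, b_j)`` for the Gaussian kernel."""
    a, b = _as_points(points_a), _as_points(points_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have {a.shape[1]} and {b.shape[1]} coordinates"
        )
    sq = cdist(a, b, "sqeuclidean")
    return np.exp(-sq / (2.0 * spec.bandwidth**2))


def median_heuristic(points) -> float:
    """Median of pairwise Euclidean distances over distinct pairs.

    The standard default bandwidth for kernel mean-embedding methods; raises
    if all points coincide (the bandwidth would be undefined).
    """
    a = _as_points(points)
    if a.shape[0] < 2:
        raise ValueError("median heuristic needs at least two points")
    d = pdist(a)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all points identical: median-heuristic bandwidth undefined")
    return float(np.median(d))
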