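"""Generalised coordinates of motion.

A trajectory is represented instantaneously by its value and temporal
derivatives up to an embedding order ``n``: the generalised vector
``u_tilde = (u, u', u'', ...)``.  Two pieces of algebra recur throughout
generalised filtering schemes and are provided here:

* the block derivative-shift operator ``D`` that maps each derivative
  block onto the slot below it (``D u_tilde = (u', u'', ..., 0)``), and
* the covariance (and precision) among derivative orders of a
  unit-variance stationary process with Gaussian autocorrelation
  ``rho(tau) = exp(-gamma * tau**2 / 2)``, which closes the precision
  algebra for smooth (analytic) random fluctuations.

Derivative blocks are stored lowest order first and all flattening is
block-contiguous by derivative order, so the shift operator is a fixed
block-superdiagonal matrix and full generalised precisions factor as
``kron(temporal_precision, spatial_precision)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneralisedVector",
    "TemporalPrecision",
    "shift_operator",
    "generalised_covariance",
]


@dataclass
class GeneralisedVector:
    """A state and its temporal derivatives to embedding order ``n``.

    ``block[k]`` holds the k-th temporal derivative; all blocks share the
    same dimension ``d``.
    """

    block: np.ndarray  # shape (n, d), order-major

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.block, dtype=float))
        if arr.ndim != 2:
            raise ValueError("block must be a 2-D (orders x dim) array")
        self.block = arr

    @property
    def orders(self) -> int:
        return self.block.shape[0]

    @property
    def dim(self) -> int:
        return self.block.shape[1]

    def flatten(self) -> np.ndarray:
        """Flatten block-contiguously by derivative order (length n*d)."""
        return self.block.reshape(-1).copy()

    @classmethod
    def from_flat(cls, flat: np.ndarray, orders: int, dim: int) -> "GeneralisedVector":
        flat = np.asarray(flat, dtype=float)
        if flat.size != orders * dim:
            raise ValueError(
                f"flat length {flat.size} incompatible with {orders} orders x dim {dim}"
            )
        return cls(flat.reshape(orders, dim))

    def shifted(self) -> "GeneralisedVector":
        """Apply the derivative shift: (u, u', ..., u^(n-1)) -> (u', ..., 0)."""
        out = np.zeros_like(self.block)
        out[:-1] = self.block[1:]
        return GeneralisedVector(out)


def shift_operator(n: int, d: int) -> np.ndarray:
    """Block-superdiagonal derivative shift operator of size (n*d, n*d).

    Maps derivative block k+1 into slot k and zero into the top slot; it
    is nilpotent of index n.
    """
    if n < 1 or d < 1:
        raise ValueError(f"embedding order and dimension must be >= 1, got n={n}, d={d}")
    D = np.zeros((n * d, n * d))
    for k in range(n - 1):
        D[k * d : (k + 1) * d, (k + 1) * d : (k + 2) * d] = np.eye(d)
    return D


def _doublefactorial(m: int) -> int:
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


@dataclass
class TemporalPrecision:
    """Precision among derivative orders of smooth Gaussian fluctuations.

    ``roughness`` is gamma, the variance of the first derivative of a
    unit-variance process with autocorrelation ``exp(-gamma tau^2 / 2)``;
    large gamma means rough (fast-decorrelating) noise.
    """

    roughness: float
    n: int
    covariance: np.ndarray = field(repr=False)
    matrix: np.ndarray = field(repr=False)  # the precision (inverse covariance)


def generalised_covariance(gamma: float, n: int) -> TemporalPrecision:
    """Covariance/precision among derivatives 0..n-1 of smooth unit noise.

    For autocorrelation ``rho(tau) = exp(-gamma tau^2/2)`` the stationary
    cross-moments are ``E[z^(i) z^(j)] = (-1)^i rho^(i+j)(0)`` with
    ``rho^(2m)(0) = (-gamma)^m (2m-1)!!`` and odd derivatives vanishing,
    e.g. Var(z') = -rho''(0) = gamma and rho''''(0) = 3 gamma^2.
    """
    if gamma <= 0:
        raise ValueError(f"roughness gamma must be positive, got {gamma}")
    if n < 1:
        raise ValueError(f"embedding order must be >= 1, got {n}")
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = i + j
            if s % 2:
                continue
            m = s // 2
            C[i, j] = (-1.0) ** i * (-gamma) ** m * _doublefactorial(s - 1)
    P = np.linalg.inv(C)
    P = 0.5 * (P + P.T)  # enforce exact symmetry
    return TemporalPrecision(roughness=float(gamma), n=int(n), covariance=C, matrix=P)
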