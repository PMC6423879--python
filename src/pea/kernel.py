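"""Garrote kernel for gene-pathway interaction testing.

The kernel between individuals k and l combines the pathway expression
profile ``P`` (N x v, one row per individual) with the expression ``G`` of a
single external gene through a scalar garrote parameter ``delta``::

    K(delta)_{kl} = (1 + delta * G_k * G_l) * (1 + <P_k, P_l>)

``delta = 0`` removes every contribution of the external gene, so the
interaction null hypothesis is H0: delta = 0.  K(delta) is affine in delta:
``K(delta) = K0 + delta * dK`` with ``K0 = 1*1' + P P'`` (the null pathway
kernel) and ``dK = (G G') ∘ (1*1' + P P')`` (elementwise product), which is
all the score test needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .errors import InputError

__all__ = [
    "garrote_kernel",
    "pathway_kernel",
    "kernel_derivative_at_null",
    "GarroteKernelParts",
]


def _validate(G: NDArray, P: NDArray) -> tuple[NDArray, NDArray]:
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    if G.ndim != 1:
        raise InputError(f"external gene vector must be 1-D, got shape {G.shape}")
    if P.ndim != 2:
        raise InputError(f"pathway matrix must be 2-D (individuals x genes), got shape {P.shape}")
    if P.shape[0] != G.shape[0]:
        raise InputError(
            f"dimension mismatch: gene vector has {G.shape[0]} individuals, "
            f"pathway matrix has {P.shape[0]} rows"
        )
    if not np.all(np.isfinite(G)) or not np.all(np.isfinite(P)):
        raise InputError("non-finite values in expression input")
    return G, P


def pathway_kernel(P: NDArray) -> NDArray:
    """Null kernel K(0) = 1*1' + P P' from pathway expression alone."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise InputError(f"pathway matrix must be 2-D, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise InputError("non-finite values in pathway matrix")
    return 1.0 + P @ P.T


def garrote_kernel(G: NDArray, P: NDArray, delta: float) -> NDArray:
    """Evaluate the garrote kernel matrix K(delta), entrywise
    ``(1 + delta G_k G_l)(1 + <P_k, P_l>)``."""
    G, P = _validate(G, P)
    if not np.isfinite(delta):
        raise InputError("delta must be finite")
    return (1.0 + delta * np.outer(G, G)) * (1.0 + P @ P.T)


def kernel_derivative_at_null(G: NDArray, P: NDArray) -> NDArray:
    """dK/d(delta) at delta = 0: entrywise ``G_k G_l (1 + <P_k, P_l>)``.

    Because K is affine in delta this equals K(1) - K(0) and is the kernel
    building block of the variance-component score statistic
    (dV/d(delta) = tau * dK).
    """
    G, P = _validate(G, P)
    return np.outer(G, G) * (1.0 + P @ P.T)


@dataclass(frozen=True)
class GarroteKernelParts:
    """The two N x N blocks of the affine decomposition K(delta) = K0 + delta*dK."""

    K0: NDArray
    dK: NDArray

    @classmethod
    def from_data(cls, G: NDArray, P: NDArray) -> "GarroteKernelParts":
        G, P = _validate(G, P)
        M = 1.0 + P @ P.T
        return cls(K0=M, dK=np.outer(G, G) * M)

    def at(self, delta: float) -> NDArray:
        return self.K0 + delta * self.dK
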