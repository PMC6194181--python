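"""Mixture algebra combining honest and fake joint distributions.

The fake joint distribution Z marginalizes the replacement kernels over
the honest pmf P under conditional independence of the two variables'
faking processes; the observed population is a two-component mixture
S = (1 - alpha) P + alpha Z with faker proportion alpha, generalized to
several faker classes with proportions alpha_l summing to at most 1.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .errors import InvalidParameterError
from .honest_model import JointPMF
from .replacement import ReplacementKernel

__all__ = [
    "fake_joint",
    "fake_joint_brute",
    "mixture_joint",
    "mixture_joint_vectorized",
    "multiclass_mixture",
]


def fake_joint(P: JointPMF, Z1: ReplacementKernel,
               Z2: ReplacementKernel) -> JointPMF:
    """Joint pmf of the fully-faked population.

    z_hk = sum_ij p_ij z_{h|i} z_{k|j}, computed in matrix form as
    K1 @ P @ K2' with K1, K2 the column-stochastic kernel grids.
    """
    if not (P.v == Z1.v == Z2.v):
        raise InvalidParameterError(
            f"dimension mismatch: pmf v={P.v}, kernels v={Z1.v}, {Z2.v}")
    return JointPMF(Z1.z @ P.p @ Z2.z.T)


def fake_joint_brute(P: JointPMF, Z1: ReplacementKernel,
                     Z2: ReplacementKernel) -> np.ndarray:
    """Reference double-sum evaluation of the fake joint distribution.

    Kept as the independent check of the matrix form; quadratic in the
    number of cells and only used in tests and self-checks.
    """
    v = P.v
    out = np.zeros((v, v))
    for h in range(v):
        for k in range(v):
            acc = 0.0
            for i in range(v):
                for j in range(v):
                    acc += P.p[i, j] * Z1.z[h, i] * Z2.z[k, j]
            out[h, k] = acc
    return out


def mixture_joint(P: JointPMF, Z: JointPMF, alpha: float) -> JointPMF:
    """Observed-population pmf: convex combination of honest and fake pmfs."""
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(
            f"faker proportion must lie in [0, 1], got {alpha}")
    if P.v != Z.v:
        raise InvalidParameterError("honest and fake pmfs must share the support")
    return JointPMF((1.0 - alpha) * P.p + alpha * Z.p)


def mixture_joint_vectorized(P: JointPMF, Z1: ReplacementKernel,
                             Z2: ReplacementKernel, alpha: float) -> JointPMF:
    """Kronecker-vectorized form of the mixture pmf.

    vec(S) = (1 - alpha) vec(P) + alpha (K2 kron K1) vec(P), with
    column-stacking vectorization.  Algebraically identical to
    ``mixture_joint(P, fake_joint(P, Z1, Z2), alpha)``; exposed so the
    two routes can be cross-checked.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(
            f"faker proportion must lie in [0, 1], got {alpha}")
    vec_p = P.p.flatten(order="F")
    vec_s = (1.0 - alpha) * vec_p + alpha * (np.kron(Z2.z, Z1.z) @ vec_p)
    return JointPMF(vec_s.reshape(P.v, P.v, order="F"))


def multiclass_mixture(P: JointPMF,
                       kernels: Sequence[tuple[ReplacementKernel,
                                               ReplacementKernel]],
                       alphas: Sequence[float]) -> JointPMF:
    """Mixture with several faker classes.

    Each class l has its own kernel pair and proportion alpha_l; the
    honest component receives the remaining weight 1 - sum(alpha_l).
    With a single class this reduces exactly to :func:`mixture_joint`.
    """
    alphas = np.asarray(alphas, dtype=float)
    if len(kernels) != alphas.size:
        raise InvalidParameterError("one kernel pair per faker class required")
    if np.any(alphas < 0) or np.any(alphas > 1):
        raise InvalidParameterError("class proportions must lie in [0, 1]")
    total = alphas.sum()
    if total > 1.0 + 1e-12:
        raise InvalidParameterError(
            f"class proportions must sum to at most 1, got {total}")
    s = (1.0 - total) * P.p
    for (Z1, Z2), a in zip(kernels, alphas):
        s = s + a * fake_joint(P, Z1, Z2).p
    return JointPMF(s)
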