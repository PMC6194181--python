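"""Fisher z transform and Cohen's Q effect size between two correlations.

Q = z(rho_m) - z(rho_d) measures how far a perturbed (mixture)
correlation rho_m has moved from the uncorrupted correlation rho_d on
the variance-stabilized Fisher scale; the sample analogue q applies the
same formula to sample estimates.  |rho| = 1 maps to an infinite z,
which is propagated (not raised) so that robust, median-based summaries
downstream remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "cohen_q",
    "rho_m_from_q",
    "sample_q",
    "EffectSizeRecord",
]


def fisher_z(rho):
    """Fisher z transform, 0.5 * log((1 + rho) / (1 - rho)).

    Accepts scalars or arrays in [-1, 1]; the endpoints map to +/-inf.
    """
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise InvalidParameterError("correlations must lie in [-1, 1]")
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    return z if z.ndim else float(z)


def inverse_fisher_z(z):
    """Inverse of the Fisher transform (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def cohen_q(rho_m, rho_d):
    """Cohen's Q: difference of Fisher transforms, z(rho_m) - z(rho_d)."""
    return fisher_z(rho_m) - fisher_z(rho_d)


def sample_q(r_m, r_d):
    """Sample effect size q on sample correlations (same formula as Q)."""
    return cohen_q(r_m, r_d)


def rho_m_from_q(rho_d, q):
    """Perturbed correlation implied by an uncorrupted correlation and a Q.

    Inverts the Fisher-transform difference; the sign of the resulting
    differential correlation rho_m - rho_d matches the sign of q.
    """
    r = np.asarray(rho_d, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise InvalidParameterError("rho_d must lie strictly inside (-1, 1)")
    return inverse_fisher_z(fisher_z(rho_d) + np.asarray(q, dtype=float))


@dataclass(frozen=True)
class EffectSizeRecord:
    """One population-level effect-size evaluation with its context.

    ``rho_d``/``rho_m`` are the correlations of the honest and mixture
    pmfs under the chosen index; ``rho_latent`` is the latent normal
    correlation that generated the honest pmf (reported for
    transparency — Q is defined on the discrete correlations, so that
    Q = 0 exactly when alpha = 0).
    """

    index: str           # "pearson" | "spearman"
    v: int
    rho_latent: float
    alpha: float
    model_x: str
    model_y: str
    direction: str       # "same" | "opposite"
    rho_d: float
    rho_m: float
    q: float
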