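"""Pearson and Spearman correlations for ordinal variables on a finite
support, at the population level (from a joint pmf) and at the sample
level (from observed pairs).

The population Spearman uses the ties-corrected form for discrete
variables (Neslehova): with cumulative marginals F, G,

    rho_S = 3 sum_ij p_ij [(F_i + F_{i-1})(G_j + G_{j-1}) - 1]
            / sqrt((1 - sum_i p_i.^3)(1 - sum_j p_.j^3)),

whose sample version (plug in the contingency-table frequencies)
coincides with the ordinary mid-rank sample formula.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DegenerateDistributionError, DegenerateSampleError, InvalidParameterError
from .honest_model import BivariateSample, JointPMF

__all__ = [
    "pearson_pop",
    "spearman_pop",
    "pearson_sample",
    "spearman_sample",
]


def pearson_pop(P: JointPMF) -> float:
    """Population product-moment correlation of the integer-coded support."""
    s = P.support.astype(float)
    px, py = P.marginal_x(), P.marginal_y()
    mx, my = s @ px, s @ py
    vx = s ** 2 @ px - mx ** 2
    vy = s ** 2 @ py - my ** 2
    if vx <= 1e-15 or vy <= 1e-15:
        raise DegenerateDistributionError(
            "a marginal has zero variance; Pearson correlation undefined")
    exy = s @ P.p @ s
    return float((exy - mx * my) / np.sqrt(vx * vy))


def spearman_pop(P: JointPMF) -> float:
    """Ties-corrected population Spearman correlation of a discrete pmf."""
    px, py = P.marginal_x(), P.marginal_y()
    den = (1.0 - np.sum(px ** 3)) * (1.0 - np.sum(py ** 3))
    if den <= 1e-15:
        raise DegenerateDistributionError(
            "a marginal is a point mass; Spearman correlation undefined")
    F = np.concatenate([[0.0], np.cumsum(px)])
    G = np.concatenate([[0.0], np.cumsum(py)])
    a = F[1:] + F[:-1]   # F_i + F_{i-1}
    b = G[1:] + G[:-1]
    num = 3.0 * float(a @ P.p @ b - 1.0)
    return num / np.sqrt(den)


def _check_sample(sample: BivariateSample) -> None:
    if sample.n < 2:
        raise InvalidParameterError("need at least two observations")
    if np.all(sample.x == sample.x[0]) or np.all(sample.y == sample.y[0]):
        raise DegenerateSampleError(
            "a column is constant; sample correlation undefined")


def pearson_sample(sample: BivariateSample) -> float:
    """Sample product-moment correlation of the integer-coded responses."""
    _check_sample(sample)
    return float(np.corrcoef(sample.x, sample.y)[0, 1])


def spearman_sample(sample: BivariateSample) -> float:
    """Sample Spearman correlation: Pearson on mid-ranks (average ranks)."""
    _check_sample(sample)
    rx = stats.rankdata(sample.x, method="average")
    ry = stats.rankdata(sample.y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])
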