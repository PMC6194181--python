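"""Honest (uncorrupted) response model.

Two ordinal variables on a common support {1, ..., v} are generated with
the underlying variable approach (UVA): a standardized bivariate normal
pair (W1, W2) with latent correlation ``rho_latent`` is discretized by a
set of ordered thresholds, one threshold set per variable.  The cell
probability of the resulting joint pmf is the rectangle probability of
the bivariate normal between consecutive thresholds.

The module provides the analytic joint pmf (used by the population-level
analysis) and an i.i.d. sampler (used by the Monte Carlo engine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

__all__ = [
    "ThresholdSet",
    "JointPMF",
    "BivariateSample",
    "default_marginals",
    "thresholds_from_marginals",
    "honest_joint_pmf",
    "sample_honest",
]

_MASS_TOL = 1e-8


def default_marginals(v: int) -> np.ndarray:
    """Default symmetric marginal mass probabilities for a given support size.

    ``v = 5`` uses the masses (0.06, 0.25, 0.38, 0.25, 0.06); ``v = 2``
    splits the mass evenly (threshold at 0); ``v = 7`` discretizes the
    standard normal at the equispaced symmetric thresholds
    (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5).  Other supports use equal-mass
    (quantile) categories, again symmetric around zero.
    """
    if v < 2:
        raise InvalidParameterError(f"support size must be >= 2, got {v}")
    if v == 2:
        return np.array([0.5, 0.5])
    if v == 5:
        return np.array([0.06, 0.25, 0.38, 0.25, 0.06])
    if v == 7:
        edges = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        cdf = np.concatenate([[0.0], stats.norm.cdf(edges), [1.0]])
        return np.diff(cdf)
    return np.full(v, 1.0 / v)


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered cut-points discretizing a standard normal latent variable.

    ``xi`` holds the v-1 finite thresholds xi_1 < ... < xi_{v-1}; the
    outer thresholds -inf and +inf are implicit.
    """

    xi: np.ndarray

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi, dtype=float)
        if xi.ndim != 1 or xi.size < 1:
            raise InvalidParameterError("need at least one threshold")
        if not np.all(np.isfinite(xi)):
            raise InvalidParameterError("thresholds must be finite")
        if not np.all(np.diff(xi) > 0):
            raise InvalidParameterError("thresholds must be strictly increasing")
        object.__setattr__(self, "xi", xi)

    @property
    def v(self) -> int:
        return self.xi.size + 1

    @property
    def edges(self) -> np.ndarray:
        """Thresholds padded with the implicit infinite endpoints."""
        return np.concatenate([[-np.inf], self.xi, [np.inf]])

    def marginals(self) -> np.ndarray:
        """Category masses induced on a standard normal latent variable."""
        return np.diff(stats.norm.cdf(self.edges))

    def discretize(self, w: np.ndarray) -> np.ndarray:
        """Map latent values to categories 1..v."""
        return np.searchsorted(self.xi, w, side="left") + 1


def thresholds_from_marginals(target_marginals) -> ThresholdSet:
    """Invert the normal discretization: thresholds whose standard-normal
    category masses equal ``target_marginals``.

    Parameters
    ----------
    target_marginals : array-like
        Positive masses summing to 1, one per category.
    """
    m = np.asarray(target_marginals, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise InvalidParameterError("need at least two categories")
    if np.any(m <= 0):
        raise InvalidParameterError("marginal masses must be strictly positive")
    if abs(m.sum() - 1.0) > _MASS_TOL:
        raise InvalidParameterError(f"marginal masses must sum to 1, got {m.sum()}")
    cum = np.cumsum(m / m.sum())[:-1]
    return ThresholdSet(stats.norm.ppf(cum))


@dataclass(frozen=True)
class JointPMF:
    """Joint pmf of two ordinal variables on the common support {1..v}.

    The grid ``p`` has p[i-1, j-1] = P(X = i, Y = j).  Construction
    validates non-negativity and unit mass (within 1e-8) and then
    renormalizes exactly, so downstream algebra can rely on total mass 1.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
            raise InvalidParameterError("joint pmf must be a square grid, v >= 2")
        if np.any(p < -1e-12):
            raise InvalidParameterError("joint pmf entries must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > _MASS_TOL:
            raise InvalidParameterError(f"joint pmf mass must be 1, got {total}")
        p = np.clip(p, 0.0, None)
        object.__setattr__(self, "p", p / p.sum())

    @property
    def v(self) -> int:
        return self.p.shape[0]

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, self.v + 1)

    def marginal_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    def cum_x(self) -> np.ndarray:
        """F_i = P(X <= i)."""
        return np.cumsum(self.marginal_x())

    def cum_y(self) -> np.ndarray:
        return np.cumsum(self.marginal_y())

    def as_dataframe(self) -> pd.DataFrame:
        s = self.support
        return pd.DataFrame(self.p, index=pd.Index(s, name="x"),
                            columns=pd.Index(s, name="y"))

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path)


@dataclass(frozen=True)
class BivariateSample:
    """n observed pairs of integer responses on the support {1..v}."""

    data: np.ndarray  # shape (n, 2), integer categories
    v: int

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2 or data.shape[1] != 2:
            raise InvalidParameterError("sample must be an (n, 2) array")
        if not np.issubdtype(data.dtype, np.integer):
            if np.any(data != np.round(data)):
                raise InvalidParameterError("sample values must be integers")
            data = data.astype(np.int64)
        if self.v < 2:
            raise InvalidParameterError("support size must be >= 2")
        if data.size and (data.min() < 1 or data.max() > self.v):
            raise InvalidParameterError(
                f"sample values must lie in 1..{self.v}")
        object.__setattr__(self, "data", data)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 1]

    def empirical_pmf(self) -> JointPMF:
        """Relative-frequency contingency table as a JointPMF."""
        grid = np.zeros((self.v, self.v))
        np.add.at(grid, (self.x - 1, self.y - 1), 1.0)
        return JointPMF(grid / self.n)


def _bvn_cdf_grid(edges_x: np.ndarray, edges_y: np.ndarray,
                  rho: float) -> np.ndarray:
    """Bivariate standard normal CDF on the grid of threshold corners.

    Infinite corners are resolved analytically (0 on the -inf faces, the
    univariate CDF on the +inf faces) so the numerical routine only sees
    finite points.
    """
    nx, ny = edges_x.size, edges_y.size
    H = np.zeros((nx, ny))
    H[-1, :] = stats.norm.cdf(edges_y)
    H[:, -1] = stats.norm.cdf(edges_x)
    H[-1, -1] = 1.0
    fin_x = edges_x[1:-1]
    fin_y = edges_y[1:-1]
    if fin_x.size and fin_y.size:
        pts = np.column_stack([
            np.repeat(fin_x, fin_y.size),
            np.tile(fin_y, fin_x.size),
        ])
        mvn = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        H[1:-1, 1:-1] = mvn.cdf(pts).reshape(fin_x.size, fin_y.size)
    return H


def honest_joint_pmf(thresholds: ThresholdSet, rho_latent: float,
                     thresholds_y: ThresholdSet | None = None) -> JointPMF:
    """Joint pmf of the discretized bivariate normal (the UVA model).

    Each cell is the rectangle probability of the standardized bivariate
    normal with correlation ``rho_latent`` between consecutive
    thresholds, computed by inclusion-exclusion on four CDF evaluations.
    By default the two variables share one threshold set.
    """
    if not -1.0 < rho_latent < 1.0:
        raise InvalidParameterError(
            f"latent correlation must lie in (-1, 1), got {rho_latent}")
    ty = thresholds if thresholds_y is None else thresholds_y
    if ty.v != thresholds.v:
        raise InvalidParameterError("both variables must share the support size")
    H = _bvn_cdf_grid(thresholds.edges, ty.edges, rho_latent)
    p = np.diff(np.diff(H, axis=0), axis=1)
    return JointPMF(p)


def sample_honest(n: int, thresholds: ThresholdSet, rho_latent: float,
                  seed=None, thresholds_y: ThresholdSet | None = None,
                  ) -> BivariateSample:
    """Draw n i.i.d. honest response pairs.

    A bivariate normal pair with the latent correlation is drawn and
    discretized through the thresholds; ``seed`` may be an int, a
    SeedSequence or a Generator.
    """
    if n < 1:
        raise InvalidParameterError("sample size must be >= 1")
    if not -1.0 < rho_latent < 1.0:
        raise InvalidParameterError(
            f"latent correlation must lie in (-1, 1), got {rho_latent}")
    ty = thresholds if thresholds_y is None else thresholds_y
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    w1 = z[:, 0]
    w2 = rho_latent * z[:, 0] + np.sqrt(1.0 - rho_latent ** 2) * z[:, 1]
    data = np.column_stack([thresholds.discretize(w1), ty.discretize(w2)])
    return BivariateSample(data, thresholds.v)
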