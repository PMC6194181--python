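"""Replacement (faking) kernels.

A faker replaces a true response i with a strictly larger value when
faking good, or a strictly smaller one when faking bad.  The conditional
probability z_{h|i} of recording fake value h given true value i follows
a discretized generalized beta distribution on the admissible interval:
for faking good the density is proportional to

    (x - i)^(gamma-1) * (v - x)^(delta-1)   on [i, v],

and the probability of category h is the normalized density at the bin
mid-point h - 1/2 (the default discretization, fixed by calibrating the
resulting population effect sizes; the bin integral over [h-1, h] is
available as an alternative variant).  The shape pair (gamma, delta)
controls faking intensity; the named presets are slight (1.5, 4),
average (3, 3) and extreme (4, 1.5).  Faking bad is the mirror image of
faking good, and a respondent already at the boundary category keeps it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

__all__ = [
    "PRESETS",
    "FakingModel",
    "ReplacementKernel",
    "gb_bin_mass",
    "replacement_kernel",
    "identity_kernel",
]

#: Named (gamma, delta) shape presets for the generalized beta kernel.
PRESETS: dict[str, tuple[float, float]] = {
    "slight": (1.5, 4.0),
    "average": (3.0, 3.0),
    "extreme": (4.0, 1.5),
}

_VARIANTS = ("bin", "midpoint")


@dataclass(frozen=True)
class FakingModel:
    """Shape parameters and direction of a faking process."""

    gamma: float
    delta: float
    direction: str = "good"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.delta <= 0:
            raise InvalidParameterError("shape parameters must be positive")
        if self.direction not in ("good", "bad"):
            raise InvalidParameterError(
                f"direction must be 'good' or 'bad', got {self.direction!r}")

    @classmethod
    def from_preset(cls, name: str, direction: str = "good") -> "FakingModel":
        try:
            gamma, delta = PRESETS[name]
        except KeyError:
            raise InvalidParameterError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(gamma, delta, direction)


def _gb_masses(i: int, v: int, gamma: float, delta: float,
               variant: str = "midpoint") -> np.ndarray:
    """Masses over the fake categories {i+1, ..., v} for origin i < v.

    ``bin``: integral of the generalized beta density on [i, v] over the
    unit bin [h-1, h]; the bins partition the interval so the masses sum
    to 1 without renormalization.  ``midpoint``: density at the bin
    mid-points h - 1/2, normalized.
    """
    a, b = float(i), float(v)
    hs = np.arange(i + 1, v + 1)
    if hs.size == 1:
        return np.ones(1)
    scale = b - a
    if variant == "bin":
        edges = (np.arange(i, v + 1) - a) / scale
        cdf = stats.beta.cdf(edges, gamma, delta)
        return np.diff(cdf)
    if variant == "midpoint":
        mids = (hs - 0.5 - a) / scale
        w = stats.beta.pdf(mids, gamma, delta)
        return w / w.sum()
    raise InvalidParameterError(
        f"unknown discretization variant {variant!r}; choose from {_VARIANTS}")


def gb_bin_mass(h: int, i: int, v: int, gamma: float, delta: float,
                variant: str = "midpoint") -> float:
    """Probability that a faker with true value i records fake value h.

    Defined for faking good, i.e. for i < h <= v; the faking-bad case is
    obtained by the mirror symmetry applied in :func:`replacement_kernel`.
    """
    if gamma <= 0 or delta <= 0:
        raise InvalidParameterError("shape parameters must be positive")
    if not (1 <= i < h <= v):
        raise InvalidParameterError(
            f"need 1 <= i < h <= v, got i={i}, h={h}, v={v}")
    return float(_gb_masses(i, v, gamma, delta, variant)[h - i - 1])


@dataclass(frozen=True)
class ReplacementKernel:
    """Column-stochastic grid of conditional replacement probabilities.

    ``z[h-1, i-1]`` is the probability of recording fake value h given
    true value i; every column sums to 1.
    """

    z: np.ndarray
    direction: str = "good"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise InvalidParameterError("kernel must be a square grid")
        if np.any(z < 0):
            raise InvalidParameterError("kernel entries must be non-negative")
        if not np.allclose(z.sum(axis=0), 1.0, atol=1e-10):
            raise InvalidParameterError("kernel columns must each sum to 1")
        object.__setattr__(self, "z", z)

    @property
    def v(self) -> int:
        return self.z.shape[0]

    def as_dataframe(self) -> pd.DataFrame:
        s = np.arange(1, self.v + 1)
        return pd.DataFrame(self.z, index=pd.Index(s, name="fake"),
                            columns=pd.Index(s, name="original"))

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path)


def replacement_kernel(v: int, model: FakingModel,
                       variant: str = "midpoint") -> ReplacementKernel:
    """Build the v x v replacement kernel for a faking model.

    Faking good places the generalized-beta bin masses on h > i and lets
    the saturated top category keep its value (z_{v|v} = 1, the only
    proper conditional distribution with no admissible strict increase).
    Faking bad is the cell-wise mirror z_{h|i}(bad) = z_{v+1-h|v+1-i}(good).
    """
    if v < 2:
        raise InvalidParameterError(f"support size must be >= 2, got {v}")
    z = np.zeros((v, v))
    for i in range(1, v):
        z[i:, i - 1] = _gb_masses(i, v, model.gamma, model.delta, variant)
    z[v - 1, v - 1] = 1.0
    if model.direction == "bad":
        z = z[::-1, ::-1].copy()
    return ReplacementKernel(z, model.direction)


def identity_kernel(v: int) -> ReplacementKernel:
    """Kernel of a non-faking (identity) replacement process."""
    return ReplacementKernel(np.eye(v), "good")
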