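"""Exact population-level analysis of faking bias.

For a grid of study conditions — faker proportion, faking model and
direction, latent correlation, support size — build the honest pmf by
normal discretization, the fake pmf by kernel marginalization, mix, and
measure the distortion with Cohen's Q for both correlation indices.
Everything here is closed-form distribution algebra: no sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from . import correlations
from .effect_size import EffectSizeRecord, cohen_q
from .errors import InvalidParameterError
from .honest_model import default_marginals, honest_joint_pmf, thresholds_from_marginals
from .mixture import fake_joint, mixture_joint
from .replacement import FakingModel, PRESETS, replacement_kernel

__all__ = ["PopulationGridSpec", "population_q", "run_population_grid",
           "latent_from_discrete"]

_INDEX_FUNCS = {
    "pearson": correlations.pearson_pop,
    "spearman": correlations.spearman_pop,
}


def _direction_pair(direction: str) -> tuple[str, str]:
    """Map a direction-pair label to per-variable faking directions.

    ``same`` fakes good on both variables; ``opposite`` fakes good on X
    and bad on Y (the mirrored assignment is reachable by passing
    explicit FakingModel objects).
    """
    if direction == "same":
        return "good", "good"
    if direction == "opposite":
        return "good", "bad"
    raise InvalidParameterError(
        f"direction must be 'same' or 'opposite', got {direction!r}")


def latent_from_discrete(target: float, marginals, index: str = "spearman",
                         thresholds_y=None) -> float:
    """Latent normal correlation whose discretized pmf attains a target
    discrete correlation.

    Discretization attenuates correlations, so a stated original
    correlation of the observed ordinal variables corresponds to a
    (larger in magnitude) latent correlation; this inverts the
    attenuation map by root finding.  The map is strictly increasing,
    so the root is unique.
    """
    if index not in _INDEX_FUNCS:
        raise InvalidParameterError(
            f"index must be 'pearson' or 'spearman', got {index!r}")
    if target == 0.0:
        return 0.0
    corr = _INDEX_FUNCS[index]
    thresholds = thresholds_from_marginals(marginals)

    def gap(r: float) -> float:
        return corr(honest_joint_pmf(thresholds, r, thresholds_y)) - target

    from scipy import optimize
    lo, hi = -1.0 + 1e-6, 1.0 - 1e-6
    if gap(lo) > 0 or gap(hi) < 0:
        raise InvalidParameterError(
            f"target correlation {target} unattainable under these marginals")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def population_q(v: int, marginals, rho_latent: float,
                 model_x: FakingModel, model_y: FakingModel,
                 alpha: float, index: str = "spearman",
                 variant: str = "midpoint") -> EffectSizeRecord:
    """Population Cohen's Q for one configuration.

    rho_d is the chosen index's correlation of the honest discrete pmf
    (not the latent correlation), so Q vanishes exactly at alpha = 0.
    """
    if index not in _INDEX_FUNCS:
        raise InvalidParameterError(
            f"index must be 'pearson' or 'spearman', got {index!r}")
    if marginals is None:
        marginals = default_marginals(v)
    thresholds = thresholds_from_marginals(marginals)
    if thresholds.v != v:
        raise InvalidParameterError(
            f"marginals imply v={thresholds.v}, expected {v}")
    P = honest_joint_pmf(thresholds, rho_latent)
    Z1 = replacement_kernel(v, model_x, variant)
    Z2 = replacement_kernel(v, model_y, variant)
    S = mixture_joint(P, fake_joint(P, Z1, Z2), alpha)
    corr = _INDEX_FUNCS[index]
    rho_d = corr(P)
    rho_m = corr(S)
    direction = "same" if model_x.direction == model_y.direction else "opposite"
    return EffectSizeRecord(
        index=index, v=v, rho_latent=rho_latent, alpha=alpha,
        model_x=f"({model_x.gamma},{model_x.delta},{model_x.direction})",
        model_y=f"({model_y.gamma},{model_y.delta},{model_y.direction})",
        direction=direction, rho_d=rho_d, rho_m=rho_m,
        q=cohen_q(rho_m, rho_d))


@dataclass(frozen=True)
class PopulationGridSpec:
    """Factor grid for the population sweep.

    ``marginals`` maps support size to marginal masses; unspecified
    sizes fall back to the package defaults.
    """

    alphas: Sequence[float] = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))
    models: Sequence[str] = ("slight", "average", "extreme")
    directions: Sequence[str] = ("same", "opposite")
    rho_levels: Sequence[float] = (-0.9, -0.6, -0.3, 0.0, 0.3, 0.6, 0.9)
    v_levels: Sequence[int] = (2, 5, 7)
    indices: Sequence[str] = ("pearson", "spearman")
    marginals: dict = field(default_factory=dict)
    variant: str = "midpoint"

    def __post_init__(self) -> None:
        if not (self.alphas and self.models and self.directions
                and self.rho_levels and self.v_levels and self.indices):
            raise InvalidParameterError("all factor grids must be non-empty")
        if any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise InvalidParameterError("faker proportions must lie in [0, 1]")

    def marginals_for(self, v: int):
        return self.marginals.get(v, default_marginals(v))


def run_population_grid(spec: PopulationGridSpec) -> pd.DataFrame:
    """Sweep the full factor crossing; one row per configuration and index.

    The output is a long-format table with the factor levels, the model
    label, the honest and mixture correlations and Q.  Deterministic.
    """
    rows = []
    for v in spec.v_levels:
        marg = spec.marginals_for(v)
        for rho in spec.rho_levels:
            for name in spec.models:
                for direction in spec.directions:
                    dx, dy = _direction_pair(direction)
                    mx = FakingModel.from_preset(name, dx)
                    my = FakingModel.from_preset(name, dy)
                    for alpha in spec.alphas:
                        for index in spec.indices:
                            rec = population_q(
                                v, marg, rho, mx, my, alpha,
                                index=index, variant=spec.variant)
                            rows.append({
                                "v": v, "rho_latent": rho, "model": name,
                                "direction": direction, "alpha": alpha,
                                "index": index, "rho_d": rec.rho_d,
                                "rho_m": rec.rho_m, "q": rec.q,
                            })
    return pd.DataFrame(rows)
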