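"""Monte Carlo study of faking bias at finite sample sizes.

Replicates the factorial simulation: honest samples are drawn from the
discretized bivariate normal, a random subset of rows (the fakers) has
both entries replaced through the faking kernels, and the sample effect
size q = z(r_m) - z(r_d) is computed per replicate for both correlation
indices.  Cells of the six-factor design — sample size N, faker
proportion A, faking model M, direction DIR, support size V, latent
correlation R_d — are summarized by the median q; the full default
crossing has 3,360 cells.

Seeding: each cell draws from a `numpy` SeedSequence spawned from the
master seed with a spawn key derived from the cell's factor levels, so
any subset of cells reproduces the corresponding values of a full run.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import pearson_sample, spearman_sample
from .effect_size import sample_q
from .errors import DegenerateSampleError, InvalidParameterError
from .honest_model import (BivariateSample, default_marginals, sample_honest,
                           thresholds_from_marginals)
from .mixture import fake_joint
from .replacement import FakingModel, ReplacementKernel, replacement_kernel

__all__ = [
    "CellLevels",
    "CellSummary",
    "SimulationDesign",
    "perturb_sample",
    "expected_row_change_probability",
    "run_cell",
    "run_design",
    "table_summary",
    "significance_crosstab",
]


def perturb_sample(sample: BivariateSample, alpha: float,
                   kernel_x: ReplacementKernel, kernel_y: ReplacementKernel,
                   seed=None) -> BivariateSample:
    """Corrupt a sample with fakers.

    Each row is independently selected with probability ``alpha``;
    selected rows have both entries replaced by draws from the
    respective replacement kernels conditioned on the original values.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(
            f"faker proportion must lie in [0, 1], got {alpha}")
    if kernel_x.v != sample.v or kernel_y.v != sample.v:
        raise InvalidParameterError("kernel and sample support sizes differ")
    rng = np.random.default_rng(seed)
    data = sample.data.copy()
    fakers = np.flatnonzero(rng.random(sample.n) < alpha)
    for kernel, col in ((kernel_x, 0), (kernel_y, 1)):
        orig = data[fakers, col]
        u = rng.random(fakers.size)
        cum = np.cumsum(kernel.z, axis=0)
        # inverse-CDF draw per row from the kernel column of its origin
        data[fakers, col] = (cum[:, orig - 1] < u).sum(axis=0) + 1
    return BivariateSample(data, sample.v)


def expected_row_change_probability(P, kernel_x: ReplacementKernel,
                                    kernel_y: ReplacementKernel,
                                    alpha: float) -> float:
    """Probability that a row of the perturbed sample differs from the
    honest one: alpha times one minus the stay-put mass of the kernel
    pair under the honest pmf.  Used as a diagnostic and test oracle."""
    zx = np.diag(kernel_x.z)
    zy = np.diag(kernel_y.z)
    stay = float(zx @ P.p @ zy)
    return alpha * (1.0 - stay)


@dataclass(frozen=True)
class CellLevels:
    """One cell of the factorial design."""

    n: int
    alpha: float
    model: str          # preset name: slight | average | extreme
    direction: str      # same | opposite
    v: int
    rho_latent: float

    def spawn_key(self) -> tuple:
        """Stable integer key identifying the cell inside a SeedSequence.

        Uses CRC32 for the categorical levels: unlike the builtin
        ``hash``, it is stable across processes, which the determinism
        contract requires.
        """
        return (self.n, int(round(self.alpha * 100)),
                zlib.crc32(self.model.encode()),
                zlib.crc32(self.direction.encode()),
                self.v, int(round(self.rho_latent * 100)) & 0xFFFFFFFF)


@dataclass(frozen=True)
class CellSummary:
    """Replicate summary of one design cell.

    Medians ignore excluded (degenerate) replicates; infinite q values
    (|r| = 1) are retained — the median is robust to them — and counted.
    """

    levels: CellLevels
    replications: int
    median_q_pearson: float
    median_q_spearman: float
    var_q_pearson: float
    var_q_spearman: float
    n_degenerate: int
    n_infinite_pearson: int
    n_infinite_spearman: int


def _kernels_for(levels: CellLevels, variant: str):
    dx, dy = (("good", "good") if levels.direction == "same"
              else ("good", "bad"))
    kx = replacement_kernel(levels.v, FakingModel.from_preset(levels.model, dx),
                            variant)
    ky = replacement_kernel(levels.v, FakingModel.from_preset(levels.model, dy),
                            variant)
    return kx, ky


def run_cell(levels: CellLevels, replications: int, seed,
             marginals=None, variant: str = "midpoint",
             return_replicates: bool = False):
    """Run all replicates of one cell.

    Per replicate: draw the honest sample D, corrupt it into X, compute
    r_d on D and r_m on X for both indices, and q = z(r_m) - z(r_d).
    Replicates where any needed correlation is undefined (a constant
    column) are excluded from the summaries and counted.

    ``seed`` may be an int or a SeedSequence.  With
    ``return_replicates`` the per-replicate table (r_d, r_m, q per
    index, and n) is returned alongside the summary, as needed by
    :func:`significance_crosstab`.
    """
    if replications < 1:
        raise InvalidParameterError("need at least one replication")
    if marginals is None:
        marginals = default_marginals(levels.v)
    thresholds = thresholds_from_marginals(marginals)
    kx, ky = _kernels_for(levels, variant)
    rng = np.random.default_rng(seed)

    rows = np.full((replications, 4), np.nan)  # rd_p, rm_p, rd_s, rm_s
    n_degenerate = 0
    for rep in range(replications):
        D = sample_honest(levels.n, thresholds, levels.rho_latent, rng)
        X = perturb_sample(D, levels.alpha, kx, ky, rng)
        try:
            rows[rep] = (pearson_sample(D), pearson_sample(X),
                         spearman_sample(D), spearman_sample(X))
        except DegenerateSampleError:
            n_degenerate += 1
    ok = ~np.isnan(rows[:, 0])
    q_p = sample_q(rows[ok, 1], rows[ok, 0])
    q_s = sample_q(rows[ok, 3], rows[ok, 2])
    if ok.sum() == 0:
        raise DegenerateSampleError(
            f"all {replications} replicates degenerate in cell {levels}")
    summary = CellSummary(
        levels=levels, replications=replications,
        median_q_pearson=float(np.median(q_p)),
        median_q_spearman=float(np.median(q_s)),
        var_q_pearson=float(np.var(q_p[np.isfinite(q_p)], ddof=1))
        if np.isfinite(q_p).sum() > 1 else np.nan,
        var_q_spearman=float(np.var(q_s[np.isfinite(q_s)], ddof=1))
        if np.isfinite(q_s).sum() > 1 else np.nan,
        n_degenerate=n_degenerate,
        n_infinite_pearson=int(np.isinf(q_p).sum()),
        n_infinite_spearman=int(np.isinf(q_s).sum()),
    )
    if return_replicates:
        reps = pd.DataFrame(rows[ok],
                            columns=["rd_pearson", "rm_pearson",
                                     "rd_spearman", "rm_spearman"])
        reps["q_pearson"] = q_p
        reps["q_spearman"] = q_s
        reps["n"] = levels.n
        return summary, reps
    return summary


@dataclass(frozen=True)
class SimulationDesign:
    """The six-factor factorial design.

    Defaults reproduce the full study conditions (3,360 cells x 2,000
    replications); scaled-down runs reduce ``replications`` or restrict
    the factor grids, never the per-cell procedure.
    """

    n_levels: Sequence[int] = (20, 50, 100, 1000)
    alphas: Sequence[float] = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))
    models: Sequence[str] = ("slight", "extreme")
    directions: Sequence[str] = ("same", "opposite")
    v_levels: Sequence[int] = (2, 5, 7)
    rho_levels: Sequence[float] = (-0.9, -0.6, -0.3, 0.0, 0.3, 0.6, 0.9)
    replications: int = 2000
    seed: int = 0
    variant: str = "midpoint"
    marginals: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return (len(self.n_levels) * len(self.alphas) * len(self.models)
                * len(self.directions) * len(self.v_levels)
                * len(self.rho_levels))

    def cells(self):
        for n, alpha, model, direction, v, rho in itertools.product(
                self.n_levels, self.alphas, self.models, self.directions,
                self.v_levels, self.rho_levels):
            yield CellLevels(n, alpha, model, direction, v, rho)

    def cell_seed(self, levels: CellLevels) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed,
                                      spawn_key=levels.spawn_key())


def run_design(design: SimulationDesign,
               progress: bool = False) -> pd.DataFrame:
    """Run every cell of a design; one row per cell.

    Deterministic given the master seed; cells are independent, so a
    filtered design reproduces the corresponding rows of the full run.
    """
    rows = []
    iterator = design.cells()
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm  # type: ignore[import-untyped]
        iterator = tqdm(iterator, total=design.n_cells)
    for levels in iterator:
        marg = design.marginals.get(levels.v)
        try:
            s = run_cell(levels, design.replications,
                         design.cell_seed(levels), marginals=marg,
                         variant=design.variant)
        except DegenerateSampleError:
            rows.append({**levels.__dict__, "failed": True})
            continue
        rows.append({
            **levels.__dict__, "failed": False,
            "median_q_pearson": s.median_q_pearson,
            "median_q_spearman": s.median_q_spearman,
            "var_q_pearson": s.var_q_pearson,
            "var_q_spearman": s.var_q_spearman,
            "n_degenerate": s.n_degenerate,
            "n_infinite_pearson": s.n_infinite_pearson,
            "n_infinite_spearman": s.n_infinite_spearman,
        })
    return pd.DataFrame(rows)


def table_summary(results: pd.DataFrame, v: int, model: str, direction: str,
                  index: str = "spearman",
                  across: str = "mean") -> pd.DataFrame:
    """Median-q grid by (original correlation x faker proportion).

    Within each sample-size level the cell median is taken from
    ``results``; the per-N medians are then combined across the sample
    sizes, by arithmetic mean by default (``across='median'`` pools the
    per-N medians by their median instead).  Spearman by default.
    Cells absent from ``results`` appear as NaN.
    """
    if across not in ("mean", "median"):
        raise InvalidParameterError("across must be 'mean' or 'median'")
    col = f"median_q_{index}"
    mask = ((results["v"] == v) & (results["model"] == model)
            & (results["direction"] == direction))
    if "failed" in results.columns:
        mask &= ~results["failed"].fillna(False)
    sub = results[mask]
    grid = sub.pivot_table(index="rho_latent", columns="alpha", values=col,
                           aggfunc=across)
    grid.index.name = "rho_d"
    grid.columns.name = "alpha"
    return grid


def significance_crosstab(replicates: pd.DataFrame, sig_level: float = 0.05,
                          index: str = "spearman") -> pd.DataFrame:
    """2x2 counts of significance agreement between honest and perturbed
    correlations across replicates.

    Each replicate's r_d and r_m are tested against zero with the
    standard t approximation, t = r sqrt((n-2)/(1-r^2)) on n-2 degrees
    of freedom, two-sided.  Rows: honest significant / not; columns:
    perturbed significant / not.
    """
    if not 0.0 < sig_level < 1.0:
        raise InvalidParameterError("significance level must be in (0, 1)")

    def pvals(r, n):
        r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
        n = np.asarray(n, dtype=float)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2.0) / (1.0 - r ** 2))
        return 2.0 * stats.t.sf(np.abs(t), n - 2.0)

    sig_d = pvals(replicates[f"rd_{index}"], replicates["n"]) < sig_level
    sig_m = pvals(replicates[f"rm_{index}"], replicates["n"]) < sig_level
    table = pd.DataFrame(
        [[int(np.sum(sig_d & sig_m)), int(np.sum(sig_d & ~sig_m))],
         [int(np.sum(~sig_d & sig_m)), int(np.sum(~sig_d & ~sig_m))]],
        index=pd.Index(["honest_sig", "honest_ns"]),
        columns=pd.Index(["perturbed_sig", "perturbed_ns"]))
    return table
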