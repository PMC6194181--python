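"""Applied-mode interface: ordinal data I/O, the faking sensitivity
report, and run manifests.

The sensitivity report answers the applied question: given an observed
two-column ordinal data set, how would its correlation look if some
unknown fraction of respondents had faked?  The empirical contingency
table is treated as the honest pmf and the mixture algebra projects the
correlation over a grid of assumed faker proportions and faking models —
a sensitivity band, not a faker-detection device.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlations import pearson_pop, spearman_pop
from .effect_size import cohen_q
from .errors import DegenerateDistributionError, InvalidParameterError
from .honest_model import BivariateSample
from .mixture import fake_joint, mixture_joint
from .replacement import FakingModel, replacement_kernel

__all__ = ["load_ordinal_csv", "save_ordinal_csv", "sensitivity_report",
           "write_manifest"]


def load_ordinal_csv(path, v: int | None = None) -> BivariateSample:
    """Read a two-column table of integer ordinal responses.

    The first two columns are used.  Missing values are an error (no
    silent imputation); so are non-integers and values outside the
    declared support.  If ``v`` is omitted the support is inferred as
    {1..max observed value}.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidParameterError(
            f"{path}: need at least two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    for col in df.columns:
        bad = df[df[col].isna()]
        if len(bad):
            raise InvalidParameterError(
                f"{path}: missing value in column {col!r}, "
                f"first at row {bad.index[0] + 2}")  # 1-based incl. header
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.round(vals)):
            raise InvalidParameterError(
                f"{path}: column {col!r} contains non-integer values")
    data = df.to_numpy().astype(np.int64)
    if v is None:
        v = int(data.max())
    outside = (data < 1) | (data > v)
    if outside.any():
        r, c = np.argwhere(outside)[0]
        raise InvalidParameterError(
            f"{path}: value {data[r, c]} outside support 1..{v} at row "
            f"{r + 2}, column {df.columns[c]!r}")
    return BivariateSample(data, v)


def save_ordinal_csv(sample: BivariateSample, path,
                     names: tuple[str, str] = ("x", "y")) -> None:
    pd.DataFrame(sample.data, columns=list(names)).to_csv(path, index=False)


def sensitivity_report(sample: BivariateSample,
                       models=("slight", "average", "extreme"),
                       directions=("same", "opposite"),
                       alphas=None,
                       variant: str = "midpoint") -> pd.DataFrame:
    """Project observed correlations through hypothetical faking scenarios.

    For each assumed model/direction and faker proportion alpha, the
    empirical pmf is mixed with its faked counterpart and both
    correlation indices of the projection are reported together with
    their displacement q from the observed value.  Degenerate
    projections (all mass in one cell, e.g. v=2 faked good at alpha=1)
    yield NaN with ``degenerate=True``.
    """
    if sample.n < 3:
        raise InvalidParameterError("need at least three observations")
    if alphas is None:
        alphas = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    P = sample.empirical_pmf()
    observed = {}
    for index, fn in (("pearson", pearson_pop), ("spearman", spearman_pop)):
        try:
            observed[index] = fn(P)
        except DegenerateDistributionError:
            raise InvalidParameterError(
                "a data column is constant; correlations undefined")
    rows = []
    for model in models:
        for direction in directions:
            dx, dy = (("good", "good") if direction == "same"
                      else ("good", "bad"))
            Z1 = replacement_kernel(sample.v, FakingModel.from_preset(model, dx),
                                    variant)
            Z2 = replacement_kernel(sample.v, FakingModel.from_preset(model, dy),
                                    variant)
            Z = fake_joint(P, Z1, Z2)
            for alpha in alphas:
                S = mixture_joint(P, Z, float(alpha))
                for index, fn in (("pearson", pearson_pop),
                                  ("spearman", spearman_pop)):
                    try:
                        proj = fn(S)
                        degenerate = False
                    except DegenerateDistributionError:
                        proj = np.nan
                        degenerate = True
                    rows.append({
                        "model": model, "direction": direction,
                        "alpha": float(alpha), "index": index,
                        "observed_r": observed[index],
                        "projected_r": proj,
                        "q": cohen_q(proj, observed[index])
                        if not degenerate else np.nan,
                        "degenerate": degenerate,
                    })
    return pd.DataFrame(rows)


def write_manifest(out_dir, subcommand: str, params: dict) -> Path:
    """Record every parameter of a run so it can be reproduced exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sgrcorr",
        "version": __version__,
        "subcommand": subcommand,
        "python": platform.python_version(),
        "params": {k: (list(val) if isinstance(val, (tuple, np.ndarray))
                       else val)
                   for k, val in params.items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
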