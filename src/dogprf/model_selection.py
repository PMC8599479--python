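"""Goodness of fit, information criteria and the model-comparison procedure.

Per voxel and model variant the pipeline reports the coefficient of
determination R^2 = 1 - RS/SS (SS the total sum of squares about the mean,
RS the residual sum of squares), its small-sample adjustment, and Akaike's
Information Criterion AIC = n*ln(RS/n) + 2p.  Voxels are screened by an R^2
threshold applied to *both* variants (the overlap set), and the headline
statistic is the percentage of overlap voxels for which the DC-balanced
variant attains the lower AIC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError, InputError, ParameterError

#: screening thresholds used in the comparison procedures
R2_THRESHOLDS = (0.05, 0.15, 0.3)


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """R^2 = 1 - RS/SS with SS = sum((y - mean)^2), RS = sum((y - yhat)^2)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InputError("observed and fitted must share a length of at least 2")
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0:
        raise DegenerateSignalError("observed series is constant")
    rs = float(np.sum((y - yhat) ** 2))
    return 1.0 - rs / ss


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2) * (n - 1) / (n - p - 1)."""
    if n <= p + 1:
        raise ParameterError("need n > p + 1 for the adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def aic(n: int, rss: float, p: int) -> float:
    """AIC = n * ln(RSS/n) + 2p; a perfect fit (RSS = 0) maps to -inf."""
    if n < 1:
        raise ParameterError("n must be at least 1")
    if rss < 0:
        raise ParameterError("RSS cannot be negative")
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * p


def aic_from_series(observed: np.ndarray, fitted: np.ndarray, p: int) -> float:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape:
        raise InputError("observed and fitted must have equal length")
    return aic(y.size, float(np.sum((y - yhat) ** 2)), p)


@dataclass
class ComparisonReport:
    """Voxelwise AIC comparison between the two variants after screening."""

    table: pd.DataFrame  # one row per overlap voxel
    percent_balanced: float
    n_overlap: int
    n_total: int
    r2_threshold: float
    group_percent: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "r2_threshold": self.r2_threshold,
            "n_total_voxels": self.n_total,
            "n_overlap_voxels": self.n_overlap,
            "percent_preferring_balanced": self.percent_balanced,
            "group_percent": self.group_percent,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def compare_models(
    fit_table: pd.DataFrame,
    n_obs: int,
    r2_threshold: float = 0.05,
    group_column: str | None = None,
) -> ComparisonReport:
    """Screen voxels and award each one to the variant with the lower AIC.

    Screening keeps voxels where BOTH variants exceed ``r2_threshold``
    (strict inequality, as the procedure states it) — the "overlap" set on
    which the AIC comparison is well defined.  Equal AICs go to the balanced
    variant (fewer parameters).  When a grouping column (e.g. hemisphere)
    is present, per-group percentages are reported alongside the pooled one.
    """
    wide = fit_table.pivot_table(
        index="voxel_id", columns="variant",
        values=["r2", "rss", "n_params"], aggfunc="first",
    )
    for variant in ("unrestricted", "balanced"):
        if ("r2", variant) not in wide.columns:
            raise InputError(f"fit table lacks the {variant} variant")
    n_total = len(wide)
    keep = (wide[("r2", "unrestricted")] > r2_threshold) & (
        wide[("r2", "balanced")] > r2_threshold
    )
    sub = wide[keep]
    aic_u = np.array([aic(n_obs, r, int(p)) for r, p in
                      zip(sub[("rss", "unrestricted")], sub[("n_params", "unrestricted")])])
    aic_b = np.array([aic(n_obs, r, int(p)) for r, p in
                      zip(sub[("rss", "balanced")], sub[("n_params", "balanced")])])
    winner = np.where(aic_b <= aic_u, "balanced", "unrestricted")
    table = pd.DataFrame({
        "voxel_id": sub.index,
        "r2_unrestricted": sub[("r2", "unrestricted")].to_numpy(),
        "r2_balanced": sub[("r2", "balanced")].to_numpy(),
        "aic_unrestricted": aic_u,
        "aic_balanced": aic_b,
        "winner": winner,
    })
    percent = 100.0 * float(np.mean(winner == "balanced")) if len(sub) else float("nan")

    group_percent: dict = {}
    if group_column is not None and group_column in fit_table.columns:
        groups = fit_table.drop_duplicates("voxel_id").set_index("voxel_id")[group_column]
        table[group_column] = groups.reindex(table["voxel_id"]).to_numpy()
        for g, sub_t in table.groupby(group_column):
            group_percent[str(g)] = 100.0 * float(np.mean(sub_t["winner"] == "balanced"))

    return ComparisonReport(table, percent, int(len(sub)), n_total, r2_threshold, group_percent)


def mean_r2_by_variant(
    fit_table: pd.DataFrame, r2_threshold: float = 0.05
) -> pd.Series:
    """Mean R^2 per variant over voxels passing the screening threshold."""
    screened = fit_table[fit_table["r2"] > r2_threshold]
    return screened.groupby("variant")["r2"].mean()


def bias_distribution(
    fit_table: pd.DataFrame,
    bounds: Sequence[float] = (1.0, 5.0),
    r2_threshold: float = 0.05,
    delta_bounds: tuple[float, float] = (0.1, 0.9),
) -> tuple[pd.DataFrame, dict]:
    """Distribution of the DC bias sigma1^2 - delta*sigma2^2 over the
    screened unrestricted fits.

    Returns a per-bound table of the fraction of voxels with |bias| <= b
    (inclusive, so a bound of 0 counts the exactly balanced voxels), plus
    a summary with the median bias and the sign skew (fraction negative
    minus fraction positive).
    """
    rows = fit_table[fit_table["variant"] == "unrestricted"]
    rows = rows[
        (rows["r2"] > r2_threshold)
        & (rows["delta"] > delta_bounds[0])
        & (rows["delta"] < delta_bounds[1])
    ]
    b = rows["sigma1"] ** 2 - rows["delta"] * rows["sigma2"] ** 2
    b = b.to_numpy()
    table = pd.DataFrame({
        "bound": list(bounds),
        "fraction_within": [
            float(np.mean(np.abs(b) <= bound)) if b.size else float("nan")
            for bound in bounds
        ],
    })
    summary = {
        "n_voxels": int(b.size),
        "median_bias": float(np.median(b)) if b.size else float("nan"),
        "sign_skew": float(np.mean(b < 0) - np.mean(b > 0)) if b.size else float("nan"),
    }
    return table, summary
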