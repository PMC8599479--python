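"""DC-offset analyses on non-normalised fits.

For raw (non-normalised) data the GLM constant term captures each voxel's
BOLD DC offset.  This module extracts those offsets, regresses them on
log-eccentricity (the offset declines from fovea to periphery), and checks
the amplitude-envelope property: the BOLD signal varies *around* its DC
offset, i.e. per voxel max(BOLD) >= offset >= min(BOLD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError, StateError
from .forward_model import VoxelTimeSeries


def extract_dc_offsets(
    fit_table: pd.DataFrame,
    dataset: Sequence[VoxelTimeSeries],
    variant: str = "balanced",
    r2_threshold: float = 0.05,
) -> pd.DataFrame:
    """One record per screened voxel: the GLM constant (DC offset), the
    eccentricity of the fitted centre, and the series' max/min.

    Refuses fits produced on detrended or z-scored data, whose constant
    term no longer carries the DC offset.
    """
    if "preprocessing" in fit_table.columns:
        states = set(fit_table["preprocessing"].unique())
        if states - {"raw"}:
            raise StateError(
                f"DC offsets require fits on raw data, got states {sorted(states)}"
            )
    for ts in dataset:
        if ts.state != "raw":
            raise StateError("dataset must be in the raw preprocessing state")
    by_id = {ts.voxel_id: ts for ts in dataset}
    rows = fit_table[
        (fit_table["variant"] == variant) & (fit_table["r2"] > r2_threshold)
    ]
    records = []
    for _, row in rows.iterrows():
        ts = by_id.get(int(row["voxel_id"]))
        if ts is None:
            continue
        records.append({
            "voxel_id": int(row["voxel_id"]),
            "dc_offset": row["constant"],
            "eccentricity": float(np.hypot(row["x0"], row["y0"])),
            "max_bold": float(ts.samples.max()),
            "min_bold": float(ts.samples.min()),
        })
    return pd.DataFrame(records,
                        columns=["voxel_id", "dc_offset", "eccentricity",
                                 "max_bold", "min_bold"])


@dataclass(frozen=True)
class OffsetRegression:
    """OLS of DC offset on ln(eccentricity)."""

    slope: float
    intercept: float
    slope_se: float
    t_value: float
    p_value: float
    r2: float
    n: int

    @property
    def slope_is_negative(self) -> bool:
        return self.slope < 0

    def summary(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "t_value": self.t_value,
            "p_value": self.p_value,
            "r2": self.r2,
            "n": self.n,
            "slope_is_negative": self.slope_is_negative,
        }


def regress_offset_on_eccentricity(records: pd.DataFrame) -> OffsetRegression:
    """Ordinary least squares: dc_offset ~ 1 + ln(eccentricity)."""
    if len(records) < 3:
        raise InputError("need at least 3 records for the regression")
    ecc = records["eccentricity"].to_numpy(dtype=float)
    if ecc.min() <= 0:
        raise InputError("eccentricities must be positive")
    if ecc.max() / ecc.min() < 2.0:
        raise InputError("eccentricity spread must exceed one octave")
    X = sm.add_constant(np.log(ecc))
    model = sm.OLS(records["dc_offset"].to_numpy(dtype=float), X).fit()
    return OffsetRegression(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        t_value=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        r2=float(model.rsquared),
        n=int(model.nobs),
    )


def pool_slopes(regressions: Sequence[OffsetRegression]) -> dict:
    """Simple pooling of per-dataset slopes (mean +/- sd), the multi-
     participant summary used in place of a mixed-effects model."""
    slopes = np.array([r.slope for r in regressions], dtype=float)
    return {
        "n_datasets": int(slopes.size),
        "mean_slope": float(slopes.mean()),
        "sd_slope": float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0,
        "all_negative": bool(np.all(slopes < 0)),
    }


def amplitude_envelope_check(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per voxel, test max_bold >= dc_offset >= min_bold.

    Returns the records augmented with the signed margins (upper: max -
    offset; lower: offset - min; both non-negative when the property holds)
    and the fraction of voxels satisfying it.
    """
    out = records.copy()
    out["upper_margin"] = out["max_bold"] - out["dc_offset"]
    out["lower_margin"] = out["dc_offset"] - out["min_bold"]
    out["within_envelope"] = (out["upper_margin"] >= 0) & (out["lower_margin"] >= 0)
    fraction = float(out["within_envelope"].mean()) if len(out) else float("nan")
    return out, fraction
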