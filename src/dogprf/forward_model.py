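"""From pRF parameters to a predicted BOLD time series, plus preprocessing.

The forward model follows the standard pRF pipeline: the receptive field is
multiplied with each TR's binary aperture and summed (the neural drive),
the neural drive is convolved with a haemodynamic response function within
each run, and the result is scaled by a gain ``beta`` and shifted by a
``constant`` term.  ``beta`` and the constant are estimated per voxel by an
ordinary-least-squares GLM, y(t) = p(t)*beta + c + e; for non-normalised
data the constant is the voxel's DC offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .dog_model import DoGParams, evaluate_dog
from .errors import (
    DegenerateDesignError,
    DegenerateSignalError,
    InputError,
    ParameterError,
)
from .stimulus import ApertureSequence


@dataclass(frozen=True)
class HRFModel:
    """Difference-of-gammas haemodynamic response function.

    The kernel is g(t; peak) - undershoot_ratio * g(t; undershoot), with
    g a gamma density of shape delay/dispersion and scale dispersion, and
    is normalised to unit maximum.  The default undershoot_ratio of 0.4
    yields a pronounced post-stimulus undershoot (|min| >= 0.2 * max),
    emulating an empirically measured HRF with a large undershoot; all
    parameters are injectable so alternative shapes can be tested.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 0.4
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ParameterError("HRF dispersions must be positive")
        if self.peak_delay <= 0 or self.undershoot_delay <= 0 or self.duration <= 0:
            raise ParameterError("HRF delays and duration must be positive")


@dataclass(frozen=True)
class VoxelTimeSeries:
    """One voxel's BOLD samples with TR metadata and preprocessing state."""

    samples: np.ndarray
    tr: float = 1.0
    state: str = "raw"  # "raw" | "detrended" | "zscored"
    voxel_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise InputError("samples must be 1D")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class GLMSolution:
    """Least-squares solution of y = p*beta + constant + e."""

    beta: float
    constant: float
    residuals: np.ndarray

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def hrf_kernel(model: HRFModel, tr: float) -> np.ndarray:
    """Sample the HRF at TR spacing over [0, duration]; unit maximum.

    Length is floor(duration/tr) + 1.
    """
    if tr <= 0:
        raise ParameterError("tr must be positive")
    n = int(np.floor(model.duration / tr)) + 1
    t = np.arange(n) * tr
    peak = stats.gamma.pdf(t, a=model.peak_delay / model.peak_dispersion,
                           scale=model.peak_dispersion)
    under = stats.gamma.pdf(t, a=model.undershoot_delay / model.undershoot_dispersion,
                            scale=model.undershoot_dispersion)
    kernel = peak - model.undershoot_ratio * under
    peak_val = kernel.max()
    if peak_val <= 0:
        raise ParameterError("HRF kernel has no positive peak")
    return kernel / peak_val


def convolve_runs(x: np.ndarray, kernel: np.ndarray, run_lengths) -> np.ndarray:
    """Causal convolution applied independently within each run, truncated
    to the run length (no bleed across run boundaries)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x, dtype=float)
    start = 0
    for length in run_lengths:
        seg = x[..., start : start + length]
        conv = np.apply_along_axis(
            lambda s: np.convolve(s, kernel)[:length], -1, seg
        ) if x.ndim > 1 else np.convolve(seg, kernel)[:length]
        out[..., start : start + length] = conv
        start += length
    return out


def neural_timecourse(params: DoGParams, apertures: ApertureSequence) -> np.ndarray:
    """Per-TR overlap between the DoG and the binary apertures:
    element t = sum over grid samples of f(x, y) * mask_t(x, y)."""
    field = evaluate_dog(params, apertures.grid)
    return apertures.matrix @ field.ravel()


def predict_bold(
    params: DoGParams,
    apertures: ApertureSequence,
    hrf: HRFModel | np.ndarray,
    beta: float = 1.0,
    constant: float = 0.0,
) -> np.ndarray:
    """Predicted BOLD series: per-run HRF convolution of the neural drive,
    scaled by beta, plus the constant."""
    kernel = hrf if isinstance(hrf, np.ndarray) else hrf_kernel(hrf, apertures.tr)
    drive = neural_timecourse(params, apertures)
    conv = convolve_runs(drive, kernel, apertures.run_lengths)
    return beta * conv + constant


def glm_fit(prediction: np.ndarray, observed: VoxelTimeSeries | np.ndarray) -> GLMSolution:
    """Ordinary least squares for y = p*beta + constant + e."""
    y = observed.samples if isinstance(observed, VoxelTimeSeries) else np.asarray(observed, float)
    p = np.asarray(prediction, dtype=float)
    if p.shape != y.shape:
        raise InputError("prediction and observed series must have equal length")
    if np.ptp(p) == 0:
        raise DegenerateDesignError("prediction is constant; beta is not identifiable")
    design = np.column_stack([p, np.ones_like(p)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    return GLMSolution(float(coef[0]), float(coef[1]), residuals)


def detrend(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Remove the least-squares straight line over the time index.

    The output has zero mean and the operation is idempotent (it is the
    orthogonal projection onto the complement of span{1, t}).
    """
    if ts.n < 3:
        raise InputError("detrend requires at least 3 samples")
    t = np.arange(ts.n, dtype=float)
    design = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, ts.samples, rcond=None)
    return replace(ts, samples=ts.samples - design @ coef, state="detrended")


def zscore(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """(y - mean) / sd with population sd; output has mean 0, sd 1."""
    sd = float(np.std(ts.samples))
    if sd == 0:
        raise DegenerateSignalError("constant series cannot be z-scored")
    return replace(ts, samples=(ts.samples - ts.samples.mean()) / sd, state="zscored")


def preprocess(ts: VoxelTimeSeries, normalise: bool) -> VoxelTimeSeries:
    """The acquisition pipeline's normalisation: detrend then z-score when
    ``normalise`` is true, otherwise the raw series unchanged."""
    return zscore(detrend(ts)) if normalise else ts


# ---------------------------------------------------------------------------
# Dataset input: CSV tables and 4D NIfTI + mask.

def load_csv_dataset(path: str | Path, tr: float = 1.0) -> list[VoxelTimeSeries]:
    """Read a voxel-by-time table (CSV with a ``voxel_id`` index column)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return [
        VoxelTimeSeries(row.to_numpy(dtype=float), tr=tr, voxel_id=int(vid))
        for vid, row in df.iterrows()
    ]


def write_csv_dataset(dataset: list[VoxelTimeSeries], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [ts.samples for ts in dataset],
        index=pd.Index([ts.voxel_id for ts in dataset], name="voxel_id"),
        columns=[f"t{i}" for i in range(dataset[0].n)],
    )
    df.to_csv(path)


def load_nifti_dataset(
    bold_path: str | Path, mask_path: str | Path, tr: float | None = None
) -> list[VoxelTimeSeries]:
    """Extract masked voxel time series from a 4D NIfTI volume.

    Voxels are taken in mask scan (C) order; ``tr`` falls back to the NIfTI
    header's time step when not given.
    """
    import nibabel as nib

    img = nib.load(str(bold_path))
    mask = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise InputError("BOLD image must be 4D")
    m = np.asanyarray(mask.dataobj) > 0
    if m.shape != data.shape[:3]:
        raise InputError("mask shape does not match the BOLD volume")
    if tr is None:
        tr = float(img.header.get_zooms()[3]) or 1.0
    series = data[m]  # (n_voxels, n_frames) in C scan order
    return [
        VoxelTimeSeries(series[i], tr=tr, voxel_id=i) for i in range(series.shape[0])
    ]
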