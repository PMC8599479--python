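"""Forward model: HRF, neural drive, GLM, and the preprocessing transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dogprf as d
from dogprf.errors import (
    DegenerateDesignError,
    DegenerateSignalError,
    InputError,
    ParameterError,
)
from dogprf.forward_model import convolve_runs


def test_hrf_kernel_shape_and_undershoot():
    kernel = d.hrf_kernel(d.HRFModel(), tr=1.0)
    assert kernel.size == math.floor(32.0 / 1.0) + 1
    assert kernel.max() == pytest.approx(1.0)
    assert kernel.min() < -0.2  # pronounced post-stimulus undershoot
    with pytest.raises(ParameterError):
        d.hrf_kernel(d.HRFModel(peak_dispersion=-1.0), tr=1.0)
    assert d.hrf_kernel(d.HRFModel(), tr=2.0).size == 17


def test_neural_timecourse_trivial_frames(small):
    grid = small.grid
    empty = np.zeros((1, grid.resolution, grid.resolution), dtype=np.uint8)
    disc = (grid.eccentricity <= 17.4).astype(np.uint8)[None]
    masks = np.concatenate([empty, disc])
    ap = d.ApertureSequence(masks, grid, tr=1.0)

    balanced = d.DoGParams(1.0, -1.0, 1.2, 2.4, d.balanced_delta(1.2, 2.4))
    tc = d.neural_timecourse(balanced, ap)
    assert tc[0] == 0.0
    # peak-overlap scale: the centre Gaussian's full response in grid units
    peak = 2 * math.pi * balanced.sigma1**2 / grid.cell_area
    assert abs(tc[1]) < 1e-3 * peak  # full field drives a balanced pRF to ~0

    biased = d.DoGParams(1.0, -1.0, 1.2, 1.6, 0.3)
    tc_b = d.neural_timecourse(biased, ap)
    expected = 2 * math.pi * d.bias(biased).value / grid.cell_area
    assert tc_b[1] == pytest.approx(expected, rel=1e-3)
    assert tc_b[1] > 0


def test_predict_bold_linearity(small):
    p = d.DoGParams(2.0, 1.0, 1.0, 2.0, 0.25)
    base = d.predict_bold(p, small.apertures, small.kernel, beta=0.0, constant=5.0)
    assert np.allclose(base, 5.0)
    one = d.predict_bold(p, small.apertures, small.kernel, beta=1.0, constant=5.0)
    two = d.predict_bold(p, small.apertures, small.kernel, beta=2.0, constant=5.0)
    assert np.allclose(two - 5.0, 2.0 * (one - 5.0))


def test_convolution_respects_run_boundaries():
    kernel = np.array([1.0, 0.5, 0.25])
    x = np.zeros(20)
    x[9] = 1.0  # last sample of run 1
    out = convolve_runs(x, kernel, (10, 10))
    assert out[9] == 1.0
    assert np.allclose(out[10:], 0.0)  # no bleed into run 2


def test_glm_exact_recovery():
    rng = np.random.default_rng(0)
    p = rng.normal(size=100)
    sol = d.glm_fit(p, 2.0 * p + 3.0)
    assert sol.beta == pytest.approx(2.0, abs=1e-10)
    assert sol.constant == pytest.approx(3.0, abs=1e-10)
    assert np.max(np.abs(sol.residuals)) < 1e-10


def test_glm_orthogonal_noise_and_residual_orthogonality():
    rng = np.random.default_rng(1)
    p = rng.normal(size=200)
    noise = rng.normal(size=200)
    noise -= noise.mean()
    pc = p - p.mean()
    noise -= (noise @ pc) / (pc @ pc) * pc  # orthogonal to prediction and constant
    sol = d.glm_fit(p, noise)
    assert abs(sol.beta) < 1e-8
    y = 1.5 * p + noise
    sol2 = d.glm_fit(p, y)
    assert abs(sol2.residuals @ p) < 1e-8
    assert abs(sol2.residuals.sum()) < 1e-8
    # RSS never exceeds total variance about the mean
    assert sol2.rss <= np.sum((y - y.mean()) ** 2) + 1e-12


def test_glm_zscored_observed_centred_prediction_zero_constant():
    rng = np.random.default_rng(2)
    p = rng.normal(size=150)
    p -= p.mean()
    y = d.zscore(d.VoxelTimeSeries(rng.normal(size=150) + 3.0 * p)).samples
    assert abs(d.glm_fit(p, y).constant) < 1e-8


def test_glm_rejects_constant_prediction():
    with pytest.raises(DegenerateDesignError):
        d.glm_fit(np.ones(50), np.arange(50.0))


def test_detrend_annihilates_affine_and_is_idempotent():
    t = np.arange(100.0)
    affine = d.detrend(d.VoxelTimeSeries(3.0 + 0.7 * t))
    assert np.max(np.abs(affine.samples)) < 1e-9
    rng = np.random.default_rng(3)
    ts = d.VoxelTimeSeries(rng.normal(size=100) + 0.2 * t)
    once = d.detrend(ts)
    assert abs(once.samples.mean()) < 1e-10
    twice = d.detrend(once)
    assert np.allclose(once.samples, twice.samples, atol=1e-10)
    assert once.state == "detrended"
    with pytest.raises(InputError):
        d.detrend(d.VoxelTimeSeries(np.array([1.0, 2.0])))


@settings(max_examples=50, deadline=None)
@given(a=st.floats(0.1, 10.0), b=st.floats(-50.0, 50.0))
def test_zscore_affine_invariance(a, b):
    rng = np.random.default_rng(4)
    y = rng.normal(size=80)
    z = d.zscore(d.VoxelTimeSeries(y))
    z_affine = d.zscore(d.VoxelTimeSeries(a * y + b))
    assert np.allclose(z.samples, z_affine.samples, atol=1e-8)
    assert abs(z.samples.mean()) < 1e-10
    assert np.std(z.samples) == pytest.approx(1.0, abs=1e-10)


def test_zscore_rejects_constant():
    with pytest.raises(DegenerateSignalError):
        d.zscore(d.VoxelTimeSeries(np.full(10, 2.0)))


def test_balanced_prf_ignores_full_field_stimulation(small):
    """Contrast/luminance separation: under full-field-only stimulation a
    balanced pRF's prediction is indistinguishable from its constant."""
    grid = small.grid
    disc = (grid.eccentricity <= 17.4).astype(np.uint8)
    masks = np.repeat(disc[None], 40, axis=0)
    ap = d.ApertureSequence(masks, grid, tr=1.0)
    p = d.DoGParams(0.5, 0.5, 1.0, 2.0, 0.25)
    beta = 3.0
    pred = d.predict_bold(p, ap, small.kernel, beta=beta, constant=10.0)
    assert np.max(np.abs(pred - 10.0)) < 1e-3 * abs(beta) / grid.cell_area


def test_csv_dataset_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    dataset = [d.VoxelTimeSeries(rng.normal(size=30), voxel_id=i) for i in range(4)]
    from dogprf.forward_model import load_csv_dataset, write_csv_dataset

    write_csv_dataset(dataset, tmp_path / "data.csv")
    back = load_csv_dataset(tmp_path / "data.csv")
    assert len(back) == 4
    for a, b in zip(dataset, back):
        assert a.voxel_id == b.voxel_id
        assert np.allclose(a.samples, b.samples)


def test_nifti_dataset_extraction(tmp_path):
    import nibabel as nib

    from dogprf.forward_model import load_nifti_dataset

    rng = np.random.default_rng(6)
    data = rng.normal(size=(3, 3, 2, 10))
    mask = np.zeros((3, 3, 2))
    mask[0, 1, 0] = 1
    mask[2, 2, 1] = 1
    nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "bold.nii")
    nib.save(nib.Nifti1Image(mask, np.eye(4)), tmp_path / "mask.nii")
    out = load_nifti_dataset(tmp_path / "bold.nii", tmp_path / "mask.nii", tr=1.0)
    assert len(out) == 2
    assert np.allclose(out[0].samples, data[0, 1, 0])  # mask scan order
    assert np.allclose(out[1].samples, data[2, 2, 1])
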