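# dogprf

Population receptive field (pRF) analysis for visual cortex with a
centre–surround **Difference of Gaussians** model, comparing a
**DC-balanced** variant against an unrestricted one.

## The problem

A voxel's pRF is modelled as

    f(x, y) = exp(−r²/2σ₁²) − δ·exp(−r²/2σ₂²),   r² = (x−x₀)² + (y−y₀)²

an excitatory Gaussian of spread σ₁ minus a wider inhibitory surround of
spread σ₂ scaled by δ. Its total (DC) energy is 2π(σ₁² − δσ₂²), so the
filter has zero response to uniform luminance — it is a *bandpass* filter
measuring pure contrast — exactly when

    δ = (σ₁/σ₂)²   (DC balance)

Whether V1 pRFs are organised this way matters: a DC-balanced pRF
separates stimulus contrast (carried by the modelled response) from
stimulus luminance (carried by the BOLD signal's DC offset). This package
implements the full analysis needed to ask that question: binary
wedge+ring stimulus apertures, a BOLD forward model (aperture overlap →
HRF convolution → GLM gain/offset), coarse-to-fine Nelder–Mead fitting of
both model variants per voxel, R²/adjusted-R²/AIC model comparison
(AIC = n·ln(RSS/n) + 2p), the bias statistic σ₁² − δσ₂² and its
distribution, and the DC-offset-vs-eccentricity analyses — all exercised
end to end on synthetic BOLD data with known ground truth. Real data can
be supplied as voxel×time CSV tables or as 4D NIfTI plus a mask.

It is intended for researchers doing retinotopy/pRF modelling who want a
testable, scriptable reference implementation of the DC-balance analysis.

## Worked example

Simulate 20 voxels with balanced ground-truth pRFs, fit both variants,
and compare them:

```python
import dogprf as d

grid      = d.VisualFieldGrid(extent=17.4, resolution=51)
apertures = d.build_protocol(d.ProtocolConfig(), grid)   # 2 runs x 225 TR
kernel    = d.hrf_kernel(d.HRFModel(), tr=1.0)

truth   = d.sample_ground_truth(20, d.GroundTruthConfig(variant="balanced"), seed=1)
raw     = d.simulate_dataset(truth, apertures, kernel, d.NoiseModel(seed=1))
series  = [d.preprocess(ts, normalise=True) for ts in raw]

coarse  = d.CoarseGrid(d.SearchSpace(), apertures, kernel)
fits    = d.fit_map(series, apertures, kernel, coarse=coarse)

report  = d.compare_models(fits, n_obs=apertures.n_frames, r2_threshold=0.05)
print(f"median R2 {fits.r2.median():.3f}")
print(f"balanced preferred in {report.percent_balanced:.1f}% "
      f"of {report.n_overlap} overlap voxels")
```

Output:

```
median R2 0.416
balanced preferred in 85.0% of 20 overlap voxels
```

The median R² ≈ 0.4 reflects the generator's calibrated noise level; the
AIC prefers the balanced model in most voxels because the data were
generated balanced, so the unrestricted variant's extra δ parameter buys
almost no residual reduction against its 2-point AIC penalty.

The same pipeline is available from the shell via a YAML config:

```sh
dogprf simulate  --config run.yaml --out artifacts/
dogprf fit       --config run.yaml --out artifacts/
dogprf compare   --config run.yaml --out artifacts/
dogprf dc-offset --config run.yaml --out artifacts/   # raw-data fits only
dogprf demo-filter --out artifacts/                   # 1D filtering demo
```

Every command snapshots its resolved configuration beside its outputs,
and outputs are bit-reproducible from the snapshot.

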