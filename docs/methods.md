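# Methods

## The model

A voxel's population receptive field (pRF) is modelled as an isotropic
Difference of Gaussians over visual-field position (degrees of visual
angle):

    f(x, y) = exp(-r² / 2σ₁²) − δ·exp(-r² / 2σ₂²),
    r² = (x − x₀)² + (y − y₀)²

with an excitatory centre of spread σ₁, an inhibitory surround of spread
σ₂ > σ₁, and a surround amplitude δ. The filter's total (DC) energy is

    ∬ f dx dy = 2π(σ₁² − δσ₂²),

so the model is **DC balanced** — a bandpass filter blind to uniform
luminance — exactly when δ = (σ₁/σ₂)². We call σ₁² − δσ₂² the **bias**;
its sign is the sign of the DC gain. Solving the balance condition for
the other parameters gives the balanced counterparts σ₁′ = σ₂√δ and
σ₂′ = σ₁/√δ used to ask how far a freely fitted model is from balance.

Two model variants are fitted per voxel:

* **unrestricted** — δ free within (0.1, 0.9). Below 0.1 the surround
  vanishes (σ₂ → ∞ under balance); above 0.9 the centre amplitude
  1 − δ collapses and beyond 1.0 the DoG inverts. Inverted models
  (σ₁ ≥ σ₂) are rejected everywhere.
* **balanced** — δ ≡ (σ₁/σ₂)², zero DC gain by construction.

Note the balanced space is *not* nested inside the unrestricted space
when σ₁/σ₂ < √0.1: the implied δ falls below the unrestricted bound.
The nesting sanity check (unrestricted RSS ≤ balanced RSS when seeded at
the balanced optimum) therefore applies only where the balanced δ is
interior.

### One- vs two-dimensional balance

The 1D filtering demonstration convolves signals with the *radial
section* of the DoG, not its 2D projection. The section's 1D integral is
√(2π)(σ₁ − δσ₂), which vanishes at δ = σ₁/σ₂ — not at the 2D balance
δ = (σ₁/σ₂)². `balanced_delta` gives the 2D condition used throughout
the pipeline; `balanced_delta_1d` gives the 1D-section condition used by
the filtering demo. Only a 1D-balanced kernel annihilates a constant
signal in the demo.

## Forward model

Per TR, the DoG field is multiplied with a binary stimulus aperture and
summed (the neural drive), the drive is convolved with a haemodynamic
response function (HRF) separately within each run (no bleed across the
run boundary), and the result is scaled by a gain β and shifted by a
constant: y(t) = p(t)β + c + e. β and c are estimated by ordinary least
squares; for non-normalised data the constant is the voxel's BOLD DC
offset.

The HRF is a difference of gamma densities (peak delay 6 s, undershoot
delay 16 s, unit dispersions, duration 32 s) normalised to unit maximum,
with undershoot ratio 0.4 giving a pronounced post-stimulus undershoot
(|min| ≈ 0.22 of the peak). The shape is injectable so alternative HRFs
can be tested; recovery should be demonstrated robust to moderate HRF
mismatch before interpreting fits of real data with an assumed shape.

## Stimulus protocol

Binary apertures on a square grid (default ±17.4°): a 45°-wide wedge
rotating once per 45 s OR-combined with a ring (thickness 0.25 of the
maximum eccentricity) sweeping the disc every 25 s, 225 volumes per run
at TR 1 s, two runs (clockwise+expanding then counter-clockwise+
contracting, the within-cycle time reversal), 450 frames total.

The wedge and ring cycle lengths are deliberately coprime-ish:
lcm(45, 25) = 225 s, exactly one run, so the joint wedge-ring phase
visits each visual-field position once per run. With *equal* cycles the
wedge angle and ring eccentricity are phase confounded — every position
along a spiral locus is co-stimulated — and pRF position becomes
unidentifiable. Any timing satisfying the volumes-per-run multiple
constraint can be configured, but equal cycles should be avoided.

## Fitting

Coarse-to-fine, per voxel, deterministic:

1. **Coarse stage.** HRF-convolved predictions are precomputed once per
   search space over a lattice of (x₀, y₀, σ₂, σ₁/σ₂, δ) — 21 sinh-warped
   positions per axis (≈1° spacing at fixation, ≈3.6° at the edge,
   matching the eccentricity scaling of pRF size), 8 log-spaced σ₂, 5
   ratios, 5 δ. The lattice point with the highest Pearson correlation
   to the observed series wins (correlation is invariant to β and c;
   ties resolve to the lowest linear index).
2. **Start refinement.** The wedge+ring protocol pins eccentricity much
   more sharply than polar angle (the ring crosses a pRF several times
   per run, the wedge once per rotation), so the coarse optimum often
   sits at the right eccentricity but a wrong angle or surround size. A
   deterministic scan of ~10² profiled-RSS candidates (rings of angles ×
   radial factors within the stimulated disc, then a geometric ladder of
   surround sizes, two rounds) moves the start into the correct basin at
   a small fraction of one simplex run's cost.
3. **Fine stage.** Nelder–Mead over smoothly reparameterised coordinates
   (x₀, y₀, log σ₂, logit ratio, scaled-logit δ), so σ₁ < σ₂ and
   0.1 < δ < 0.9 are hard bounds without penalties. β and c are profiled
   out in closed form at every evaluation. Explicit initial simplex
   steps (1° positions, 0.3 in log/logit coordinates) with one polish
   restart at quarter steps. Termination: parameter tolerance 1e-4,
   objective tolerance 1e-8 *relative to the starting RSS* (an absolute
   1e-8 is meaningless across raw-BOLD RSS scales), max 2000 evaluations
   per pass; all config-exposed.
4. Both variants share the coarse start; the balanced (simpler) variant
   is fitted first and its optimum seeds the unrestricted fit alongside
   the scanned start — whichever has the lower profiled RSS.

DoG evaluation inside the objective is truncated at 6σ₂ around the
centre (tail < 1.6e-8 of the peak), keeping the per-evaluation cost
proportional to the pixels actually covered.

## Model comparison

R² = 1 − RS/SS with SS = Σ(y − ȳ)², RS = Σ(y − ŷ)²; adjusted
R̄² = 1 − (1 − R²)(n − 1)/(n − p − 1); AIC = n·ln(RS/n) + 2p, with a
perfect fit mapped to −∞. Parameter counts: balanced 6 (x₀, y₀, σ₂,
ratio, β, c), unrestricted 7 (+δ); only Δp = 1 affects the comparison,
and the counts are config-exposed and reported. Voxels are screened by
R² > threshold (strict; 0.05/0.15/0.3 supported) in *both* variants —
the overlap set — and each overlap voxel is awarded to the variant with
the lower AIC (ties to balanced). The headline statistic is the percent
of overlap voxels preferring the balanced model, pooled and optionally
per grouping (e.g. hemisphere): with two models differing by one
parameter, the balanced model wins unless the unrestricted RSS is
smaller by a factor below exp(−2/n).

## Synthetic data

The generator emulates the structure the analysis assumes, and its
defaults are the package's study conditions:

* eccentricity uniform in (0.5, 17.4)°, uniform polar angle;
* surround size σ₂ = (0.5 + 0.2·ecc)·lognormal(0, 0.15) — linear
  eccentricity–size scaling typical of V1;
* σ₁/σ₂ uniform in (0.35, 0.7); balanced maps set δ = (σ₁/σ₂)², biased
  maps draw δ uniform in (0.15, 0.85), optionally resampled until
  |bias| exceeds a floor;
* gain β = uniform(0.8, 1.2) × 1.5/σ₁² — the 1/σ₁² factor makes BOLD
  response amplitude roughly independent of pRF size, as in real data,
  since the raw overlap drive grows with pRF area;
* DC offset = 300 − 30·ln(ecc) BOLD units (declining from fovea to
  periphery);
* noise: white Gaussian, sd 8 BOLD units, calibrated once so that fitted
  voxels land at a median R² near 0.45 (the 0.3–0.6 regime) under the
  default study conditions, plus a linear drift of 0.05 units/TR;
* seeding: one master seed; each voxel's stream is keyed by
  (seed, voxel id), so series are independent of iteration order.

What the generator does **not** emulate: temporal autocorrelation and
physiological oscillations, spatial correlation between voxels, motion,
multi-participant variance components, HRF variability. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not performance on scanner data.

### Attainable recovery precision

At the calibrated SNR a linearisation of the forward model
(Cramér–Rao) gives per-voxel estimator sds of roughly 0.9 (σ₁), 1.1
(σ₂) and 0.8 (δ) against population spreads of 0.6, 1.0 and 0.11 —
positions are recovered almost perfectly, sizes approximately, and δ
only weakly (its information lives in the near-collinear difference of
the two Gaussians' timecourses). The fitted recovery matches these
bounds, i.e. the fitter is near-efficient; δ cannot be pinned per voxel
at realistic noise, which is precisely why the balance-restricted
variant is attractive. What *is* sharply testable at noise is the
structure of balance scatters: fitted parameters against their
balance-computed counterparts.

## DC-offset analysis

For fits on raw data only (guarded by a preprocessing-state check), the
GLM constant per screened voxel is paired with the eccentricity of the
fitted centre; ordinary least squares of offset on ln(ecc) recovers the
generative gradient (natural log; the base affects only the slope's
scale). Multi-dataset pooling is a simple mean ± sd of per-dataset
slopes — a deliberate simplification of a mixed-effects
(random-coefficient) model, adequate because the recoverable content is
the slope's sign and magnitude. The amplitude-envelope check verifies
max(BOLD) ≥ offset ≥ min(BOLD) per voxel, i.e. the series varies around
its DC offset rather than deviating from a common baseline.

## Problem sizes and numerical choices

The test-suite and acceptance-script study conditions use a 51×51
analysis grid over ±17.4° (≈0.7°/cell, several cells per σ for the
smallest simulated pRFs) with the full 2×225-TR protocol; noiseless
round trips use 50 voxels, noisy recovery 200, model-comparison datasets
60–200, and the DC-offset gradient 12 voxels × 20 seeds. Balance
classification uses |bias| ≤ 1e-6 deg² (inclusive at the boundary);
integration is plain Riemann summation (accurate to ~1e-3 relative on
≥6σ₂ grids given Gaussian smoothness); the frequency axis is cycles per
degree with F(0) = 2π·bias. Degenerate inputs raise typed errors
(constant series, constant predictions, inverted DoGs, incompatible
protocol timing); per-voxel fit failures are recorded with
converged=false and never abort a map.

## Known limitations

* δ is weakly identified at realistic SNR (see above); unrestricted-fit
  δ values pile against the 0.1/0.9 bounds on noisy voxels.
* Receptive fields centred at the stimulus edge are only partially
  constrained; the estimated-eccentricity ≤ max-eccentricity screen is
  applied downstream, not during fitting.
* The coarse stage shares one lattice between variants; a
  variant-specific coarse stage would double the precompute for little
  gain.
* The 1D filtering demo and the 2D pipeline use different balance
  conditions by construction (see above); users comparing DC gains
  across dimensionalities must pick the matching condition.
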