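"""Coarse-to-fine per-voxel estimation of DoG pRF parameters.

Two model variants are fitted from a shared coarse start:

* ``unrestricted`` — delta is free within (0.1, 0.9);
* ``balanced``     — delta is tied to (sigma1/sigma2)^2, enforcing zero DC
  gain exactly by construction.

The coarse stage precomputes HRF-convolved predictions over a parameter
lattice once per search space and picks, per voxel, the lattice point with
the highest Pearson correlation to the observed series (correlation is
invariant to the voxel's unknown gain and offset).  The fine stage runs a
Nelder-Mead simplex over smoothly reparameterised coordinates

    (x0, y0, log sigma2, logit ratio[, scaled-logit delta])

with ratio = sigma1/sigma2 in (0, 1), so the sigma1 < sigma2 and
0.1 < delta < 0.9 restrictions are hard bounds without penalty terms.  The
gain beta and the constant are profiled out in closed form at every
objective evaluation, exactly as the per-voxel GLM implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dog_model import DoGParams, balanced_delta
from .errors import DegenerateSignalError, InputError, ParameterError
from .forward_model import VoxelTimeSeries, convolve_runs
from .stimulus import ApertureSequence

VARIANTS = ("unrestricted", "balanced")

#: parameter counts used for AIC: x0, y0, sigma2, ratio, beta, constant
#: (+ delta for the unrestricted variant)
N_PARAMS = {"balanced": 6, "unrestricted": 7}

_DELTA_LO, _DELTA_HI = 0.1, 0.9
_EPS = 1e-9


@dataclass(frozen=True)
class SearchSpace:
    """Coarse lattice over pRF parameters.

    Positions span +/- extent on each axis; sigma2 values are log-spaced;
    ratio = sigma1/sigma2 and delta lie strictly inside their restrictions.

    Because receptive-field size grows with eccentricity, the position
    lattice is sinh-warped by default: spacing near fixation is a few times
    finer than at the edge, so small foveal pRFs still land within one
    lattice cell of a coarse point.  ``foveal_density`` = 0 recovers a
    uniform lattice.
    """

    extent: float = 17.4
    n_positions: int = 21
    foveal_density: float = 2.0
    sigma2_values: tuple[float, ...] = tuple(np.geomspace(0.3, 8.7, 8).round(6))
    ratios: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8)
    deltas: tuple[float, ...] = (0.15, 0.325, 0.5, 0.675, 0.85)

    def __post_init__(self) -> None:
        if self.n_positions < 1 or self.extent <= 0:
            raise ParameterError("invalid position lattice")
        if self.foveal_density < 0:
            raise ParameterError("foveal_density must be non-negative")
        if any(s <= 0 for s in self.sigma2_values):
            raise ParameterError("sigma2 values must be positive")
        if any(not 0 < r < 1 for r in self.ratios):
            raise ParameterError("ratios must lie in (0, 1) so sigma1 < sigma2")
        if any(not _DELTA_LO < d < _DELTA_HI for d in self.deltas):
            raise ParameterError(f"deltas must lie in ({_DELTA_LO}, {_DELTA_HI})")

    @property
    def positions(self) -> np.ndarray:
        u = np.linspace(-1.0, 1.0, self.n_positions)
        a = self.foveal_density
        if a == 0:
            return self.extent * u
        return self.extent * np.sinh(a * u) / math.sinh(a)


@dataclass(frozen=True)
class FitOptions:
    """Simplex termination and evaluation controls (config-exposed)."""

    xatol: float = 1e-4
    fatol_rel: float = 1e-8  # objective tolerance, relative to the starting RSS
    maxfev: int = 2000
    restarts: int = 1  # extra simplex polish passes from the current optimum
    support_sigma: float = 6.0  # DoG evaluation truncated at this many sigma2
    angle_scan: int = 16  # angular start candidates per ring before the simplex
    radius_factors: tuple[float, ...] = (0.5, 0.7, 0.85, 1.0, 1.2, 1.5, 2.0)
    scan_sigma_factors: tuple[float, ...] = (1.0,)  # sigma spread in the angle pass
    sigma_factors: tuple[float, ...] = (0.25, 0.5, 0.71, 1.0, 1.41, 2.0, 4.0, 8.0)
    scan_rounds: int = 2


@dataclass(frozen=True)
class FitResult:
    variant: str
    params: DoGParams
    beta: float
    constant: float
    rss: float
    r2: float
    converged: bool
    n_params: int
    n_fev: int = 0


class CoarseGrid:
    """Precomputed, standardised predictions for every search-space point.

    Building the grid costs one pass over positions x unique sigma values;
    it is shared across voxels (and across datasets using the same
    apertures and HRF).
    """

    def __init__(
        self,
        space: SearchSpace,
        apertures: ApertureSequence,
        hrf_kernel: np.ndarray,
        position_chunk: int = 16,
    ) -> None:
        self.space = space
        self.apertures = apertures
        self.hrf_kernel = np.asarray(hrf_kernel, dtype=float)

        pos = space.positions
        sigma2s = np.asarray(space.sigma2_values)
        ratios = np.asarray(space.ratios)
        deltas = np.asarray(space.deltas)

        sigma1s = np.unique(np.round(np.outer(ratios, sigma2s).ravel(), 9))
        all_sigmas = np.unique(np.concatenate([sigma2s, sigma1s]))
        sig_index = {s: i for i, s in enumerate(all_sigmas)}

        grid = apertures.grid
        X, Y = grid.coords
        xs, ys = X.ravel(), Y.ravel()
        n_frames = apertures.n_frames
        masks_t = apertures.matrix_by_pixel  # (n_pix, n_frames)

        n_pos = pos.size
        # convolved single-Gaussian timecourses, (n_pos, n_pos, n_sigma, T)
        gauss_tc = np.empty((n_pos, n_pos, all_sigmas.size, n_frames))
        inv = 1.0 / (2.0 * all_sigmas**2)
        for iy, y0 in enumerate(pos):
            for ix, x0 in enumerate(pos):
                r2 = (xs - x0) ** 2 + (ys - y0) ** 2
                fields = np.exp(-np.outer(inv, r2))  # (n_sigma, n_pix)
                tc = fields @ masks_t  # (n_sigma, T)
                gauss_tc[iy, ix] = convolve_runs(tc, self.hrf_kernel, apertures.run_lengths)

        # assemble DoG combos: pred = tc(sigma1) - delta * tc(sigma2)
        combos = []
        preds = []
        for iy, y0 in enumerate(pos):
            for ix, x0 in enumerate(pos):
                for s2 in sigma2s:
                    t2 = gauss_tc[iy, ix, sig_index[s2]]
                    for r in ratios:
                        s1 = round(r * s2, 9)
                        t1 = gauss_tc[iy, ix, sig_index[s1]]
                        for d in deltas:
                            combos.append((x0, y0, s1, s2, d))
                            preds.append(t1 - d * t2)
        self.params_table = pd.DataFrame(
            combos, columns=["x0", "y0", "sigma1", "sigma2", "delta"]
        )
        P = np.asarray(preds)
        P -= P.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(P, axis=1)
        good = norms > 1e-12
        P[good] /= norms[good, None]
        P[~good] = 0.0  # degenerate (flat) predictions can never win
        self.predictions_std = P

    def best_match(self, observed: VoxelTimeSeries | np.ndarray) -> tuple[int, DoGParams, float]:
        """Index, parameters and correlation of the best-matching point."""
        y = observed.samples if isinstance(observed, VoxelTimeSeries) else np.asarray(observed)
        yc = y - y.mean()
        norm = np.linalg.norm(yc)
        if norm == 0:
            raise DegenerateSignalError("observed series is constant")
        corr = self.predictions_std @ (yc / norm)
        idx = int(np.argmax(corr))  # ties resolve to the lowest linear index
        row = self.params_table.iloc[idx]
        params = DoGParams(row.x0, row.y0, row.sigma1, row.sigma2, row.delta)
        return idx, params, float(corr[idx])


def coarse_fit(observed: VoxelTimeSeries | np.ndarray, coarse: CoarseGrid) -> DoGParams:
    """Best coarse-lattice parameters for one voxel (correlation maximiser)."""
    return coarse.best_match(observed)[1]


# ---------------------------------------------------------------------------
# Fine stage


def _logit(p: float) -> float:
    p = min(max(p, _EPS), 1.0 - _EPS)
    return math.log(p / (1.0 - p))


def _expit(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _encode(params: DoGParams, variant: str) -> np.ndarray:
    ratio = params.sigma1 / params.sigma2
    vec = [params.x0, params.y0, math.log(params.sigma2), _logit(ratio)]
    if variant == "unrestricted":
        vec.append(_logit((params.delta - _DELTA_LO) / (_DELTA_HI - _DELTA_LO)))
    return np.array(vec)


def _decode(vec: np.ndarray, variant: str) -> DoGParams:
    x0, y0 = float(vec[0]), float(vec[1])
    sigma2 = math.exp(min(float(vec[2]), 50.0))
    ratio = _expit(float(vec[3]))
    sigma1 = ratio * sigma2
    if variant == "balanced":
        delta = balanced_delta(sigma1, sigma2)
    else:
        delta = _DELTA_LO + (_DELTA_HI - _DELTA_LO) * _expit(float(vec[4]))
    return DoGParams(x0, y0, sigma1, sigma2, delta)


class _Objective:
    """Profiled residual sum of squares for one voxel.

    The DoG field is evaluated only inside a +/- support_sigma * sigma2 box
    around the centre (the Gaussian tail beyond it is < 1.6e-8 of the peak),
    which keeps each evaluation linear in the truly covered pixels.
    """

    def __init__(
        self,
        observed: np.ndarray,
        apertures: ApertureSequence,
        hrf_kernel: np.ndarray,
        variant: str,
        support_sigma: float,
    ) -> None:
        self.y = np.asarray(observed, dtype=float)
        self.yc = self.y - self.y.mean()
        self.sst = float(self.yc @ self.yc)
        if self.sst == 0:
            raise DegenerateSignalError("observed series is constant")
        self.apertures = apertures
        self.kernel = hrf_kernel
        self.variant = variant
        self.support_sigma = support_sigma
        grid = apertures.grid
        self.axis = grid.axis
        self.res = grid.resolution
        self.masks_t = apertures.matrix_by_pixel
        self.n_fev = 0

    def drive(self, params: DoGParams) -> np.ndarray:
        half = self.support_sigma * params.sigma2
        ax = self.axis
        i0, i1 = np.searchsorted(ax, [params.y0 - half, params.y0 + half])
        j0, j1 = np.searchsorted(ax, [params.x0 - half, params.x0 + half])
        i1 = min(i1 + 1, self.res)
        j1 = min(j1 + 1, self.res)
        if i0 >= i1 or j0 >= j1:
            return np.zeros(self.apertures.n_frames)
        ysub = ax[i0:i1, None]
        xsub = ax[None, j0:j1]
        r2 = (xsub - params.x0) ** 2 + (ysub - params.y0) ** 2
        f = np.exp(-r2 / (2 * params.sigma1**2)) - params.delta * np.exp(
            -r2 / (2 * params.sigma2**2)
        )
        cols = (np.arange(i0, i1)[:, None] * self.res + np.arange(j0, j1)[None, :]).ravel()
        return f.ravel() @ self.masks_t[cols]

    def rss_for(self, params: DoGParams) -> tuple[float, float, float]:
        """(rss, beta, constant) with the GLM profiled out in closed form."""
        drive = self.drive(params)
        p = convolve_runs(drive, self.kernel, self.apertures.run_lengths)
        pm = p.mean()
        pc = p - pm
        vp = float(pc @ pc)
        if vp < 1e-12:
            return self.sst, 0.0, float(self.y.mean())
        cov = float(pc @ self.yc)
        beta = cov / vp
        constant = float(self.y.mean() - beta * pm)
        rss = self.sst - beta * cov
        return max(rss, 0.0), beta, constant

    def __call__(self, vec: np.ndarray) -> float:
        self.n_fev += 1
        try:
            params = _decode(vec, self.variant)
        except (OverflowError, ParameterError):
            return 2.0 * self.sst
        rss, _, _ = self.rss_for(params)
        if not math.isfinite(rss):
            return 2.0 * self.sst
        return rss


def _scan_start(obj: "_Objective", start: DoGParams, options: FitOptions) -> DoGParams:
    """Cheap deterministic start refinement before the simplex.

    The wedge+ring protocol pins eccentricity much more sharply than polar
    angle (the ring sweeps several times per run, the wedge passes once per
    rotation), so the coarse optimum frequently sits near the right
    eccentricity but at a wrong angle or with a wrong surround size.  Scan
    profiled-RSS candidates over (a) a few rings of angles around fixation,
    (b) a geometric ladder of surround sizes at fixed sigma1/sigma2, and
    (c) a final angle pass at the chosen size.  ~100 objective evaluations,
    a small fraction of one simplex run.
    """
    if options.angle_scan <= 1:
        return start
    best = (obj.rss_for(start)[0], start)
    extent = obj.apertures.grid.extent

    def angle_pass(best):
        _, s = best
        ecc = math.hypot(s.x0, s.y0)
        if ecc < 1e-6:
            return best
        base = math.atan2(s.y0, s.x0)
        ratio = s.sigma1 / s.sigma2
        for fac in options.radius_factors:
            radius = fac * ecc
            if radius > extent:  # centres outside the stimulus are not
                continue         # useful starts (and invite runaway betas)
            for sfac in options.scan_sigma_factors:
                sigma2 = s.sigma2 * sfac
                if sigma2 > extent:
                    continue
                for k in range(options.angle_scan):
                    theta = base + 2.0 * math.pi * k / options.angle_scan
                    cand = DoGParams(radius * math.cos(theta),
                                     radius * math.sin(theta),
                                     ratio * sigma2, sigma2, s.delta)
                    rss = obj.rss_for(cand)[0]
                    if rss < best[0]:
                        best = (rss, cand)
        return best

    def sigma_pass(best):
        _, s = best
        ratio = s.sigma1 / s.sigma2
        for fac in options.sigma_factors:
            sigma2 = s.sigma2 * fac
            if sigma2 > extent:  # a surround wider than the stimulated field
                continue         # is indistinguishable from a flat response
            cand = DoGParams(s.x0, s.y0, ratio * sigma2, sigma2, s.delta)
            rss = obj.rss_for(cand)[0]
            if rss < best[0]:
                best = (rss, cand)
        return best

    for _ in range(max(options.scan_rounds, 1)):
        best = angle_pass(best)
        best = sigma_pass(best)
    return best[1]


def fine_fit(
    observed: VoxelTimeSeries | np.ndarray,
    start: DoGParams,
    variant: str,
    apertures: ApertureSequence,
    hrf_kernel: np.ndarray,
    options: FitOptions = FitOptions(),
    extra_starts: Sequence[DoGParams] = (),
) -> FitResult:
    """Nelder-Mead refinement of one voxel's pRF from a coarse start.

    beta and the constant are profiled out at every objective evaluation;
    the returned RSS never exceeds the RSS at the start (the simplex result
    is the best vertex seen, and the start is a vertex of the initial
    simplex).  ``extra_starts`` offers additional candidate starts (e.g.
    the balanced variant's optimum when seeding the unrestricted fit); the
    candidate with the lowest profiled RSS wins.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}")
    y = observed.samples if isinstance(observed, VoxelTimeSeries) else np.asarray(observed)
    obj = _Objective(y, apertures, hrf_kernel, variant, options.support_sigma)

    start = _scan_start(obj, start, options)
    for cand in extra_starts:
        if variant == "unrestricted" and not _DELTA_LO < cand.delta < _DELTA_HI:
            cand = DoGParams(cand.x0, cand.y0, cand.sigma1, cand.sigma2,
                             min(max(cand.delta, _DELTA_LO + 1e-6), _DELTA_HI - 1e-6))
        if obj.rss_for(cand)[0] < obj.rss_for(start)[0]:
            start = cand

    x = _encode(start, variant)
    f_start = obj(x)
    if not math.isfinite(f_start):
        raise InputError("objective is not finite at the starting parameters")
    fatol = max(options.fatol_rel * max(f_start, 1e-300), 1e-300)

    best_x, best_f = x, f_start
    converged = False
    # explicit simplex scales: half a coarse-lattice cell for the positions,
    # a moderate step in the log/logit coordinates; shrunk on restarts
    steps = np.array([1.0, 1.0] + [0.3] * (x.size - 2))
    for attempt in range(1 + max(options.restarts, 0)):
        simplex = np.vstack([best_x, best_x + np.diag(steps)])
        res = minimize(
            obj,
            best_x,
            method="Nelder-Mead",
            options={
                "xatol": options.xatol,
                "fatol": fatol,
                "maxfev": options.maxfev,
                "disp": False,
                "initial_simplex": simplex,
            },
        )
        steps = steps / 4.0
        improved = res.fun < best_f - fatol
        if res.fun <= best_f:
            best_x, best_f = res.x, float(res.fun)
        converged = bool(res.success)
        if not improved:
            break

    params = _decode(best_x, variant)
    rss, beta, constant = obj.rss_for(params)
    r2 = 1.0 - rss / obj.sst
    return FitResult(
        variant=variant,
        params=params,
        beta=beta,
        constant=constant,
        rss=rss,
        r2=r2,
        converged=converged,
        n_params=N_PARAMS[variant],
        n_fev=obj.n_fev,
    )


def _result_row(voxel_id: int, result: FitResult, preprocessing: str) -> dict:
    p = result.params
    return {
        "voxel_id": voxel_id,
        "variant": result.variant,
        "x0": p.x0,
        "y0": p.y0,
        "sigma1": p.sigma1,
        "sigma2": p.sigma2,
        "delta": p.delta,
        "beta": result.beta,
        "constant": result.constant,
        "rss": result.rss,
        "r2": result.r2,
        "converged": result.converged,
        "n_params": result.n_params,
        "preprocessing": preprocessing,
    }


def fit_map(
    dataset: Sequence[VoxelTimeSeries],
    apertures: ApertureSequence,
    hrf_kernel: np.ndarray,
    coarse: CoarseGrid | None = None,
    space: SearchSpace | None = None,
    options: FitOptions = FitOptions(),
    variants: Iterable[str] = VARIANTS,
) -> pd.DataFrame:
    """Fit every voxel independently, both variants from the shared coarse
    start (the unrestricted coarse optimum; the balanced start ties delta to
    ratio^2).  Per-voxel failures are recorded with converged=False and the
    coarse parameters; the map never aborts.

    Returns one row per voxel per variant with columns voxel_id, variant,
    x0, y0, sigma1, sigma2, delta, beta, constant, rss, r2, converged,
    n_params, preprocessing.
    """
    if coarse is None:
        coarse = CoarseGrid(space or SearchSpace(extent=apertures.grid.extent),
                            apertures, hrf_kernel)
    rows = []
    for ts in dataset:
        state = ts.state
        try:
            start = coarse_fit(ts, coarse)
        except DegenerateSignalError:
            for variant in variants:
                rows.append(_result_row(ts.voxel_id, FitResult(
                    variant, DoGParams(0, 0, 1.0, 2.0, 0.25), 0.0, 0.0,
                    rss=float("nan"), r2=float("nan"), converged=False,
                    n_params=N_PARAMS[variant]), state))
            continue
        # fit the balanced (nested) variant first; its optimum seeds the
        # unrestricted fit alongside the coarse start
        results: dict[str, FitResult] = {}
        order = sorted(variants, key=lambda v: v != "balanced")
        for variant in order:
            s = start
            extra: tuple[DoGParams, ...] = ()
            if variant == "balanced":
                s = DoGParams(s.x0, s.y0, s.sigma1, s.sigma2,
                              balanced_delta(s.sigma1, s.sigma2))
            elif "balanced" in results and results["balanced"].converged:
                extra = (results["balanced"].params,)
            try:
                result = fine_fit(ts, s, variant, apertures, hrf_kernel,
                                  options, extra_starts=extra)
            except Exception:
                result = FitResult(variant, s, 0.0, 0.0, float("nan"),
                                   float("nan"), False, N_PARAMS[variant])
            results[variant] = result
        for variant in variants:
            rows.append(_result_row(ts.voxel_id, results[variant], state))
    return pd.DataFrame(rows)
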