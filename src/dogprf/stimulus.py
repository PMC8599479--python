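"""Binary stimulus apertures for the wedge+ring retinotopic mapping protocol.

The acquisition protocol pairs a rotating wedge with a simultaneously
expanding (or contracting) ring; one run of each direction is concatenated
into a single time series.  Apertures are binary visual-field masks, one per
TR, restricted to the stimulated disc.  The textured carrier (high-contrast
ripples updated at 8 Hz) is abstracted away: the forward model consumes
binary masks only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .dog_model import VisualFieldGrid
from .errors import ConfigError, InputError

DIRECTIONS = ("cw_expanding", "ccw_contracting")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and geometry of the wedge+ring protocol.

    Defaults: TR 1 s, 225 volumes per run, 45 deg wedge rotating once per
    45 s, ring of thickness 0.25*max_eccentricity sweeping the disc every
    25 s, maximum eccentricity 17.4 deg.  The wedge and ring cycles are
    deliberately different (joint period lcm(45, 25) = 225 s, exactly one
    run): with equal cycles, polar angle and eccentricity are phase
    confounded — every position along a spiral locus is co-stimulated —
    and pRF positions become unidentifiable.
    """

    tr: float = 1.0
    volumes_per_run: int = 225
    wedge_width: float = 45.0
    ring_duty: float = 0.25
    wedge_cycle: float = 45.0
    ring_cycle: float = 25.0
    max_eccentricity: float = 17.4
    wedge_start_angle: float = 90.0

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.volumes_per_run <= 0:
            raise ConfigError("tr and volumes_per_run must be positive")
        if not 0.0 <= self.wedge_width <= 360.0:
            raise ConfigError("wedge_width must lie in [0, 360] degrees")
        if not 0.0 < self.ring_duty <= 1.0:
            raise ConfigError("ring_duty must lie in (0, 1]")
        run_duration = self.volumes_per_run * self.tr
        for name, cycle in (("wedge_cycle", self.wedge_cycle), ("ring_cycle", self.ring_cycle)):
            if cycle <= 0:
                raise ConfigError(f"{name} must be positive")
            n_cycles = run_duration / cycle
            if abs(n_cycles - round(n_cycles)) > 1e-9:
                raise ConfigError(
                    f"run duration {run_duration}s is not an integer multiple of "
                    f"{name}={cycle}s"
                )


@dataclass(frozen=True)
class ApertureSequence:
    """Time-ordered stack of binary visual-field masks sharing one grid."""

    masks: np.ndarray  # (n_frames, resolution, resolution), uint8
    grid: VisualFieldGrid
    tr: float
    run_lengths: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.masks.ndim != 3:
            raise InputError("masks must be a (frames, rows, cols) stack")
        if self.masks.shape[1:] != (self.grid.resolution, self.grid.resolution):
            raise InputError("mask shape does not match the grid resolution")
        if self.run_lengths is None:
            object.__setattr__(self, "run_lengths", (self.masks.shape[0],))
        if sum(self.run_lengths) != self.masks.shape[0]:
            raise InputError("run_lengths must sum to the number of frames")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @cached_property
    def matrix(self) -> np.ndarray:
        """(n_frames, n_pixels) float view used by the forward model."""
        return self.masks.reshape(self.n_frames, -1).astype(np.float64)

    @cached_property
    def matrix_by_pixel(self) -> np.ndarray:
        """(n_pixels, n_frames) contiguous copy for pixel-subset products."""
        return np.ascontiguousarray(self.matrix.T)

    def save(self, prefix: str | Path) -> None:
        """Write the mask tensor (``<prefix>.npy``) and a JSON sidecar
        (``<prefix>.json``) with grid, TR and run-structure metadata."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.masks)
        meta = {
            "extent": self.grid.extent,
            "resolution": self.grid.resolution,
            "tr": self.tr,
            "n_frames": self.n_frames,
            "run_lengths": list(self.run_lengths),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "ApertureSequence":
        prefix = Path(prefix)
        masks = np.load(prefix.with_suffix(".npy"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        grid = VisualFieldGrid(meta["extent"], meta["resolution"])
        return cls(masks.astype(np.uint8), grid, meta["tr"], tuple(meta["run_lengths"]))


def wedge_mask(
    center_angle: float, width: float, grid: VisualFieldGrid, max_ecc: float
) -> np.ndarray:
    """Binary wedge: samples whose polar angle lies within +/- width/2 of
    ``center_angle`` (mod 360) and whose eccentricity is <= max_ecc."""
    if width < 0 or width > 360:
        raise InputError("wedge width must lie in [0, 360] degrees")
    in_disc = grid.eccentricity <= max_ecc
    if width == 0:
        return np.zeros_like(in_disc, dtype=np.uint8)
    if width == 360:
        return in_disc.astype(np.uint8)
    diff = (grid.polar_angle - center_angle + 180.0) % 360.0 - 180.0
    return (in_disc & (np.abs(diff) <= width / 2.0)).astype(np.uint8)


def ring_mask(r_inner: float, r_outer: float, grid: VisualFieldGrid) -> np.ndarray:
    """Binary annulus: r_inner <= eccentricity < r_outer (half-open)."""
    if r_inner < 0 or r_inner > r_outer:
        raise InputError("require 0 <= r_inner <= r_outer")
    ecc = grid.eccentricity
    return ((ecc >= r_inner) & (ecc < r_outer)).astype(np.uint8)


def _ring_at_phase(phase: float, duty: float, max_ecc: float, grid: VisualFieldGrid) -> np.ndarray:
    """Ring with inner edge at phase*max_ecc, thickness duty*max_ecc,
    wrapping past the disc edge back into the fovea."""
    inner = phase * max_ecc
    outer = inner + duty * max_ecc
    mask = ring_mask(inner, min(outer, max_ecc + grid.cell_size), grid)
    # include the outer rim: eccentricity == max_ecc samples belong to the disc
    mask &= (grid.eccentricity <= max_ecc).astype(np.uint8)
    if outer > max_ecc:
        mask |= ring_mask(0.0, outer - max_ecc, grid)
    return mask


def build_protocol(config: ProtocolConfig, grid: VisualFieldGrid) -> ApertureSequence:
    """Build the two-run aperture sequence.

    Run 1: clockwise wedge + expanding ring.  Run 2: counter-clockwise wedge
    + contracting ring (the within-cycle time reversal of run 1's phases).
    Each frame is the elementwise OR of that TR's wedge and ring masks.
    """
    frames = []
    run_lengths = []
    for direction in DIRECTIONS:
        run = _build_run(config, grid, direction)
        frames.append(run)
        run_lengths.append(run.shape[0])
    masks = np.concatenate(frames, axis=0)
    return ApertureSequence(masks, grid, config.tr, tuple(run_lengths))


def _build_run(config: ProtocolConfig, grid: VisualFieldGrid, direction: str) -> np.ndarray:
    if direction not in DIRECTIONS:
        raise ConfigError(f"unknown direction {direction!r}")
    n = config.volumes_per_run
    out = np.empty((n, grid.resolution, grid.resolution), dtype=np.uint8)
    for t in range(n):
        time = t * config.tr
        if direction == "cw_expanding":
            angle = config.wedge_start_angle - 360.0 * time / config.wedge_cycle
            ring_phase = (time % config.ring_cycle) / config.ring_cycle
        else:
            angle = config.wedge_start_angle + 360.0 * time / config.wedge_cycle
            rev = (config.ring_cycle - time) % config.ring_cycle
            ring_phase = rev / config.ring_cycle
        wedge = wedge_mask(angle, config.wedge_width, grid, config.max_eccentricity)
        ring = _ring_at_phase(ring_phase, config.ring_duty, config.max_eccentricity, grid)
        out[t] = wedge | ring
    return out
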