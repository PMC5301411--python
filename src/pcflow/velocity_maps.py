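"""Velocity mapping from reconstructed complex image pairs.

The through-plane velocity is encoded in the phase difference between the
flow-encoded and flow-compensated series:

    V(r, t) = dphi(r, t) / pi * VENC,   dphi in (-pi, pi]

so a phase difference of pi maps to the encoding velocity VENC and true
velocities beyond +/-VENC alias (wrap around); no unwrapping is attempted.
The phase difference is computed through the complex product
``angle(rho_v * conj(rho_1))`` rather than by subtracting angles, which
avoids double-wrapping artifacts.

Eddy currents leave a smooth, temporally constant background phase offset;
`background_phase_correction` removes it by fitting a low-order 2-D
polynomial to the temporal-mean phase over automatically detected static
tissue and subtracting the fitted surface from every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kt_data import Grid2D, ImageSeries, ValidationError, VelocitySeries

__all__ = [
    "PhaseSeries",
    "phase_difference",
    "background_phase_correction",
    "to_velocity",
    "poly2d_design_matrix",
]


@dataclass
class PhaseSeries:
    """Phase-difference maps dphi(r, t) in radians, wrapped to (-pi, pi].

    ``reliable`` flags voxels whose magnitude supports a meaningful phase
    (False where both input magnitudes fall below the floor)."""

    values: np.ndarray        # (N, M) float radians
    frame_times: np.ndarray   # (M,) ms
    grid: Grid2D
    reliable: np.ndarray | None = None  # (N,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def validate(self) -> None:
        if np.any((self.values <= -np.pi) | (self.values > np.pi)):
            raise ValidationError("phase values outside (-pi, pi]")


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def phase_difference(encoded: ImageSeries, compensated: ImageSeries,
                     magnitude_floor_rel: float = 1e-3) -> PhaseSeries:
    """Wrapped phase difference ``angle(rho_v * conj(rho_1))`` per voxel and
    frame. Voxels whose magnitude stays below ``magnitude_floor_rel`` times
    the series maximum in both inputs are flagged unreliable."""
    if encoded.data.shape != compensated.data.shape:
        raise ValidationError(
            f"series shapes differ: {encoded.data.shape} vs "
            f"{compensated.data.shape}")
    if not np.allclose(encoded.frame_times, compensated.frame_times):
        raise ValidationError("series frame_times differ")
    prod = encoded.data * np.conj(compensated.data)
    phi = _wrap(np.angle(prod))
    floor = magnitude_floor_rel * max(np.abs(encoded.data).max(),
                                      np.abs(compensated.data).max(), 1e-30)
    weak = (np.abs(encoded.data) < floor) & (np.abs(compensated.data) < floor)
    reliable = ~np.all(weak, axis=1)
    return PhaseSeries(phi, encoded.frame_times, encoded.grid, reliable)


def poly2d_design_matrix(order: int, ny: int, nx: int) -> np.ndarray:
    """Design matrix of 2-D monomials up to total degree ``order`` on
    normalised coordinates x, y in [-1, 1]; shape (ny*nx, n_coeffs)."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    y = (2.0 * yy / max(ny - 1, 1) - 1.0).ravel()
    x = (2.0 * xx / max(nx - 1, 1) - 1.0).ravel()
    cols = [x ** i * y ** j
            for d in range(order + 1)
            for i, j in [(i, d - i) for i in range(d + 1)]]
    return np.stack(cols, axis=1)


def background_phase_correction(phase: PhaseSeries, magnitude: ImageSeries,
                                order: int = 2,
                                magnitude_rel_threshold: float = 0.1,
                                temporal_std_threshold: float = 0.1):
    """Remove the eddy-current background phase.

    Static tissue is detected as voxels whose temporal-mean magnitude
    exceeds ``magnitude_rel_threshold`` times the maximum AND whose phase
    difference has temporal standard deviation below
    ``temporal_std_threshold`` rad (pulsatile lumen voxels fail this). A
    2-D polynomial of total degree ``order`` (0, 1 or 2) is least-squares
    fitted to the temporal-mean phase over that mask and subtracted from
    every frame; the result is re-wrapped to (-pi, pi].

    Returns the corrected :class:`PhaseSeries` and the static mask (flat
    boolean array of length N)."""
    if order not in (0, 1, 2):
        raise ValidationError(f"polynomial order must be 0, 1 or 2, got {order}")
    mean_mag = np.mean(np.abs(magnitude.data), axis=1)
    tstd = np.std(phase.values, axis=1)
    static = (mean_mag > magnitude_rel_threshold * mean_mag.max()) \
        & (tstd < temporal_std_threshold)
    ny, nx = magnitude.grid.shape
    A = poly2d_design_matrix(order, ny, nx)
    if static.sum() < A.shape[1]:
        raise ValidationError(
            f"static mask has {int(static.sum())} voxels, fewer than the "
            f"{A.shape[1]} polynomial coefficients")
    mean_phi = np.mean(phase.values, axis=1)
    coef, *_ = np.linalg.lstsq(A[static], mean_phi[static], rcond=None)
    surface = A @ coef
    corrected = _wrap(phase.values - surface[:, None])
    out = PhaseSeries(corrected, phase.frame_times, phase.grid, phase.reliable)
    return out, static


def to_velocity(phase: PhaseSeries, VENC: float) -> VelocitySeries:
    """Scale the wrapped phase difference to velocity: V = dphi / pi * VENC.

    Linear and odd in dphi; bounded by VENC because the phase is wrapped."""
    if VENC <= 0:
        raise ValidationError("VENC must be positive")
    return VelocitySeries(phase.values / np.pi * VENC, phase.frame_times,
                          phase.grid, VENC)
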