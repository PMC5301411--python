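"""Digital pulsatile-flow phantom.

Emulates the bench experiment used to validate real-time phase-contrast
flow imaging: a straight plastic tube (circular cross-section, default
15 mm diameter) carrying blood-mimicking fluid with a pump-programmed
waveform, immersed in a static water bath. Through-plane velocity is
encoded in the image phase: the flow-compensated image (v = 1) has zero
phase, the flow-encoded image (v = 2) carries ``pi * v_true / VENC``
radians inside the lumen.

Two stock waveforms are provided:

* **I** — a 1 s raised-cosine "bell" followed by constant flow, repeating
  at a 2 s period (periodic; a gated cine acquisition can capture it);
* **II** — two different 1 s bells separated by constant flow, repeating
  at a 4 s period (aperiodic with respect to an assumed 2 s beat; the
  case where gated cine folds the two bells into one wrong peak).

`acquire` applies the full multi-coil forward model: coil-weighted images,
centred unitary 2-D FFT, line-by-line (k,t) sampling per a
:class:`~pcflow.sampling.SamplingPattern`, plus i.i.d. complex Gaussian
noise (``noise_sd`` is the standard deviation per complex sample; the real
and imaginary parts each get ``noise_sd / sqrt(2)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fourier import fft2c
from .kt_data import (FlowWaveform, Grid2D, ImageSeries, KTSamples, ROIMask,
                      SensitivityMaps, ValidationError)
from .sampling import SamplingPattern

__all__ = [
    "PhantomGeometry",
    "WaveformSpec",
    "make_waveform",
    "sample_periodic",
    "render_truth",
    "make_sensitivities",
    "acquire",
]


@dataclass
class PhantomGeometry:
    """Circular vessel inside an elliptical static-tissue bath."""

    grid: Grid2D
    vessel_center: tuple[float, float] = None  # (row, col) px; default centre
    vessel_radius_mm: float = 7.5              # 15-mm-diameter tube
    tissue_semiaxes: tuple[float, float] = None  # (rows, cols) px
    tissue_contrast: float = 0.8               # bath magnitude vs lumen 1.0

    def __post_init__(self) -> None:
        ny, nx = self.grid.shape
        if self.vessel_center is None:
            self.vessel_center = (ny / 2.0, nx / 2.0)
        if self.tissue_semiaxes is None:
            self.tissue_semiaxes = (0.42 * ny, 0.42 * nx)
        if self.vessel_radius_mm <= 0:
            raise ValidationError("vessel radius must be positive")
        r_px = self.vessel_radius_mm / min(self.grid.pixel_size)
        cy, cx = self.vessel_center
        if (cy - r_px < 0 or cy + r_px > ny or cx - r_px < 0 or cx + r_px > nx):
            raise ValidationError("vessel does not fit inside the grid")

    def _radius_mm_map(self) -> np.ndarray:
        """Distance (mm) of each pixel centre from the vessel axis."""
        ny, nx = self.grid.shape
        dy, dx = self.grid.pixel_size
        yy, xx = np.mgrid[0:ny, 0:nx]
        return np.hypot((yy + 0.5 - self.vessel_center[0]) * dy,
                        (xx + 0.5 - self.vessel_center[1]) * dx)

    def vessel_mask(self) -> np.ndarray:
        return self._radius_mm_map() <= self.vessel_radius_mm

    def tissue_mask(self) -> np.ndarray:
        """Static bath: ellipse minus the lumen."""
        ny, nx = self.grid.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        ell = (((yy + 0.5 - ny / 2.0) / self.tissue_semiaxes[0]) ** 2
               + ((xx + 0.5 - nx / 2.0) / self.tissue_semiaxes[1]) ** 2) <= 1.0
        return ell & ~self.vessel_mask()

    def magnitude(self) -> np.ndarray:
        mag = np.zeros(self.grid.shape)
        mag[self.tissue_mask()] = self.tissue_contrast
        mag[self.vessel_mask()] = 1.0
        return mag

    def vessel_roi(self) -> ROIMask:
        return ROIMask(self.vessel_mask(), self.grid.pixel_area_mm2)

    def static_roi(self) -> ROIMask:
        return ROIMask(self.tissue_mask(), self.grid.pixel_area_mm2)

    def background_roi(self) -> ROIMask:
        return ROIMask(~(self.tissue_mask() | self.vessel_mask()),
                       self.grid.pixel_area_mm2)


@dataclass
class WaveformSpec:
    """Pump programme for the phantom.

    kind ``I``: one 1 s raised-cosine bell per period, constant flow for the
    remainder. kind ``II``: two bells per period (second peak =
    ``second_peak_ratio`` x first), separated by constant segments; the
    default period is 4 s. kind ``custom``: pass-through of user samples.
    """

    kind: str = "I"
    period_s: float = 2.0
    peak_cm_s: float = 60.0
    baseline_cm_s: float = 10.0
    sample_interval_s: float = 0.01
    second_peak_ratio: float = 0.6
    bell_duration_s: float = 1.0
    custom_times: np.ndarray | None = None
    custom_values: np.ndarray | None = None


def _bell(t: np.ndarray, start: float, duration: float, baseline: float,
          peak: float) -> np.ndarray:
    """Raised-cosine lobe from baseline up to peak and back."""
    u = (t - start) / duration
    lobe = np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2
    return baseline + (peak - baseline) * lobe


def make_waveform(spec: WaveformSpec) -> FlowWaveform:
    """Sample one period of the specified pump waveform."""
    if spec.kind == "custom":
        if spec.custom_times is None or spec.custom_values is None:
            raise ValidationError("custom waveform requires times and values")
        return FlowWaveform(np.asarray(spec.custom_times, float),
                            np.asarray(spec.custom_values, float))
    if spec.period_s <= 0:
        raise ValidationError(f"period must be positive, got {spec.period_s}")
    n_bells = {"I": 1, "II": 2}.get(spec.kind)
    if n_bells is None:
        raise ValidationError(f"unknown waveform kind '{spec.kind}'")
    if spec.period_s < n_bells * spec.bell_duration_s:
        raise ValidationError("period too short for the bell segments")
    t = np.arange(0.0, spec.period_s, spec.sample_interval_s)
    vals = np.full_like(t, spec.baseline_cm_s)
    in1 = (t >= 0) & (t < spec.bell_duration_s)
    vals[in1] = _bell(t[in1], 0.0, spec.bell_duration_s,
                      spec.baseline_cm_s, spec.peak_cm_s)
    if spec.kind == "II":
        # Second bell centred in the second half of the period.
        gap = (spec.period_s - 2 * spec.bell_duration_s) / 2.0
        start2 = spec.bell_duration_s + gap
        in2 = (t >= start2) & (t < start2 + spec.bell_duration_s)
        vals[in2] = _bell(t[in2], start2, spec.bell_duration_s,
                          spec.baseline_cm_s,
                          spec.second_peak_ratio * spec.peak_cm_s)
    return FlowWaveform(t, vals)


def sample_periodic(wave: FlowWaveform, t_s: np.ndarray) -> np.ndarray:
    """Evaluate a uniformly sampled waveform at arbitrary times, extending it
    periodically (period = sample span plus one interval)."""
    t_s = np.asarray(t_s, dtype=np.float64)
    if wave.n < 2:
        return np.full_like(t_s, wave.values[0] if wave.n else 0.0)
    dt = wave.times[1] - wave.times[0]
    period = wave.times[-1] - wave.times[0] + dt
    tp = np.concatenate([wave.times, [wave.times[0] + period]])
    vp = np.concatenate([wave.values, [wave.values[0]]])
    return np.interp((t_s - wave.times[0]) % period + wave.times[0], tp, vp)


def render_truth(geometry: PhantomGeometry, waveform: FlowWaveform,
                 frame_times_ms: np.ndarray, VENC: float,
                 profile: str = "plug",
                 eddy_phase: np.ndarray | None = None,
                 ) -> tuple[ImageSeries, ImageSeries]:
    """Render the ground-truth flow-compensated / flow-encoded image pair.

    Magnitude is 1 in the lumen, ``tissue_contrast`` in the bath, 0 outside.
    The flow-compensated series has zero phase; the flow-encoded series
    carries ``pi * v_true(r, t) / VENC`` in the lumen, where the velocity
    profile is ``plug`` (spatially uniform, equal to the waveform value) or
    ``parabolic`` (centreline equal to the waveform value, zero at the
    wall; its lumen mean is centreline / 2). An optional ``eddy_phase``
    map (radians, shape (ny, nx)) is added to the flow-encoded phase
    everywhere to mimic eddy-current background offsets.
    """
    if profile not in ("plug", "parabolic"):
        raise ValidationError(f"unknown velocity profile '{profile}'")
    frame_times_ms = np.asarray(frame_times_ms, dtype=np.float64)
    w = sample_periodic(waveform, frame_times_ms / 1000.0)
    if np.any(np.abs(w) > VENC):
        warnings.warn("waveform exceeds VENC; velocities will alias",
                      stacklevel=2)
    mag = geometry.magnitude().ravel()
    vessel = geometry.vessel_mask().ravel()
    if profile == "plug":
        shape_r = np.ones(vessel.sum())
    else:
        d = geometry._radius_mm_map().ravel()[vessel]
        shape_r = 1.0 - (d / geometry.vessel_radius_mm) ** 2
    M = frame_times_ms.size
    N = geometry.grid.n_voxels
    comp = np.repeat(mag[:, None].astype(np.complex128), M, axis=1)
    enc = comp.copy()
    phase = np.zeros((N, M))
    phase[vessel, :] = np.pi / VENC * shape_r[:, None] * w[None, :]
    if eddy_phase is not None:
        phase += np.asarray(eddy_phase, float).ravel()[:, None]
    enc *= np.exp(1j * phase)
    series_kw = dict(frame_times=frame_times_ms, grid=geometry.grid, VENC=VENC)
    return (ImageSeries(comp, **series_kw), ImageSeries(enc, **series_kw))


def make_sensitivities(Nc: int, grid: Grid2D, seed: int = 0) -> SensitivityMaps:
    """Smooth synthetic coil sensitivities, RSS-normalised.

    Gaussian-bump magnitudes centred at ``Nc`` points on a ring around the
    FOV with slowly varying (low-order polynomial) phase; deterministic in
    ``seed``. Support is the full grid (every coil magnitude is strictly
    positive)."""
    if Nc < 1:
        raise ValidationError("need at least one coil")
    ny, nx = grid.shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    yn = (yy - ny / 2.0) / (ny / 2.0)
    xn = (xx - nx / 2.0) / (nx / 2.0)
    maps = np.empty((Nc, ny, nx), dtype=np.complex128)
    angles = 2 * np.pi * (np.arange(Nc) + rng.uniform(0, 1)) / Nc
    for i, th in enumerate(angles):
        cy, cx = 1.1 * np.sin(th), 1.1 * np.cos(th)
        sigma = 1.0 + 0.2 * rng.standard_normal()
        magn = np.exp(-((yn - cy) ** 2 + (xn - cx) ** 2) / (2 * sigma ** 2))
        a, b, c = rng.uniform(-1.0, 1.0, size=3)
        phase = a * xn + b * yn + 0.3 * c * xn * yn
        maps[i] = magn * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    sens = SensitivityMaps(maps, np.ones((ny, nx), dtype=bool), grid)
    sens.validate()
    return sens


def acquire(truth: tuple[ImageSeries, ImageSeries] | list,
            sens: SensitivityMaps, pattern: SamplingPattern,
            noise_sd: float = 0.0, seed: int = 0) -> KTSamples:
    """Sample noisy multi-coil (k,t)-space lines from the truth series.

    For each pattern slot, the ky line of the centred unitary 2-D FFT of
    ``S_i * rho_v`` at the nearest truth frame is recorded for every coil;
    i.i.d. complex Gaussian noise of standard deviation ``noise_sd`` per
    sample is added (real/imaginary each ``noise_sd / sqrt(2)``).
    """
    truth = list(truth)
    Nv = len(truth)
    grid = truth[0].grid
    ny, nx = grid.shape
    Nc = sens.Nc
    if np.any(pattern.ky >= ny):
        raise ValidationError("pattern references ky outside the grid")
    if pattern.Nv != Nv:
        raise ValidationError(f"pattern has Nv={pattern.Nv}, truth has {Nv}")
    rng = np.random.default_rng(seed)

    # Nearest truth frame per slot.
    frame_of_slot = []
    for series in truth:
        ft = series.frame_times
        idx = np.clip(np.searchsorted(ft, pattern.t_ms), 1, ft.size - 1)
        nearest = np.where(np.abs(pattern.t_ms - ft[idx - 1])
                           <= np.abs(pattern.t_ms - ft[idx]), idx - 1, idx)
        # slots with t before the first frame map to frame 0
        nearest[pattern.t_ms <= ft[0]] = 0
        frame_of_slot.append(nearest)

    n_slots = pattern.n_slots
    data = np.empty((n_slots * Nc, nx), dtype=np.complex128)
    v_rec = np.repeat(pattern.v, Nc)
    coil_rec = np.tile(np.arange(Nc), n_slots)
    ky_rec = np.repeat(pattern.ky, Nc)
    t_rec = np.repeat(pattern.t_ms, Nc)
    role_rec = np.repeat(pattern.role, Nc)

    # FFT each needed (encoding, frame, coil) image once.
    for vi in range(1, Nv + 1):
        sel = np.flatnonzero(pattern.v == vi)
        if sel.size == 0:
            continue
        frames_needed = np.unique(frame_of_slot[vi - 1][sel])
        imgs = truth[vi - 1].data[:, frames_needed].T.reshape(-1, ny, nx)
        ksp = fft2c(sens.maps[:, None] * imgs[None])  # (Nc, F, ny, nx)
        frame_pos = {f: j for j, f in enumerate(frames_needed)}
        for s in sel:
            j = frame_pos[frame_of_slot[vi - 1][s]]
            for c in range(Nc):
                data[s * Nc + c] = ksp[c, j, pattern.ky[s], :]

    if noise_sd > 0:
        scale = noise_sd / np.sqrt(2.0)
        data += (rng.normal(scale=scale, size=data.shape)
                 + 1j * rng.normal(scale=scale, size=data.shape))

    kt = KTSamples(v=v_rec, coil=coil_rec, ky=ky_rec, t_ms=t_rec,
                   role=role_rec, data=data, Nv=Nv, Nc=Nc,
                   TR_ms=pattern.TR_ms, VENC=truth[0].VENC, grid=grid)
    kt.validate()
    return kt
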