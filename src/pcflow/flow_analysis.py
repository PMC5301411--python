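"""Quantitative flow analytics.

ROI-mean velocity waveforms, beat-by-beat segmentation and cycle averaging,
peak velocity and stroke volume, a cine-style gated-folding surrogate (the
mechanism by which retrospective gating misestimates aperiodic flow),
SNR/VNR image-quality ratios, and Bland-Altman agreement statistics with a
paired t-test.

Beat segmentation uses threshold upstrokes: a cycle starts where the
waveform crosses ``threshold_frac * global max`` from below, with
consecutive starts at least ``min_period_s`` apart; the trailing partial
cycle is discarded. Stroke volume integrates ROI velocity times pixel area
over the frames of one cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from .kt_data import (FlowWaveform, ImageSeries, ROIMask, ValidationError,
                      VelocitySeries)

__all__ = [
    "BeatSegmentation",
    "AgreementStats",
    "roi_mean_waveform",
    "segment_beats",
    "average_cycles",
    "peak_velocity",
    "stroke_volume",
    "fold_to_cycle",
    "snr",
    "vnr",
    "bland_altman",
]


@dataclass
class BeatSegmentation:
    """Half-open frame-index intervals [start, end), one per cardiac cycle."""

    intervals: list[tuple[int, int]]
    n_frames: int

    def __post_init__(self) -> None:
        prev_end = 0
        for (a, b) in self.intervals:
            if not (0 <= a < b <= self.n_frames):
                raise ValidationError(f"interval [{a}, {b}) outside series")
            if a < prev_end:
                raise ValidationError("intervals overlap or are unordered")
            if b - a < 3:
                raise ValidationError(f"cycle [{a}, {b}) spans < 3 frames")
            prev_end = b

    @property
    def n_cycles(self) -> int:
        return len(self.intervals)


@dataclass
class AgreementStats:
    """Bland-Altman agreement plus a paired Student's t-test."""

    bias: float          # mean of differences a - b
    lower: float         # bias - 1.96 * SD(differences)
    upper: float         # bias + 1.96 * SD(differences)
    pearson_r: float     # correlation of a with b (nan if degenerate)
    t_stat: float
    p_value: float
    n: int


def roi_mean_waveform(vel: VelocitySeries, roi: ROIMask) -> FlowWaveform:
    """Per-frame mean velocity over the ROI, times converted to seconds."""
    if roi.mask.shape != vel.grid.shape:
        raise ValidationError("ROI grid does not match velocity series")
    values = vel.values[roi.flat()].mean(axis=0)
    return FlowWaveform(vel.frame_times / 1000.0, values, "mean_velocity_cm_s")


def segment_beats(wave: FlowWaveform, min_period_s: float = 0.4,
                  threshold_frac: float = 0.3) -> BeatSegmentation:
    """Detect cardiac cycles as upward threshold crossings.

    The threshold is ``threshold_frac`` times the global maximum. A new
    cycle starts at each upward crossing separated by at least
    ``min_period_s`` from the previous start; the final partial cycle (from
    the last crossing to the end of the record) is discarded. No crossings
    yields an empty segmentation."""
    if wave.n < 3:
        raise ValidationError("waveform must have at least 3 samples")
    thr = threshold_frac * wave.values.max()
    up = np.flatnonzero((wave.values[:-1] < thr) & (wave.values[1:] >= thr)) + 1
    starts: list[int] = []
    for i in up:
        if not starts or wave.times[i] - wave.times[starts[-1]] >= min_period_s:
            starts.append(int(i))
    intervals = [(a, b) for a, b in zip(starts[:-1], starts[1:]) if b - a >= 3]
    return BeatSegmentation(intervals, wave.n)


def average_cycles(wave: FlowWaveform, seg: BeatSegmentation,
                   n_points: int = 64) -> FlowWaveform:
    """Average the detected cycles into one synthetic cardiac cycle.

    Each cycle is resampled by linear interpolation onto ``n_points``
    uniformly spaced normalised-time points, then averaged pointwise; the
    output duration is the mean cycle duration (cycles of differing length
    are normalised before averaging). Cycles shorter than 2 frames are
    skipped with a warning."""
    if seg.n_cycles == 0:
        raise ValidationError("cannot average an empty segmentation")
    u = np.linspace(0.0, 1.0, n_points, endpoint=False)
    resampled, durations = [], []
    for (a, b) in seg.intervals:
        if b - a < 2:
            warnings.warn(f"cycle [{a}, {b}) too short; skipped", stacklevel=2)
            continue
        t = wave.times[a:b]
        dur = (wave.times[b] if b < wave.n else
               wave.times[-1] + (wave.times[-1] - wave.times[-2])) - t[0]
        resampled.append(np.interp(u * dur + t[0], t, wave.values[a:b]))
        durations.append(dur)
    if not resampled:
        raise ValidationError("no usable cycles to average")
    mean_dur = float(np.mean(durations))
    return FlowWaveform(u * mean_dur, np.mean(resampled, axis=0),
                        wave.quantity)


def peak_velocity(wave: FlowWaveform,
                  seg: BeatSegmentation | None = None):
    """Maximum of the waveform per cycle (array), or overall (scalar) when
    no segmentation is given."""
    if wave.n == 0:
        raise ValidationError("empty waveform")
    if seg is None:
        return float(wave.values.max())
    return np.array([wave.values[a:b].max() for (a, b) in seg.intervals])


def stroke_volume(vel: VelocitySeries, roi: ROIMask,
                  cycle: tuple[int, int]) -> float:
    """Volume through the ROI over one cycle, in mL.

    Sum over the cycle's frames of (ROI-sum of velocity [cm/s]) x pixel
    area [cm^2] x frame duration [s]; frame durations come from
    ``frame_times``."""
    a, b = cycle
    if not (0 <= a < b <= vel.n_frames):
        raise ValidationError(f"cycle [{a}, {b}) outside series")
    if roi.mask.shape != vel.grid.shape:
        raise ValidationError("ROI grid does not match velocity series")
    t = vel.frame_times / 1000.0
    dt = np.diff(t, append=t[-1] + (t[-1] - t[-2] if t.size > 1 else 0.0))
    pixel_area_cm2 = roi.pixel_area_mm2 / 100.0
    flow_ml_s = vel.values[roi.flat()][:, a:b].sum(axis=0) * pixel_area_cm2
    return float(np.sum(flow_ml_s * dt[a:b]))


def fold_to_cycle(wave: FlowWaveform, assumed_period_s: float,
                  n_bins: int | None = None) -> FlowWaveform:
    """Fold a long record into one assumed cardiac cycle (gated-cine
    surrogate): time stamps are reduced modulo the assumed period, binned
    into ``n_bins`` uniform phase bins and averaged. For flow that is not
    periodic at the assumed period, the folded waveform mixes distinct
    beats — the mechanism behind erroneous gated peak-flow estimates."""
    span = wave.times[-1] - wave.times[0]
    if span < assumed_period_s:
        raise ValidationError("record shorter than the assumed period")
    if n_bins is None:
        dt = np.median(np.diff(wave.times))
        n_bins = max(int(round(assumed_period_s / dt)), 1)
    phase = (wave.times - wave.times[0]) % assumed_period_s
    idx = np.minimum((phase / assumed_period_s * n_bins).astype(int),
                     n_bins - 1)
    sums = np.bincount(idx, weights=wave.values, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    filled = counts > 0
    centres = (np.arange(n_bins)[filled] + 0.5) * assumed_period_s / n_bins
    return FlowWaveform(centres, sums[filled] / counts[filled], wave.quantity)


def snr(mag_frame: np.ndarray, roi: ROIMask, background: ROIMask) -> float:
    """Signal-to-noise ratio: mean |signal| over the ROI divided by the
    standard deviation of |signal| over the background region."""
    if np.any(roi.mask & background.mask):
        raise ValidationError("ROI and background masks overlap")
    sig = np.abs(np.asarray(mag_frame))[roi.mask].mean()
    noise = np.abs(np.asarray(mag_frame))[background.mask].std()
    if noise == 0:
        warnings.warn("zero background standard deviation; SNR is infinite",
                      stacklevel=2)
        return float("inf")
    return float(sig / noise)


def vnr(vel_frame: np.ndarray, roi: ROIMask, static: ROIMask) -> float:
    """Velocity-to-noise ratio: mean velocity over the ROI divided by the
    standard deviation of velocity over static tissue."""
    if np.any(roi.mask & static.mask):
        raise ValidationError("ROI and static masks overlap")
    sig = np.asarray(vel_frame)[roi.mask].mean()
    noise = np.asarray(vel_frame)[static.mask].std()
    if noise == 0:
        warnings.warn("zero static-tissue standard deviation; VNR is infinite",
                      stacklevel=2)
        return float("inf")
    return float(sig / noise)


def bland_altman(a, b) -> AgreementStats:
    """Bland-Altman agreement between paired measurements.

    Differences ``d = a - b``; bias = mean(d); limits of agreement =
    bias +/- 1.96 * SD(d) (sample SD, ddof=1); Pearson r between a and b
    (NaN-flagged when either series has zero variance); paired two-sided
    Student's t-test ``t = bias / (SD(d) / sqrt(n))`` with n-1 degrees of
    freedom."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("inputs must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValidationError(f"need at least 2 pairs, got {n}")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    if sd == 0:
        t_stat = 0.0 if bias == 0 else float(np.inf * np.sign(bias))
        p = 1.0 if bias == 0 else 0.0
    else:
        t_stat = bias / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    return AgreementStats(bias=bias, lower=bias - 1.96 * sd,
                          upper=bias + 1.96 * sd, pearson_r=r,
                          t_stat=float(t_stat), p_value=p, n=int(n))
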