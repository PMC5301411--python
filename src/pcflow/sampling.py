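"""Interleaved training/imaging (k,t)-space sampling patterns.

Real-time flow imaging without gating acquires, per TR, a single ky line of
a single velocity encoding. The scheme interleaves two kinds of lines:

* **training** lines from the central k-space band — revisited at a high
  temporal rate, they drive the PCA estimate of the temporal subspace;
* **imaging** lines drawn at random from the outer k-space — accumulated
  over time, they provide the spatial coverage needed for the spatial
  subspace.

Each reconstruction frame spans ``2 * Nv * TR`` ms and contains exactly one
training and one imaging line per encoding, which is what fixes the nominal
temporal resolution of the method at ``2 * Nv * TR`` (18 ms at Nv=2,
TR=4.5 ms). The same ky schedule is applied to every encoding so the
flow-compensated and flow-encoded data see identical sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kt_data import IMAGING, TRAINING, ValidationError

__all__ = [
    "SamplingPattern",
    "make_interleaved_pattern",
    "nominal_temporal_resolution",
    "cine_temporal_resolution",
    "coverage_report",
]


@dataclass
class SamplingPattern:
    """Ordered per-TR acquisition slots plus generating parameters."""

    slot: np.ndarray    # (n,) int slot index
    t_ms: np.ndarray    # (n,) float, slot start time
    v: np.ndarray       # (n,) int, 1-based encoding
    ky: np.ndarray      # (n,) int
    role: np.ndarray    # (n,) str
    ny: int
    Nv: int
    TR_ms: float
    central_halfwidth: int
    seed: int

    @property
    def n_slots(self) -> int:
        return int(self.slot.size)

    @property
    def frame_period_ms(self) -> float:
        return nominal_temporal_resolution(self.Nv, self.TR_ms)

    @property
    def n_frames(self) -> int:
        return self.n_slots // (2 * self.Nv)

    def frame_times(self) -> np.ndarray:
        """Centre time (ms) of each reconstruction frame."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_period_ms

    def validate(self) -> None:
        centre = self.ny // 2
        w = self.central_halfwidth
        train = self.role == TRAINING
        if np.any((self.ky[train] < centre - w) | (self.ky[train] > centre + w)):
            raise ValidationError("training ky outside the central band")
        if np.any((self.ky < 0) | (self.ky >= self.ny)):
            raise ValidationError("ky index outside 0..ny-1")
        # Per frame, each encoding appears the same number of times and the
        # ky schedule is shared across encodings.
        per = 2 * self.Nv
        n_full = self.n_slots // per
        vv = self.v[: n_full * per].reshape(n_full, per)
        kk = self.ky[: n_full * per].reshape(n_full, per)
        rr = self.role[: n_full * per].reshape(n_full, per)
        for f in range(n_full):
            counts = np.bincount(vv[f], minlength=self.Nv + 1)[1:]
            if not np.all(counts == 2):
                raise ValidationError(f"frame {f}: encodings not balanced")
            sched = {}
            for vi, ki, ri in zip(vv[f], kk[f], rr[f]):
                sched.setdefault(vi, []).append((ri, ki))
            ref = sorted(sched[1])
            for vi in range(2, self.Nv + 1):
                if sorted(sched[vi]) != ref:
                    raise ValidationError(
                        f"frame {f}: ky schedule differs between encodings")


def nominal_temporal_resolution(Nv: int, TR_ms: float) -> float:
    """Nominal temporal resolution 2 * Nv * TR of the interleaved scheme, ms.

    One frame needs one training and one imaging line for each of the ``Nv``
    encodings, i.e. ``2 * Nv`` TRs.
    """
    if Nv < 1:
        raise ValidationError(f"Nv must be >= 1, got {Nv}")
    if TR_ms <= 0:
        raise ValidationError(f"TR must be positive, got {TR_ms}")
    return 2.0 * Nv * TR_ms

def cine_temporal_resolution(period_s: float, n_phases: int) -> float:
    """Temporal resolution (ms) of a gated cine acquisition that folds an
    assumed cardiac period into ``n_phases`` phases."""
    if period_s <= 0 or n_phases < 1:
        raise ValidationError("period and phase count must be positive")
    return 1000.0 * period_s / n_phases


def make_interleaved_pattern(ny: int, Nv: int, TR_ms: float, n_frames: int,
                             central_halfwidth: int = 0,
                             seed: int = 0) -> SamplingPattern:
    """Generate the interleaved training/imaging pattern.

    Per reconstruction frame (duration ``2*Nv*TR``) the slots run
    ``training(v=1), imaging(v=1), training(v=2), imaging(v=2), ...``, one TR
    each. Training ky is drawn from the central band
    ``[ny//2 - w, ny//2 + w]`` (the single centre line when ``w = 0``);
    imaging ky is drawn uniformly at random without replacement from the
    remaining lines, re-drawn once a sweep exhausts them. The drawn ky pair
    of a frame is reused for all encodings. Deterministic in ``seed``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    centre = ny // 2
    w = central_halfwidth
    if w < 0 or ny <= 2 * w + 1:
        raise ValidationError(
            f"central band half-width {w} leaves no imaging lines for ny={ny}")
    band = np.arange(centre - w, centre + w + 1)
    outer = np.setdiff1d(np.arange(ny), band)
    rng = np.random.default_rng(seed)

    train_ky = rng.choice(band, size=n_frames) if band.size > 1 else \
        np.full(n_frames, centre, dtype=np.int64)
    # Uniform-without-replacement sweeps over the outer lines.
    n_sweeps = int(np.ceil(n_frames / outer.size))
    imaging_ky = np.concatenate(
        [rng.permutation(outer) for _ in range(n_sweeps)])[:n_frames]

    per = 2 * Nv
    slot = np.arange(n_frames * per)
    v = np.empty(slot.size, dtype=np.int64)
    ky = np.empty(slot.size, dtype=np.int64)
    role = np.empty(slot.size, dtype="U8")
    for f in range(n_frames):
        for vi in range(Nv):
            base = f * per + 2 * vi
            v[base: base + 2] = vi + 1
            ky[base] = train_ky[f]
            ky[base + 1] = imaging_ky[f]
            role[base] = TRAINING
            role[base + 1] = IMAGING
    pattern = SamplingPattern(slot=slot, t_ms=slot * TR_ms, v=v, ky=ky,
                              role=role, ny=ny, Nv=Nv, TR_ms=TR_ms,
                              central_halfwidth=w, seed=seed)
    pattern.validate()
    return pattern


def coverage_report(pattern: SamplingPattern) -> dict:
    """QC summary: per-encoding acceleration, ky histogram, training rate."""
    report: dict = {
        "n_slots": pattern.n_slots,
        "n_frames": pattern.n_frames,
        "frame_period_ms": pattern.frame_period_ms,
        "training_rate": float(np.mean(pattern.role == TRAINING)),
        "ky_histogram": np.bincount(pattern.ky, minlength=pattern.ny).tolist(),
        "acceleration": {},
    }
    for vi in range(1, pattern.Nv + 1):
        sel = (pattern.v == vi) & (pattern.role == IMAGING)
        lines_per_frame = sel.sum() / max(pattern.n_frames, 1)
        report["acceleration"][vi] = float(pattern.ny / lines_per_frame) \
            if lines_per_frame > 0 else float("inf")
    return report
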