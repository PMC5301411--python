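"""Shared fixtures and builders for the test suite.

All test data is generated programmatically: phantom geometries, synthetic
coil maps, and (k,t)-space acquisitions built either through the interleaved
sampling generator or directly (when a test needs a denser-than-real-time
per-frame line budget, e.g. for exactly determined solver checks).
"""

from __future__ import annotations

import numpy as np
import pytest

from pcflow.fourier import fft2c
from pcflow.kt_data import Grid2D, ImageSeries, KTSamples, SensitivityMaps
from pcflow.kt_data import IMAGING, TRAINING
from pcflow.phantom_sim import (PhantomGeometry, WaveformSpec, make_waveform,
                                make_sensitivities, render_truth)
from pcflow.sampling import nominal_temporal_resolution


@pytest.fixture(scope="session")
def grid32() -> Grid2D:
    return Grid2D(32, 32, (1.2, 1.2))


@pytest.fixture(scope="session")
def geom32(grid32) -> PhantomGeometry:
    return PhantomGeometry(grid32, vessel_radius_mm=7.5)


@pytest.fixture(scope="session")
def sens32(grid32) -> SensitivityMaps:
    return make_sensitivities(4, grid32, seed=7)


@pytest.fixture()
def waveform_I():
    return make_waveform(WaveformSpec(kind="I", period_s=2.0, peak_cm_s=60.0,
                                      baseline_cm_s=10.0))


def build_dense_kt(truth: list[ImageSeries], sens: SensitivityMaps,
                   lines_per_frame: int, TR_ms: float, seed: int,
                   noise_sd: float = 0.0) -> KTSamples:
    """KTSamples with ``lines_per_frame`` ky lines per frame per encoding.

    The first line of each frame is the centre (training) line; the rest are
    random distinct outer lines (imaging). Line times are spread inside each
    frame's ``2*Nv*TR`` window so the solver's frame assignment recovers the
    frame exactly. Used to build better-conditioned systems than the
    one-imaging-line-per-frame real-time scheme provides at small M.
    """
    Nv = len(truth)
    grid = truth[0].grid
    ny, nx = grid.shape
    M = truth[0].n_frames
    Nc = sens.Nc
    period = nominal_temporal_resolution(Nv, TR_ms)
    rng = np.random.default_rng(seed)
    centre = ny // 2
    outer = np.setdiff1d(np.arange(ny), [centre])

    v_l, coil_l, ky_l, t_l, role_l, data_l = [], [], [], [], [], []
    n_per_frame = Nv * lines_per_frame
    dt = period / n_per_frame
    for m in range(M):
        kys = np.concatenate([[centre],
                              rng.choice(outer, lines_per_frame - 1,
                                         replace=False)])
        j = 0
        for v in range(1, Nv + 1):
            img = truth[v - 1].frame(m)
            ksp = fft2c(sens.maps * img[None])  # (Nc, ny, nx)
            for li, ky in enumerate(kys):
                t = m * period + j * dt
                role = TRAINING if li == 0 else IMAGING
                for c in range(Nc):
                    v_l.append(v); coil_l.append(c); ky_l.append(ky)
                    t_l.append(t); role_l.append(role)
                    data_l.append(ksp[c, ky, :])
                j += 1
    data = np.array(data_l)
    if noise_sd > 0:
        s = noise_sd / np.sqrt(2)
        data = data + rng.normal(scale=s, size=data.shape) \
            + 1j * rng.normal(scale=s, size=data.shape)
    kt = KTSamples(v=np.array(v_l), coil=np.array(coil_l),
                   ky=np.array(ky_l), t_ms=np.array(t_l),
                   role=np.array(role_l), data=data, Nv=Nv, Nc=Nc,
                   TR_ms=TR_ms, VENC=truth[0].VENC, grid=grid)
    kt.validate()
    return kt


def plug_truth(geom: PhantomGeometry, velocities_cm_s, VENC: float = 100.0,
               frame_period_ms: float = 20.0) -> list[ImageSeries]:
    """Truth pair whose flow-encoded phase steps through the given plug
    velocities, one per frame."""
    vals = np.asarray(velocities_cm_s, dtype=float)
    times = (np.arange(vals.size) + 0.5) * frame_period_ms
    from pcflow.kt_data import FlowWaveform
    wave = FlowWaveform(times / 1000.0, vals)
    return list(render_truth(geom, wave, times, VENC, profile="plug"))
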