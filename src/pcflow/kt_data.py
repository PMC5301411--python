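"""Core domain types and file I/O for raw (k,t)-space flow MRI data.

The central objects of the pipeline live here:

* :class:`KTSamples` — the acquired multi-coil, multi-encoding k-space lines
  with per-line time stamps and training/imaging role labels; the raw input
  of reconstruction.
* :class:`ImageSeries` — one reconstructed complex image sequence
  ``rho_v(r, t)`` on a fixed Cartesian grid (one per velocity encoding).
* :class:`TemporalSubspace` / :class:`SpatialSubspace` — the rank-L factors
  ``V`` (L x time) and ``U`` (voxels x L) of the low-rank Casorati model
  ``C = U V``.
* :class:`VelocitySeries` / :class:`FlowWaveform` — velocity maps in cm/s
  (bounded by the encoding velocity VENC) and ROI time series, the units of
  all downstream flow analytics.

Raw data is persisted in a documented HDF5 layout (see :func:`write_kt`);
attribute names mirror ISMRMRD conventions where a one-to-one mapping exists,
without requiring the full standard.

Conventions: all indices are 0-based; the k-space origin sits at the array
centre ``(ny // 2, nx // 2)`` (centred-FFT convention); image grids are
row-major ``(ny, nx)``; line time stamps are in ms at TR granularity, one ky
line of one encoding per TR slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SolverError",
    "TRAINING",
    "IMAGING",
    "Grid2D",
    "KTSamples",
    "ImageSeries",
    "SensitivityMaps",
    "TemporalSubspace",
    "SpatialSubspace",
    "VelocitySeries",
    "ROIMask",
    "FlowWaveform",
    "read_kt",
    "write_kt",
    "read_image_series",
    "write_image_series",
    "read_velocity_series",
    "write_velocity_series",
    "read_waveform_csv",
    "write_waveform_csv",
    "write_outputs",
]

TRAINING = "training"
IMAGING = "imaging"


class FormatError(Exception):
    """A file does not conform to the documented container layout."""


class ValidationError(Exception):
    """A domain object violates one of its stated invariants."""


class SolverError(Exception):
    """An iterative solver failed to make progress."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid2D:
    """Fixed 2-D Cartesian image grid.

    Parameters
    ----------
    nx : int
        Readout (frequency-encode) samples per line.
    ny : int
        Phase-encode lines.
    pixel_size : (float, float)
        Pixel size in mm, ``(dy, dx)``.
    """

    nx: int
    ny: int
    pixel_size: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValidationError(f"grid must be at least 2x2, got {self.ny}x{self.nx}")
        if min(self.pixel_size) <= 0:
            raise ValidationError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def n_voxels(self) -> int:
        """N = nx * ny, the row dimension of the Casorati matrix."""
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_size[0] * self.pixel_size[1])


@dataclass
class KTSamples:
    """Acquired (k,t)-space lines with coil/encoding/ky/time/role metadata.

    One record per (line, coil): ``data[j]`` is the complex readout of length
    ``nx`` acquired by coil ``coil[j]`` for encoding ``v[j]`` at phase-encode
    index ``ky[j]`` and time ``t_ms[j]``, labelled ``role[j]`` (``training``
    lines come from the central k-space band and drive temporal-subspace
    estimation; ``imaging`` lines are randomly sampled outer lines).
    """

    v: np.ndarray          # (n,) int, 1-based encoding index
    coil: np.ndarray       # (n,) int, 0-based coil index
    ky: np.ndarray         # (n,) int, 0-based phase-encode index
    t_ms: np.ndarray       # (n,) float, acquisition time stamp
    role: np.ndarray       # (n,) str, 'training' | 'imaging'
    data: np.ndarray       # (n, nx) complex readouts
    Nv: int
    Nc: int
    TR_ms: float
    VENC: float            # encoding velocity, cm/s
    grid: Grid2D

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.int64)
        self.coil = np.asarray(self.coil, dtype=np.int64)
        self.ky = np.asarray(self.ky, dtype=np.int64)
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        self.role = np.asarray(self.role, dtype="U8")
        self.data = np.asarray(self.data, dtype=np.complex128)

    @property
    def n_lines(self) -> int:
        return int(self.v.size)

    def validate(self) -> None:
        """Check every stated invariant; raise :class:`ValidationError` with
        the index of the first offending line."""
        n = self.n_lines
        for name, arr in (("v", self.v), ("coil", self.coil), ("ky", self.ky),
                          ("t_ms", self.t_ms), ("role", self.role)):
            if arr.shape[0] != n:
                raise ValidationError(f"metadata field '{name}' has length "
                                      f"{arr.shape[0]}, expected {n}")
        if self.data.shape != (n, self.grid.nx):
            raise ValidationError(f"data has shape {self.data.shape}, expected "
                                  f"({n}, {self.grid.nx})")
        bad = np.flatnonzero((self.v < 1) | (self.v > self.Nv))
        if bad.size:
            raise ValidationError(f"line {bad[0]}: encoding {self.v[bad[0]]} "
                                  f"outside 1..{self.Nv}")
        bad = np.flatnonzero((self.coil < 0) | (self.coil >= self.Nc))
        if bad.size:
            raise ValidationError(f"line {bad[0]}: coil {self.coil[bad[0]]} "
                                  f"outside 0..{self.Nc - 1}")
        bad = np.flatnonzero((self.ky < 0) | (self.ky >= self.grid.ny))
        if bad.size:
            raise ValidationError(f"line {bad[0]}: ky {self.ky[bad[0]]} outside "
                                  f"0..{self.grid.ny - 1}")
        bad = np.flatnonzero(~np.isin(self.role, [TRAINING, IMAGING]))
        if bad.size:
            raise ValidationError(f"line {bad[0]}: unknown role "
                                  f"'{self.role[bad[0]]}'")
        # Time stamps nondecreasing in acquisition order.
        dec = np.flatnonzero(np.diff(self.t_ms) < 0)
        if dec.size:
            raise ValidationError(f"line {dec[0] + 1}: time stamp decreases "
                                  f"({self.t_ms[dec[0] + 1]} < {self.t_ms[dec[0]]} ms)")
        # Every (v, coil, ky, t) combination appears at most once.
        key = np.rec.fromarrays([self.v, self.coil, self.ky, self.t_ms])
        uniq, counts = np.unique(key, return_counts=True)
        if np.any(counts > 1):
            dup = uniq[np.argmax(counts > 1)]
            idx = int(np.flatnonzero(key == dup)[1])
            raise ValidationError(f"line {idx}: duplicate (v, coil, ky, t) "
                                  f"combination {tuple(dup)}")
        # All coils must share an identical (v, ky, t, role) line set.
        slot_key = list(zip(self.v.tolist(), self.ky.tolist(),
                            self.t_ms.tolist(), self.role.tolist()))
        ref = {k for k, c in zip(slot_key, self.coil.tolist()) if c == 0}
        for c in range(1, self.Nc):
            this = {k for k, cc in zip(slot_key, self.coil.tolist()) if cc == c}
            if this != ref:
                raise ValidationError(f"coil {c} line set differs from coil 0")

    def training(self) -> "KTSamples":
        """Subset of training lines only."""
        return self._subset(self.role == TRAINING)

    def imaging(self) -> "KTSamples":
        return self._subset(self.role == IMAGING)

    def _subset(self, mask: np.ndarray) -> "KTSamples":
        return KTSamples(self.v[mask], self.coil[mask], self.ky[mask],
                         self.t_ms[mask], self.role[mask], self.data[mask],
                         self.Nv, self.Nc, self.TR_ms, self.VENC, self.grid)


@dataclass
class ImageSeries:
    """Complex dynamic image sequence ``rho_v(r, t)`` for one encoding.

    ``data`` has Casorati layout ``(N, M)`` with ``N = nx * ny`` voxels
    (row-major over the ``(ny, nx)`` grid) and ``M`` frames.
    """

    data: np.ndarray        # (N, M) complex
    frame_times: np.ndarray  # (M,) ms
    grid: Grid2D
    VENC: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def frame(self, m: int) -> np.ndarray:
        """Frame ``m`` reshaped to the ``(ny, nx)`` image grid."""
        return self.data[:, m].reshape(self.grid.shape)

    def validate(self) -> None:
        if self.data.shape != (self.grid.n_voxels, self.n_frames):
            raise ValidationError(f"data shape {self.data.shape} does not match "
                                  f"({self.grid.n_voxels}, {self.n_frames})")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(self.data.view(np.float64))):
            raise ValidationError("image data contains non-finite values")


@dataclass
class SensitivityMaps:
    """Per-coil complex sensitivity maps S_i(r), RSS-normalised on support."""

    maps: np.ndarray      # (Nc, ny, nx) complex
    support: np.ndarray   # (ny, nx) bool
    grid: Grid2D

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        self.support = np.asarray(self.support, dtype=bool)

    @property
    def Nc(self) -> int:
        return int(self.maps.shape[0])

    def validate(self) -> None:
        if self.maps.shape[1:] != self.grid.shape:
            raise ValidationError(f"maps shape {self.maps.shape} does not match "
                                  f"grid {self.grid.shape}")
        rss = np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))
        if np.any(np.abs(rss[self.support] - 1.0) > 1e-6):
            raise ValidationError("RSS of sensitivities deviates from 1 on support")
        if np.any(rss[~self.support] != 0.0):
            raise ValidationError("sensitivities must be zero outside support")


@dataclass
class TemporalSubspace:
    """Estimated temporal subspace V-hat of the low-rank Casorati model.

    In ``joint`` mode a single ``(L, Nv*M)`` orthonormal-row matrix spans the
    shared temporal subspace of the column-concatenated (joint) Casorati
    matrix ``[C_1, ..., C_Nv]``; in ``separate`` mode ``basis`` holds one
    ``(L, M)`` matrix per encoding, stacked as ``(Nv, L, M)``.
    """

    basis: np.ndarray
    mode: str                 # 'joint' | 'separate'
    frame_times: np.ndarray   # (M,) ms
    Nv: int

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=np.complex128)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.mode not in ("joint", "separate"):
            raise ValidationError(f"unknown subspace mode '{self.mode}'")

    @property
    def L(self) -> int:
        return int(self.basis.shape[-2])

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def block(self, v: int) -> np.ndarray:
        """The (L, M) temporal basis block for 1-based encoding ``v``."""
        M = self.n_frames
        if self.mode == "joint":
            return self.basis[:, (v - 1) * M: v * M]
        return self.basis[v - 1]

    def validate(self) -> None:
        mats = [self.basis] if self.mode == "joint" else list(self.basis)
        for mat in mats:
            T = mat.shape[1]
            if self.L > T:
                raise ValidationError(f"L={self.L} exceeds T_total={T}")
            gram = mat @ mat.conj().T
            if not np.allclose(gram, np.eye(self.L), atol=1e-8):
                raise ValidationError("temporal subspace rows are not orthonormal")
        expect = self.Nv * self.n_frames if self.mode == "joint" else self.n_frames
        if mats[0].shape[1] != expect:
            raise ValidationError(f"basis has {mats[0].shape[1]} columns, "
                                  f"expected {expect}")


@dataclass
class SpatialSubspace:
    """Spatial subspace U-hat: ``(N, L)`` in joint mode, ``(Nv, N, L)`` in
    separate mode (one factor per encoding)."""

    basis: np.ndarray
    mode: str
    grid: Grid2D

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=np.complex128)

    @property
    def L(self) -> int:
        return int(self.basis.shape[-1])

    def block(self, v: int) -> np.ndarray:
        return self.basis if self.mode == "joint" else self.basis[v - 1]

    def validate(self, V: TemporalSubspace | None = None) -> None:
        if not np.all(np.isfinite(self.basis.view(np.float64))):
            raise ValidationError("spatial subspace contains non-finite values")
        if self.basis.shape[-2] != self.grid.n_voxels:
            raise ValidationError("spatial subspace row count differs from N")
        if V is not None and self.L != V.L:
            raise ValidationError(f"spatial L={self.L} does not match temporal "
                                  f"L={V.L}")


@dataclass
class VelocitySeries:
    """Real-valued through-plane velocity maps in cm/s, ``(N, M)`` layout.

    Values are bounded by the encoding velocity: ``|v| <= VENC`` (velocities
    beyond VENC alias by construction of the wrapped phase).
    """

    values: np.ndarray       # (N, M) float, cm/s
    frame_times: np.ndarray  # (M,) ms
    grid: Grid2D
    VENC: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def frame(self, m: int) -> np.ndarray:
        return self.values[:, m].reshape(self.grid.shape)

    def validate(self) -> None:
        if self.values.shape != (self.grid.n_voxels, self.n_frames):
            raise ValidationError(f"values shape {self.values.shape} does not "
                                  f"match ({self.grid.n_voxels}, {self.n_frames})")
        if np.any(np.abs(self.values) > self.VENC * (1 + 1e-12)):
            raise ValidationError("velocity magnitude exceeds VENC")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("velocity contains non-finite values")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask on the image grid."""

    mask: np.ndarray          # (ny, nx) bool
    pixel_area_mm2: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValidationError("ROI mask has no true pixels")
        if self.pixel_area_mm2 <= 0:
            raise ValidationError("pixel area must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_cm2(self) -> float:
        return self.n_pixels * self.pixel_area_mm2 / 100.0

    def flat(self) -> np.ndarray:
        return self.mask.ravel()


@dataclass
class FlowWaveform:
    """Time series of ROI-mean velocity (cm/s) or volumetric flow (mL/s)."""

    times: np.ndarray     # (n,) seconds
    values: np.ndarray
    quantity: str = "mean_velocity_cm_s"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("waveform times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("waveform values must be finite")

    @property
    def n(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# HDF5 / CSV I/O
# ---------------------------------------------------------------------------

_KT_META = ("v", "coil", "ky", "t_ms", "role")
_KT_ATTRS = ("TR_ms", "VENC_cm_s", "Nv", "Nc", "nx", "ny", "pixel_mm")


def write_kt(kt: KTSamples, path: str | Path) -> None:
    """Persist raw k-t samples to the documented HDF5 layout.

    Layout: ``/data/lines`` (n, nx) complex readouts; ``/data/meta/{v, coil,
    ky, t_ms, role}``; root attributes ``TR_ms, VENC_cm_s, Nv, Nc, nx, ny,
    pixel_mm``.
    """
    kt.validate()
    with h5py.File(path, "w") as f:
        g = f.create_group("data")
        g.create_dataset("lines", data=kt.data)
        m = g.create_group("meta")
        m.create_dataset("v", data=kt.v)
        m.create_dataset("coil", data=kt.coil)
        m.create_dataset("ky", data=kt.ky)
        m.create_dataset("t_ms", data=kt.t_ms)
        m.create_dataset("role", data=kt.role.astype("S8"))
        f.attrs["TR_ms"] = kt.TR_ms
        f.attrs["VENC_cm_s"] = kt.VENC
        f.attrs["Nv"] = kt.Nv
        f.attrs["Nc"] = kt.Nc
        f.attrs["nx"] = kt.grid.nx
        f.attrs["ny"] = kt.grid.ny
        f.attrs["pixel_mm"] = np.asarray(kt.grid.pixel_size)


def read_kt(path: str | Path) -> KTSamples:
    """Read raw k-t samples, validating layout and invariants.

    Raises
    ------
    FormatError
        If a required dataset or attribute is missing (named in the message).
    ValidationError
        If the stored records violate a KTSamples invariant.
    """
    with h5py.File(path, "r") as f:
        for a in _KT_ATTRS:
            if a not in f.attrs:
                raise FormatError(f"missing required attribute '{a}'")
        if "data" not in f or "lines" not in f["data"] or "meta" not in f["data"]:
            raise FormatError("missing required group/dataset under /data "
                              "(need 'lines' and 'meta')")
        meta = f["data/meta"]
        for d in _KT_META:
            if d not in meta:
                raise FormatError(f"missing required dataset '/data/meta/{d}'")
        grid = Grid2D(int(f.attrs["nx"]), int(f.attrs["ny"]),
                      tuple(np.atleast_1d(f.attrs["pixel_mm"]).tolist()[:2]))
        kt = KTSamples(
            v=meta["v"][()], coil=meta["coil"][()], ky=meta["ky"][()],
            t_ms=meta["t_ms"][()],
            role=np.char.decode(meta["role"][()].astype("S8")),
            data=f["data/lines"][()],
            Nv=int(f.attrs["Nv"]), Nc=int(f.attrs["Nc"]),
            TR_ms=float(f.attrs["TR_ms"]), VENC=float(f.attrs["VENC_cm_s"]),
            grid=grid,
        )
    kt.validate()
    return kt


def _write_series(path: str | Path, data: np.ndarray, frame_times: np.ndarray,
                  grid: Grid2D, venc: float, kind: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("frame_times_ms", data=frame_times)
        f.attrs["kind"] = kind
        f.attrs["VENC_cm_s"] = venc
        f.attrs["nx"] = grid.nx
        f.attrs["ny"] = grid.ny
        f.attrs["pixel_mm"] = np.asarray(grid.pixel_size)


def _read_series_raw(path: str | Path):
    with h5py.File(path, "r") as f:
        for a in ("VENC_cm_s", "nx", "ny", "pixel_mm"):
            if a not in f.attrs:
                raise FormatError(f"missing required attribute '{a}'")
        if "data" not in f or "frame_times_ms" not in f:
            raise FormatError("missing 'data' or 'frame_times_ms' dataset")
        grid = Grid2D(int(f.attrs["nx"]), int(f.attrs["ny"]),
                      tuple(np.atleast_1d(f.attrs["pixel_mm"]).tolist()[:2]))
        return f["data"][()], f["frame_times_ms"][()], grid, float(f.attrs["VENC_cm_s"])


def write_image_series(series: ImageSeries, path: str | Path) -> None:
    series.validate()
    _write_series(path, series.data, series.frame_times, series.grid,
                  series.VENC, "complex_image")


def read_image_series(path: str | Path) -> ImageSeries:
    data, t, grid, venc = _read_series_raw(path)
    s = ImageSeries(data, t, grid, venc)
    s.validate()
    return s


def write_velocity_series(vel: VelocitySeries, path: str | Path) -> None:
    vel.validate()
    _write_series(path, vel.values, vel.frame_times, vel.grid, vel.VENC,
                  "velocity")


def read_velocity_series(path: str | Path) -> VelocitySeries:
    data, t, grid, venc = _read_series_raw(path)
    v = VelocitySeries(data, t, grid, venc)
    v.validate()
    return v


def write_waveform_csv(wave: FlowWaveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": wave.times, "value": wave.values,
                  "quantity": wave.quantity}).to_csv(path, index=False)


def read_waveform_csv(path: str | Path) -> FlowWaveform:
    df = pd.read_csv(path)
    for col in ("time_s", "value", "quantity"):
        if col not in df.columns:
            raise FormatError(f"waveform CSV missing column '{col}'")
    quantity = str(df["quantity"].iloc[0]) if len(df) else "mean_velocity_cm_s"
    return FlowWaveform(df["time_s"].to_numpy(), df["value"].to_numpy(), quantity)


def _nifti_export(vol4d: np.ndarray, grid: Grid2D, path: Path) -> None:
    import nibabel as nib  # optional dependency

    affine = np.diag([grid.pixel_size[1], grid.pixel_size[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol4d.astype(np.float32), affine), str(path))


def write_outputs(series: ImageSeries, velocity: VelocitySeries,
                  waveforms: Sequence[FlowWaveform], out_dir: str | Path,
                  nifti: bool = False) -> dict:
    """Write magnitude/velocity series plus waveform CSVs; return a manifest.

    The magnitude and velocity series go to HDF5 (optionally also NIfTI, with
    the frame index as 4th dimension); each waveform becomes a CSV with header
    ``time_s, value, quantity``. The manifest (also saved as
    ``manifest.json``) lists every file written.
    """
    if series.grid.shape != velocity.grid.shape:
        raise ValidationError("image and velocity series grids differ")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}}

    mag_path = out / "magnitude.h5"
    _write_series(mag_path, np.abs(series.data), series.frame_times,
                  series.grid, series.VENC, "magnitude")
    manifest["outputs"]["magnitude"] = mag_path.name

    vel_path = out / "velocity.h5"
    write_velocity_series(velocity, vel_path)
    manifest["outputs"]["velocity"] = vel_path.name

    if nifti:
        ny, nx = series.grid.shape
        mag4d = np.abs(series.data).reshape(ny, nx, series.n_frames)[:, :, None, :]
        vel4d = velocity.values.reshape(ny, nx, velocity.n_frames)[:, :, None, :]
        _nifti_export(np.transpose(mag4d, (1, 0, 2, 3)), series.grid,
                      out / "magnitude.nii.gz")
        _nifti_export(np.transpose(vel4d, (1, 0, 2, 3)), series.grid,
                      out / "velocity.nii.gz")
        manifest["outputs"]["magnitude_nifti"] = "magnitude.nii.gz"
        manifest["outputs"]["velocity_nifti"] = "velocity.nii.gz"

    manifest["outputs"]["waveforms"] = []
    for i, wave in enumerate(waveforms):
        name = f"waveform_{i}_{wave.quantity}.csv"
        write_waveform_csv(wave, out / name)
        manifest["outputs"]["waveforms"].append(name)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
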