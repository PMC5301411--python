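"""Low-rank subspace reconstruction with SENSE parallel imaging.

The dynamic image sequences of a phase-contrast acquisition are arranged as
Casorati matrices ``C_v`` (voxels x frames). Spatiotemporal correlation of
the flow series — and correlation *between* the flow-compensated and
flow-encoded series — is captured by a joint low-rank model: the
column-concatenated matrix ``C = [C_1, ..., C_Nv]`` satisfies
``rank(C) <= L`` and is factored explicitly as ``C = U V`` with
``U in C^{N x L}`` (spatial subspace) and ``V in C^{L x Nv*M}`` (temporal
subspace).

The reconstruction proceeds in two stages, which turns the otherwise
non-convex bilinear recovery into a convex one:

1. ``V`` is pre-estimated by PCA (an SVD) of the high-rate central-k-space
   *training* data, after temporal interpolation onto the reconstruction
   frame grid.
2. With ``V`` fixed, ``U`` solves the least-squares problem

   ``U = argmin sum_i || d_i - Omega[ F S_i (U V) ] ||_2^2``

   over the coils ``i``, where ``S_i`` are coil sensitivities (estimated
   from temporally averaged flow-compensated k-space), ``F`` the centred
   unitary 2-D Fourier transform and ``Omega`` the (k,t) sampling operator.
   The normal equations are solved by conjugate gradient from zero
   initialisation.

``mode='separate'`` instead constrains each ``C_v`` independently (its own
``U_v``, ``V_v``); the joint model shares one subspace pair across the
encodings and is the recommended default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from .fourier import fft2c, ifft2c
from .kt_data import (Grid2D, ImageSeries, KTSamples, SensitivityMaps,
                      SolverError, SpatialSubspace, TemporalSubspace,
                      ValidationError)
from .sampling import nominal_temporal_resolution

__all__ = [
    "TrainingMatrix",
    "ReconConfig",
    "interpolate_training",
    "estimate_temporal_subspace",
    "estimate_sensitivities",
    "solve_spatial_subspace",
    "compose",
    "reconstruct",
    "joint_casorati",
    "cg_solve",
    "make_operators",
]


@dataclass
class TrainingMatrix:
    """Interpolated training data: ``data[channel, v, frame]`` where a
    channel is one (coil, training-ky, readout-sample) triple, shared by
    all encodings (the ky schedule is identical across encodings)."""

    data: np.ndarray          # (n_channels, Nv, M) complex
    frame_times: np.ndarray   # (M,) ms
    Nv: int

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def as_matrix(self, mode: str) -> np.ndarray | list[np.ndarray]:
        """Joint: (n_channels, Nv*M) with columns ordered [C_1 | C_2 | ...];
        separate: list of per-encoding (n_channels, M) matrices."""
        n_ch = self.data.shape[0]
        if mode == "joint":
            return self.data.reshape(n_ch, self.Nv * self.n_frames)
        return [self.data[:, v, :] for v in range(self.Nv)]


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    ``L`` is the rank of the low-rank model (default 20 — balances
    representational power against measurement count and SNR); ``mode``
    selects the joint or per-encoding low-rank constraint; ``cg_tol`` /
    ``cg_maxiter`` control the conjugate-gradient solve of the normal
    equations; ``interp_kind`` is the temporal interpolation of the
    training data (linear or cubic)."""

    L: int = 20
    mode: str = "joint"
    cg_tol: float = 1e-6
    cg_maxiter: int = 100
    interp_kind: str = "linear"
    sens_rel_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValidationError("rank L must be >= 1")
        if self.cg_tol <= 0:
            raise ValidationError("CG tolerance must be positive")
        if self.mode not in ("joint", "separate"):
            raise ValidationError(f"unknown mode '{self.mode}'")


def frame_period_ms(kt: KTSamples) -> float:
    return nominal_temporal_resolution(kt.Nv, kt.TR_ms)


def assign_frames(t_ms: np.ndarray, period_ms: float) -> np.ndarray:
    """Reconstruction frame index whose ``2*Nv*TR`` window contains t."""
    return np.floor(np.asarray(t_ms) / period_ms).astype(np.int64)


def default_frame_times(kt: KTSamples) -> np.ndarray:
    """Centres of the complete reconstruction frames covered by ``kt``."""
    period = frame_period_ms(kt)
    n_frames = int(assign_frames(kt.t_ms.max(), period)) + 1
    return (np.arange(n_frames) + 0.5) * period


# ---------------------------------------------------------------------------
# Stage 1: temporal subspace from training data
# ---------------------------------------------------------------------------


def interpolate_training(kt: KTSamples, target_times_ms: np.ndarray,
                         kind: str = "linear") -> TrainingMatrix:
    """Interpolate every training channel onto the reconstruction frame grid.

    Each (encoding, training-ky) group carries all coils' readouts at the
    training time stamps; real and imaginary parts are interpolated
    independently (componentwise) over time, with edge clamping outside the
    sampled span. Raises :class:`ValidationError` naming any channel with
    fewer than two samples."""
    target = np.asarray(target_times_ms, dtype=np.float64)
    train = kt.training()
    if train.n_lines == 0:
        raise ValidationError("no training lines present")
    kys = np.unique(train.ky)
    nx, Nc, Nv = kt.grid.nx, kt.Nc, kt.Nv
    M = target.size
    data = np.empty((kys.size * Nc * nx, Nv, M), dtype=np.complex128)
    for v in range(1, Nv + 1):
        for a, ky in enumerate(kys):
            for c in range(Nc):
                sel = (train.v == v) & (train.ky == ky) & (train.coil == c)
                n = int(sel.sum())
                if n < 2:
                    raise ValidationError(
                        f"training channel (v={v}, ky={ky}, coil={c}) has "
                        f"{n} sample(s); need at least 2 for interpolation")
                t = train.t_ms[sel]
                y = train.data[sel]  # (n, nx), time-ordered by construction
                f = interp1d(t, y, kind=kind, axis=0, bounds_error=False,
                             fill_value=(y[0], y[-1]), assume_sorted=True)
                rows = slice((a * Nc + c) * nx, (a * Nc + c + 1) * nx)
                data[rows, v - 1, :] = f(target).T
    return TrainingMatrix(data=data, frame_times=target, Nv=Nv)


def estimate_temporal_subspace(train: TrainingMatrix, L: int,
                               mode: str = "joint") -> TemporalSubspace:
    """PCA estimate of the temporal subspace: the ``L`` leading right
    singular vectors (as rows) of the training matrix. Joint mode uses the
    column-concatenated matrix across encodings; separate mode returns one
    basis per encoding. If ``L`` exceeds the numerical rank, the trailing
    rows span an arbitrary orthonormal complement (a warning is issued)."""

    def _lead_rows(X: np.ndarray) -> np.ndarray:
        T = X.shape[1]
        if L > T:
            raise ValidationError(f"L={L} exceeds column count {T}")
        full = L > min(X.shape)
        _, s, Vh = np.linalg.svd(X, full_matrices=full)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        if L > rank:
            warnings.warn(f"requested L={L} exceeds training-matrix rank "
                          f"{rank}; trailing subspace rows are arbitrary",
                          stacklevel=3)
        return Vh[:L]

    if mode == "joint":
        basis = _lead_rows(train.as_matrix("joint"))
    elif mode == "separate":
        basis = np.stack([_lead_rows(X) for X in train.as_matrix("separate")])
    else:
        raise ValidationError(f"unknown mode '{mode}'")
    V = TemporalSubspace(basis=basis, mode=mode,
                         frame_times=train.frame_times, Nv=train.Nv)
    V.validate()
    return V


# ---------------------------------------------------------------------------
# Coil sensitivities from temporally averaged k-space
# ---------------------------------------------------------------------------


def estimate_sensitivities(kt: KTSamples, rel_threshold: float = 0.05
                           ) -> SensitivityMaps:
    """Coil sensitivities from temporally averaged flow-compensated k-space.

    All v=1 samples (training and imaging) are averaged per (coil, ky, kx)
    over time; unvisited ky rows are zero-filled. When the visited rows do
    not cover all of ky, a Hann window over the filled band apodises the
    truncation before the inverse FFT (fully covered data needs no window).
    Each coil image is divided by the root-sum-of-squares across coils;
    support is where the RSS exceeds ``rel_threshold`` times its maximum,
    and the maps are zeroed outside it."""
    ny, nx = kt.grid.shape
    sel = kt.v == 1
    if not np.any(sel):
        raise ValidationError("no flow-compensated (v=1) lines to average")
    acc = np.zeros((kt.Nc, ny, nx), dtype=np.complex128)
    cnt = np.zeros((kt.Nc, ny), dtype=np.int64)
    np.add.at(acc, (kt.coil[sel], kt.ky[sel]), kt.data[sel])
    np.add.at(cnt, (kt.coil[sel], kt.ky[sel]), 1)
    filled = cnt[0] > 0
    avg = np.zeros_like(acc)
    avg[:, filled, :] = acc[:, filled, :] / cnt[:, filled, None]

    if not filled.all():
        k0, k1 = np.flatnonzero(filled)[[0, -1]]
        span = k1 - k0 + 1
        window = np.zeros(ny)
        window[k0:k1 + 1] = np.hanning(span + 2)[1:-1]
        avg *= window[None, :, None]

    imgs = ifft2c(avg)
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    support = rss >= rel_threshold * rss.max()
    maps = np.zeros_like(imgs)
    maps[:, support] = imgs[:, support] / rss[support][None]
    sens = SensitivityMaps(maps, support, kt.grid)
    sens.validate()
    return sens


# ---------------------------------------------------------------------------
# Stage 2: spatial subspace by CG on the SENSE normal equations
# ---------------------------------------------------------------------------


def cg_solve(apply_normal, b: np.ndarray, tol: float, maxiter: int):
    """Conjugate gradient for the Hermitian system ``A^H A x = b``.

    Starts from zero; stops at relative residual <= ``tol`` or ``maxiter``,
    returning the iterate with the smallest residual seen. If the residual
    increases for 5 consecutive iterations it either raises ``SolverError``
    (carrying the residual history) when the residual has grown well beyond
    the best seen — genuine divergence — or stops early when it is merely
    stagnating at the attainable accuracy of an ill-conditioned system."""
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.real(np.vdot(r, r))
    r0 = np.sqrt(rs)
    history = [1.0]
    if r0 == 0:
        return x, history
    x_best, best = x.copy(), 1.0
    n_increase = 0
    for _ in range(maxiter):
        Ap = apply_normal(p)
        denom = np.real(np.vdot(p, Ap))
        if denom <= 0:
            break  # numerically rank-deficient direction; accept x
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ap
        rs_new = np.real(np.vdot(r, r))
        relres = np.sqrt(rs_new) / r0
        n_increase = n_increase + 1 if relres > history[-1] else 0
        history.append(float(relres))
        if relres < best:
            best = relres
            x_best = x.copy()
        if n_increase >= 5:
            if relres > 2.0 * best:
                raise SolverError(f"CG diverged: residual increased for 5 "
                                  f"consecutive iterations; history={history}")
            break  # stagnation at the attainable accuracy
        if relres <= tol:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x_best, history


def _build_column_system(kt: KTSamples, n_frames: int, encodings: list[int],
                         period: float):
    """Aggregate measured lines into per-column sampling weights and sums.

    Columns enumerate (encoding, frame) pairs in the order of ``encodings``.
    Returns integer weights ``W[col, ky]`` (sample multiplicity) and the
    coil-wise accumulated k-space sums ``Y[coil][col, ky, :]``."""
    ny, nx = kt.grid.shape
    n_cols = len(encodings) * n_frames
    frames = assign_frames(kt.t_ms, period)
    W = np.zeros((n_cols, ny), dtype=np.float64)
    Y = np.zeros((kt.Nc, n_cols, ny, nx), dtype=np.complex128)
    col_of_v = {v: j for j, v in enumerate(encodings)}
    keep = (frames < n_frames) & np.isin(kt.v, encodings)
    cols = np.array([col_of_v[v] for v in kt.v[keep]]) * n_frames + frames[keep]
    np.add.at(Y, (kt.coil[keep], cols, kt.ky[keep]), kt.data[keep])
    coil0 = kt.coil[keep] == 0
    np.add.at(W, (cols[coil0], kt.ky[keep][coil0]), 1.0)
    return W, Y


def make_operators(sens: SensitivityMaps, W: np.ndarray, Vb: np.ndarray):
    """Forward operator and adjoint of the subspace-constrained SENSE model.

    ``A`` maps the flattened spatial subspace ``U`` (N*L,) to the weighted
    sampled k-space ``sqrt(W) * F S_i (U Vb)`` flattened over
    (coil, column, ky, kx); ``AH`` is its exact adjoint under the standard
    inner products. ``W[col, ky]`` is the sampling multiplicity (0/1 for
    ordinary patterns); the square-root split makes ``AH(A(x))`` apply the
    multiplicity once, so weighted least squares is handled exactly."""
    ny, nx = sens.grid.shape
    N = ny * nx
    L, n_cols = Vb.shape
    S = sens.maps
    Nc = S.shape[0]
    sqrtW = np.sqrt(W)

    def A(uflat: np.ndarray) -> np.ndarray:
        U = uflat.reshape(N, L)
        imgs = (U @ Vb).T.reshape(n_cols, ny, nx)
        out = np.empty((Nc, n_cols, ny, nx), dtype=np.complex128)
        for i in range(Nc):
            out[i] = sqrtW[:, :, None] * fft2c(S[i][None] * imgs)
        return out.ravel()

    def AH(dflat: np.ndarray) -> np.ndarray:
        D = dflat.reshape(Nc, n_cols, ny, nx)
        B = np.zeros((n_cols, ny, nx), dtype=np.complex128)
        for i in range(Nc):
            B += np.conj(S[i])[None] * ifft2c(sqrtW[:, :, None] * D[i])
        return (B.reshape(n_cols, N).T @ Vb.conj().T).ravel()

    def normal(uflat: np.ndarray) -> np.ndarray:
        # Fused A^H A without materialising the (Nc, cols, ny, nx) k-space.
        U = uflat.reshape(N, L)
        imgs = (U @ Vb).T.reshape(n_cols, ny, nx)
        G = np.zeros_like(imgs)
        for i in range(Nc):
            ksp = fft2c(S[i][None] * imgs)
            ksp *= W[:, :, None]
            G += np.conj(S[i])[None] * ifft2c(ksp)
        return (G.reshape(n_cols, N).T @ Vb.conj().T).ravel()

    return A, AH, normal


def _solve_one(Vb: np.ndarray, W: np.ndarray, Y: np.ndarray,
               sens: SensitivityMaps, cfg: ReconConfig):
    """CG solve of ``U = argmin sum_i ||d_i - Omega F S_i U Vb||^2`` for one
    (joint or per-encoding) column system."""
    ny, nx = sens.grid.shape
    N = ny * nx
    L, n_cols = Vb.shape
    S = sens.maps
    _, _, apply_normal = make_operators(sens, W, Vb)

    # b = A^H d : adjoint of sampling (weighted zero-fill already in Y),
    # inverse FFT, conjugate-coil combine, project onto the temporal basis.
    B = np.zeros((n_cols, ny, nx), dtype=np.complex128)
    for i in range(S.shape[0]):
        B += np.conj(S[i])[None] * ifft2c(Y[i])
    b = (B.reshape(n_cols, N).T @ Vb.conj().T).ravel()

    uflat, history = cg_solve(apply_normal, b, cfg.cg_tol, cfg.cg_maxiter)
    return uflat.reshape(N, L), history


def solve_spatial_subspace(kt: KTSamples, sens: SensitivityMaps,
                           V: TemporalSubspace, cfg: ReconConfig,
                           return_info: bool = False):
    """Solve the convex least-squares problem for the spatial subspace U.

    Both training and imaging samples enter the data-consistency term (all
    are valid measurements). In joint mode one system couples all encodings
    through the shared temporal basis; in separate mode the problem
    decouples into one system per encoding."""
    period = frame_period_ms(kt)
    M = V.n_frames
    info: dict = {"mode": cfg.mode, "L": V.L, "cg": []}
    if cfg.mode == "joint":
        W, Y = _build_column_system(kt, M, list(range(1, kt.Nv + 1)), period)
        U, hist = _solve_one(V.basis, W, Y, sens, cfg)
        info["cg"].append({"iterations": len(hist) - 1,
                           "final_relres": hist[-1], "history": hist})
        sub = SpatialSubspace(U, "joint", kt.grid)
    else:
        Us = []
        for v in range(1, kt.Nv + 1):
            W, Y = _build_column_system(kt, M, [v], period)
            Uv, hist = _solve_one(V.block(v), W, Y, sens, cfg)
            info["cg"].append({"encoding": v, "iterations": len(hist) - 1,
                               "final_relres": hist[-1], "history": hist})
            Us.append(Uv)
        sub = SpatialSubspace(np.stack(Us), "separate", kt.grid)
    sub.validate(V)
    return (sub, info) if return_info else sub


def compose(U: SpatialSubspace, V: TemporalSubspace,
            VENC: float = 0.0) -> list[ImageSeries]:
    """Reconstruct ``C = U V`` and split columns back into the per-encoding
    image series (columns ``(v-1)*M .. v*M-1`` belong to encoding v)."""
    if U.mode != V.mode:
        raise ValidationError("spatial and temporal subspace modes differ")
    out = []
    for v in range(1, V.Nv + 1):
        data = U.block(v) @ V.block(v)
        out.append(ImageSeries(data, V.frame_times, U.grid, VENC))
    return out


def reconstruct(kt: KTSamples, cfg: ReconConfig | None = None,
                return_info: bool = False):
    """End-to-end reconstruction: interpolate training data, estimate the
    temporal subspace (PCA) and coil sensitivities, solve for the spatial
    subspace by CG, and compose the per-encoding image series."""
    cfg = cfg or ReconConfig()
    frame_times = default_frame_times(kt)
    train = interpolate_training(kt, frame_times, cfg.interp_kind)
    V = estimate_temporal_subspace(train, cfg.L, cfg.mode)
    sens = estimate_sensitivities(kt, cfg.sens_rel_threshold)
    U, info = solve_spatial_subspace(kt, sens, V, cfg, return_info=True)
    series = compose(U, V, kt.VENC)
    info.update({"n_frames": V.n_frames,
                 "frame_period_ms": frame_period_ms(kt)})
    return (series, info) if return_info else series


def joint_casorati(series: list[ImageSeries] | tuple) -> np.ndarray:
    """Column-concatenated Casorati matrix ``[C_1, ..., C_Nv]``."""
    return np.hstack([s.data for s in series])
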